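"""Population-sequence geometry across stimulation conditions.

The population response to a 5-pulse train is summarized as a
neurons x 30 matrix: each unit's activity after each pulse is averaged
over the five pulses and all trains, z-scored against the pre-train
baseline, and binned into exactly 30 bins.  In *relative* mode the bin
width scales with the ISI (10 ms for 300 ms, 16.6 ms for 500 ms) so
both conditions occupy the same 30-bin grid; in *absolute* mode the
bins are fixed 10 ms covering the first 300 ms regardless of ISI.

Conditions are compared through the 30 x 30 Euclidean distance matrix
between population column vectors and its diagonal asymmetry index:
the per-row offset between the distance minimum and the identity
diagonal, expressed in degrees (an offset of 30 bins = 360 degrees).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io import Session
from .perievent import peth, zscore_peth

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationSequence",
    "GeometryReport",
    "averaged_sequence",
    "sort_by_peak_time",
    "apply_sort",
    "distance_matrix",
    "asymmetry_index",
    "subsample_units",
    "N_BINS",
    "DEGREES_PER_BIN",
]

N_BINS = 30
DEGREES_PER_BIN = 360.0 / N_BINS


@dataclass
class PopulationSequence:
    """Neurons x 30 averaged z-scored activity for one condition."""

    matrix: np.ndarray
    mode: str
    isi_ms: int
    bin_width_s: float
    unit_ids: list[str]
    sort_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_BINS:
            raise ValueError(f"population sequence must have exactly {N_BINS} bins")
        if self.mode not in ("relative", "absolute"):
            raise ValueError("mode must be 'relative' or 'absolute'")
        if len(self.unit_ids) != self.matrix.shape[0]:
            raise ValueError("unit_ids length does not match matrix rows")


@dataclass
class GeometryReport:
    """Cross-condition geometry of two population sequences."""

    distance: np.ndarray
    mean_distance: float
    min_distance_vector: np.ndarray
    asymmetry_bins: np.ndarray
    asymmetry_degrees: np.ndarray
    mean_degrees: float
    mean_min_distance: float


def averaged_sequence(
    session: Session,
    isi_ms: int,
    mode: str = "relative",
    units: list[str] | None = None,
    baseline: tuple[float, float] = (-1.0, 0.0),
) -> PopulationSequence:
    """Average 30-bin sequence per unit for one ISI condition.

    Activity after each of the 5 pulses is pooled (all pulses of all
    trains are treated as repeats) and binned into 30 bins of ISI/30
    (relative) or 10 ms covering the first 300 ms (absolute).  Units
    with an undefined baseline z-score are excluded and logged.
    """
    if mode == "relative":
        span = isi_ms / 1000.0
    elif mode == "absolute":
        span = 0.300
    else:
        raise ValueError("mode must be 'relative' or 'absolute'")
    bin_w = span / N_BINS
    pulses = np.concatenate(session.stim_trains(isi_ms))
    if pulses.size == 0:
        raise ValueError(f"no stimulus pulses for ISI {isi_ms}")
    unit_ids = units if units is not None else session.unit_ids

    rows, kept = [], []
    # z-scale from the pre-train baseline at the same bin width; the
    # response itself is pooled over every pulse of every train
    onsets = session.train_onsets(isi_ms)
    n_base = max(1, int(round((baseline[1] - baseline[0]) / bin_w)))
    for uid in unit_ids:
        train = session.unit(uid)
        resp = peth(train, pulses, (0.0, span), bin_w).trial_average()
        base = peth(train, onsets, (baseline[0], baseline[0] + n_base * bin_w), bin_w)
        bavg = base.trial_average()
        mu, sd = float(bavg.mean()), float(bavg.std())
        if sd == 0.0:
            logger.info("unit %s excluded from sequence: zero baseline SD", uid)
            continue
        rows.append((resp - mu) / sd)
        kept.append(uid)
    if not rows:
        raise ValueError("no units with defined baseline z-score")
    return PopulationSequence(np.vstack(rows), mode, isi_ms, bin_w, kept)


def sort_by_peak_time(seq: PopulationSequence) -> np.ndarray:
    """Unit order by the time of the peak bin (first inter-stimulus window).

    Mirrors sorting units by their highest firing rate between the first
    and second stimuli of the reference condition.
    """
    peaks = np.argmax(seq.matrix, axis=1)
    return np.argsort(peaks, kind="stable")


def apply_sort(seq: PopulationSequence, order: np.ndarray) -> PopulationSequence:
    return PopulationSequence(
        seq.matrix[order], seq.mode, seq.isi_ms, seq.bin_width_s,
        [seq.unit_ids[i] for i in order], sort_order=np.asarray(order),
    )


def distance_matrix(a: PopulationSequence, b: PopulationSequence) -> np.ndarray:
    """30 x 30 Euclidean distances between population column vectors.

    Entry (i, j) is the distance between population vector (column) i of
    ``a`` and column j of ``b``; both sequences must hold the same units
    in the same order.
    """
    if a.unit_ids != b.unit_ids:
        raise ValueError("sequences must share the same unit set and order")
    return cdist(a.matrix.T, b.matrix.T, metric="euclidean")


def asymmetry_index(distance: np.ndarray) -> GeometryReport:
    """Diagonal asymmetry of a square cross-condition distance matrix.

    Per row i the offset is |argmin_j D[i, j] - i| with ties resolved to
    the smallest offset, then the lower column; degrees = offset x 12
    (30 bins = 360 degrees).  A self-comparison yields thirty zeros.
    """
    distance = np.asarray(distance, dtype=float)
    if distance.ndim != 2 or distance.shape[0] != distance.shape[1]:
        raise ValueError("distance matrix must be square")
    n = distance.shape[0]
    offsets = np.empty(n, dtype=int)
    minima = np.empty(n)
    for i in range(n):
        row = distance[i]
        m = row.min()
        cand = np.flatnonzero(row == m)
        j = min(cand, key=lambda c: (abs(int(c) - i), int(c)))
        offsets[i] = abs(int(j) - i)
        minima[i] = m
    degrees = offsets * DEGREES_PER_BIN
    return GeometryReport(
        distance=distance,
        mean_distance=float(distance.mean()),
        min_distance_vector=minima,
        asymmetry_bins=offsets,
        asymmetry_degrees=degrees,
        mean_degrees=float(degrees.mean()),
        mean_min_distance=float(minima.mean()),
    )


def subsample_units(
    seq: PopulationSequence, n: int, rng: np.random.Generator
) -> PopulationSequence:
    """Seeded subsample to equalize unit counts across cohorts.

    Distances scale with sqrt(n_units), so cross-cohort comparisons
    require equal counts.
    """
    if n > seq.matrix.shape[0]:
        raise ValueError("cannot subsample more units than available")
    idx = np.sort(rng.choice(seq.matrix.shape[0], size=n, replace=False))
    return apply_sort(seq, idx)
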