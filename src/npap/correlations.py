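"""Correlation analyses linking evoked, spontaneous and movement activity.

Pairs of simultaneously recorded units are compared through (i) the
Pearson correlation of their z-scored evoked traces during stimulation,
classified high/low against the 99.5th percentile of a circular-
surrogate null, (ii) the correlation of their smoothed spontaneous
rates (100 ms bins, Gaussian kernel of s.d. 200 ms), and (iii) the
center-of-mass lag of their movement-window cross-correlogram, which is
related to their difference in stimulation-evoked response latency.
Single units are linked across regimes through signed response
amplitudes (the z extremum around an alignment event, carrying its
sign) and through the correlation of their responses across stimulation
conditions against a surrogate null.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import norm, pearsonr

from .io import Session, SpikeTrain
from .perievent import binarize, peth, zscore_peth
from .surrogate import SurrogateSpec, circular_surrogate, nearest_rank_percentile

logger = logging.getLogger(__name__)

__all__ = [
    "PairCorrelation",
    "LagEstimate",
    "CrossConditionResult",
    "evoked_pair_correlation",
    "spontaneous_pair_correlation",
    "cross_condition_response_correlation",
    "signed_amplitude",
    "crosscorr_lag",
    "classify_pair",
]


@dataclass
class PairCorrelation:
    unit_a: str
    unit_b: str
    r_stimulation: float
    r_spontaneous: float | None = None
    high: bool | None = None  # vs the 99.5th surrogate percentile


@dataclass
class LagEstimate:
    unit_a: str
    unit_b: str
    lag_s: float
    latency_difference_ms: float | None = None


@dataclass
class CrossConditionResult:
    """Per-stimulus correlation between two conditions, with null."""

    r_per_stimulus: np.ndarray
    null_values: np.ndarray | None = None

    def percentile(self, q: float = 99.5) -> float:
        if self.null_values is None:
            raise ValueError("no surrogate null attached")
        return nearest_rank_percentile(self.null_values, q)


def _evoked_z(session: Session, unit_id: str, isi_ms: int, bin_width_s: float,
              train: SpikeTrain | None = None) -> np.ndarray:
    onsets = session.train_onsets(isi_ms)
    span = isi_ms / 1000.0 * 5
    st = train if train is not None else session.unit(unit_id)
    pm = peth(st, onsets, (-1.0, span), bin_width_s)
    z = zscore_peth(pm)
    if not z.valid:
        raise ValueError(f"unit {unit_id}: zero baseline SD")
    return z.values[z.bin_lefts >= -1e-12]


def evoked_pair_correlation(
    session: Session, unit_a: str, unit_b: str, isi_ms: int = 300,
    bin_width_s: float = 0.01,
) -> float:
    """Pearson r between two units' z-scored evoked traces."""
    za = _evoked_z(session, unit_a, isi_ms, bin_width_s)
    zb = _evoked_z(session, unit_b, isi_ms, bin_width_s)
    if za.std() == 0 or zb.std() == 0:
        raise ValueError("zero-variance evoked trace")
    return float(pearsonr(za, zb).statistic)


def classify_pair(
    r_observed: float, null_values: np.ndarray, q: float = 99.5
) -> bool:
    """High/low pair class: observed r above the q-th null percentile."""
    return bool(r_observed > nearest_rank_percentile(null_values, q))


def spontaneous_pair_correlation(
    train_a: SpikeTrain,
    train_b: SpikeTrain,
    segments: list[tuple[float, float]],
    bin_width_s: float = 0.1,
    smooth_sd_s: float = 0.2,
    min_total_s: float = 60.0,
) -> tuple[float, bool]:
    """Pearson r of smoothed spontaneous rates over task-free segments.

    Rates are binned at 100 ms and smoothed with a Gaussian kernel
    (s.d. 200 ms) within each segment; s.d. 0 reduces to the raw binned
    correlation.  Returns (r, warned) where ``warned`` flags a total
    segment length under ``min_total_s``.
    """
    if not segments:
        raise ValueError("at least one spontaneous segment is required")
    total = sum(t1 - t0 for t0, t1 in segments)
    warned = total < min_total_s
    if warned:
        warnings.warn(f"spontaneous segments total {total:.1f} s < {min_total_s} s",
                      stacklevel=2)
    xs, ys = [], []
    sigma_bins = smooth_sd_s / bin_width_s
    for t0, t1 in segments:
        n = int(np.floor((t1 - t0) / bin_width_s))
        if n < 1:
            continue
        ca = binarize(train_a, t0, t0 + n * bin_width_s, bin_width_s).astype(float)
        cb = binarize(train_b, t0, t0 + n * bin_width_s, bin_width_s).astype(float)
        if sigma_bins > 0:
            ca = gaussian_filter1d(ca, sigma_bins)
            cb = gaussian_filter1d(cb, sigma_bins)
        xs.append(ca)
        ys.append(cb)
    x, y = np.concatenate(xs), np.concatenate(ys)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance spontaneous rate")
    return float(pearsonr(x, y).statistic), warned


def _per_stimulus_traces(
    session: Session, unit_id: str, isi_ms: int, bin_width_s: float,
    train: SpikeTrain | None = None,
) -> np.ndarray:
    """5 x 30 z-trace, first 300 ms after each stimulus of the train."""
    z = _evoked_z(session, unit_id, isi_ms, bin_width_s, train=train)
    per_pulse = int(round(isi_ms / 1000.0 / bin_width_s))
    keep = int(round(0.300 / bin_width_s))
    return np.vstack([z[k * per_pulse : k * per_pulse + keep] for k in range(5)])


def cross_condition_response_correlation(
    session: Session,
    unit_id: str,
    isi_a: int = 300,
    isi_b: int = 500,
    bin_width_s: float = 0.01,
    n_surrogates: int = 0,
    surrogate_seed: int = 0,
) -> CrossConditionResult:
    """Per-stimulus r between a unit's responses under two ISI conditions.

    Responses are compared on the common grid of the first 300 ms after
    each stimulus.  When ``n_surrogates`` > 0, the condition-A spike
    train is circularly surrogated and the five correlations recomputed
    per repeat, yielding a per-unit null distribution.
    """
    ta = _per_stimulus_traces(session, unit_id, isi_a, bin_width_s)
    tb = _per_stimulus_traces(session, unit_id, isi_b, bin_width_s)
    r_obs = np.array([pearsonr(ta[k], tb[k]).statistic for k in range(5)])

    null = None
    if n_surrogates > 0:
        spec = SurrogateSpec(n_repeats=n_surrogates, seed=surrogate_seed)
        st = session.unit(unit_id)
        vals = []
        for rep in range(n_surrogates):
            rng = np.random.default_rng(
                np.random.SeedSequence((surrogate_seed, rep, zlib.crc32(unit_id.encode())))
            )
            surr = circular_surrogate(st, spec, rng=rng)
            tsur = _per_stimulus_traces(session, unit_id, isi_a, bin_width_s, train=surr)
            for k in range(5):
                if tsur[k].std() == 0:
                    continue
                vals.append(pearsonr(tsur[k], tb[k]).statistic)
        null = np.asarray(vals)
    return CrossConditionResult(r_per_stimulus=r_obs, null_values=null)


def signed_amplitude(
    z_values: np.ndarray,
    bin_lefts: np.ndarray,
    window: tuple[float, float] = (-0.2, 0.2),
) -> float:
    """Signed z extremum in a window around the alignment event.

    Positive amplitudes are activity increases, negative ones pauses;
    the value with the largest |z| wins.  A flat trace returns 0.
    """
    m = (bin_lefts >= window[0] - 1e-12) & (bin_lefts < window[1] - 1e-12)
    seg = np.asarray(z_values)[m]
    if seg.size == 0:
        raise ValueError("empty amplitude window")
    return float(seg[np.argmax(np.abs(seg))])


def crosscorr_lag(
    train_a: SpikeTrain,
    train_b: SpikeTrain,
    movement_onsets: np.ndarray,
    half_window_s: float = 2.0,
    bin_width_s: float = 0.01,
    subtract_baseline: bool = True,
) -> float:
    """Center-of-mass lag of the movement-window cross-correlogram.

    Spike-time differences t_b - t_a are pooled over +/- ``half_window_s``
    around each movement onset and histogrammed at 10 ms.  By default a
    shift-predictor correlogram (unit A's spikes around movement m paired
    with unit B's around movement m+1) is subtracted before the center
    of mass, removing chance coincidences and movement-locked common
    modulation; the center of mass is then taken over the bins of the
    corrected correlogram that rise significantly above zero (robust-SD
    threshold, Bonferroni-controlled across bins), so chance-level bins
    at large lags cannot dominate the estimate through their leverage.
    ``subtract_baseline=False`` uses the raw counts.  A positive lag
    means unit B follows unit A.
    """
    movement_onsets = np.asarray(movement_onsets, dtype=float)
    if movement_onsets.size == 0:
        raise ValueError("crosscorr_lag requires movement onsets")
    if movement_onsets.size < 20:
        logger.info("crosscorr_lag: only %d movement onsets (>=20 recommended)",
                    movement_onsets.size)
    rel_a, rel_b = [], []
    for m in movement_onsets:
        rel_a.append(train_a.times[(train_a.times >= m - half_window_s)
                                   & (train_a.times < m + half_window_s)] - m)
        rel_b.append(train_b.times[(train_b.times >= m - half_window_s)
                                   & (train_b.times < m + half_window_s)] - m)

    def _hist(pairs: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
        ds = []
        for a, b in pairs:
            if a.size and b.size:
                d = (b[None, :] - a[:, None]).ravel()
                ds.append(d[np.abs(d) <= half_window_s])
        if not ds:
            return np.zeros(n_bins)
        counts, _ = np.histogram(np.concatenate(ds), bins=n_bins,
                                 range=(-half_window_s, half_window_s))
        return counts.astype(float)

    n_bins = int(round(2 * half_window_s / bin_width_s))
    centers = -half_window_s + bin_width_s * (np.arange(n_bins) + 0.5)
    w = _hist(list(zip(rel_a, rel_b)))
    if w.sum() == 0:
        raise ValueError("no coincident spikes around movement onsets")
    if subtract_baseline:
        n_m = len(rel_a)
        shift = _hist([(rel_a[m], rel_b[(m + 1) % n_m]) for m in range(n_m)])
        resid = w - shift
        sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
        thresh = norm.isf(0.05 / n_bins) * sigma  # family-wise 5% across bins
        masked = np.where(resid > thresh, resid, 0.0) if sigma > 0 else np.clip(resid, 0, None)
        w = masked if masked.sum() > 0 else np.clip(resid, 0.0, None)
    if w.sum() == 0:
        raise ValueError("degenerate cross-correlogram (no mass above baseline)")
    return float(np.sum(centers * w) / np.sum(w))
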