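"""Session data model and plain-text readers/writers.

A *session* bundles everything recorded on one clock: sorted-unit spike
trains, labeled event times (optogenetic stimulus pulses grouped into
5-pulse trains, rewards, movement onsets), and an optional lever
displacement trace sampled at 250 Hz.  Synthetic sessions additionally
carry a ground-truth table mapping units to the pattern labels that were
planted by the generator.

The on-disk format is a directory of columnar text files (the normative
format; diffable and portable):

    manifest.yaml    animal id, lever metadata, file inventory
    units.csv        unit_id, t_start_s, t_stop_s
    spikes.csv       unit_id, time_s
    events.csv       kind, time_s, label
    lever.csv        displacement_mm          (only when a trace exists)
    ground_truth.yaml                         (synthetic sessions only)

All times are seconds on the session clock.  Bin conventions used
throughout the package: 0-based bin indices, half-open intervals
[left, right).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

EVENT_KINDS = ("stim_pulse", "train_onset", "reward", "movement_onset", "trial_start")

#: tolerance when comparing times across a write/read roundtrip (seconds)
TIME_TOL = 1e-9

#: allowed deviation of within-train pulse spacing from the labeled ISI,
#: one sample on the 1 ms analysis grid plus float slack
ISI_SPACING_TOL = 1.5e-3


class SessionError(ValueError):
    """A session object violates a structural invariant."""


class ParseError(SessionError):
    """A session file failed validation; carries file and row context."""

    def __init__(self, message: str, file: str | None = None, row: int | None = None):
        self.file = file
        self.row = row
        loc = ""
        if file is not None:
            loc = f" [{file}" + (f", row {row}" if row is not None else "") + "]"
        super().__init__(message + loc)


@dataclass
class SpikeTrain:
    """Ordered spike times of one unit over one session."""

    unit_id: str
    times: np.ndarray
    t_start: float
    t_stop: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.t_stop <= self.t_start:
            raise SessionError(
                f"unit {self.unit_id}: t_stop ({self.t_stop}) must exceed t_start ({self.t_start})"
            )
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise SessionError(f"unit {self.unit_id}: spike times not strictly increasing")
            if self.times[0] < self.t_start or self.times[-1] > self.t_stop:
                raise SessionError(f"unit {self.unit_id}: spike times outside [t_start, t_stop]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class EventSet:
    """Labeled event times of one kind.

    ``labels`` carries the per-event condition tag: the ISI in ms
    ("300"/"500") for stimulus events, or the required movement duration
    in ms ("200"/"500") for behavioral events.  Empty string when a kind
    has no natural label.
    """

    kind: str
    times: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise SessionError(f"unknown event kind {self.kind!r}")
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) < 0):
            raise SessionError(f"events of kind {self.kind!r} not sorted")
        if self.labels is None:
            self.labels = np.full(self.times.shape, "", dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != self.times.shape:
                raise SessionError(f"events of kind {self.kind!r}: labels/times length mismatch")

    def __len__(self) -> int:
        return int(self.times.size)

    def select(self, label: str) -> np.ndarray:
        """Times of events carrying the given label."""
        return self.times[self.labels == label]


@dataclass
class LeverTrace:
    """Lever displacement in mm, uniformly sampled (default 250 Hz)."""

    samples: np.ndarray
    rate: float = 250.0
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise SessionError("lever sampling rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.samples.size) / self.rate

    @property
    def t_stop(self) -> float:
        return self.t_start + self.samples.size / self.rate


@dataclass
class Session:
    """One recording session: spike trains + events + optional lever trace."""

    animal_id: str
    spike_trains: list[SpikeTrain] = field(default_factory=list)
    events: dict[str, EventSet] = field(default_factory=dict)
    lever: LeverTrace | None = None
    ground_truth: dict[str, dict] | None = None
    session_id: str = "session0"

    def __post_init__(self) -> None:
        ids = [st.unit_id for st in self.spike_trains]
        if len(set(ids)) != len(ids):
            raise SessionError("unit_ids are not unique")
        for kind, ev in self.events.items():
            if ev.kind != kind:
                raise SessionError(f"events dict key {kind!r} does not match EventSet.kind {ev.kind!r}")

    @property
    def unit_ids(self) -> list[str]:
        return [st.unit_id for st in self.spike_trains]

    def unit(self, unit_id: str) -> SpikeTrain:
        for st in self.spike_trains:
            if st.unit_id == unit_id:
                return st
        raise KeyError(unit_id)

    def stim_trains(self, isi_ms: int) -> list[np.ndarray]:
        """Group stimulus pulses of one ISI condition into 5-pulse trains.

        Returns one array of 5 pulse times per train, validated against
        the labeled inter-stimulus interval.
        """
        ev = self.events.get("stim_pulse")
        if ev is None:
            return []
        times = ev.select(str(isi_ms))
        if times.size == 0:
            return []
        if times.size % 5:
            raise SessionError(
                f"ISI {isi_ms}: {times.size} stim pulses do not group into 5-pulse trains"
            )
        trains = [times[i : i + 5] for i in range(0, times.size, 5)]
        isi_s = isi_ms / 1000.0
        for tr in trains:
            if np.any(np.abs(np.diff(tr) - isi_s) > ISI_SPACING_TOL):
                raise SessionError(
                    f"ISI {isi_ms}: within-train spacing deviates from labeled ISI at t={tr[0]:.3f}"
                )
        return trains

    def train_onsets(self, isi_ms: int) -> np.ndarray:
        """Onset (first-pulse) times of each 5-pulse stimulation train."""
        return np.array([tr[0] for tr in self.stim_trains(isi_ms)])


# ---------------------------------------------------------------------------
# readers / writers

_FLOAT_FMT = "%.9f"


def write_session(session: Session, path: str | Path) -> list[Path]:
    """Write a session as a directory of columnar text files.

    Output is deterministic: identical sessions produce identical bytes.
    Returns the list of files written.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    units = pd.DataFrame(
        {
            "unit_id": [st.unit_id for st in session.spike_trains],
            "t_start_s": [st.t_start for st in session.spike_trains],
            "t_stop_s": [st.t_stop for st in session.spike_trains],
        }
    )
    units.to_csv(path / "units.csv", index=False, float_format=_FLOAT_FMT)
    written.append(path / "units.csv")

    spikes = pd.DataFrame(
        {
            "unit_id": np.concatenate(
                [[st.unit_id] * st.n_spikes for st in session.spike_trains] or [[]]
            ),
            "time_s": np.concatenate([st.times for st in session.spike_trains] or [[]]),
        }
    )
    spikes.to_csv(path / "spikes.csv", index=False, float_format=_FLOAT_FMT)
    written.append(path / "spikes.csv")

    rows = []
    for kind in EVENT_KINDS:
        ev = session.events.get(kind)
        if ev is None:
            continue
        for t, lab in zip(ev.times, ev.labels):
            rows.append((kind, t, lab))
    events = pd.DataFrame(rows, columns=["kind", "time_s", "label"])
    events.to_csv(path / "events.csv", index=False, float_format=_FLOAT_FMT)
    written.append(path / "events.csv")

    manifest: dict = {
        "animal_id": session.animal_id,
        "session_id": session.session_id,
        "has_lever": session.lever is not None,
        "has_ground_truth": session.ground_truth is not None,
    }
    if session.lever is not None:
        pd.DataFrame({"displacement_mm": session.lever.samples}).to_csv(
            path / "lever.csv", index=False, float_format="%.6f"
        )
        written.append(path / "lever.csv")
        manifest["lever_rate_hz"] = float(session.lever.rate)
        manifest["lever_t_start_s"] = float(session.lever.t_start)
    if session.ground_truth is not None:
        with open(path / "ground_truth.yaml", "w") as fh:
            yaml.safe_dump(session.ground_truth, fh, sort_keys=True)
        written.append(path / "ground_truth.yaml")
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    written.append(path / "manifest.yaml")
    logger.info("wrote session %s to %s (%d files)", session.session_id, path, len(written))
    return written


def _require_columns(df: pd.DataFrame, cols: list[str], file: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", file=file)


def read_session(path: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`.

    Raises :class:`ParseError` (naming file and row) on missing columns,
    non-monotone spike times, or events referencing an unknown dialect.
    """
    path = Path(path)
    if not path.is_dir():
        raise ParseError(f"session directory {path} does not exist")
    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)

    units = pd.read_csv(path / "units.csv", dtype={"unit_id": str})
    _require_columns(units, ["unit_id", "t_start_s", "t_stop_s"], "units.csv")
    spikes = pd.read_csv(path / "spikes.csv", dtype={"unit_id": str})
    _require_columns(spikes, ["unit_id", "time_s"], "spikes.csv")

    trains: list[SpikeTrain] = []
    grouped = dict(iter(spikes.groupby("unit_id", sort=False))) if len(spikes) else {}
    for _, urow in units.iterrows():
        uid = urow["unit_id"]
        g = grouped.get(uid)
        times = g["time_s"].to_numpy() if g is not None else np.array([])
        if times.size and np.any(np.diff(times) <= 0):
            bad = int(np.argmax(np.diff(times) <= 0)) + 1
            row = int(g.index[bad]) + 2  # 1-based incl. header
            raise ParseError(f"unit {uid}: spike times not strictly increasing", "spikes.csv", row)
        try:
            trains.append(
                SpikeTrain(uid, times, float(urow["t_start_s"]), float(urow["t_stop_s"]))
            )
        except SessionError as exc:
            raise ParseError(str(exc), file="units.csv") from exc
    unknown = set(grouped) - set(units["unit_id"])
    if unknown:
        raise ParseError(f"spikes reference unknown units {sorted(unknown)}", file="spikes.csv")

    events_df = pd.read_csv(
        path / "events.csv", dtype={"kind": str, "label": str}, keep_default_na=False
    )
    _require_columns(events_df, ["kind", "time_s", "label"], "events.csv")
    events: dict[str, EventSet] = {}
    for kind, g in events_df.groupby("kind", sort=False):
        if kind not in EVENT_KINDS:
            raise ParseError(f"unknown event kind {kind!r}", file="events.csv")
        try:
            events[kind] = EventSet(kind, g["time_s"].to_numpy(), g["label"].to_numpy(object))
        except SessionError as exc:
            raise ParseError(str(exc), file="events.csv") from exc

    lever = None
    if manifest.get("has_lever"):
        lever_df = pd.read_csv(path / "lever.csv")
        _require_columns(lever_df, ["displacement_mm"], "lever.csv")
        lever = LeverTrace(
            lever_df["displacement_mm"].to_numpy(),
            rate=float(manifest["lever_rate_hz"]),
            t_start=float(manifest["lever_t_start_s"]),
        )

    ground_truth = None
    if manifest.get("has_ground_truth"):
        with open(path / "ground_truth.yaml") as fh:
            ground_truth = yaml.safe_load(fh)

    session = Session(
        animal_id=str(manifest["animal_id"]),
        spike_trains=trains,
        events=events,
        lever=lever,
        ground_truth=ground_truth,
        session_id=str(manifest.get("session_id", path.name)),
    )
    # cross-file invariants: pulse grouping per labeled ISI
    ev = session.events.get("stim_pulse")
    if ev is not None:
        for isi in sorted({str(l) for l in ev.labels}):
            try:
                session.stim_trains(int(isi))
            except SessionError as exc:
                raise ParseError(str(exc), file="events.csv") from exc
    logger.info(
        "read session %s: %d units, %d event kinds", session.session_id, len(trains), len(events)
    )
    return session


def validate_session_dir(path: str | Path) -> list[str]:
    """Validate a session directory; returns a list of problems (empty = ok)."""
    try:
        read_session(path)
    except (ParseError, SessionError, FileNotFoundError, KeyError) as exc:
        return [str(exc)]
    return []


def sessions_equal(a: Session, b: Session, time_tol: float = TIME_TOL) -> bool:
    """Field-by-field equality up to ``time_tol`` on times."""
    if a.animal_id != b.animal_id or a.unit_ids != b.unit_ids:
        return False
    for sa, sb in zip(a.spike_trains, b.spike_trains):
        if sa.n_spikes != sb.n_spikes:
            return False
        if sa.n_spikes and np.max(np.abs(sa.times - sb.times)) > time_tol:
            return False
        if abs(sa.t_start - sb.t_start) > time_tol or abs(sa.t_stop - sb.t_stop) > time_tol:
            return False
    if set(a.events) != set(b.events):
        return False
    for kind in a.events:
        ea, eb = a.events[kind], b.events[kind]
        if len(ea) != len(eb) or list(ea.labels) != list(eb.labels):
            return False
        if len(ea) and np.max(np.abs(ea.times - eb.times)) > time_tol:
            return False
    if (a.lever is None) != (b.lever is None):
        return False
    if a.lever is not None:
        if a.lever.rate != b.lever.rate or a.lever.samples.size != b.lever.samples.size:
            return False
        if np.max(np.abs(a.lever.samples - b.lever.samples)) > 1e-6:
            return False
    return True
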