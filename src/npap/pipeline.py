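"""End-to-end pipeline runner with config, seed fan-out and a report.

Composes the analysis graph over one or more sessions: stability
filtering, per-unit latencies and component amplitudes, pattern
classification per ISI and across ISIs, population geometry, and (when
a lever trace is present) behavioral segmentation and movement
parameters.  Output is a machine-readable summary plus per-stage tables;
identical config + seed yields identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, patterns, perievent, popgeom
from .io import Session

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""

    def __init__(self, stage: str, context: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed on {context}: {cause}")


@dataclass
class PipelineConfig:
    """Stage toggles and parameters; defaults follow the recorded protocol."""

    stages: tuple[str, ...] = ("stability", "latency", "amplitudes", "classify", "popgeom",
                               "behavior")
    isis_ms: tuple[int, ...] = (300, 500)
    bin_width_s: float = 0.01
    latency_bin_s: float = 0.001
    baseline_s: float = 1.0
    stability_window_s: float = 5.0
    stability_max_silent_frac: float = 0.4
    stability_min_rate_hz: float = 0.1
    k_range: tuple[int, int] = (2, 10)
    n_runs: int = 1000
    n_pcs: int = 3
    min_units_prevalence: int = 8
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        for key in ("stages", "isis_ms", "k_range"):
            if key in known and isinstance(known[key], list):
                known[key] = tuple(known[key])
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        # named substream per stage from the master seed
        h = int(hashlib.sha256(stage.encode()).hexdigest()[:8], 16)
        return int(np.random.SeedSequence((self.seed, h)).generate_state(1)[0] % (2**31 - 1))


def _stable_units(session: Session, config: PipelineConfig, isi: int) -> list[str]:
    onsets = session.train_onsets(isi)
    keep = []
    for uid in session.unit_ids:
        res = perievent.stability_filter(
            session.unit(uid), onsets,
            window_s=config.stability_window_s,
            max_silent_frac=config.stability_max_silent_frac,
            min_rate_hz=config.stability_min_rate_hz,
        )
        if res.keep:
            keep.append(uid)
    logger.info("session %s ISI %d: %d/%d units pass stability",
                session.session_id, isi, len(keep), len(session.unit_ids))
    return keep


def run_pipeline(
    sessions: list[Session],
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the configured stages over the sessions; return a report dict.

    With all stages off the report is empty (exit success).  A stage
    failure raises :class:`StageError` naming the stage and session.
    """
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "sessions": [s.session_id for s in sessions],
        "stages": {},
    }
    if not sessions:
        raise ValueError("run_pipeline requires at least one session")

    stable: dict[tuple[str, int], list[str]] = {}
    if "stability" in config.stages:
        st = {}
        for s in sessions:
            for isi in config.isis_ms:
                if s.train_onsets(isi).size == 0:
                    continue
                try:
                    stable[(s.session_id, isi)] = _stable_units(s, config, isi)
                except Exception as exc:
                    raise StageError("stability", f"session {s.session_id}", exc) from exc
                st[f"{s.session_id}/{isi}"] = {
                    "n_in": len(s.unit_ids),
                    "n_out": len(stable[(s.session_id, isi)]),
                }
        report["stages"]["stability"] = st

    def units_for(s: Session, isi: int) -> list[str]:
        return stable.get((s.session_id, isi), s.unit_ids)

    if "latency" in config.stages:
        rows = []
        for s in sessions:
            for isi in config.isis_ms:
                onsets = s.train_onsets(isi)
                if onsets.size == 0:
                    continue
                for uid in units_for(s, isi):
                    try:
                        pm = perievent.peth(s.unit(uid), onsets, (-1.0, 4.0), config.latency_bin_s)
                        res = perievent.response_latency(pm, baseline_s=config.baseline_s)
                    except Exception as exc:
                        raise StageError("latency", f"{s.session_id}/{uid}", exc) from exc
                    rows.append({"session": s.session_id, "unit": uid, "isi_ms": isi,
                                 "increase_ms": res.increase_latency_ms,
                                 "decrease_ms": res.decrease_latency_ms})
        report["stages"]["latency"] = rows

    if "amplitudes" in config.stages:
        rows = []
        for s in sessions:
            for isi in config.isis_ms:
                onsets = s.train_onsets(isi)
                if onsets.size == 0:
                    continue
                offsets = isi / 1000.0 * np.arange(5)
                for uid in units_for(s, isi):
                    try:
                        pm = perievent.peth(s.unit(uid), onsets, (-1.0, isi / 1000.0 * 5),
                                            config.latency_bin_s)
                        z = perievent.zscore_peth(pm)
                        if not z.valid:
                            continue
                        amp = perievent.component_amplitudes(z, offsets)
                    except Exception as exc:
                        raise StageError("amplitudes", f"{s.session_id}/{uid}", exc) from exc
                    rows.append({"session": s.session_id, "unit": uid, "isi_ms": isi,
                                 "short": amp.short.tolist(),
                                 "decremental": amp.decremental.tolist(),
                                 "long": amp.long.tolist()})
        report["stages"]["amplitudes"] = rows

    assignments: dict[int, patterns.PatternAssignment] = {}
    if "classify" in config.stages:
        out = {}
        for isi in config.isis_ms:
            feats, sess_map = [], {}
            for s in sessions:
                if s.train_onsets(isi).size == 0:
                    continue
                try:
                    fm = patterns.evoked_feature_matrix(
                        s, isi, bin_width_s=config.bin_width_s, units=units_for(s, isi)
                    )
                except Exception as exc:
                    raise StageError("classify", f"session {s.session_id}", exc) from exc
                prefixed = [f"{s.session_id}:{u}" for u in fm.unit_ids]
                feats.append(patterns.FeatureMatrix(fm.values, prefixed, fm.bin_width_s, isi))
                sess_map.update({p: s.session_id for p in prefixed})
            if not feats:
                continue
            pooled = patterns.FeatureMatrix(
                np.vstack([f.values for f in feats]),
                sum((f.unit_ids for f in feats), []),
                config.bin_width_s, isi,
            )
            try:
                asg = patterns.classify_patterns(
                    pooled, k_range=range(config.k_range[0], config.k_range[1] + 1),
                    n_runs=config.n_runs, n_pcs=config.n_pcs,
                    seed=config.stage_seed(f"classify-{isi}"),
                )
            except Exception as exc:
                raise StageError("classify", f"ISI {isi}", exc) from exc
            assignments[isi] = asg
            percent, animals = patterns.pattern_prevalence(
                asg, sess_map, min_units=config.min_units_prevalence
            )
            out[str(isi)] = {
                "chosen_k": asg.chosen_k,
                "silhouette": asg.silhouette,
                "labels": asg.labels,
                "prevalence_percent": percent.to_dict(),
                "animal_counts": animals.to_dict(),
            }
        report["stages"]["classify"] = out

    if "popgeom" in config.stages and len(config.isis_ms) >= 2:
        isi_a, isi_b = config.isis_ms[0], config.isis_ms[1]
        out = {}
        for s in sessions:
            if s.train_onsets(isi_a).size == 0 or s.train_onsets(isi_b).size == 0:
                continue
            common = sorted(set(units_for(s, isi_a)) & set(units_for(s, isi_b)))
            if not common:
                continue
            try:
                geo = {}
                for mode in ("relative", "absolute"):
                    sa = popgeom.averaged_sequence(s, isi_a, mode, units=common)
                    sb = popgeom.averaged_sequence(s, isi_b, mode, units=sa.unit_ids)
                    sa2 = popgeom.averaged_sequence(s, isi_a, mode, units=sb.unit_ids)
                    order = popgeom.sort_by_peak_time(sa2)
                    rep = popgeom.asymmetry_index(popgeom.distance_matrix(
                        popgeom.apply_sort(sa2, order), popgeom.apply_sort(sb, order)))
                    geo[mode] = {"mean_distance": rep.mean_distance,
                                 "mean_degrees": rep.mean_degrees,
                                 "mean_min_distance": rep.mean_min_distance}
            except Exception as exc:
                raise StageError("popgeom", f"session {s.session_id}", exc) from exc
            out[s.session_id] = geo
        report["stages"]["popgeom"] = out

    if "behavior" in config.stages:
        out = {}
        for s in sessions:
            if s.lever is None or "reward" not in s.events:
                continue
            try:
                trials = behavior.segment_trials(s.lever, s.events)
                by_label: dict[int, list] = {}
                for t in trials:
                    by_label.setdefault(t.block_label, []).append(t)
                out[s.session_id] = {
                    str(lab): asdict(behavior.movement_metrics(ts, s.lever))
                    for lab, ts in sorted(by_label.items()) if any(t.valid for t in ts)
                }
            except Exception as exc:
                raise StageError("behavior", f"session {s.session_id}", exc) from exc
        report["stages"]["behavior"] = out

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
        if "latency" in report["stages"]:
            pd.DataFrame(report["stages"]["latency"]).to_csv(out_dir / "latency.csv", index=False)
        logger.info("pipeline report written to %s", out_dir)
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
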