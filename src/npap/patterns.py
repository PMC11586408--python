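"""PCA/silhouette pattern classification and GLM validation.

Evoked (or behavioral) response traces are projected onto their first
three principal components; k-means partitions the projection for every
candidate cluster number, each (k, restart) is scored with the mean
silhouette, and the best-scoring projection determines both the number
of pattern clusters and the assignment.  Cluster ids follow a stable
convention: Type 1 is the cluster with the smallest response energy
(the non-responsive pattern), the remaining clusters are ordered by
their template's short-latency amplitude, descending.

A generalized linear model cross-validates the clustering: each unit's
binned rate is regressed on the five cluster templates plus one random
trajectory, and the unit is assigned to the predictor with the highest
standardized coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.ndimage import gaussian_filter1d
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .io import Session
from .perievent import peth, zscore_peth

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "PatternAssignment",
    "GlmAssignment",
    "evoked_feature_matrix",
    "classify_patterns",
    "pattern_prevalence",
    "match_clusters",
    "glm_pattern_assignment",
    "DegenerateFeaturesError",
]


class DegenerateFeaturesError(ValueError):
    """The feature matrix cannot support the requested projection."""


@dataclass
class FeatureMatrix:
    """Units x bins z-scored response matrix."""

    values: np.ndarray
    unit_ids: list[str]
    bin_width_s: float
    isi_ms: int
    cross_isi: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.unit_ids):
            raise ValueError("unit_ids length does not match rows")


@dataclass
class PatternAssignment:
    """Chosen clustering of response patterns."""

    labels: dict[str, int]
    chosen_k: int
    silhouette: float
    templates: np.ndarray  # k x bins mean z-trace per cluster, row i = cluster i+1
    pc_loadings: np.ndarray  # 3 x bins
    silhouette_by_k: dict[int, float]
    unit_ids: list[str]

    def label_array(self) -> np.ndarray:
        return np.array([self.labels[u] for u in self.unit_ids])


@dataclass
class GlmAssignment:
    """Best GLM trajectory predictor per unit (6 = random trajectory)."""

    best: dict[str, int]
    coefficients: pd.DataFrame  # index unit_id, columns pred1..pred6
    flagged: list[str]


def evoked_feature_matrix(
    session: Session,
    isi_ms: int,
    bin_width_s: float = 0.01,
    cross_isi: bool = False,
    units: list[str] | None = None,
    baseline: tuple[float, float] = (-1.0, 0.0),
) -> FeatureMatrix:
    """Per-unit z-scored evoked trace aligned to train onset.

    The window covers the whole 5-pulse train (1.5 s for the 300 ms ISI,
    2.5 s for 500 ms).  In ``cross_isi`` mode only the first 300 ms
    after each pulse is kept so both conditions produce the same column
    count.  Units with undefined baseline z are dropped (logged).
    """
    onsets = session.train_onsets(isi_ms)
    if onsets.size == 0:
        raise ValueError(f"no trains for ISI {isi_ms}")
    span = isi_ms / 1000.0 * 5
    unit_ids = units if units is not None else session.unit_ids
    if not unit_ids:
        raise ValueError("empty unit set")

    rows, kept = [], []
    for uid in unit_ids:
        pm = peth(session.unit(uid), onsets, (baseline[0], span), bin_width_s)
        z = zscore_peth(pm, baseline)
        if not z.valid:
            logger.info("unit %s dropped from features: zero baseline SD", uid)
            continue
        resp = z.values[z.bin_lefts >= -1e-12]
        if cross_isi:
            per_pulse = int(round(isi_ms / 1000.0 / bin_width_s))
            keep_bins = int(round(0.300 / bin_width_s))
            resp = np.concatenate(
                [resp[k * per_pulse : k * per_pulse + keep_bins] for k in range(5)]
            )
        rows.append(resp)
        kept.append(uid)
    if not rows:
        raise ValueError("no units with defined features")
    return FeatureMatrix(np.vstack(rows), kept, bin_width_s, isi_ms, cross_isi=cross_isi)


def _relabel(labels: np.ndarray, features: np.ndarray, k: int,
             short_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Stable cluster naming: 1 = least energy, rest by short-latency z desc."""
    templates = np.vstack([features[labels == c].mean(axis=0) for c in range(k)])
    energy = (templates ** 2).mean(axis=1)
    type1 = int(np.argmin(energy))
    others = [c for c in range(k) if c != type1]
    short_amp = templates[:, :short_bins].max(axis=1)
    others.sort(key=lambda c: -short_amp[c])
    mapping = {type1: 1}
    for rank, c in enumerate(others, start=2):
        mapping[c] = rank
    new_labels = np.array([mapping[c] for c in labels])
    ordered = np.vstack([templates[c] for c, lab in sorted(mapping.items(), key=lambda kv: kv[1])])
    return new_labels, ordered


def classify_patterns(
    features: FeatureMatrix,
    k_range: range = range(2, 11),
    n_runs: int = 1000,
    n_pcs: int = 3,
    seed: int = 0,
    short_latency_s: float = 0.030,
) -> PatternAssignment:
    """Silhouette-selected k-means clustering in 3-PC space.

    For each k in ``k_range``, ``n_runs`` k-means++ initializations are
    scored by the mean silhouette in the PCA projection; the single best
    (k, partition) wins, ties resolved toward the smaller k.
    Deterministic given ``seed``.
    """
    X = features.values
    n = X.shape[0]
    if n < max(k_range) + 1:
        raise DegenerateFeaturesError(
            f"{n} units cannot support clustering up to k={max(k_range)}"
        )
    # row standardization: cluster on response *shape*, not amplitude
    sd = X.std(axis=1, keepdims=True)
    Xn = np.where(sd > 0, (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0), 0.0)
    if np.linalg.matrix_rank(Xn - Xn.mean(axis=0)) < n_pcs:
        raise DegenerateFeaturesError(
            f"feature matrix rank < {n_pcs}: PCA projection is degenerate"
        )
    pca = PCA(n_components=n_pcs)
    scores = pca.fit_transform(Xn)

    rng = np.random.default_rng(seed)
    best = None  # (silhouette, k, labels)
    sil_by_k: dict[int, float] = {}
    for k in k_range:
        best_k = None
        for _ in range(n_runs):
            km = KMeans(n_clusters=k, n_init=1, init="k-means++",
                        random_state=int(rng.integers(2**31 - 1)))
            lab = km.fit_predict(scores)
            if len(np.unique(lab)) < 2:
                continue
            s = float(silhouette_score(scores, lab))
            if best_k is None or s > best_k[0]:
                best_k = (s, lab)
        sil_by_k[k] = best_k[0] if best_k else float("nan")
        if best_k and (best is None or best_k[0] > best[0]):
            best = (best_k[0], k, best_k[1])
    if best is None:
        raise DegenerateFeaturesError("no valid clustering found")
    sil, k, raw_labels = best
    short_bins = max(1, int(round(short_latency_s / features.bin_width_s)))
    labels, templates = _relabel(raw_labels, X, k, short_bins)
    logger.info("classify_patterns: chose k=%d with silhouette %.3f over k=%s",
                k, sil, list(k_range))
    return PatternAssignment(
        labels=dict(zip(features.unit_ids, (int(l) for l in labels))),
        chosen_k=k,
        silhouette=sil,
        templates=templates,
        pc_loadings=pca.components_,
        silhouette_by_k=sil_by_k,
        unit_ids=list(features.unit_ids),
    )


def pattern_prevalence(
    assignment: PatternAssignment,
    unit_session: dict[str, str],
    session_animal: dict[str, str] | None = None,
    min_units: int = 8,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-session pattern percentages and per-pattern animal counts.

    Percentage rows are restricted to sessions with at least
    ``min_units`` simultaneously recorded units; each retained row sums
    to 100.  Animal presence counts use all sessions.
    """
    labels = pd.Series(assignment.labels, name="label")
    sessions = pd.Series({u: unit_session[u] for u in assignment.unit_ids}, name="session")
    df = pd.concat([labels, sessions], axis=1)
    all_labels = sorted(set(assignment.labels.values()))

    counts = df.groupby("session")["label"].value_counts().unstack(fill_value=0)
    counts = counts.reindex(columns=all_labels, fill_value=0)
    eligible = counts.sum(axis=1) >= min_units
    percent = counts.loc[eligible].div(counts.loc[eligible].sum(axis=1), axis=0) * 100.0

    if session_animal is None:
        session_animal = {s: s for s in counts.index}
    animal = counts.groupby(counts.index.map(session_animal.get)).sum()
    animal_counts = (animal > 0).sum(axis=0)
    animal_counts.name = "n_animals"
    return percent, animal_counts


@dataclass
class MatchResult:
    mapping: dict[int, int]
    correlations: dict[int, float]
    unmatched_a: list[int]
    unmatched_b: list[int]


def match_clusters(a: PatternAssignment, b: PatternAssignment) -> MatchResult:
    """Greedy max-correlation matching between two sets of templates."""
    if a.templates.shape[1] != b.templates.shape[1]:
        raise ValueError("template bin counts are incompatible")
    ka, kb = a.templates.shape[0], b.templates.shape[0]
    corr = np.empty((ka, kb))
    for i in range(ka):
        for j in range(kb):
            corr[i, j] = np.corrcoef(a.templates[i], b.templates[j])[0, 1]
    mapping: dict[int, int] = {}
    correlations: dict[int, float] = {}
    free_a, free_b = set(range(ka)), set(range(kb))
    while free_a and free_b:
        i, j = max(((i, j) for i in free_a for j in free_b), key=lambda ij: corr[ij])
        mapping[i + 1] = j + 1
        correlations[i + 1] = float(corr[i, j])
        free_a.discard(i)
        free_b.discard(j)
    return MatchResult(mapping, correlations,
                       sorted(i + 1 for i in free_a), sorted(j + 1 for j in free_b))


def random_trajectory(n_bins: int, rng: np.random.Generator, smooth_bins: float = 2.0) -> np.ndarray:
    """White noise smoothed to template bandwidth; the GLM's null predictor."""
    return gaussian_filter1d(rng.normal(size=n_bins), smooth_bins)


def glm_pattern_assignment(
    rates: dict[str, np.ndarray],
    templates: np.ndarray,
    seed: int = 0,
) -> GlmAssignment:
    """Best trajectory predictor per unit from a Gaussian GLM.

    ``rates`` maps each unit to its 10 ms-binned rate with trials
    accumulated one after the other; ``templates`` (5 x bins-per-trial)
    are tiled to the same length.  The design holds the five cluster
    templates plus one random trajectory, all standardized; the unit's
    label is the argmax coefficient (6 = the random trajectory).
    Constant-rate units are flagged and skipped.
    """
    templates = np.asarray(templates, dtype=float)
    if templates.shape[0] != 5:
        raise ValueError("exactly five pattern templates are required")
    rng = np.random.default_rng(seed)

    best: dict[str, int] = {}
    rows, flagged = {}, []
    rand_per_trial = random_trajectory(templates.shape[1], rng)
    for uid, y in rates.items():
        y = np.asarray(y, dtype=float)
        n_rep, rem = divmod(y.size, templates.shape[1])
        if rem:
            raise ValueError(f"unit {uid}: rate length is not a multiple of the template length")
        if y.std() == 0:
            flagged.append(uid)
            continue
        X = np.vstack([np.tile(t, n_rep) for t in templates] + [np.tile(rand_per_trial, n_rep)]).T
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        yz = (y - y.mean()) / y.std()
        fit = sm.OLS(yz, sm.add_constant(X)).fit()
        coefs = fit.params[1:]  # drop intercept
        best[uid] = int(np.argmax(coefs)) + 1
        rows[uid] = coefs
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=[f"pred{i}" for i in range(1, 7)])
    return GlmAssignment(best=best, coefficients=table, flagged=flagged)
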