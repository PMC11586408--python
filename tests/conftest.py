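import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import npap

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stim_session() -> npap.Session:
    """Small two-condition stimulation session with planted patterns."""
    cfg = npap.GenConfig(n_neurons=40, n_trains_300=30, n_trains_500=30, seed=11)
    return npap.generate_session(cfg)


@pytest.fixture(scope="session")
def behavioral_session() -> npap.Session:
    cfg = npap.GenConfig(n_neurons=12, n_blocks=4, seed=11)
    return npap.generate_behavioral_session(cfg)


@pytest.fixture(scope="session")
def classified_cohort():
    """Default-condition cohort with its silhouette-selected clustering."""
    cfg = npap.GenConfig(n_neurons=200, n_trains_300=50, n_trains_500=0, seed=3)
    session = npap.generate_session(cfg)
    features = npap.evoked_feature_matrix(session, 300)
    assignment = npap.classify_patterns(features, n_runs=100, seed=7)
    return session, features, assignment


def matched_accuracy(assignment: "npap.PatternAssignment", truth: dict[str, int],
                     nonflat_only: bool = True) -> float:
    """Label accuracy after optimal cluster-to-truth permutation matching."""
    from scipy.optimize import linear_sum_assignment

    units = assignment.unit_ids
    labs = np.array([assignment.labels[u] for u in units])
    true = np.array([truth[u] for u in units])
    n = max(labs.max(), true.max())
    cost = np.zeros((n, n))
    for a, b in zip(labs, true):
        cost[a - 1, b - 1] += 1
    rows, cols = linear_sum_assignment(-cost)
    mapping = {r + 1: c + 1 for r, c in zip(rows, cols)}
    mapped = np.array([mapping.get(l, -1) for l in labs])
    mask = true != 1 if nonflat_only else np.ones_like(true, bool)
    return float(np.mean(mapped[mask] == true[mask]))
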