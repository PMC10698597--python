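import numpy as np
import pytest

from embaudit import SyntheticConfig, generate_cohort, generate_embeddings


@pytest.fixture(scope="session")
def small_config():
    """Small but fully featured synthetic cohort configuration."""
    return SyntheticConfig(n_patients=600, embed_dim=16, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_embeddings(small_config, small_cohort):
    return generate_embeddings(small_cohort, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def ks_brute_force(a, b):
    """O(n^2) supremum of |F_a - F_b| over all pooled sample points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    fa = (a[:, None] <= pooled[None, :]).mean(axis=0)
    fb = (b[:, None] <= pooled[None, :]).mean(axis=0)
    return float(np.max(np.abs(fa - fb)))


def auc_brute_force(y, scores):
    """Mann–Whitney pairwise-comparison AUC with ties counted 1/2."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins / (pos.size * neg.size))


def by_hand_formula(p):
    """BY adjustment straight from the displayed step-down formula."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    c = sum(1.0 / k for k in range(1, m + 1))
    out = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        out[order[i]] = min(
            1.0, min(sorted_p[j] * m * c / (j + 1) for j in range(i, m))
        )
    return out
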