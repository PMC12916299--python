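import numpy as np
import pytest

import ctenrich as ce


@pytest.fixture(scope="session")
def mesh3():
    """642-vertex icosphere shared across tests."""
    return ce.build_icosphere(3)


@pytest.fixture(scope="session")
def atlas16(mesh3):
    return ce.generate_feature_atlas(mesh3, seed=101)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort with clinical outcomes (seed fixed)."""
    return ce.generate_full_cohort(seed=42)


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    return ce.fit_vertexwise_glm(default_cohort)


def brute_force_bh(p):
    """Independent step-up implementation of Benjamini-Hochberg."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def brute_force_ranks(x):
    """Average ranks with ties, computed by explicit enumeration."""
    x = np.asarray(x, float)
    r = np.empty(len(x))
    for i, xi in enumerate(x):
        less = np.sum(x < xi)
        eq = np.sum(x == xi)
        r[i] = less + (eq + 1) / 2.0
    return r
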