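import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import storysync as ss

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def tiny_dataset():
    """5 subjects x 14 regions x 2 stories with every effect planted."""
    params = ss.SynthParams(
        n_subjects=5,
        n_regions=14,
        voxels_per_region=4,
        n_stories=2,
        segments_per_condition=2,
        seed=11,
    )
    return ss.simulate_dataset(params, include_voxels=True)


@pytest.fixture(scope="session")
def schedule_one_story():
    return ss.make_schedule(4, 30.0, version=1, seed=7, story=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_loo_spearman(vectors):
    """Independent oracle: explicit ranks + explicit Pearson on ranks
    against the explicit mean of the other subjects' raw vectors."""
    X = np.asarray(vectors, dtype=float)
    n = X.shape[0]
    out = np.empty(n)
    for i in range(n):
        others = np.mean([X[j] for j in range(n) if j != i], axis=0)
        ra = _rank(X[i])
        rb = _rank(others)
        ra = ra - ra.mean()
        rb = rb - rb.mean()
        denom = np.sqrt((ra @ ra) * (rb @ rb))
        out[i] = (ra @ rb) / denom if denom > 0 else np.nan
    return out


def assert_loo_matches_oracle(mine, ref, tol=1e-12):
    mine = np.asarray(mine)
    ref = np.asarray(ref)
    assert np.array_equal(np.isnan(mine), np.isnan(ref))
    ok = ~np.isnan(mine)
    if ok.any():
        assert np.max(np.abs(mine[ok] - ref[ok])) < tol


def _rank(x):
    """Average ranks, by explicit enumeration."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks
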