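"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import ferrosig as fs


@pytest.fixture(scope="session")
def default_sc_sim():
    """The default synthetic scRNA-seq dataset (seeded, shared read-only)."""
    matrix, truth = fs.simulate_sc(fs.ScSimParams())
    return matrix, truth


@pytest.fixture(scope="session")
def default_sc_normalized(default_sc_sim):
    matrix, _ = default_sc_sim
    return fs.normalize(fs.qc_filter(matrix))


@pytest.fixture()
def small_log_matrix():
    """A tiny deterministic log-normalized matrix with two conditions."""
    rng = np.random.default_rng(42)
    values = rng.gamma(2.0, 1.0, size=(6, 10))
    return fs.ExpressionMatrix(
        values=values,
        gene_ids=[f"G{i}" for i in range(6)],
        obs_ids=[f"C{i}" for i in range(10)],
        condition=np.array(["a"] * 5 + ["b"] * 5, dtype=object),
        layer=fs.Layer.LOG_NORMALIZED,
    )


# ---------------------------------------------------------------------------
# independent oracles


def walk_es_oracle(stats: pd.Series, members: set[str], weight_exponent: float = 1.0) -> float:
    """Step-by-step running-sum enrichment score, O(N) pure-Python walk.

    Kept deliberately independent of the vectorized implementation:
    explicit sort, explicit loop, explicit extremum tracking.
    """
    genes = [str(g).upper() for g in stats.index]
    values = {g: float(v) for g, v in zip(genes, stats.to_numpy(float))}
    order = sorted(genes, key=lambda g: (-values[g], g))
    hit = {g for g in members if g in values}
    n, m = len(order), len(hit)
    denom = sum(abs(values[g]) ** weight_exponent for g in hit)
    run = 0.0
    best = 0.0
    for g in order:
        if g in hit:
            run += (abs(values[g]) ** weight_exponent / denom) if denom > 0 else 1.0 / m
        else:
            run -= 1.0 / (n - m)
        if abs(run) > abs(best):
            best = run
    return best


def exact_wilcoxon_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating every group assignment."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u_all = []
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        u_all.append(u)
    u_all = np.array(u_all)
    p_le = np.mean(u_all <= u_obs)
    p_ge = np.mean(u_all >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))
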