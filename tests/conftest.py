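"""Shared fixtures and independent brute-force oracles.

The oracle helpers here recompute statistics by naive enumeration or hand
formulas; they deliberately share no code with the package internals.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations

import numpy as np
import pytest

from bsmv import (
    ExpressionMatrix,
    VariantGrouping,
    generate_scenario,
    make_site,
    reversal_scenario,
)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(8)]
    conds = [f"c{i}" for i in range(5)]
    return ExpressionMatrix(genes, conds, rng.normal(size=(8, 5)))


@pytest.fixture
def simple_sites():
    """Genes g0..g4 with Mcm1-style sites: nucleotides A,A,T,T,C at position 4."""
    seqs = {"g0": "A", "g1": "A", "g2": "T", "g3": "T", "g4": "C"}
    return [
        make_site("TFX", g, "GGG" + nt + "GGGG", 0.9) for g, nt in seqs.items()
    ]


@pytest.fixture(scope="session")
def reversal_data():
    """The bundled planted-reversal dataset (seed 7)."""
    return generate_scenario(reversal_scenario(seed=7))


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_force_f(rank_rows: np.ndarray, labels: np.ndarray) -> tuple[float, int, int]:
    """F, N, M by explicit enumeration of every gene pair."""
    within, between = [], []
    n = len(labels)
    for i, j in combinations(range(n), 2):
        d = math.dist(rank_rows[i], rank_rows[j])
        (within if labels[i] == labels[j] else between).append(d)
    return (
        sum(within) / len(within) - sum(between) / len(between),
        len(within),
        len(between),
    )


def exact_vdre_p(rank_rows: np.ndarray, labels: np.ndarray) -> float:
    """Exact left-tail permutation p of F over all label arrangements."""
    f_obs, _, _ = brute_force_f(rank_rows, labels)
    arrangements = set(permutations(labels.tolist()))
    hits = sum(
        1 for arr in arrangements
        if brute_force_f(rank_rows, np.array(arr))[0] <= f_obs + 1e-12
    )
    return hits / len(arrangements)


def brute_force_clustering(ranks: np.ndarray, types: list[str]):
    """(S, C_W, C_Q, A, B) by explicit pair enumeration on experiment ranks."""
    within, between = [], []
    for i, j in combinations(range(len(ranks)), 2):
        d = abs(ranks[i] - ranks[j])
        (within if types[i] == types[j] else between).append(d)
    c_w = sum(within) / len(within)
    c_q = sum(between) / len(between)
    return c_q - c_w, c_w, c_q, len(within), len(between)


def exact_clustering_p(ranks: np.ndarray, types: list[str]) -> float:
    """Exact right-tail permutation p of S over all type-label arrangements."""
    s_obs = brute_force_clustering(ranks, types)[0]
    arrangements = set(permutations(types))
    hits = sum(
        1 for arr in arrangements
        if brute_force_clustering(ranks, list(arr))[0] >= s_obs - 1e-12
    )
    return hits / len(arrangements)


def hypergeom_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with the same margins,
    summing probabilities <= that of the observed table."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def table_prob(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = table_prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(
        table_prob(x) for x in range(lo, hi + 1)
        if table_prob(x) <= p_obs * (1 + 1e-9)
    )


def fisher_attainable_level(r1: int, r2: int, c1: int, alpha: float) -> float:
    """Exact rejection probability of the two-sided Fisher test at nominal
    level alpha, given the table margins (row totals r1, r2; column total
    c1).  Discreteness makes this at most — usually well below — alpha."""
    n = r1 + r2

    def table_prob(x: int) -> float:
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    level = 0.0
    for a in range(lo, hi + 1):
        p_obs = table_prob(a)
        p_val = sum(
            table_prob(x) for x in range(lo, hi + 1)
            if table_prob(x) <= p_obs * (1 + 1e-9)
        )
        if p_val < alpha:
            level += p_obs
    return level


def poisson_binomial_99_interval(probs: list[float]) -> tuple[int, int]:
    """Exact central 99% acceptance region for a sum of independent
    Bernoulli variables, by direct convolution."""
    dist = np.array([1.0])
    for p in probs:
        nxt = np.zeros(len(dist) + 1)
        nxt[:-1] += dist * (1 - p)
        nxt[1:] += dist * p
        dist = nxt
    cdf = np.cumsum(dist)
    lo = int(np.searchsorted(cdf, 0.005))
    hi = int(np.searchsorted(cdf, 0.995))
    return lo, hi


def storey_q_oracle(p_values: list[float], lam: float = 0.5) -> list[float]:
    """Direct transcription of the fixed-lambda Storey q-value formula."""
    m = len(p_values)
    pi0 = min(1.0, sum(1 for p in p_values if p > lam) / (m * (1 - lam)))
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pi0 * m * p_values[i] / rank)
        q[i] = min(val, 1.0)
        prev = val
    return q


def wilson_oracle(k: int, n: int, z: float = 1.959964) -> tuple[float, float]:
    """Closed-form Wilson score interval."""
    phat = k / n
    denom = 1 + z**2 / n
    centre = phat + z**2 / (2 * n)
    half = z * math.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2))
    return (centre - half) / denom, (centre + half) / denom


def welch_oracle(x: list[float], y: list[float]) -> float:
    """Welch t statistic from the textbook formula."""
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    return (mx - my) / math.sqrt(vx / nx + vy / ny)


def grouping_from_labels(labels: dict[str, tuple[str, ...]]) -> VariantGrouping:
    return VariantGrouping("TFX", 1, labels)
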