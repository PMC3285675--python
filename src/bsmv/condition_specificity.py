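"""Condition-specific characterization of functional motif-variant positions.

For a pair of nucleotide variants at a functional position, experiments are
ordered by the standardized difference between the two variant groups' mean
expression.  Three characterizations follow:

* a clustering score S = C_Q - C_W over the experiment ordering, where C_W
  (C_Q) is the mean absolute rank distance between experiments of the same
  (different) experiment-type class — a positive S means like experiments
  bunch together; significance by permuting the type labels;
* a rank-reversal test: Spearman correlation between the two groups'
  per-condition mean expression ranks — a significantly negative
  correlation means the variants invert their targets' expression ranking,
  the signature of cofactor-mediated (rather than pure-affinity) effects;
* a slope-sign test: least-squares lines through each group's mean ranks
  along the experiment ordering must have significant, opposite slopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import linregress, spearmanr

from .io_formats import (
    ConditionMetadata,
    ExpressionMatrix,
    ValidationError,
    VariantGrouping,
)
from .vdre import RankedProfileMatrix

logger = logging.getLogger("bsmv")


# ---------------------------------------------------------------------------
# Experiment ordering
# ---------------------------------------------------------------------------

@dataclass
class ExperimentOrdering:
    """Experiments ordered by standardized between-variant mean difference.

    ``statistics`` is aligned with the expression matrix's condition order;
    ``ordering`` lists condition ids from the most variant-a-favouring to the
    most variant-b-favouring experiment; ``experiment_rank`` maps each
    condition to its 1-based rank in that ordering.
    """

    variant_pair: tuple[str, str]
    condition_ids: list[str]
    statistics: np.ndarray
    ordering: list[str]
    experiment_rank: dict[str, int]


def order_experiments(
    grouping: VariantGrouping,
    matrix: ExpressionMatrix,
    variant_pair: tuple[str, str],
    normalize: Literal["sd", "var"] = "sd",
) -> ExperimentOrdering:
    """Sort experiments by (mean_a - mean_b) / pooled spread per condition.

    The pooled spread in each condition is taken over the two target sets'
    expression values combined (sample sd by default, variance with
    ``normalize="var"``).  Zero spread yields statistic 0 with a warning.
    Ties are broken by condition id, ascending, for determinism.
    """
    nt_a, nt_b = variant_pair
    for nt in variant_pair:
        if len(grouping.groups.get(nt, ())) < 2:
            raise ValidationError(
                f"variant {nt!r} needs >=2 target genes with expression data"
            )
    a = matrix.values[matrix.row_indices(grouping.groups[nt_a])]
    b = matrix.values[matrix.row_indices(grouping.groups[nt_b])]
    diff = a.mean(axis=0) - b.mean(axis=0)
    pooled = np.vstack([a, b])
    spread = pooled.std(axis=0, ddof=1)
    if normalize == "var":
        spread = spread**2
    elif normalize != "sd":
        raise ValueError(f"unknown normalize mode {normalize!r}")
    zero = spread == 0
    if zero.any():
        logger.warning(
            "%d condition(s) with zero pooled spread; statistic set to 0",
            int(zero.sum()),
        )
    stats = np.where(zero, 0.0, diff / np.where(zero, 1.0, spread))
    order = sorted(
        range(matrix.n_conditions),
        key=lambda i: (-stats[i], matrix.condition_ids[i]),
    )
    ordering = [matrix.condition_ids[i] for i in order]
    return ExperimentOrdering(
        variant_pair=(nt_a, nt_b),
        condition_ids=list(matrix.condition_ids),
        statistics=stats,
        ordering=ordering,
        experiment_rank={c: r for r, c in enumerate(ordering, start=1)},
    )


# ---------------------------------------------------------------------------
# Experiment-type clustering (score S and permutation test)
# ---------------------------------------------------------------------------

def _rank_and_type_arrays(
    ordering: ExperimentOrdering, metadata: ConditionMetadata
) -> tuple[np.ndarray, np.ndarray]:
    conds = ordering.condition_ids
    ranks = np.array([ordering.experiment_rank[c] for c in conds], dtype=float)
    types = np.array(metadata.types_for(conds))
    return ranks, types


def clustering_score(
    ordering: ExperimentOrdering, metadata: ConditionMetadata
) -> tuple[float, float, float, int, int]:
    """Return (S, C_W, C_Q, A, B) for one experiment ordering.

    Distances are absolute differences of experiment ranks; C_W averages the
    A same-type pairs, C_Q the B different-type pairs, and S = C_Q - C_W.
    """
    ranks, types = _rank_and_type_arrays(ordering, metadata)
    if len(set(types)) < 2:
        raise ValidationError("clustering needs >=2 experiment types")
    li, lj = np.triu_indices(len(ranks), k=1)
    d = np.abs(ranks[li] - ranks[lj])
    same = types[li] == types[lj]
    a_count, b_count = int(same.sum()), int((~same).sum())
    if a_count == 0:
        raise ValidationError("no same-type experiment pair; cannot form C_W")
    c_w = float(d[same].mean())
    c_q = float(d[~same].mean())
    return c_q - c_w, c_w, c_q, a_count, b_count


@dataclass
class ClusteringResult:
    """Experiment-type clustering of one variant pair's ordering."""

    variant_pair: tuple[str, str]
    S: float
    C_W: float
    C_Q: float
    A: int
    B: int
    p_value: float
    n_permutations: int
    seed: int | None


def clustering_permutation_test(
    ordering: ExperimentOrdering,
    metadata: ConditionMetadata,
    n_permutations: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ClusteringResult:
    """Right-tailed permutation test of S, shuffling experiment-type labels.

    The ordering stays fixed; p = (1 + #{S_perm >= S_obs}) / (1 + n).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    s_obs, c_w, c_q, a_count, b_count = clustering_score(ordering, metadata)
    ranks, types = _rank_and_type_arrays(ordering, metadata)
    codes = np.unique(types, return_inverse=True)[1]
    li, lj = np.triu_indices(len(ranks), k=1)
    d = np.abs(ranks[li] - ranks[lj])
    perms = rng.permuted(np.tile(codes, (n_permutations, 1)), axis=1)
    same = perms[:, li] == perms[:, lj]
    n_same = same.sum(axis=1)  # constant (label multiset fixed)
    sum_same = same @ d
    s_perm = (d.sum() - sum_same) / (len(d) - n_same) - sum_same / n_same
    p = (1.0 + int(np.sum(s_perm >= s_obs - 1e-12))) / (1.0 + n_permutations)
    return ClusteringResult(
        variant_pair=ordering.variant_pair,
        S=s_obs, C_W=c_w, C_Q=c_q, A=a_count, B=b_count,
        p_value=p, n_permutations=n_permutations, seed=seed,
    )


# ---------------------------------------------------------------------------
# Reversal and slope-sign tests
# ---------------------------------------------------------------------------

def reversal_rank_test(
    grouping: VariantGrouping,
    ranks: RankedProfileMatrix,
    variant_pair: tuple[str, str],
) -> tuple[float, float]:
    """Spearman correlation between the two variants' mean-rank profiles.

    Returns (rho, one-sided p for rho < 0).  A significantly negative rho
    means the variants' target-gene rankings across conditions are reversed.
    Constant mean-rank vectors give (nan, 1.0): non-significant by fiat.
    """
    nt_a, nt_b = variant_pair
    for nt in variant_pair:
        if len(grouping.groups.get(nt, ())) < 2:
            raise ValidationError(f"variant {nt!r} needs >=2 target genes")
    mean_a = ranks.rows(grouping.groups[nt_a]).mean(axis=0)
    mean_b = ranks.rows(grouping.groups[nt_b]).mean(axis=0)
    if np.ptp(mean_a) == 0 or np.ptp(mean_b) == 0:
        logger.warning("constant mean-rank vector; reversal correlation undefined")
        return float("nan"), 1.0
    rho, p_two = spearmanr(mean_a, mean_b)
    if np.isnan(rho):
        return float("nan"), 1.0
    p_one = p_two / 2.0 if rho < 0 else 1.0 - p_two / 2.0
    return float(rho), float(p_one)


def slope_sign_test(
    grouping: VariantGrouping,
    ranks: RankedProfileMatrix,
    ordering: ExperimentOrdering,
    variant_pair: tuple[str, str],
    alpha: float = 0.05,
) -> tuple[float, float, float, float, bool]:
    """Fit each variant's mean rank against the experiment ordering 1..E.

    Returns (slope_a, p_a, slope_b, p_b, passes); passes requires opposite
    slope signs with both two-sided slope t-test p-values below ``alpha``.
    """
    nt_a, nt_b = variant_pair
    e = len(ordering.ordering)
    if e < 3:
        raise ValidationError("slope test needs >=3 experiments")
    cond_pos = {c: i for i, c in enumerate(ordering.condition_ids)}
    order_idx = np.array([cond_pos[c] for c in ordering.ordering])
    x = np.arange(1, e + 1, dtype=float)
    out: list[tuple[float, float]] = []
    for nt in (nt_a, nt_b):
        y = ranks.rows(grouping.groups[nt]).mean(axis=0)[order_idx]
        if np.ptp(y) == 0:
            out.append((0.0, 1.0))
            continue
        fit = linregress(x, y)
        out.append((float(fit.slope), float(fit.pvalue)))
    (slope_a, p_a), (slope_b, p_b) = out
    passes = (slope_a * slope_b < 0) and (p_a < alpha) and (p_b < alpha)
    return slope_a, p_a, slope_b, p_b, passes


@dataclass
class ReversalResult:
    """Combined reversal + slope-sign assessment of one variant pair."""

    variant_pair: tuple[str, str]
    rank_reversal_stat: float
    rank_reversal_p: float
    slope_a: float
    slope_a_p: float
    slope_b: float
    slope_b_p: float
    passes_both: bool


def reversal_assessment(
    grouping: VariantGrouping,
    ranks: RankedProfileMatrix,
    ordering: ExperimentOrdering,
    variant_pair: tuple[str, str],
    alpha: float = 0.05,
) -> ReversalResult:
    """Run the reversal-rank and slope-sign tests for one variant pair."""
    rho, p_rev = reversal_rank_test(grouping, ranks, variant_pair)
    slope_a, p_a, slope_b, p_b, slopes_pass = slope_sign_test(
        grouping, ranks, ordering, variant_pair, alpha
    )
    reversal_pass = (not np.isnan(rho)) and rho < 0 and p_rev < alpha
    return ReversalResult(
        variant_pair=variant_pair,
        rank_reversal_stat=rho,
        rank_reversal_p=p_rev,
        slope_a=slope_a,
        slope_a_p=p_a,
        slope_b=slope_b,
        slope_b_p=p_b,
        passes_both=reversal_pass and slopes_pass,
    )
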