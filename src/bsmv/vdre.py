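"""The VDRE functionality statistic and its permutation machinery.

VDRE ("variant distance of ranked experiments") compares gene expression
profiles after rank-transforming each gene across conditions, which removes
per-gene baselines and any monotone per-gene scale.  For one variable motif
position the functionality score is

    F = mean(D_W) - mean(D_B)

where D_W are the Euclidean rank-profile distances between pairs of target
genes carrying the *same* nucleotide at the position, D_B between pairs
carrying *different* nucleotides, and all nucleotide groups with at least
two genes are considered simultaneously.  A functional position makes
within-variant profiles more alike than between-variant profiles, so the
test is one-sided towards negative F.  Significance comes from permuting
the gene -> nucleotide assignment (group sizes fixed); the false discovery
rate is estimated from the observed p-values with a fixed-lambda Storey
estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, ttest_ind

from .io_formats import (
    BindingSiteAnnotation,
    ExpressionMatrix,
    ValidationError,
    VariantGrouping,
    select_single_primary_targets,
)

logger = logging.getLogger("bsmv")


# ---------------------------------------------------------------------------
# Rank profiles and distances
# ---------------------------------------------------------------------------

@dataclass
class RankedProfileMatrix:
    """Within-gene ranks of expression across conditions (ties averaged).

    Rank 1 is the lowest expression.  Every row sums to E(E+1)/2 regardless
    of ties, E being the number of conditions.
    """

    gene_ids: list[str]
    condition_ids: list[str]
    ranks: np.ndarray

    def __post_init__(self) -> None:
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.ranks[self._gene_index[gene_id]]

    def rows(self, gene_ids: Sequence[str]) -> np.ndarray:
        return self.ranks[[self._gene_index[g] for g in gene_ids]]


def rank_profiles(matrix: ExpressionMatrix) -> RankedProfileMatrix:
    """Rank each gene's expression across conditions (average ranks on ties)."""
    if matrix.n_conditions < 2:
        raise ValidationError("ranking requires at least 2 conditions")
    ranks = rankdata(matrix.values, axis=1, method="average")
    constant = np.ptp(matrix.values, axis=1) == 0
    if constant.any():
        logger.info("%d constant expression rows (all ranks tied)", int(constant.sum()))
    return RankedProfileMatrix(list(matrix.gene_ids), list(matrix.condition_ids), ranks)


def rank_distance(g1: np.ndarray, g2: np.ndarray) -> float:
    """Euclidean distance between two rank vectors."""
    g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
    if g1.shape != g2.shape:
        raise ValueError(f"length mismatch: {g1.shape} vs {g2.shape}")
    return float(np.linalg.norm(g1 - g2))


# ---------------------------------------------------------------------------
# The functionality score F
# ---------------------------------------------------------------------------

def _testable_labels(
    grouping: VariantGrouping, include_singletons: bool = False
) -> tuple[list[str], np.ndarray]:
    """Genes of qualifying (>=2-gene) groups with integer group labels.

    With ``include_singletons`` the 1-gene groups enter too (each under its
    own label, so their pairs are all between-group); the default excludes
    them from both the within and the between sums.
    """
    if not grouping.testable:
        raise ValidationError(
            f"grouping {grouping.tf_id} position {grouping.motif_position} is "
            "not testable (needs >=2 groups with >=2 genes); skip it"
        )
    nts = (
        sorted(grouping.groups) if include_singletons else grouping.testable_nucleotides
    )
    # canonical gene order (sorted by id, not by group) so that relabelling
    # nucleotides leaves the permutation stream — hence the p-value — intact
    pairs = sorted(
        (g, k) for k, nt in enumerate(nts) for g in grouping.groups[nt]
    )
    genes = [g for g, _ in pairs]
    labels = np.asarray([k for _, k in pairs])
    return genes, labels


def _f_from_condensed(d: np.ndarray, same: np.ndarray) -> float:
    return float(d[same].mean() - d[~same].mean())


def _pair_same_mask(labels: np.ndarray) -> np.ndarray:
    """Condensed (pdist-ordered) boolean mask: pair is within one group."""
    li, lj = np.triu_indices(len(labels), k=1)
    return labels[li] == labels[lj]


def vdre_score(
    grouping: VariantGrouping,
    ranks: RankedProfileMatrix,
    include_singletons_in_between: bool = False,
) -> tuple[float, int, int]:
    """Compute (F, N, M) for a testable grouping.

    N = number of within-group pairs, M = number of between-group pairs,
    counting only groups with >=2 genes unless
    ``include_singletons_in_between`` is set.
    """
    genes, labels = _testable_labels(grouping, include_singletons_in_between)
    d = pdist(ranks.rows(genes), metric="euclidean")
    same = _pair_same_mask(labels)
    n, m = int(same.sum()), int((~same).sum())
    return _f_from_condensed(d, same), n, m


def min_comparison_count(grouping: VariantGrouping) -> int:
    """min(N, M): the limiting number of comparisons for a position (a power
    diagnostic; positions with few comparisons carry little information)."""
    sizes = [len(grouping.groups[nt]) for nt in grouping.testable_nucleotides]
    n = sum(s * (s - 1) // 2 for s in sizes)
    m = sum(a * b for a, b in combinations(sizes, 2))
    return min(n, m)


# ---------------------------------------------------------------------------
# Permutation test and FDR
# ---------------------------------------------------------------------------

@dataclass
class VdreResult:
    """Outcome of the VDRE functionality test at one motif position."""

    tf_id: str
    motif_position: int
    group_sizes: dict[str, int]
    F: float
    N: int
    M: int
    p_value: float
    n_permutations: int
    seed: int | None
    q_value: float | None = None


def vdre_permutation_test(
    grouping: VariantGrouping,
    ranks: RankedProfileMatrix,
    n_permutations: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    include_singletons_in_between: bool = False,
) -> VdreResult:
    """One-sided label-permutation test of F (towards negative F).

    Gene -> nucleotide assignments are shuffled with group sizes fixed;
    p = (1 + #{F_perm <= F_obs}) / (1 + n_permutations), so p is never 0.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    genes, labels = _testable_labels(grouping, include_singletons_in_between)
    d = pdist(ranks.rows(genes), metric="euclidean")
    same_obs = _pair_same_mask(labels)
    f_obs = _f_from_condensed(d, same_obs)

    li, lj = np.triu_indices(len(labels), k=1)
    perms = rng.permuted(np.tile(labels, (n_permutations, 1)), axis=1)
    same = perms[:, li] == perms[:, lj]  # (n_perm, n_pairs)
    n_within = same.sum(axis=1)
    sum_within = same @ d
    f_perm = sum_within / n_within - (d.sum() - sum_within) / (len(d) - n_within)
    p = (1.0 + int(np.sum(f_perm <= f_obs))) / (1.0 + n_permutations)
    return VdreResult(
        tf_id=grouping.tf_id,
        motif_position=grouping.motif_position,
        group_sizes=grouping.group_sizes,
        F=f_obs,
        N=int(same_obs.sum()),
        M=int((~same_obs).sum()),
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
    )


def estimate_fdr(p_values: Sequence[float], lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed tuning parameter lambda.

    pi0 is estimated as min(1, #{p > lambda} / (m (1 - lambda))); q-values
    are the step-up minima of pi0 * m * p / rank and are monotone in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("estimate_fdr needs at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < lam < 1:
        raise ValueError("lambda must lie in (0, 1)")
    m = p.size
    pi0 = min(1.0, np.sum(p > lam) / (m * (1.0 - lam)))
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def expected_true_discoveries(n_discoveries: int, fdr: float) -> float:
    """Expected true positives among n discoveries at a given FDR level."""
    if not 0 <= fdr <= 1:
        raise ValueError("fdr must lie in [0, 1]")
    return n_discoveries * (1.0 - fdr)


# ---------------------------------------------------------------------------
# Distance-class diagnostics (shared-site similarity, Welch t-test)
# ---------------------------------------------------------------------------

DistanceClass = Literal["one_primary", "multi_primary", "secondary", "random"]


def _pairs_sharing(site_map: dict[str, set[str]]) -> set[tuple[str, str]]:
    """Unordered gene pairs sharing at least one key's membership."""
    pairs: set[tuple[str, str]] = set()
    for genes in site_map.values():
        for a, b in combinations(sorted(genes), 2):
            pairs.add((a, b))
    return pairs


def distance_class_samples(
    sites: Sequence[BindingSiteAnnotation],
    ranks: RankedProfileMatrix,
    distance_class: DistanceClass,
    rng: np.random.Generator | None = None,
    max_pairs: int = 20000,
) -> np.ndarray:
    """Pairwise rank-profile distances for one class of shared binding sites.

    ``one_primary``: both genes are single-primary-input targets of the same
    TF.  ``multi_primary``: both genes share a primary site for the same TF,
    with at least one of them carrying multiple primary sites.
    ``secondary``: genes sharing a secondary site for the same TF.
    ``random``: random gene pairs (requires ``rng``).
    """
    present = {g for g in ranks.gene_ids}
    if distance_class == "random":
        if rng is None:
            rng = np.random.default_rng()
        genes = sorted(present)
        n = min(max_pairs, len(genes) * (len(genes) - 1) // 2)
        pairs = set()
        while len(pairs) < n:
            a, b = rng.choice(len(genes), size=2, replace=False)
            pairs.add((genes[min(a, b)], genes[max(a, b)]))
        pair_list = sorted(pairs)
    else:
        tfs = sorted({s.tf_id for s in sites})
        if distance_class == "one_primary":
            per_tf = {
                tf: select_single_primary_targets(sites, tf, "all_tfs") & present
                for tf in tfs
            }
            pair_list = sorted(_pairs_sharing(per_tf))
        elif distance_class == "multi_primary":
            primary_counts: dict[str, int] = {}
            for s in sites:
                if s.site_class == "primary":
                    primary_counts[s.gene_id] = primary_counts.get(s.gene_id, 0) + 1
            per_tf = {
                tf: {s.gene_id for s in sites
                     if s.tf_id == tf and s.site_class == "primary"} & present
                for tf in tfs
            }
            pair_list = sorted(
                (a, b) for a, b in _pairs_sharing(per_tf)
                if primary_counts.get(a, 0) > 1 or primary_counts.get(b, 0) > 1
            )
        elif distance_class == "secondary":
            per_tf = {
                tf: {s.gene_id for s in sites
                     if s.tf_id == tf and s.site_class == "secondary"} & present
                for tf in tfs
            }
            pair_list = sorted(_pairs_sharing(per_tf))
        else:
            raise ValueError(f"unknown distance class {distance_class!r}")
        if len(pair_list) > max_pairs:
            if rng is None:
                rng = np.random.default_rng()
            idx = rng.choice(len(pair_list), size=max_pairs, replace=False)
            pair_list = [pair_list[i] for i in sorted(idx)]
    return np.array(
        [rank_distance(ranks.gene_row(a), ranks.gene_row(b)) for a, b in pair_list]
    )


@dataclass
class DistanceClassComparison:
    class_a: str
    class_b: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    degenerate: bool = False


def distance_class_comparison(
    sites: Sequence[BindingSiteAnnotation],
    matrix: ExpressionMatrix,
    class_a: DistanceClass,
    class_b: DistanceClass,
    seed: int | None = None,
    max_pairs: int = 20000,
) -> DistanceClassComparison:
    """Welch two-sample t-test between two classes of pairwise distances."""
    rng = np.random.default_rng(seed)
    ranks = rank_profiles(matrix)
    a = distance_class_samples(sites, ranks, class_a, rng, max_pairs)
    b = distance_class_samples(sites, ranks, class_b, rng, max_pairs)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each distance class needs >=2 pairs")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # zero variance on both sides: no detectable difference
        equal = float(a.mean()) == float(b.mean())
        return DistanceClassComparison(
            class_a, class_b, float(a.mean()), float(b.mean()), len(a), len(b),
            t_statistic=0.0 if equal else np.inf, p_value=1.0 if equal else 0.0,
            degenerate=True,
        )
    t, p = ttest_ind(a, b, equal_var=False)
    return DistanceClassComparison(
        class_a, class_b, float(a.mean()), float(b.mean()), len(a), len(b),
        float(t), float(p),
    )
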