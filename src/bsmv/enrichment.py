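"""GO-process enrichment and secondary-site co-occurrence screens.

Two sanity screens around a functional motif-variant position:

* permutation GO enrichment: are one variant's target genes enriched for a
  biological process?  The null shuffles the gene -> variant-group
  assignment (group sizes fixed, gene annotations untouched), and the
  enrichment p-value is right-tailed on the in-group annotation count;
* co-occurrence screen: could the position's expression signal instead be
  driven by low-confidence (secondary) sites of some *other* TF piggybacking
  on one variant?  Each (variant nucleotide, other TF) combination is
  tallied into a 2x2 table over the position's target genes and tested with
  Fisher's exact test; any flag at the chosen level means the position's
  signal cannot be cleanly attributed to the variant itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .io_formats import BindingSiteAnnotation, VariantGrouping

logger = logging.getLogger("bsmv")


# ---------------------------------------------------------------------------
# GO enrichment by group-assignment permutation
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Enrichment of one GO process in one variant group's target genes."""

    tf_id: str
    motif_position: int
    nucleotide: str
    go_process: str
    observed_count: int
    group_size: int
    p_value: float
    n_permutations: int
    seed: int | None


def go_enrichment(
    grouping: VariantGrouping,
    go_map: Mapping[str, set[str]],
    n_permutations: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[EnrichmentResult]:
    """Right-tailed permutation enrichment of GO processes per variant group.

    The universe is the grouping's testable target genes.  For each
    (group, process) with at least one annotated target gene,
    p = (1 + #{null count >= observed}) / (1 + n_permutations).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    nts = grouping.testable_nucleotides
    genes = grouping.genes(nts)
    processes = sorted({p for g in genes for p in go_map.get(g, ())})
    if not processes:
        logger.warning(
            "no annotated genes among targets of %s position %d",
            grouping.tf_id, grouping.motif_position,
        )
        return []
    ann = np.array(
        [[1 if p in go_map.get(g, ()) else 0 for p in processes] for g in genes],
        dtype=float,
    )
    sizes = [len(grouping.groups[nt]) for nt in nts]
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    perms = rng.permuted(
        np.tile(np.arange(len(genes)), (n_permutations, 1)), axis=1
    )
    results: list[EnrichmentResult] = []
    for gi, nt in enumerate(nts):
        seg = slice(bounds[gi], bounds[gi + 1])
        observed = ann[seg].sum(axis=0)
        null_counts = ann[perms[:, seg]].sum(axis=1)  # (n_perm, n_proc)
        exceed = (null_counts >= observed[None, :] - 1e-9).sum(axis=0)
        p_vals = (1.0 + exceed) / (1.0 + n_permutations)
        for pi, proc in enumerate(processes):
            if observed[pi] == 0 and not np.any(ann[:, pi]):
                continue
            results.append(
                EnrichmentResult(
                    tf_id=grouping.tf_id,
                    motif_position=grouping.motif_position,
                    nucleotide=nt,
                    go_process=proc,
                    observed_count=int(observed[pi]),
                    group_size=sizes[gi],
                    p_value=float(p_vals[pi]),
                    n_permutations=n_permutations,
                    seed=seed,
                )
            )
    return results


# ---------------------------------------------------------------------------
# Fisher's exact co-occurrence screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows = has/lacks focal nucleotide, cols = has/lacks the
    other TF's coincident secondary site, over the position's target genes."""

    a: int  # variant & secondary site
    b: int  # variant, no secondary site
    c: int  # other variant & secondary site
    d: int  # other variant, no secondary site

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p (probability-ordering definition).

    An empty row or column margin gives p = 1 (no association testable).
    """
    if (
        table.a + table.b == 0 or table.c + table.d == 0
        or table.a + table.c == 0 or table.b + table.d == 0
    ):
        return 1.0
    _, p = fisher_exact([[table.a, table.b], [table.c, table.d]], alternative="two-sided")
    return float(p)


def cooccurrence_screen(
    grouping: VariantGrouping,
    sites: Sequence[BindingSiteAnnotation],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Fisher screen for secondary-site confounding at one position.

    One test per (variant nucleotide, other TF with >=1 secondary site among
    the position's target genes); "coincident" means annotated to the same
    target gene.  Returns a DataFrame with columns tf_id, motif_position,
    nucleotide, other_tf, a, b, c, d, p_value, flagged; empty if no
    secondary sites touch the targets.
    """
    targets = set(grouping.genes())
    secondary: dict[str, set[str]] = {}
    for s in sites:
        if s.site_class == "secondary" and s.tf_id != grouping.tf_id and s.gene_id in targets:
            secondary.setdefault(s.tf_id, set()).add(s.gene_id)
    rows = []
    for nt in sorted(grouping.groups):
        with_nt = set(grouping.groups[nt])
        without_nt = targets - with_nt
        for other_tf in sorted(secondary):
            hit = secondary[other_tf]
            tab = ContingencyTable2x2(
                a=len(with_nt & hit),
                b=len(with_nt - hit),
                c=len(without_nt & hit),
                d=len(without_nt - hit),
            )
            p = fisher_exact_2x2(tab)
            rows.append(
                (grouping.tf_id, grouping.motif_position, nt, other_tf,
                 tab.a, tab.b, tab.c, tab.d, p, p < alpha)
            )
    return pd.DataFrame(
        rows,
        columns=["tf_id", "motif_position", "nucleotide", "other_tf",
                 "a", "b", "c", "d", "p_value", "flagged"],
    )


def any_cooccurrence_flag(screen: pd.DataFrame) -> bool:
    """Whether any (nucleotide, other TF) combination is flagged — the
    exclusion criterion for attributing the position's signal to the BSMV."""
    return bool(screen["flagged"].any()) if len(screen) else False
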