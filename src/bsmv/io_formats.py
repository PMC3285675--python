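"""Tabular input/output, validation, and target-gene selection.

All tables are plain tab-separated UTF-8 text with "." as the decimal
separator.  Motif positions are 1-based throughout the package.

Binding sites are classified from their annotation posterior probability:
``primary`` for posterior >= 0.7, ``secondary`` for 0.2 < posterior < 0.7,
``discard`` otherwise.  Discarded sites are retained in memory so that
counts remain auditable, but they never enter any analysis.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("bsmv")

NUCLEOTIDES = ("A", "C", "G", "T")
PRIMARY_THRESHOLD = 0.7
SECONDARY_FLOOR = 0.2

SiteClass = Literal["primary", "secondary", "discard"]
GeneFilter = Literal["single_primary", "any_primary"]
SinglePrimaryScope = Literal["all_tfs", "same_tf"]


class ParseError(ValueError):
    """A structural problem in an input file (wrong field count, bad cell)."""


class ValidationError(ValueError):
    """A well-formed file whose content violates an invariant."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x conditions matrix of normalized (log-scale) expression.

    Attributes
    ----------
    gene_ids : list of str
        Unique row identifiers.
    condition_ids : list of str
        Unique column identifiers (one per experiment).
    values : ndarray, shape (n_genes, n_conditions)
        Finite real expression values.
    """

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_g, n_c = len(self.gene_ids), len(self.condition_ids)
        if self.values.shape != (n_g, n_c):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{n_g} genes x {n_c} conditions"
            )
        for label, ids in (("gene", self.gene_ids), ("condition", self.condition_ids)):
            dup = [k for k, v in Counter(ids).items() if v > 1]
            if dup:
                raise ValidationError(f"duplicate {label} ids: {dup[:5]}")
            if any(not i for i in ids):
                raise ValidationError(f"empty {label} id")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self._gene_index[gene_id]]

    def row_indices(self, gene_ids: Iterable[str]) -> np.ndarray:
        return np.array([self._gene_index[g] for g in gene_ids], dtype=int)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._gene_index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.condition_ids)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = condition ids, col 1 = gene ids).

    Raises :class:`ParseError` naming the 1-based line number on a malformed
    row, and :class:`ValidationError` on duplicate identifiers.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        conditions = header[1:]
        if not conditions:
            raise ParseError(f"{path}: header has no condition columns")
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, fields in enumerate(reader, start=2):
            if not fields or (len(fields) == 1 and not fields[0]):
                continue  # trailing blank line
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            genes.append(fields[0])
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    return ExpressionMatrix(genes, conditions, np.array(rows, dtype=float))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# Condition metadata
# ---------------------------------------------------------------------------

@dataclass
class ConditionMetadata:
    """Mapping from condition id to an experiment-type class label."""

    experiment_type: dict[str, str]

    def __post_init__(self) -> None:
        if not self.experiment_type:
            raise ValidationError("condition metadata is empty")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.experiment_type.values()))

    def types_for(self, condition_ids: Sequence[str]) -> list[str]:
        missing = [c for c in condition_ids if c not in self.experiment_type]
        if missing:
            raise ValidationError(f"conditions without experiment type: {missing[:5]}")
        return [self.experiment_type[c] for c in condition_ids]


def read_condition_metadata(path: str | Path) -> ConditionMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["condition_id", "experiment_type"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    if df["condition_id"].duplicated().any():
        dup = df.loc[df["condition_id"].duplicated(), "condition_id"].tolist()
        raise ValidationError(f"duplicate condition ids: {dup[:5]}")
    return ConditionMetadata(dict(zip(df["condition_id"], df["experiment_type"])))


def write_condition_metadata(meta: ConditionMetadata, path: str | Path) -> None:
    pd.DataFrame(
        sorted(meta.experiment_type.items()), columns=["condition_id", "experiment_type"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Binding-site annotations
# ---------------------------------------------------------------------------

def classify_site(
    posterior: float,
    primary_threshold: float = PRIMARY_THRESHOLD,
    secondary_floor: float = SECONDARY_FLOOR,
) -> SiteClass:
    """Classify one annotated site by its posterior probability.

    Sites at exactly the primary threshold are primary; sites at exactly the
    secondary floor are discarded (the secondary interval is open below).
    """
    if posterior >= primary_threshold:
        return "primary"
    if posterior > secondary_floor:
        return "secondary"
    return "discard"


@dataclass(frozen=True)
class BindingSiteAnnotation:
    """One annotated TF binding site on one target gene's promoter."""

    tf_id: str
    gene_id: str
    site_sequence: str
    posterior: float
    site_class: SiteClass = field(compare=False, default="discard")

    def __post_init__(self) -> None:
        if not 0.0 <= self.posterior <= 1.0:
            raise ValidationError(
                f"posterior {self.posterior} for {self.tf_id}/{self.gene_id} "
                "outside [0, 1]"
            )
        if any(b not in NUCLEOTIDES for b in self.site_sequence) or not self.site_sequence:
            raise ValidationError(
                f"site sequence {self.site_sequence!r} for {self.tf_id}/"
                f"{self.gene_id} is not a non-empty ACGT string"
            )


def make_site(
    tf_id: str,
    gene_id: str,
    site_sequence: str,
    posterior: float,
    primary_threshold: float = PRIMARY_THRESHOLD,
    secondary_floor: float = SECONDARY_FLOOR,
) -> BindingSiteAnnotation:
    return BindingSiteAnnotation(
        tf_id,
        gene_id,
        site_sequence,
        posterior,
        classify_site(posterior, primary_threshold, secondary_floor),
    )


def read_binding_sites(
    path: str | Path,
    primary_threshold: float = PRIMARY_THRESHOLD,
    secondary_floor: float = SECONDARY_FLOOR,
) -> list[BindingSiteAnnotation]:
    """Read a binding-site annotation TSV and classify each site.

    Columns: ``tf_id  gene_id  site_sequence  posterior``.  Sites below the
    secondary floor are kept with class ``discard``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"tf_id": str, "gene_id": str, "site_sequence": str})
    expected = ["tf_id", "gene_id", "site_sequence", "posterior"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    sites = [
        make_site(r.tf_id, r.gene_id, r.site_sequence, float(r.posterior),
                  primary_threshold, secondary_floor)
        for r in df.itertuples(index=False)
    ]
    # one motif length per TF
    lengths: dict[str, set[int]] = defaultdict(set)
    for s in sites:
        lengths[s.tf_id].add(len(s.site_sequence))
    bad = {tf: ls for tf, ls in lengths.items() if len(ls) > 1}
    if bad:
        raise ValidationError(f"inconsistent motif lengths per TF: {bad}")
    return sites


def write_binding_sites(sites: Sequence[BindingSiteAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(s.tf_id, s.gene_id, s.site_sequence, s.posterior) for s in sites],
        columns=["tf_id", "gene_id", "site_sequence", "posterior"],
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def motif_length(sites: Sequence[BindingSiteAnnotation], tf_id: str) -> int:
    for s in sites:
        if s.tf_id == tf_id:
            return len(s.site_sequence)
    raise ValidationError(f"no sites for TF {tf_id!r}")


# ---------------------------------------------------------------------------
# GO annotation map
# ---------------------------------------------------------------------------

def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column ``gene_id<TAB>go_process_id`` file into a gene -> set map.

    Genes absent from the map are simply unannotated; this never errors on
    unknown genes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["gene_id", "go_process_id"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    out: dict[str, set[str]] = defaultdict(set)
    for g, p in zip(df["gene_id"], df["go_process_id"]):
        out[g].add(p)
    return dict(out)


def write_go_map(go_map: Mapping[str, set[str]], path: str | Path) -> None:
    rows = [(g, p) for g in sorted(go_map) for p in sorted(go_map[g])]
    pd.DataFrame(rows, columns=["gene_id", "go_process_id"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Target-gene selection and variant grouping
# ---------------------------------------------------------------------------

def select_single_primary_targets(
    sites: Sequence[BindingSiteAnnotation],
    tf_id: str,
    scope: SinglePrimaryScope = "all_tfs",
) -> set[str]:
    """Genes whose promoter carries exactly one primary site, for this TF.

    ``scope="all_tfs"`` counts primary sites genome-wide across every
    annotated TF (the default reading: the gene has a single primary
    regulatory input of any identity, and that input is ``tf_id``).
    ``scope="same_tf"`` counts only the focal TF's primary sites.
    """
    if not any(s.tf_id == tf_id for s in sites):
        logger.warning("select_single_primary_targets: unknown TF %r", tf_id)
        return set()
    counts: Counter[str] = Counter()
    focal_genes: set[str] = set()
    for s in sites:
        if s.site_class != "primary":
            continue
        if scope == "all_tfs" or s.tf_id == tf_id:
            counts[s.gene_id] += 1
        if s.tf_id == tf_id:
            focal_genes.add(s.gene_id)
    return {g for g in focal_genes if counts[g] == 1}


@dataclass
class VariantGrouping:
    """Target genes of one TF grouped by the nucleotide at one motif position.

    ``groups`` maps nucleotide -> sorted tuple of gene ids.  A grouping is
    *testable* when at least two nucleotide groups each hold at least two
    genes; smaller groups are retained for reporting but never enter the
    functionality test.
    """

    tf_id: str
    motif_position: int  # 1-based
    groups: dict[str, tuple[str, ...]]

    @property
    def group_sizes(self) -> dict[str, int]:
        return {nt: len(g) for nt, g in self.groups.items()}

    @property
    def testable_nucleotides(self) -> list[str]:
        return sorted(nt for nt, g in self.groups.items() if len(g) >= 2)

    @property
    def testable(self) -> bool:
        return len(self.testable_nucleotides) >= 2

    def genes(self, nucleotides: Iterable[str] | None = None) -> list[str]:
        nts = sorted(self.groups) if nucleotides is None else list(nucleotides)
        return [g for nt in nts for g in self.groups[nt]]


def build_variant_groupings(
    sites: Sequence[BindingSiteAnnotation],
    tf_id: str,
    motif_position: int,
    gene_filter: GeneFilter = "single_primary",
    single_primary_scope: SinglePrimaryScope = "all_tfs",
    expression_genes: set[str] | None = None,
) -> VariantGrouping:
    """Group the TF's eligible target genes by nucleotide at ``motif_position``.

    ``gene_filter="single_primary"`` restricts to single-primary-input genes
    (the main analysis); ``"any_primary"`` admits every gene with a primary
    site for the TF.  Genes whose multiple primary sites for the TF disagree
    at the position are dropped with a warning; genes missing from
    ``expression_genes`` (when given) are dropped with a warning.
    """
    mlen = motif_length(sites, tf_id)
    if not 1 <= motif_position <= mlen:
        raise IndexError(
            f"motif position {motif_position} outside 1..{mlen} for TF {tf_id!r}"
        )
    if gene_filter == "single_primary":
        eligible = select_single_primary_targets(sites, tf_id, single_primary_scope)
    elif gene_filter == "any_primary":
        eligible = {s.gene_id for s in sites if s.tf_id == tf_id and s.site_class == "primary"}
    else:
        raise ValueError(f"unknown gene_filter {gene_filter!r}")

    per_gene: dict[str, set[str]] = defaultdict(set)
    for s in sites:
        if s.tf_id == tf_id and s.site_class == "primary" and s.gene_id in eligible:
            per_gene[s.gene_id].add(s.site_sequence[motif_position - 1])

    groups: dict[str, list[str]] = defaultdict(list)
    for gene, nts in per_gene.items():
        if len(nts) > 1:
            logger.warning(
                "gene %s has primary sites for %s disagreeing at position %d; dropped",
                gene, tf_id, motif_position,
            )
            continue
        if expression_genes is not None and gene not in expression_genes:
            logger.warning("gene %s absent from expression matrix; dropped", gene)
            continue
        groups[next(iter(nts))].append(gene)
    return VariantGrouping(
        tf_id, motif_position, {nt: tuple(sorted(gs)) for nt, gs in groups.items()}
    )
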