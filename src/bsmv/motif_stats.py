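"""Motif information content and alignment-column diversity summaries.

Information content at a motif position is computed against a non-uniform
genomic background as R = H(background) - H(position), both Shannon
entropies in bits (0*log 0 = 0).  With the yeast intergenic background
frequencies used here (f_A=0.307, f_C=f_G=0.188, f_T=0.316) a fully
conserved position reaches R = H(background) ~ 1.95 bits.  Positions with
R <= 1 bit are called "highly variable".  No small-sample correction is
applied, and negative R is reported as-is.

Alignment-column summaries (for user-supplied or synthetic cross-species
columns): the proportion of invariant columns with a Wilson 95% score
interval, and the mean number of distinct nucleotides per column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .io_formats import NUCLEOTIDES, ParseError, ValidationError

# published frequency tables are typically rounded to 3 decimals, so their
# sum can be off unity by up to 2e-3 (the default yeast set sums to 0.999)
_BG_SUM_TOL = 2e-3


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Genomic background nucleotide frequencies (must sum to ~1)."""

    f_A: float = 0.307
    f_C: float = 0.188
    f_G: float = 0.188
    f_T: float = 0.316

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals <= 0) or np.any(vals >= 1):
            raise ValidationError("background frequencies must lie in (0, 1)")
        if abs(vals.sum() - 1.0) > _BG_SUM_TOL:
            raise ValidationError(f"background frequencies sum to {vals.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.f_A, self.f_C, self.f_G, self.f_T], dtype=float)


@dataclass(frozen=True)
class PositionFrequencyVector:
    """Nucleotide frequencies at one (1-based) motif position."""

    position: int
    frequencies: tuple[float, float, float, float]  # A, C, G, T

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValidationError("position frequencies must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > _BG_SUM_TOL:
            raise ValidationError(f"position frequencies sum to {vals.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array(self.frequencies, dtype=float)


def shannon_entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0*log(0) = 0 convention."""
    p = np.asarray(p, dtype=float)
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def information_content(
    pos: PositionFrequencyVector, bg: BackgroundFrequencies | None = None
) -> float:
    """R = H(background) - H(position), in bits; may be negative."""
    if bg is None:
        bg = BackgroundFrequencies()
    return shannon_entropy_bits(bg.as_array()) - shannon_entropy_bits(pos.as_array())


def classify_position_variability(
    pos: PositionFrequencyVector,
    bg: BackgroundFrequencies | None = None,
    threshold_bits: float = 1.0,
) -> Literal["highly_variable", "variable"]:
    """"highly_variable" iff information content <= threshold (default 1 bit)."""
    r = information_content(pos, bg)
    return "highly_variable" if r <= threshold_bits else "variable"


# ---------------------------------------------------------------------------
# Alignment-column diversity
# ---------------------------------------------------------------------------

@dataclass
class AlignmentColumnSet:
    """Ungapped per-species nucleotide columns for one site class.

    Each column is a string of one base per species (>=2 species); gapped or
    unalignable columns are expected to be excluded upstream.
    """

    label: str
    columns: list[str]

    def __post_init__(self) -> None:
        for col in self.columns:
            if len(col) < 2:
                raise ValidationError(f"column {col!r} has fewer than 2 species")
            if any(b not in NUCLEOTIDES for b in col):
                raise ValidationError(f"column {col!r} contains non-ACGT characters")


@dataclass(frozen=True)
class WilsonInterval:
    estimate: float
    lower: float
    upper: float
    confidence: float = 0.95


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> WilsonInterval:
    """Wilson score interval for a binomial proportion k/n."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    lower, upper = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    return WilsonInterval(k / n, float(lower), float(upper), confidence)


def invariant_proportion(cols: AlignmentColumnSet) -> tuple[float, WilsonInterval]:
    """Proportion of columns where all species share one nucleotide,
    with its Wilson 95% confidence interval."""
    if not cols.columns:
        raise ValidationError("empty alignment column set")
    k = sum(1 for c in cols.columns if len(set(c)) == 1)
    n = len(cols.columns)
    return k / n, wilson_interval(k, n)


def mean_alleles_per_position(cols: AlignmentColumnSet) -> float:
    """Mean count of distinct nucleotides per column (in [1, 4])."""
    if not cols.columns:
        raise ValidationError("empty alignment column set")
    return float(np.mean([len(set(c)) for c in cols.columns]))


def diversity_table(col_sets: Sequence[AlignmentColumnSet]) -> pd.DataFrame:
    """Per-class diversity summary: invariant proportion, Wilson 95% CI,
    mean nucleotides per column."""
    rows = []
    for cs in col_sets:
        prop, ci = invariant_proportion(cs)
        rows.append(
            (cs.label, len(cs.columns), prop, ci.lower, ci.upper,
             mean_alleles_per_position(cs))
        )
    return pd.DataFrame(
        rows,
        columns=["site_class", "n_columns", "invariant_proportion",
                 "ci_lower", "ci_upper", "mean_nucleotides_per_position"],
    )


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

def read_pwm(path: str | Path) -> list[PositionFrequencyVector]:
    """Read a PWM TSV: columns ``position  A  C  G  T`` (frequencies)."""
    df = pd.read_csv(path, sep="\t")
    expected = ["position", "A", "C", "G", "T"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return [
        PositionFrequencyVector(int(r.position), (r.A, r.C, r.G, r.T))
        for r in df.itertuples(index=False)
    ]


def read_alignment_columns(path: str | Path) -> list[AlignmentColumnSet]:
    """Read alignment columns TSV: columns ``site_class  column`` where
    ``column`` is one base per species (e.g. ``AATAA``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["site_class", "column"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return [
        AlignmentColumnSet(label, group["column"].tolist())
        for label, group in df.groupby("site_class", sort=True)
    ]


def information_table(
    pwm: Sequence[PositionFrequencyVector],
    bg: BackgroundFrequencies | None = None,
    threshold_bits: float = 1.0,
) -> pd.DataFrame:
    """Per-position information content and variability class for one PWM."""
    rows = [
        (p.position, information_content(p, bg),
         classify_position_variability(p, bg, threshold_bits))
        for p in pwm
    ]
    return pd.DataFrame(rows, columns=["position", "information_bits", "variability"])
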