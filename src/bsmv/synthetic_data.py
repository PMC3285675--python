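"""Synthetic regulatory datasets with planted variant-by-condition effects.

The generator emulates the structure of a genome-wide binding-site /
expression-compendium study: several TFs, each with a 6-16 bp motif that is
consensus everywhere except one variable position, target genes carrying a
single primary site (posterior >= 0.7), sprinkled secondary sites
(posterior in (0.2, 0.7)), experiments grouped into experiment-type
classes, and expression built as

    expression(g, c) = baseline(g) + condition_effect(c)
                       + interaction(nucleotide(g), experiment_type(c))
                       + Gaussian(0, noise_sd)

Per-gene baselines are drawn once and shared across conditions, so the
within-gene rank transform used downstream removes them exactly.  The
interaction term is the planted ground truth: a ``reversal`` regime gives
two nucleotides opposite-signed effects across experiment types (the
cofactor-switch signature), ``affinity_scaling`` gives same-signed effects
of different magnitude, and ``null`` plants nothing.

One master seed drives a :class:`numpy.random.SeedSequence`; independent
sub-streams per component (baselines, condition effects, noise, motifs,
secondary sites, GO annotations) keep components reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io_formats import (
    BindingSiteAnnotation,
    ConditionMetadata,
    ExpressionMatrix,
    NUCLEOTIDES,
    make_site,
    write_binding_sites,
    write_condition_metadata,
    write_expression_matrix,
    write_go_map,
)

Regime = Literal["null", "affinity_scaling", "reversal"]

MIN_MOTIF_LENGTH = 6
MAX_MOTIF_LENGTH = 16


class ConfigError(ValueError):
    """An internally inconsistent scenario configuration."""


@dataclass
class PlantedEffect:
    """Ground-truth interaction planted at one TF's variable motif position.

    ``nucleotide_effects[nt][experiment_type]`` is the expression shift (in
    expression units) applied to genes whose site carries ``nt`` under
    conditions of that experiment type.
    """

    tf_id: str
    motif_position: int  # 1-based
    nucleotide_effects: dict[str, dict[str, float]]
    regime: Regime = "null"

    def validate(self, experiment_types: Sequence[str]) -> None:
        for nt, eff in self.nucleotide_effects.items():
            if nt not in NUCLEOTIDES:
                raise ConfigError(f"unknown nucleotide {nt!r}")
            unknown = set(eff) - set(experiment_types)
            if unknown:
                raise ConfigError(f"unknown experiment types {unknown}")
        flat = [
            v for eff in self.nucleotide_effects.values() for v in eff.values()
        ]
        if self.regime == "null":
            if any(v != 0 for v in flat):
                raise ConfigError("null regime requires all effects to be 0")
            return
        if self.regime == "reversal":
            vecs = {
                nt: np.array([eff.get(t, 0.0) for t in experiment_types])
                for nt, eff in self.nucleotide_effects.items()
            }
            nts = sorted(vecs)
            for i, a in enumerate(nts):
                for b in nts[i + 1:]:
                    if np.ptp(vecs[a]) == 0 or np.ptp(vecs[b]) == 0:
                        continue
                    rho = spearmanr(vecs[a], vecs[b]).statistic
                    if rho < 0:
                        return
            raise ConfigError(
                "reversal regime requires two nucleotides with negatively "
                "rank-correlated effect vectors"
            )

    def effect(self, nucleotide: str, experiment_type: str) -> float:
        return self.nucleotide_effects.get(nucleotide, {}).get(experiment_type, 0.0)


def _default_experiment_types() -> dict[str, int]:
    return {"rich_media": 6, "sporulation": 6, "MMS": 6, "desiccation": 6}


@dataclass
class SyntheticScenario:
    """Configuration for one synthetic dataset.

    Defaults give a desk-scale compendium: 6 TFs with 8 bp motifs, one
    variable position each with three nucleotide groups of 6 single-primary
    target genes, and 24 experiments in 4 experiment-type classes.  Noise,
    baseline and condition-effect scales are in the same (log-like)
    expression units; noise_sd = 1 with per-condition effects of sd 0.5 is a
    typical signal-to-noise setting for normalized compendium data.
    """

    n_tfs: int = 6
    motif_length: int = 8
    variable_position: int = 4  # 1-based
    variant_nucleotides: tuple[str, ...] = ("A", "T", "C")
    genes_per_group: int = 6
    experiment_types: dict[str, int] = field(default_factory=_default_experiment_types)
    baseline_sd: float = 1.0
    condition_effect_sd: float = 0.5
    noise_sd: float = 1.0
    secondary_site_fraction: float = 0.3
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    go_signal: dict[str, str] | None = None  # nucleotide -> enriched process
    n_background_processes: int = 5
    background_annotation_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not MIN_MOTIF_LENGTH <= self.motif_length <= MAX_MOTIF_LENGTH:
            raise ConfigError(
                f"motif length {self.motif_length} outside "
                f"[{MIN_MOTIF_LENGTH}, {MAX_MOTIF_LENGTH}]"
            )
        if not 1 <= self.variable_position <= self.motif_length:
            raise ConfigError("variable position outside motif")
        if self.n_tfs < 1 or self.genes_per_group < 1:
            raise ConfigError("counts must be positive")
        if len(self.variant_nucleotides) < 2 or len(self.variant_nucleotides) > 4:
            raise ConfigError("need 2-4 variant nucleotides")
        if len(set(self.variant_nucleotides)) != len(self.variant_nucleotides):
            raise ConfigError("variant nucleotides must be distinct")
        if not self.experiment_types or any(v < 1 for v in self.experiment_types.values()):
            raise ConfigError("every experiment type needs >=1 condition")
        if any(sd < 0 for sd in (self.baseline_sd, self.condition_effect_sd, self.noise_sd)):
            raise ConfigError("standard deviations must be non-negative")
        if not 0 <= self.secondary_site_fraction <= 1:
            raise ConfigError("secondary_site_fraction must lie in [0, 1]")
        tf_ids = set(self.tf_ids)
        types = list(self.experiment_types)
        for pe in self.planted_effects:
            if pe.tf_id not in tf_ids:
                raise ConfigError(f"planted effect on unknown TF {pe.tf_id!r}")
            if pe.motif_position != self.variable_position:
                raise ConfigError(
                    "planted effect position must be the scenario's variable position"
                )
            if pe.regime != "null" and self.genes_per_group < 2:
                raise ConfigError("non-null regimes require groups of >=2 genes")
            pe.validate(types)

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i + 1:02d}" for i in range(self.n_tfs)]

    @property
    def condition_ids(self) -> list[str]:
        return [
            f"{t}_{i + 1:02d}"
            for t in self.experiment_types
            for i in range(self.experiment_types[t])
        ]


@dataclass
class ScenarioData:
    """A generated dataset plus its planted ground truth."""

    expression: ExpressionMatrix
    metadata: ConditionMetadata
    sites: list[BindingSiteAnnotation]
    go_map: dict[str, set[str]]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_expression_matrix(self.expression, outdir / "expression.tsv")
        write_condition_metadata(self.metadata, outdir / "conditions.tsv")
        write_binding_sites(self.sites, outdir / "sites.tsv")
        write_go_map(self.go_map, outdir / "go_map.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.6g")


def generate_scenario(config: SyntheticScenario) -> ScenarioData:
    """Generate expression, metadata, sites, GO map and truth for a scenario."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_baseline, rng_cond, rng_noise, rng_motif, rng_sites, rng_go = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )

    tf_ids = config.tf_ids
    cond_ids = config.condition_ids
    cond_types = [t for t in config.experiment_types
                  for _ in range(config.experiment_types[t])]
    planted = {pe.tf_id: pe for pe in config.planted_effects}

    # genes and primary sites: one consensus motif per TF, one variable position
    genes: list[str] = []
    gene_tf: list[str] = []
    gene_nt: list[str] = []
    sites: list[BindingSiteAnnotation] = []
    for tf in tf_ids:
        consensus = "".join(rng_motif.choice(list(NUCLEOTIDES), size=config.motif_length))
        for nt in config.variant_nucleotides:
            seq = (
                consensus[: config.variable_position - 1]
                + nt
                + consensus[config.variable_position:]
            )
            for k in range(config.genes_per_group):
                gene = f"{tf}_{nt}{k + 1:02d}"
                genes.append(gene)
                gene_tf.append(tf)
                gene_nt.append(nt)
                sites.append(make_site(tf, gene, seq, float(rng_sites.uniform(0.7, 1.0))))

    # sprinkled secondary sites for non-focal TFs (exercise the co-occurrence null)
    for gi, gene in enumerate(genes):
        if config.secondary_site_fraction and rng_sites.random() < config.secondary_site_fraction:
            others = [t for t in tf_ids if t != gene_tf[gi]]
            if others:
                other = others[int(rng_sites.integers(len(others)))]
                seq = "A" * config.motif_length
                sites.append(
                    make_site(other, gene, seq,
                              float(rng_sites.uniform(0.2 + 1e-6, 0.7 - 1e-6)))
                )

    # expression = baseline + condition effect + interaction + noise
    n_g, n_c = len(genes), len(cond_ids)
    baseline = rng_baseline.normal(0.0, config.baseline_sd, size=n_g)
    cond_effect = rng_cond.normal(0.0, config.condition_effect_sd, size=n_c)
    values = baseline[:, None] + cond_effect[None, :]
    for gi in range(n_g):
        pe = planted.get(gene_tf[gi])
        if pe is not None:
            values[gi] += np.array(
                [pe.effect(gene_nt[gi], t) for t in cond_types]
            )
    if config.noise_sd > 0:
        values = values + rng_noise.normal(0.0, config.noise_sd, size=(n_g, n_c))
    expression = ExpressionMatrix(genes, cond_ids, values)
    metadata = ConditionMetadata(dict(zip(cond_ids, cond_types)))

    # GO annotations: planted signal on the focal TF's groups, plus background
    go_map: dict[str, set[str]] = {}
    if config.go_signal:
        signal_tfs = [pe.tf_id for pe in config.planted_effects
                      if pe.regime != "null"] or tf_ids[:1]
        for gi, gene in enumerate(genes):
            if gene_tf[gi] in signal_tfs and gene_nt[gi] in config.go_signal:
                go_map.setdefault(gene, set()).add(config.go_signal[gene_nt[gi]])
    for gene in genes:
        for b in range(config.n_background_processes):
            if rng_go.random() < config.background_annotation_rate:
                go_map.setdefault(gene, set()).add(f"GO:BG{b + 1:04d}")

    # ground-truth table
    rows = []
    for tf in tf_ids:
        pe = planted.get(tf)
        for nt in config.variant_nucleotides:
            for t in config.experiment_types:
                rows.append(
                    (tf, config.variable_position,
                     pe.regime if pe else "null", nt, t,
                     pe.effect(nt, t) if pe else 0.0)
                )
    truth = pd.DataFrame(
        rows,
        columns=["tf_id", "motif_position", "regime", "nucleotide",
                 "experiment_type", "effect"],
    )
    return ScenarioData(expression, metadata, sites, go_map, truth)


# ---------------------------------------------------------------------------
# Canned scenarios
# ---------------------------------------------------------------------------

def null_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """All-null scenario: no interaction anywhere (type-I-error calibration)."""
    return SyntheticScenario(seed=seed, **overrides)


def reversal_effects(
    effect_size: float,
    up_type: str = "desiccation",
    down_type: str = "MMS",
) -> dict[str, dict[str, float]]:
    """Opposite-signed effect vectors for nucleotides A and T (C stays 0)."""
    return {
        "A": {up_type: +effect_size, down_type: -effect_size},
        "T": {up_type: -effect_size, down_type: +effect_size},
    }


def reversal_scenario(
    seed: int = 0, effect_size: float = 4.0, **overrides
) -> SyntheticScenario:
    """The bundled positive control: a sign-reversing variant on TF01.

    Genes with "A" at the variable position are induced under desiccation
    and repressed under MMS; "T" genes show the mirror image; "C" genes are
    inert.  The "A" group additionally carries a planted GO process
    ("GO:SPORULATION"), mirroring a sporulation-style enrichment.  The
    default effect size (4 expression units at noise_sd 1) is the
    calibration point at which every downstream test should fire.
    """
    cfg = SyntheticScenario(seed=seed, **overrides)
    cfg.planted_effects = [
        PlantedEffect(
            tf_id=cfg.tf_ids[0],
            motif_position=cfg.variable_position,
            nucleotide_effects=reversal_effects(effect_size),
            regime="reversal",
        )
    ]
    cfg.go_signal = {"A": "GO:SPORULATION"}
    return cfg


def affinity_scenario(
    seed: int = 0, effect_size: float = 4.0, scaling: float = 0.4, **overrides
) -> SyntheticScenario:
    """Same-signed effects of different magnitude (pure affinity model)."""
    cfg = SyntheticScenario(seed=seed, **overrides)
    cfg.planted_effects = [
        PlantedEffect(
            tf_id=cfg.tf_ids[0],
            motif_position=cfg.variable_position,
            nucleotide_effects={
                "A": {"desiccation": effect_size, "MMS": effect_size / 2},
                "T": {"desiccation": effect_size * scaling,
                      "MMS": effect_size * scaling / 2},
            },
            regime="affinity_scaling",
        )
    ]
    return cfg


def plant_cooccurrence(
    sites: Sequence[BindingSiteAnnotation],
    tf_id: str,
    motif_position: int,
    nucleotide: str,
    confounder_tf: str,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[BindingSiteAnnotation]:
    """Add confounding secondary sites to one variant's target genes.

    Every gene with a primary ``tf_id`` site carrying ``nucleotide`` at
    ``motif_position`` gains, with probability ``rate``, one secondary site
    (posterior uniform in (0.2, 0.7)) for ``confounder_tf``.  Returns a new
    site list; the input is not modified.
    """
    if not 0 <= rate <= 1:
        raise ConfigError("rate must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = list(sites)
    if rate == 0:
        return out
    length = next(
        (len(s.site_sequence) for s in sites if s.tf_id == confounder_tf), 8
    )
    seq = "A" * length
    targets = sorted({
        s.gene_id
        for s in sites
        if s.tf_id == tf_id
        and s.site_class == "primary"
        and s.site_sequence[motif_position - 1] == nucleotide
    })
    for gene in targets:
        if rng.random() < rate:
            out.append(
                make_site(confounder_tf, gene, seq,
                          float(rng.uniform(0.2 + 1e-6, 0.7 - 1e-6)))
            )
    return out
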