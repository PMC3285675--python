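"""End-to-end orchestration: candidate positions -> VDRE -> characterization.

The pipeline mirrors the analysis order of the underlying study: enumerate
testable variant positions, score each with the VDRE permutation test and
attach Storey q-values, then push the significant positions (raw p below
the gate, 0.05 by default, optionally an FDR gate) through the
condition-specificity, reversal, GO-enrichment and co-occurrence stages.
Every stage writes a TSV with floats at 6 significant digits, and a JSON
manifest records the config, per-stage seeds, input digests and row counts
so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .condition_specificity import (
    clustering_permutation_test,
    order_experiments,
    reversal_assessment,
)
from .enrichment import any_cooccurrence_flag, cooccurrence_screen, go_enrichment
from .io_formats import (
    BindingSiteAnnotation,
    ConditionMetadata,
    ExpressionMatrix,
    VariantGrouping,
    build_variant_groupings,
    motif_length,
    read_binding_sites,
    read_condition_metadata,
    read_expression_matrix,
    read_go_map,
)
from .synthetic_data import (
    SyntheticScenario,
    affinity_scenario,
    generate_scenario,
    null_scenario,
    reversal_scenario,
)
from .vdre import estimate_fdr, min_comparison_count, rank_profiles, vdre_permutation_test

logger = logging.getLogger("bsmv")

FLOAT_FORMAT = "%.6g"


def candidate_groupings(
    sites: Sequence[BindingSiteAnnotation],
    expression: ExpressionMatrix,
    gene_filter: str = "single_primary",
    single_primary_scope: str = "all_tfs",
) -> list[VariantGrouping]:
    """All testable (TF, position) groupings, ordered by TF then position."""
    expr_genes = set(expression.gene_ids)
    out: list[VariantGrouping] = []
    for tf in sorted({s.tf_id for s in sites}):
        for pos in range(1, motif_length(sites, tf) + 1):
            grouping = build_variant_groupings(
                sites, tf, pos,
                gene_filter=gene_filter,
                single_primary_scope=single_primary_scope,
                expression_genes=expr_genes,
            )
            if grouping.testable:
                out.append(grouping)
    return out


def run_vdre(
    sites: Sequence[BindingSiteAnnotation],
    expression: ExpressionMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
    gene_filter: str = "single_primary",
    fdr_lambda: float = 0.5,
) -> tuple[pd.DataFrame, dict[tuple[str, int], VariantGrouping]]:
    """VDRE permutation test over every testable position, plus q-values.

    Returns the results table and a (tf_id, position) -> grouping lookup for
    the downstream stages.  One random sub-stream per position is derived
    from ``seed``, so adding positions does not perturb existing ones.
    """
    ranks = rank_profiles(expression)
    groupings = candidate_groupings(sites, expression, gene_filter)
    lookup = {(g.tf_id, g.motif_position): g for g in groupings}
    rows = []
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(groupings))
    for grouping, child in zip(groupings, streams):
        res = vdre_permutation_test(
            grouping, ranks, n_permutations=n_permutations,
            rng=np.random.default_rng(child), seed=seed,
        )
        rows.append({
            "tf_id": res.tf_id,
            "motif_position": res.motif_position,
            "group_sizes": ";".join(
                f"{nt}:{n}" for nt, n in sorted(res.group_sizes.items())
            ),
            "F": res.F,
            "N": res.N,
            "M": res.M,
            "min_comparisons": min_comparison_count(grouping),
            "p_value": res.p_value,
            "n_permutations": res.n_permutations,
            "seed": seed,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = estimate_fdr(df["p_value"].to_numpy(), lam=fdr_lambda)
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df, lookup


def significant_positions(
    vdre_df: pd.DataFrame, alpha: float = 0.05, q_max: float | None = None
) -> pd.DataFrame:
    """Rows passing the significance gate (raw p, optionally also q-value)."""
    mask = vdre_df["p_value"] < alpha
    if q_max is not None:
        mask &= vdre_df["q_value"] <= q_max
    return vdre_df[mask]


def run_condition_specificity(
    significant: pd.DataFrame,
    lookup: Mapping[tuple[str, int], VariantGrouping],
    expression: ExpressionMatrix,
    metadata: ConditionMetadata,
    n_permutations: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Clustering + reversal + slope tests for every variant pair of every
    significant position."""
    ranks = rank_profiles(expression)
    rows = []
    ss = np.random.SeedSequence(seed)
    for _, vrow in significant.iterrows():
        grouping = lookup[(vrow["tf_id"], int(vrow["motif_position"]))]
        pairs = list(combinations(grouping.testable_nucleotides, 2))
        streams = ss.spawn(len(pairs))
        for pair, child in zip(pairs, streams):
            ordering = order_experiments(grouping, expression, pair)
            clust = clustering_permutation_test(
                ordering, metadata, n_permutations=n_permutations,
                rng=np.random.default_rng(child), seed=seed,
            )
            rev = reversal_assessment(grouping, ranks, ordering, pair)
            rows.append({
                "tf_id": grouping.tf_id,
                "motif_position": grouping.motif_position,
                "variant_a": pair[0],
                "variant_b": pair[1],
                "S": clust.S,
                "C_W": clust.C_W,
                "C_Q": clust.C_Q,
                "A": clust.A,
                "B": clust.B,
                "clustering_p": clust.p_value,
                "reversal_rho": rev.rank_reversal_stat,
                "reversal_p": rev.rank_reversal_p,
                "slope_a": rev.slope_a,
                "slope_a_p": rev.slope_a_p,
                "slope_b": rev.slope_b,
                "slope_b_p": rev.slope_b_p,
                "passes_both": rev.passes_both,
                "n_permutations": n_permutations,
                "seed": seed,
            })
    return pd.DataFrame(rows, columns=[
        "tf_id", "motif_position", "variant_a", "variant_b", "S", "C_W", "C_Q",
        "A", "B", "clustering_p", "reversal_rho", "reversal_p", "slope_a",
        "slope_a_p", "slope_b", "slope_b_p", "passes_both", "n_permutations",
        "seed",
    ])


def run_enrichment(
    significant: pd.DataFrame,
    lookup: Mapping[tuple[str, int], VariantGrouping],
    go_map: Mapping[str, set[str]],
    n_permutations: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    rows = []
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(max(len(significant), 1))
    for (_, vrow), child in zip(significant.iterrows(), streams):
        grouping = lookup[(vrow["tf_id"], int(vrow["motif_position"]))]
        for er in go_enrichment(
            grouping, go_map, n_permutations=n_permutations,
            rng=np.random.default_rng(child), seed=seed,
        ):
            rows.append({
                "tf_id": er.tf_id,
                "motif_position": er.motif_position,
                "nucleotide": er.nucleotide,
                "go_process": er.go_process,
                "observed_count": er.observed_count,
                "group_size": er.group_size,
                "p_value": er.p_value,
                "n_permutations": er.n_permutations,
                "seed": seed,
            })
    return pd.DataFrame(rows, columns=[
        "tf_id", "motif_position", "nucleotide", "go_process",
        "observed_count", "group_size", "p_value", "n_permutations", "seed",
    ])


def run_cooccurrence(
    significant: pd.DataFrame,
    lookup: Mapping[tuple[str, int], VariantGrouping],
    sites: Sequence[BindingSiteAnnotation],
    alpha: float = 0.01,
) -> pd.DataFrame:
    frames = []
    for _, vrow in significant.iterrows():
        grouping = lookup[(vrow["tf_id"], int(vrow["motif_position"]))]
        screen = cooccurrence_screen(grouping, sites, alpha=alpha)
        if len(screen):
            screen = screen.assign(any_flag_for_position=any_cooccurrence_flag(screen))
            frames.append(screen)
    if frames:
        return pd.concat(frames, ignore_index=True)
    return pd.DataFrame(columns=[
        "tf_id", "motif_position", "nucleotide", "other_tf", "a", "b", "c",
        "d", "p_value", "flagged", "any_flag_for_position",
    ])


def summarize(vdre_df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-TF and global counts of considered vs functional positions."""
    if "p_value" not in vdre_df.columns:
        raise ValueError("vdre table lacks a p_value column")
    rows = []
    for tf, sub in vdre_df.groupby("tf_id", sort=True):
        n_cons = len(sub)
        n_func = int((sub["p_value"] < alpha).sum())
        rows.append((tf, n_cons, n_func, 100.0 * n_func / n_cons))
    total_cons = len(vdre_df)
    total_func = int((vdre_df["p_value"] < alpha).sum())
    rows.append((
        "ALL", total_cons, total_func,
        100.0 * total_func / total_cons if total_cons else 0.0,
    ))
    return pd.DataFrame(
        rows,
        columns=["tf_id", "positions_considered", "positions_functional",
                 "percent_functional"],
    )


# ---------------------------------------------------------------------------
# Full run with manifest
# ---------------------------------------------------------------------------

_SCENARIOS = {
    "null": null_scenario,
    "reversal": reversal_scenario,
    "affinity": affinity_scenario,
}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_inputs(config: Mapping) -> tuple[
    ExpressionMatrix, ConditionMetadata, list[BindingSiteAnnotation],
    dict[str, set[str]], dict[str, str],
]:
    """Resolve a run config into in-memory inputs plus file digests.

    The config either names a synthetic scenario (``synthetic`` key with a
    ``scenario`` name and scenario keyword overrides) or points at the four
    input files (``inputs`` key with expression/conditions/sites and an
    optional go_map).
    """
    digests: dict[str, str] = {}
    if "synthetic" in config:
        params = dict(config["synthetic"])
        name = params.pop("scenario", "null")
        if name not in _SCENARIOS:
            raise ValueError(f"unknown scenario {name!r}; use one of {sorted(_SCENARIOS)}")
        data = generate_scenario(_SCENARIOS[name](**params))
        return data.expression, data.metadata, data.sites, data.go_map, digests
    if "inputs" not in config:
        raise ValueError("config needs a 'synthetic' or an 'inputs' section")
    paths = {k: Path(v) for k, v in config["inputs"].items()}
    for key in ("expression", "conditions", "sites"):
        if key not in paths:
            raise ValueError(f"inputs section lacks {key!r}")
        if not paths[key].exists():
            raise FileNotFoundError(f"input file for {key!r} not found: {paths[key]}")
        digests[key] = _digest(paths[key])
    expression = read_expression_matrix(paths["expression"])
    metadata = read_condition_metadata(paths["conditions"])
    sites = read_binding_sites(paths["sites"])
    go_map: dict[str, set[str]] = {}
    if "go_map" in paths:
        digests["go_map"] = _digest(paths["go_map"])
        go_map = read_go_map(paths["go_map"])
    return expression, metadata, sites, go_map, digests


def run_pipeline(config: Mapping, outdir: str | Path) -> dict:
    """Run all stages, write per-stage TSVs plus ``manifest.json``.

    Returns the manifest.  Config keys (with defaults): ``seed`` (0),
    ``n_perm_vdre`` (1000), ``n_perm_clustering`` (10000), ``n_perm_go``
    (10000), ``alpha`` (0.05), ``q_max`` (None), ``cooccurrence_alpha``
    (0.01), ``gene_filter`` ("single_primary"), ``fdr_lambda`` (0.5), and a
    ``synthetic`` or ``inputs`` section.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", 0.05))
    q_max = config.get("q_max")
    expression, metadata, sites, go_map, digests = load_inputs(config)
    if not sites:
        raise ValueError("binding-site input is empty")

    ss = np.random.SeedSequence(seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(("vdre", "condition_specificity", "enrichment"), ss.spawn(3))
    }

    vdre_df, lookup = run_vdre(
        sites, expression,
        n_permutations=int(config.get("n_perm_vdre", 1000)),
        seed=stage_seeds["vdre"],
        gene_filter=config.get("gene_filter", "single_primary"),
        fdr_lambda=float(config.get("fdr_lambda", 0.5)),
    )
    sig = significant_positions(vdre_df, alpha=alpha,
                                q_max=None if q_max is None else float(q_max))
    cs_df = run_condition_specificity(
        sig, lookup, expression, metadata,
        n_permutations=int(config.get("n_perm_clustering", 10000)),
        seed=stage_seeds["condition_specificity"],
    )
    enr_df = run_enrichment(
        sig, lookup, go_map,
        n_permutations=int(config.get("n_perm_go", 10000)),
        seed=stage_seeds["enrichment"],
    )
    cooc_df = run_cooccurrence(
        sig, lookup, sites, alpha=float(config.get("cooccurrence_alpha", 0.01))
    )
    summary_df = summarize(vdre_df, alpha=alpha)

    tables = {
        "vdre.tsv": vdre_df,
        "condition_specificity.tsv": cs_df,
        "enrichment.tsv": enr_df,
        "cooccurrence.tsv": cooc_df,
        "summary.tsv": summary_df,
    }
    for name, df in tables.items():
        df.to_csv(outdir / name, sep="\t", index=False, float_format=FLOAT_FORMAT)

    manifest = {
        "version": __version__,
        "config": json.loads(json.dumps(dict(config), default=str)),
        "seed": seed,
        "stage_seeds": stage_seeds,
        "input_digests": digests,
        "row_counts": {name: int(len(df)) for name, df in tables.items()},
        "n_significant_positions": int(len(sig)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info(
        "pipeline complete: %d positions tested, %d significant at p<%g",
        len(vdre_df), len(sig), alpha,
    )
    return manifest
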