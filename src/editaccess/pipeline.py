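"""End-to-end orchestration of the synthetic reproduction scenario.

The study design: a fixed panel of designed 3' UTRs (the "genome") is folded
once to obtain target-site accessibilities for the unedited and edited
variants; cohorts of individuals are then simulated on top of it, sites are
called from pileups and filtered, and the population, structure and
miRNA-targeting analyses are run.  Each analysis returns the synthetic
counterpart of one of the simulation study's headline observations, and
:func:`run_pipeline` writes the corresponding artifacts plus a
machine-readable summary.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io as eio
from .config import RunConfig
from .mirtarget import find_seed_matches, stratified_comparison
from .popstats import EditingMatrix, prevalence_table
from .sitecall import a2g_fraction, filter_sites, sites_from_results
from .structacc import (
    ViennaEngine,
    accessibility_expression_correlation,
    fold_sequence,
    fold_window,
    relative_accessibility,
)
from .syndata import (
    CohortData,
    CohortParams,
    MIR24,
    SyntheticTranscript,
    default_population_config,
    editing_accessibility_profile,
    generate_annotation_tracks,
    generate_population,
    make_gene_panel,
    simulate_cohort,
    simulate_pileup,
)

__all__ = [
    "PanelFold",
    "fold_gene_panel",
    "build_cohort",
    "ago2_editing_correlation",
    "adar1_stratified_shift",
    "ago2_kd_editing_contrast",
    "distance_accessibility_correlation",
    "cohort_pileup",
    "run_pipeline",
    "summary_report",
]


@dataclass
class PanelFold:
    """Folding products of one panel gene (unedited and edited variants)."""

    gene_id: str
    pair_table_unedited: np.ndarray
    pair_table_edited: np.ndarray | None
    acc_unedited: np.ndarray
    acc_edited: np.ndarray | None
    target_acc_u: float | None
    target_acc_e: float | None
    delta_at_target: float | None
    distance: int | None
    site_in_window: int | None


def fold_gene_panel(
    genes: Sequence[SyntheticTranscript],
    window: int = 1001,
    engine: ViennaEngine | None = None,
) -> dict[str, PanelFold]:
    """Fold every panel gene; record target-site accessibilities.

    The 7mer accessibility at a target site is read at the centre of the
    seed interval.  Genes without an editing site are folded once (their
    edited accessibility equals the unedited one by construction).
    """
    engine = engine or ViennaEngine()
    folds: dict[str, PanelFold] = {}
    for gene in genes:
        if gene.edit_pos is not None:
            fu, fe, start = fold_window(gene.sequence, gene.edit_pos, window, engine)
            site_in_window = gene.edit_pos - start
            pt_e, acc_e = fe.pair_table, fe.accessibility
        else:
            fu = fold_sequence(gene.sequence, engine)
            start, site_in_window = 0, None
            fe, pt_e, acc_e = None, None, None
        t_acc_u = t_acc_e = delta = None
        dist = gene.target_distance
        if gene.target_interval is not None:
            centre = (gene.target_interval[0] + gene.target_interval[1]) // 2 - start
            t_acc_u = float(fu.accessibility[centre])
            t_acc_e = float(acc_e[centre]) if acc_e is not None else t_acc_u
            floor = 1e-8
            delta = float(
                np.log2(max(t_acc_e, floor)) - np.log2(max(t_acc_u, floor))
            )
        folds[gene.gene_id] = PanelFold(
            gene.gene_id,
            fu.pair_table,
            pt_e,
            fu.accessibility,
            acc_e,
            t_acc_u,
            t_acc_e,
            delta,
            dist,
            site_in_window,
        )
    return folds


def panel_accessibilities(
    genes: Sequence[SyntheticTranscript],
    base_accessibility: float = 0.7,
) -> dict[str, tuple[float, float]]:
    """Target-site accessibilities fed to the degradation model.

    These are the model-level quantities of the simulation: a distance-
    decaying editing effect (see
    :func:`editaccess.syndata.editing_accessibility_profile`) whose sign and
    spatial scale mirror the folded near-site behaviour.  Genes without an
    editing site keep equal accessibilities for both variants.
    """
    out = {}
    for g in genes:
        if g.target_interval is None:
            continue
        if g.edit_pos is None or g.target_distance is None:
            out[g.gene_id] = (base_accessibility, base_accessibility)
        else:
            out[g.gene_id] = editing_accessibility_profile(
                g.target_distance, base_accessibility
            )
    return out


def build_cohort(
    genes: Sequence[SyntheticTranscript],
    seed: int,
    n_per_population: int = 100,
    k: float = 1.0,
    params: CohortParams | None = None,
) -> CohortData:
    """Simulate one cohort of individuals over the gene panel."""
    params = params or CohortParams(k=k)
    if params.k != k:
        params = CohortParams(**{**asdict(params), "k": k})
    config = default_population_config(n_per_population, seed=seed, k=k)
    profiles = generate_population(config)
    return simulate_cohort(
        profiles, genes, panel_accessibilities(genes), params, seed=seed + 1
    )


def ago2_editing_correlation(cohort: CohortData) -> tuple[float, dict[str, float]]:
    """Pearson correlation of AGO2 expression with mean observed editing.

    Mean editing per individual is taken over measured levels (alt/depth) at
    the cohort's edited genes, testable cells only.  The correlation is
    computed within each population (between-population differences in ADAR
    expression would otherwise enter as noise) and averaged.  Returns the
    mean r and the per-population values.
    """
    matrix = cohort.to_editing_matrix()
    mean_editing = matrix.levels.mean(axis=0)
    per_pop: dict[str, float] = {}
    for pop in sorted(cohort.profiles["population"].unique()):
        ids = [
            i
            for i in mean_editing.index
            if cohort.profiles.loc[i, "population"] == pop
            and not np.isnan(mean_editing[i])
        ]
        r, _ = sps.pearsonr(
            cohort.profiles.loc[ids, "AGO2"], mean_editing[ids]
        )
        per_pop[pop] = float(r)
    return float(np.mean(list(per_pop.values()))), per_pop


def adar1_stratified_shift(
    cohort: CohortData, max_distance: int = 500, covariate_stratum: int | None = None
) -> dict:
    """ADAR1 high-vs-low expression contrast for target genes.

    Eligible genes carry an editing site within ``max_distance`` nt of a
    miRNA target site; control genes have no editing site.  Covariates (AGO2
    and miRNA level) must be matched between the compared tertiles.  Returns
    the per-gene log2 fold changes and their medians.
    """
    eligible = [
        g.gene_id
        for g in cohort.genes
        if g.edit_pos is not None
        and g.target_interval is not None
        and (g.target_distance or 0) <= max_distance
    ]
    control = [g.gene_id for g in cohort.genes if g.edit_pos is None]
    mirna_cols = [c for c in cohort.profiles.columns if c.startswith("miR")]
    comp = stratified_comparison(
        cohort.expression,
        cohort.profiles,
        grouping="ADAR1",
        covariates=["AGO2"] + mirna_cols[:1],
        eligible_genes=eligible,
        control_genes=control,
        covariate_stratum=covariate_stratum,
    )
    return {
        "comparison": comp,
        "median_log2fc_edited": float(comp.log2_fold_change.median())
        if comp.feasible and len(comp.log2_fold_change)
        else float("nan"),
        "median_log2fc_no_editing": float(comp.control_log2_fold_change.median())
        if comp.feasible and len(comp.control_log2_fold_change)
        else float("nan"),
    }


def ago2_kd_editing_contrast(
    genes: Sequence[SyntheticTranscript],
    seed: int,
    n_per_population: int = 100,
    k: float = 1.0,
    params: CohortParams | None = None,
) -> dict:
    """Simulated AGO2 knockdown: editing change at near-target vs no-target.

    The knockdown cohort reuses the control cohort's individuals and noise
    stream but removes AGO2-miRNA degradation (k -> 0).  Reported are the
    mean editing differences (KD minus control) for sites near a target and
    for sites in genes without target sites, plus the rank-sum p between the
    two groups of per-gene differences.
    """
    control = build_cohort(genes, seed, n_per_population, k=k, params=params)
    kd = build_cohort(genes, seed, n_per_population, k=0.0, params=params)
    diff = (kd.observed_levels - control.observed_levels).mean(axis=1)
    near = [
        g.gene_id
        for g in genes
        if g.edit_pos is not None and g.target_interval is not None
    ]
    no_target = [
        g.gene_id for g in genes if g.edit_pos is not None and g.target_interval is None
    ]
    from .popstats import rank_sum_test

    near_diff = diff.loc[near]
    ctrl_diff = diff.loc[no_target]
    p = (
        rank_sum_test(near_diff.to_numpy(), ctrl_diff.to_numpy())
        if len(near_diff) and len(ctrl_diff)
        else float("nan")
    )
    return {
        "near_target_mean_diff": float(near_diff.mean()),
        "no_target_mean_diff": float(ctrl_diff.mean()),
        "p": float(p),
        "per_gene_diff": diff,
    }


def distance_accessibility_correlation(
    cohort: CohortData,
    edited_min_level: float = 0.3,
    min_individuals: int = 3,
    min_expression: float = 0.1,
    window: int = 10,
) -> tuple[float, float, pd.DataFrame]:
    """Correlation of target-site accessibility change with expression ratio.

    Per gene: individuals with measured editing level >= ``edited_min_level``
    form the edited group, individuals with no edited reads the unedited
    group (testable cells only, at least ``min_individuals`` per side); the
    response is the log2 ratio of their mean expression.  The accessibility
    change is the cohort's own relative accessibility at the closest target
    site.  Genes are grouped by editing-site-to-target distance into sliding
    windows before the Pearson correlation.
    """
    matrix = cohort.to_editing_matrix()
    rows = []
    for g in cohort.genes:
        if g.edit_pos is None or g.target_interval is None:
            continue
        acc_u, acc_e = cohort.accessibilities[g.gene_id]
        levels = matrix.levels.loc[g.gene_id]
        alts = matrix.alts.loc[g.gene_id]
        testable = matrix.testable.loc[g.gene_id]
        expr = cohort.expression.loc[g.gene_id]
        if expr.mean() < min_expression:
            continue
        edited_ids = levels.index[(levels >= edited_min_level) & testable]
        unedited_ids = levels.index[(alts == 0) & testable]
        if len(edited_ids) < min_individuals or len(unedited_ids) < min_individuals:
            continue
        ratio = expr[edited_ids].mean() / expr[unedited_ids].mean()
        rows.append(
            {
                "gene": g.gene_id,
                "distance": g.target_distance,
                "delta": float(np.log2(acc_e / acc_u)),
                "log2_ratio": float(np.log2(ratio)),
            }
        )
    per_gene = pd.DataFrame(rows)
    if per_gene.empty:
        return float("nan"), float("nan"), per_gene
    r, p, table = accessibility_expression_correlation(per_gene, window=window)
    return r, p, table


def cohort_pileup(cohort: CohortData, seed: int = 0) -> list:
    """Materialise pileup observations for every edited gene x individual."""
    rng = np.random.default_rng(seed)
    observations = []
    for g in cohort.genes:
        if g.edit_pos is None:
            continue
        gid = g.gene_id
        for ind in cohort.profiles.index:
            depth = int(cohort.depths.loc[gid, ind])
            obs = simulate_pileup(
                float(cohort.observed_levels.loc[gid, ind]),
                depth,
                error_rate=cohort.params.error_rate,
                seed=int(rng.integers(2**31)),
                contig=gid,
                pos0=g.edit_pos,
                individual=ind,
            )
            observations.append(obs)
    return observations


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages end to end; write artifacts and a summary.

    Stage order: syndata -> sitecall -> popstats -> structacc -> mirtarget.
    Every output file name carries the configuration digest; the summary JSON
    aggregates the headline statistics.  A stage failure aborts the run with
    the failing stage named, keeping partial outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    summary: dict = {
        "config_digest": digest,
        "seed": config.seed,
        "stages": {},
    }
    stage = "syndata"
    try:
        if not config.run_syndata:
            if not (config.fasta and config.pileup):
                raise FileNotFoundError(
                    "syndata stage disabled but no fasta/pileup inputs provided"
                )
            raise NotImplementedError(
                "external-input mode expects pre-simulated artifacts"
            )
        genes = make_gene_panel(
            n_edited_target=config.n_edited_target,
            n_edited_no_target=config.n_edited_no_target,
            n_unedited_target=config.n_unedited_target,
            utr_length=config.utr_length,
            seed=config.seed,
        )
        engine = ViennaEngine(
            u=config.accessibility_u, L=config.accessibility_L, W=config.accessibility_W
        )
        folds = fold_gene_panel(genes, window=config.fold_window, engine=engine)
        cohort = build_cohort(
            genes, config.seed, config.n_per_population, k=config.degradation_k
        )
        eio.write_fasta(
            {g.gene_id: g.sequence for g in genes},
            out / f"utrs.{digest}.fa",
            header_note=f"seed={config.seed}",
        )
        eio.write_expression(cohort.expression, out / f"expression.{digest}.tsv")
        observations = cohort_pileup(cohort, seed=config.seed + 2)
        eio.write_pileup(observations, out / f"pileup.{digest}.tsv")
        tracks = generate_annotation_tracks(genes, snp_density=0.0, seed=config.seed)
        summary["stages"]["syndata"] = {
            "n_genes": len(genes),
            "n_individuals": len(cohort.profiles),
            "n_observations": len(observations),
        }

        stage = "sitecall"
        if config.run_sitecall:
            results = filter_sites(
                observations,
                tracks,
                min_depth=config.min_depth,
                min_alt=config.min_alt,
                min_level=config.min_level,
                min_llr=config.min_llr,
            )
            sites = sites_from_results(results, tracks)
            eio.write_site_table(results, out / f"sites.{digest}.vcf.tsv")
            frac = a2g_fraction([r.observation for r in results if r.passed]) if sites else float("nan")
            by_context = {k: int(v) for k, v in pd.Series([s.context for s in sites]).value_counts().items()}
            summary["stages"]["sitecall"] = {
                "n_observations": len(results),
                "n_passed": sum(r.passed for r in results),
                "a2g_fraction": frac,
                "sites_by_context": by_context,
            }

        stage = "popstats"
        if config.run_popstats:
            matrix = cohort.to_editing_matrix()
            prev = prevalence_table(matrix)
            prev.to_csv(out / f"prevalence.{digest}.tsv", sep="\t")
            summary["stages"]["popstats"] = {
                "prevalence_categories": {k: int(v) for k, v in prev["category"].value_counts().items()},
            }

        stage = "structacc"
        if config.run_structacc:
            deltas = [
                f.delta_at_target for f in folds.values() if f.delta_at_target is not None
            ]
            summary["stages"]["structacc"] = {
                "mean_delta_at_target": float(np.mean(deltas)) if deltas else None,
                "n_folded": len(folds),
            }

        stage = "mirtarget"
        if config.run_mirtarget:
            r_ago2, _perpop = ago2_editing_correlation(cohort)
            shift = adar1_stratified_shift(cohort, config.max_target_distance)
            r_dist, p_dist, table = distance_accessibility_correlation(
                cohort, window=config.distance_window
            )
            table.to_csv(out / f"distance_windows.{digest}.tsv", sep="\t", index=False)
            summary["stages"]["mirtarget"] = {
                "ago2_editing_r": r_ago2,
                "adar1_shift_edited_median": shift["median_log2fc_edited"],
                "adar1_shift_no_editing_median": shift["median_log2fc_no_editing"],
                "accessibility_expression_r": r_dist,
                "accessibility_expression_p": p_dist,
            }
    except Exception as err:
        summary["failed_stage"] = stage
        summary["error"] = str(err)
        (out / f"summary.{digest}.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / f"summary.{digest}.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


_FIGURE_ANALOGS = [
    ("syndata", "population profiles and designed UTRs (cohort scaffold)"),
    ("sitecall", "site counts by genomic context; A-to-G fraction"),
    ("popstats", "prevalence histogram; differential-editing counts"),
    ("structacc", "relative accessibility at target sites (direction: negative)"),
    ("mirtarget", "AGO2-editing correlation (+); ADAR1 shift (+ vs 0); "
                  "distance-windowed accessibility-expression correlation (-)"),
]


def summary_report(out_dir: str | Path) -> str:
    """Human-readable report over a run directory's summary JSON."""
    out = Path(out_dir)
    candidates = sorted(out.glob("summary.*.json"))
    if not candidates:
        raise FileNotFoundError(f"no summary JSON under {out}")
    summary = json.loads(candidates[-1].read_text())
    lines = [
        f"run summary (config {summary['config_digest']}, seed {summary['seed']})",
        "-" * 60,
    ]
    for stage, description in _FIGURE_ANALOGS:
        info = summary["stages"].get(stage)
        if info is None:
            lines.append(f"{stage:10s} SKIPPED  {description}")
            continue
        lines.append(f"{stage:10s} done  {description}")
        for k, v in info.items():
            lines.append(f"    {k}: {v}")
    if "failed_stage" in summary:
        lines.append(f"FAILED at stage {summary['failed_stage']}: {summary['error']}")
    return "\n".join(lines)
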