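"""End-to-end orchestration of the subtype-discovery analysis.

The stages mirror the analysis contract: preprocess each layer, build the
chromosome-21 co-expression clusters, consensus-cluster the trisomic samples,
derive composite scores, run the differential contrasts, score the ratio
classifiers, and assess longitudinal stability.  ``analyze_cohort`` runs the
whole chain in memory on a :class:`~trisomics.sim.MultiOmicsCohort`;
``run_pipeline`` adds file output plus a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import RatioIndex, combine_indexes, evaluate_index
from .coexpression import cluster_genes, correlation_matrix
from .consensus import assign_subtypes, run_consensus, select_k
from .preprocess import (adjust_covariates, log2_transform, mask_outliers_iqr,
                         median_normalize, replace_zeros, zscore_vs_controls)
from .scores import cytokine_score, polygenic_score, select_score_analytes
from .sim import MultiOmicsCohort, substream
from .stats import ContrastSpec, gsea_preranked, linear_diff, longitudinal_stability
from .stats import GeneSet, correlate_feature_vs_layer

logger = logging.getLogger(__name__)

COVARIATES = ("age", "sex", "source")

__all__ = ["AnalysisResult", "default_ratio_indexes", "analyze_cohort", "run_pipeline"]


def default_ratio_indexes() -> list[RatioIndex]:
    """The four inflammatory-marker / lymphocyte ratio indexes."""
    return [
        RatioIndex("CRP_to_abs_lymphocytes", "somalike_proteome", "CRP",
                   "cbc", "abs_lymphocytes"),
        RatioIndex("IL6_to_pct_lymphocytes", "somalike_proteome", "IL-6",
                   "cbc", "pct_lymphocytes"),
        RatioIndex("SAA1_to_abs_lymphocytes", "somalike_proteome", "SAA1",
                   "cbc", "abs_lymphocytes"),
        RatioIndex("neutrophils_to_abs_lymphocytes", "cell_fractions", "neutrophils",
                   "cbc", "abs_lymphocytes"),
    ]


@dataclass
class AnalysisResult:
    """Everything the pipeline derives from one cohort."""

    gene_clusters: object = None
    correlation: object = None
    consensus: object = None
    selected_k: int | None = None
    subtypes: pd.Series | None = None
    scores: dict = field(default_factory=dict)
    differentials: dict = field(default_factory=dict)
    score_analytes: list = field(default_factory=list)
    classifier: dict = field(default_factory=dict)
    stability: pd.DataFrame | None = None
    gsea: list = field(default_factory=list)
    intermediates: dict = field(default_factory=dict)


def _grouped_samples(samples: pd.DataFrame, subtypes: pd.Series | None) -> pd.DataFrame:
    """Sample table with a 'group' column: D21 for euploids, subtype for T21."""
    out = samples.copy()
    out["group"] = np.where(out["karyotype"] == "D21", "D21", "")
    if subtypes is not None:
        out.loc[subtypes.index, "group"] = subtypes
    else:
        out.loc[out["karyotype"] == "T21", "group"] = out.loc[
            out["karyotype"] == "T21", "subtype_true"]
    return out


def preprocess_expression(cohort: MultiOmicsCohort, pseudocount: float = 1.0) -> dict:
    """Log2, covariate adjustment, and the two z-score views of expression."""
    expr = cohort.layers["expression"]
    log2 = log2_transform(expr, pseudocount)
    adjusted = adjust_covariates(log2, cohort.samples, COVARIATES)
    hsa21 = list(cohort.feature_truth["expression"]
                 .query("chromosome == '21' and coding").index)
    t21 = cohort.t21_ids
    z_ctrl = zscore_vs_controls(adjusted, cohort.control_ids)
    z_t21 = zscore_vs_controls(adjusted.subset_samples(t21), t21)
    return {"log2": log2, "adjusted": adjusted, "hsa21_genes": hsa21,
            "z_vs_controls": z_ctrl, "z_among_t21": z_t21}


def preprocess_panel(cohort: MultiOmicsCohort, layer: str) -> dict:
    """Log2 + per-karyotype outlier mask + covariate adjustment for a panel."""
    m = cohort.layers[layer]
    log2 = log2_transform(m, 0.0)
    masked = mask_outliers_iqr(log2, cohort.samples["karyotype"])
    adjusted = adjust_covariates(masked, cohort.samples, COVARIATES)
    return {"log2": masked, "adjusted": adjusted}


def preprocess_metabolome(cohort: MultiOmicsCohort, seed: int = 0) -> dict:
    """Zero replacement, median normalisation, log2, outlier mask, adjustment."""
    m = cohort.layers["metabolome"]
    rng = substream(seed, "preprocess_metabolome")
    filled = replace_zeros(m, rng)
    normed = median_normalize(filled)
    log2 = log2_transform(normed, 0.0)
    masked = mask_outliers_iqr(log2, cohort.samples["karyotype"])
    adjusted = adjust_covariates(masked, cohort.samples, COVARIATES)
    return {"log2": masked, "adjusted": adjusted}


def analyze_cohort(cohort: MultiOmicsCohort, max_k: int = 6, n_iter: int = 100,
                   p_item: float = 0.8, seed: int = 0, k_override: int | None = None,
                   truth_for_classifier: bool = True,
                   gene_sets: list | None = None, n_perm: int = 500) -> AnalysisResult:
    """Run the full analysis chain on a cohort and return all artefacts."""
    res = AnalysisResult()
    expr = preprocess_expression(cohort)
    res.intermediates["expression"] = expr

    # -- chromosome-21 co-expression clusters --------------------------------
    z_t21_hsa21 = expr["z_among_t21"].subset_features(expr["hsa21_genes"])
    res.correlation = correlation_matrix(z_t21_hsa21)
    res.gene_clusters = cluster_genes(res.correlation, k=2)

    # -- consensus subtypes ---------------------------------------------------
    res.consensus = run_consensus(z_t21_hsa21, max_k=max_k, n_iter=n_iter,
                                  p_item=p_item, seed=seed)
    res.selected_k = k_override if k_override is not None else select_k(res.consensus)
    z_ctrl_t21 = expr["z_vs_controls"].subset_samples(cohort.t21_ids)
    anchor = polygenic_score(z_ctrl_t21, res.gene_clusters.genes_in(1), "cluster1").values
    res.subtypes = assign_subtypes(res.consensus, res.selected_k, anchor=anchor)

    # -- polygenic scores -----------------------------------------------------
    res.scores["cluster1"] = polygenic_score(z_ctrl_t21, res.gene_clusters.genes_in(1),
                                             "cluster1")
    res.scores["cluster2"] = polygenic_score(z_ctrl_t21, res.gene_clusters.genes_in(2),
                                             "cluster2")

    grouped = _grouped_samples(cohort.samples, res.subtypes)

    # -- expression contrasts (dosage + transporter panel) -------------------
    t21_spec = ContrastSpec("karyotype", "D21", "T21", covariates=COVARIATES)
    res.differentials["expression:T21_vs_D21"] = linear_diff(
        expr["log2"], grouped, t21_spec)
    transp = list(cohort.feature_truth["expression"]
                  .query("transporter != 'none'").index)
    ms3_ms1 = ContrastSpec("group", "MS1", "MS3", covariates=COVARIATES)
    res.differentials["transporters:MS3_vs_MS1"] = linear_diff(
        expr["log2"].subset_features(transp), grouped, ms3_ms1)

    # -- targeted cytokine panel: analyte selection and score ----------------
    msd = preprocess_panel(cohort, "msd_panel")
    res.intermediates["msd_panel"] = msd
    d21_spec = ContrastSpec("group", "D21", "MS3", covariates=COVARIATES)
    diff_ctrl = linear_diff(msd["log2"], grouped, d21_spec)
    diff_ms1 = linear_diff(msd["log2"], grouped, ms3_ms1)
    res.differentials["msd_panel:MS3_vs_D21"] = diff_ctrl
    res.differentials["msd_panel:MS3_vs_MS1"] = diff_ms1
    res.score_analytes = select_score_analytes(diff_ctrl, diff_ms1)
    z_msd = zscore_vs_controls(msd["adjusted"], cohort.control_ids)
    if res.score_analytes:
        res.scores["cytokine"] = cytokine_score(z_msd, res.score_analytes)

    # -- metabolome -----------------------------------------------------------
    metab = preprocess_metabolome(cohort, seed=seed)
    res.intermediates["metabolome"] = metab
    res.differentials["metabolome:MS3_vs_MS1"] = linear_diff(
        metab["log2"], grouped, ms3_ms1)

    # -- ratio classifiers ----------------------------------------------------
    truth_labels = cohort.samples["subtype_true"] if truth_for_classifier else \
        grouped["group"]
    t21_ids = cohort.t21_ids
    truth = (truth_labels.loc[t21_ids] == "MS3")
    reports = [evaluate_index(idx, cohort.layers, truth, cohort.control_ids)
               for idx in default_ratio_indexes()]
    combined = combine_indexes(reports, rule="all-positive")
    res.classifier = {"indexes": reports, "combined": combined}

    # -- longitudinal stability ----------------------------------------------
    if "msd_panel" in cohort.visits:
        v2 = cohort.visits["msd_panel"]
        v1 = cohort.layers["msd_panel"].subset_samples(list(v2.sample_ids))
        res.stability = longitudinal_stability(v1, v2)

    # -- enrichment of cytokine-score correlates -----------------------------
    if gene_sets is None:
        gc = res.gene_clusters
        gene_sets = [
            GeneSet("CLUSTER1_COEXPRESSION", frozenset(gc.genes_in(1))),
            GeneSet("CLUSTER2_COEXPRESSION", frozenset(gc.genes_in(2))),
        ]
    if "cytokine" in res.scores and gene_sets:
        score = res.scores["cytokine"].values
        corr = correlate_feature_vs_layer(
            score, expr["adjusted"].subset_samples(cohort.t21_ids))
        ranking = corr["rho"].dropna()
        if len(ranking) >= 10:
            res.gsea = gsea_preranked(ranking, gene_sets, n_perm=n_perm, seed=seed)
    return res


# ---------------------------------------------------------------------------
# file-writing front end
# ---------------------------------------------------------------------------

def run_pipeline(out_dir, config: dict | None = None, seed: int = 0) -> Path:
    """Simulate (or ingest) a cohort, run every stage, and write artefacts.

    Returns the output directory; a ``manifest.json`` records the package
    version, seeds, output hashes and per-stage dimensions.
    """
    from .io import write_json, write_matrix, write_sample_table
    from .sim import SimConfig, simulate_cohort

    config = config or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_kwargs = config.get("simulate", {})
    sim_config = SimConfig(**sim_kwargs, seed=seed) if "seed" not in sim_kwargs else \
        SimConfig(**sim_kwargs)
    cohort = simulate_cohort(sim_config)

    cons = config.get("consensus", {})
    res = analyze_cohort(cohort,
                         max_k=int(cons.get("max_k", 6)),
                         n_iter=int(cons.get("n_iter", 100)),
                         p_item=float(cons.get("p_item", 0.8)),
                         seed=seed,
                         k_override=cons.get("k"))

    stage = "run_pipeline"
    counts: dict[str, tuple] = {}
    for name, layer in cohort.layers.items():
        write_matrix(layer, out / f"layer_{name}.tsv", stage=stage, seed=seed)
        counts[f"layer_{name}"] = layer.shape
    write_sample_table(cohort.samples, out / "samples.tsv", stage=stage, seed=seed)

    res.gene_clusters.labels.to_frame().to_csv(out / "gene_clusters.tsv", sep="\t")
    res.subtypes.to_frame().to_csv(out / "subtypes.tsv", sep="\t")
    for name, diff in res.differentials.items():
        safe = name.replace(":", "__")
        diff.table.to_csv(out / f"diff_{safe}.tsv", sep="\t")
    pd.concat([s.to_frame() for s in res.scores.values()]).to_csv(
        out / "scores.tsv", sep="\t")
    if res.stability is not None:
        res.stability.to_csv(out / "stability.tsv", sep="\t")
    area_table = pd.DataFrame({
        "k": sorted(res.consensus.areas),
        "area": [res.consensus.areas[k] for k in sorted(res.consensus.areas)],
        "delta_area": [res.consensus.delta_areas[k] for k in sorted(res.consensus.areas)],
    })
    area_table.to_csv(out / "consensus_areas.tsv", sep="\t", index=False)

    clf = res.classifier
    classifier_report = {
        "rule": "all-positive",
        "indexes": [{
            "name": r.index.name, "cutoff": r.index.cutoff, "pct": r.index.pct,
            "sensitivity": r.sensitivity, "specificity": r.specificity,
            "confusion": r.confusion,
        } for r in clf["indexes"]],
        "combined": {
            "sensitivity": clf["combined"].sensitivity,
            "specificity": clf["combined"].specificity,
            "confusion": clf["combined"].confusion,
        },
    }
    write_json(classifier_report, out / "classifier.json")

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "selected_k": res.selected_k,
        "score_analytes": list(res.score_analytes),
        "stage_counts": {k: list(v) for k, v in counts.items()},
        "subtype_sizes": res.subtypes.value_counts().to_dict(),
        "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
    }
    write_json(manifest, out / "manifest.json")
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()
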