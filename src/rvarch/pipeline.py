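"""End-to-end orchestration of the analysis stages on a cohort.

``run_pipeline`` chains simulate -> QC -> association -> burden ->
winner's curse -> LVE -> enrichment -> scores with one global seed and
returns a JSON-serializable report bundle embedding the configuration
snapshot.  Stages can be toggled; a failed stage halts with a
stage-scoped error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import burden as burden_mod
from . import enrichment as enrich_mod
from . import lve as lve_mod
from . import qc as qc_mod
from . import scores as scores_mod
from .assoc import associate_cohort
from .io import config_to_dict, write_cohort
from .masks import stratum_annotations
from .synthetic import CohortConfig, SimulatedCohort, effective_sample_size, simulate_cohort
from .winners_curse import WcInput, threshold_from_pvalue, wc_correct


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Stage toggles, thresholds (defaults = the study's printed values)
    and the global seed."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    run_qc: bool = True
    run_assoc: bool = True
    run_burden: bool = True
    run_wc: bool = True
    run_lve: bool = True
    run_enrichment: bool = True
    run_scores: bool = True
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    alpha_gene: float = 0.05
    n_genes_genome: int = 19020
    enrichment_top_k: int = 50
    enrichment_q: float = 0.01
    or_threshold: float = 3.0
    prevalence: float = 0.08
    wc_p_threshold: float = 0.05
    seed: int = 0


def synthetic_annotations(cohort: SimulatedCohort) -> pd.DataFrame:
    """Annotation flags consistent with each simulated variant's stratum.

    Rare variants get flags that place them back in their generating
    mask stratum; common variants get low-impact flags excluded from
    every stratum.
    """
    rows = []
    for _, v in cohort.variants.iterrows():
        if v["is_common"] or not v["mask"]:
            row = stratum_annotations("0of5_1pct", max_maf=0.5)
            row["vep_impact"] = "LOW"
        else:
            row = stratum_annotations(v["mask"], max_maf=float(v["base_maf"]))
        row["variant_id"] = v["variant_id"]
        row["gene_id"] = v["gene_id"]
        rows.append(row)
    return pd.DataFrame(rows)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def qc_from_cohort(cohort: SimulatedCohort) -> pd.DataFrame:
    """Compute the per-variant QC record table from cohort genotypes.

    The simulator has no missingness/GQ/depth process, so sequencing-
    quality fields are set to passing values and the statistical tests
    (HWE overall/in cases/in controls) are computed from the data.
    """
    y = cohort.phenotype
    rows = []
    for j, vid in enumerate(cohort.variants["variant_id"]):
        d = cohort.dosages[:, j]
        counts = [int((d == k).sum()) for k in (0, 1, 2)]
        case = d[y == 1]
        ctrl = d[y == 0]
        rows.append(
            {
                "variant_id": vid,
                "biallelic": True,
                "autosomal": True,
                "diff_missingness_p": 1.0,
                "hwe_p": qc_mod.hwe_test(*counts),
                "hwe_p_cases": qc_mod.hwe_test(
                    *[int((case == k).sum()) for k in (0, 1, 2)]
                ),
                "hwe_p_controls": qc_mod.hwe_test(
                    *[int((ctrl == k).sum()) for k in (0, 1, 2)]
                ),
                "alt_gq": 99.0,
                "call_rate": 1.0,
                "depth": 60.0,
                "firth_p": 1.0,
                "fisher_p": 1.0,
                "gnomad_rf_pass": True,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the enabled stages and return the report bundle."""
    report: dict = {
        "config": {
            "seed": config.seed,
            "cohort": config_to_dict(config.cohort),
            "thresholds": {
                "alpha_gene": config.alpha_gene,
                "n_genes_genome": config.n_genes_genome,
                "enrichment_q": config.enrichment_q,
                "or_threshold": config.or_threshold,
                "prevalence": config.prevalence,
            },
        },
        "stages": [],
    }

    cohort = _stage("simulate")(simulate_cohort)(config.cohort)
    report["stages"].append("simulate")
    report["effective_sample_size"] = round(
        effective_sample_size(config.cohort.n_cases, config.cohort.n_controls)
    )
    if outdir is not None:
        write_cohort(cohort, Path(outdir) / "cohort")

    variant_ids = cohort.variants["variant_id"].tolist()
    annotations = synthetic_annotations(cohort)
    covariates = cohort.covariate_matrix(n_pcs=4)
    phenotype = cohort.phenotype

    if config.run_qc:
        records = _stage("qc")(qc_from_cohort)(cohort)
        passed, tally = _stage("qc")(qc_mod.apply_variant_filters)(records)
        keep = set(passed["variant_id"])
        report["qc"] = {"n_input": len(records), "n_pass": len(passed), "failures": tally}
        report["stages"].append("qc")
    else:
        keep = set(variant_ids)

    keep_idx = [j for j, v in enumerate(variant_ids) if v in keep]
    dosages = cohort.dosages[:, keep_idx]
    kept_ids = [variant_ids[j] for j in keep_idx]
    kept_ann = annotations[annotations["variant_id"].isin(keep)].reset_index(drop=True)

    assoc_df = None
    if config.run_assoc:
        common = cohort.variants.set_index("variant_id").loc[kept_ids, "is_common"]
        cidx = [j for j, v in enumerate(kept_ids) if common.iloc[j]]
        if cidx:
            assoc_df = _stage("assoc")(associate_cohort)(
                dosages[:, cidx],
                phenotype,
                covariates,
                cohort.samples["cluster"].to_numpy(),
                [kept_ids[j] for j in cidx],
            )
            report["assoc"] = {"n_variants": len(assoc_df)}
        report["stages"].append("assoc")

    gene_results = None
    gene_df = None
    if config.run_burden:
        gene_results = _stage("burden")(burden_mod.gene_burden_scan)(
            dosages, kept_ids, phenotype, kept_ann, covariates
        )
        gene_df = burden_mod.gene_results_frame(gene_results)
        threshold = burden_mod.gene_significance_threshold(
            config.alpha_gene, config.n_genes_genome
        )
        report["burden"] = {
            "n_genes": len(gene_df),
            "threshold": threshold,
            "n_significant": int((gene_df["consolidated_p"] < threshold).sum())
            if len(gene_df)
            else 0,
        }
        report["stages"].append("burden")

    wc_by_gene: dict[str, float] = {}
    if config.run_wc and gene_df is not None and len(gene_df):
        c = threshold_from_pvalue(config.wc_p_threshold)
        for _, g in gene_df.iterrows():
            if not np.isfinite(g["beta"]) or not np.isfinite(g["se"]) or g["se"] <= 0:
                continue
            if abs(g["beta"] / g["se"]) < c:
                continue
            est = wc_correct(WcInput(beta_obs=g["beta"], se=g["se"], c=c))
            wc_by_gene[g["gene_id"]] = est.beta_true
        report["winners_curse"] = {"n_corrected": len(wc_by_gene)}
        report["stages"].append("winners_curse")

    if config.run_lve and gene_df is not None and len(gene_df):
        lves = []
        for _, g in gene_df.iterrows():
            if not np.isfinite(g["beta"]) or g["cumulative_af"] <= 0:
                continue
            beta = wc_by_gene.get(g["gene_id"], g["beta"])
            try:
                est = lve_mod.lve_bias_correct(
                    beta, g["se"], g["cumulative_af"], config.prevalence
                )
            except ValueError:
                continue
            lves.append(
                {"gene_id": g["gene_id"], "lve_raw": est.lve_raw,
                 "lve_corrected": est.lve_corrected}
            )
        report["lve"] = {
            "n_genes": len(lves),
            "total_corrected": float(sum(e["lve_corrected"] for e in lves)),
        }
        report["stages"].append("lve")

    if config.run_enrichment and gene_df is not None and len(gene_df) and config.gene_sets:
        gene_ps = gene_df.set_index("gene_id")["consolidated_p"]
        features = gene_df.set_index("gene_id")[["n_carriers", "cumulative_af"]]
        features = features.rename(columns={"n_carriers": "n_variants"})
        enr = _stage("enrichment")(enrich_mod.enrich_gene_sets)(
            gene_ps,
            config.gene_sets,
            features=features,
            top_k=min(config.enrichment_top_k, len(gene_ps)),
            q_threshold=config.enrichment_q,
            background_fold=5,
        )
        sig = {
            s: config.gene_sets[s]
            for s in enr.loc[enr["significant"], "set"]
        }
        tiers = enrich_mod.assign_tiers(
            gene_ps, sig, top_k=min(config.enrichment_top_k, len(gene_ps))
        )
        report["enrichment"] = {
            "n_sets": len(enr),
            "n_significant": int(enr["significant"].sum()),
            "tier3": tiers.loc[tiers["tier"] == 3, "gene_id"].tolist(),
            "tier4": tiers.loc[tiers["tier"] == 4, "gene_id"].tolist(),
        }
        report["stages"].append("enrichment")

    if config.run_scores and gene_results is not None:
        common_mask = cohort.variants.set_index("variant_id").loc[kept_ids, "is_common"]
        cidx = [j for j, v in enumerate(kept_ids) if common_mask.iloc[j]]
        weights = (
            assoc_df.set_index("variant_id")["beta"]
            .reindex([kept_ids[j] for j in cidx])
            .fillna(0.0)
            .to_numpy()
            if assoc_df is not None and len(assoc_df)
            else np.zeros(len(cidx))
        )
        ancestry = cohort.samples["cluster"].astype(str).to_numpy()
        betas = {a: 0.89 for a in np.unique(ancestry)}
        common = scores_mod.common_score(
            dosages[:, cidx], weights, ancestry, betas
        ) if cidx else np.zeros(len(phenotype))
        gene_mask_table = burden_mod.build_masks(kept_ann)
        rare = scores_mod.rare_score_unique_fit(
            dosages, kept_ids, gene_mask_table, phenotype, covariates
        )
        frame = pd.DataFrame(
            {
                "sample_id": cohort.samples["sample_id"],
                "common": common,
                "rare": rare,
                "mody": False,
            }
        )
        frame["combined"] = frame["common"] + frame["rare"]
        cases = frame.loc[phenotype == 1]
        table = scores_mod.classify_and_report(cases, config.or_threshold)
        report["scores"] = {
            "categories": table.to_dict(orient="records"),
        }
        report["stages"].append("scores")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
        if gene_df is not None:
            gene_df.to_csv(outdir / "gene_results.tsv", sep="\t", index=False)
        if assoc_df is not None:
            assoc_df.to_csv(outdir / "single_variant.tsv", sep="\t", index=False)
    return report
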