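"""Cohort serialization: VCF + phenotype/covariate TSV + truth JSON.

The VCF writer emits plain uncompressed VCF 4.2 with GT genotypes and
1-based positions; the reader accepts anything cyvcf2 can open (and
falls back to a plain-text parser when cyvcf2 is unavailable, so the
round-trip works in minimal environments).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import CohortConfig, CommonVariantSpec, GeneSpec, SimulatedCohort

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(cohort: SimulatedCohort, path) -> None:
    """Write cohort genotypes as an uncompressed VCF with GT fields."""
    path = Path(path)
    samples = cohort.samples["sample_id"].tolist()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted({str(c) for c in cohort.variants["chrom"]}, key=lambda x: int(x)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        order = cohort.variants.sort_values(
            ["chrom", "pos"], key=lambda s: s.astype(int)
        ).index
        for i in order:
            row = cohort.variants.loc[i]
            gts = "\t".join(_GT[int(g)] for g in cohort.dosages[:, i])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf_dosages(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read GT dosages from a VCF: (samples x variants, variant ids, sample ids)."""
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, cols = [], []
    for rec in vcf:
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        gt = np.asarray(rec.gt_types)
        # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=0)
        cols.append(dos)
    return np.column_stack(cols).astype(np.int8), ids, samples


def _read_vcf_text(path) -> tuple[np.ndarray, list[str], list[str]]:
    samples, ids, cols = [], [], []
    conv = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": 0}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            ids.append(parts[2])
            cols.append([conv.get(g.split(":")[0], 0) for g in parts[9:]])
    return np.array(cols, dtype=np.int8).T, ids, samples


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    """Write VCF + phenotype/covariate TSV + truth JSON + config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "samples": outdir / "samples.tsv",
        "variants": outdir / "variants.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "config.yaml",
    }
    write_vcf(cohort, paths["vcf"])
    cohort.samples.to_csv(paths["samples"], sep="\t", index=False)
    cohort.variants.to_csv(paths["variants"], sep="\t", index=False)
    truth = {
        "threshold": cohort.truth["threshold"],
        "gene_effects": cohort.truth["gene_effects"],
        "population_drawn": int(cohort.truth["population_drawn"]),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2))
    paths["config"].write_text(yaml.safe_dump(config_to_dict(cohort.config)))
    return paths


def config_to_dict(config: CohortConfig) -> dict:
    return {
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "n_clusters": config.n_clusters,
        "prevalence": config.prevalence,
        "shared_control_fraction": config.shared_control_fraction,
        "seed": config.seed,
        "cluster_weights": list(config.cluster_weights),
        "cluster_maf_multipliers": list(config.cluster_maf_multipliers),
        "cluster_liability_offsets": list(config.cluster_liability_offsets),
        "population_cap_factor": config.population_cap_factor,
        "genes": [
            {
                "gene_id": g.gene_id,
                "n_variants": g.n_variants,
                "maf_range": list(g.maf_range),
                "mask_labels": list(g.mask_labels),
                "effects": dict(g.effects),
            }
            for g in config.genes
        ],
        "common_variants": [
            {"variant_id": v.variant_id, "maf": v.maf, "effect": v.effect}
            for v in config.common_variants
        ],
    }


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    genes = [
        GeneSpec(
            gene_id=g["gene_id"],
            n_variants=g["n_variants"],
            maf_range=tuple(g.get("maf_range", (1e-4, 5e-3))),
            mask_labels=g.get("mask_labels"),
            effects=dict(g.get("effects", {})),
        )
        for g in d.pop("genes", [])
    ]
    commons = [
        CommonVariantSpec(
            variant_id=v["variant_id"], maf=v["maf"], effect=v.get("effect", 0.0)
        )
        for v in d.pop("common_variants", [])
    ]
    return CohortConfig(genes=genes, common_variants=commons, **d)


def load_config(path) -> CohortConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
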