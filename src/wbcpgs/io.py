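"""Readers and writers for the pipeline's on-disk formats.

Summary statistics and catalogs travel as tab-separated tables, cohorts
as CSV, dosages either as a VCF with a per-genotype DS (dosage) FORMAT
field (written with pysam, read back with cyvcf2) or as a plain matrix
TSV.  Every writer can drop a sidecar JSON echoing the generating
configuration, seed included.  The fitted score model is written as a
PGS-Catalog-style scoring file with a JSON exclusion-log sidecar.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .pgs import PgsModel
from .synthdata import GenotypePanel

SUMMARY_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele",
                   "other_allele", "beta", "p", "eaf", "info"]


def write_config_sidecar(config: SimConfig, path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")


def write_summary_tsv(summary: pd.DataFrame, path, config: SimConfig | None = None):
    summary[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)
    if config is not None:
        write_config_sidecar(config, str(path) + ".config.json")


def read_summary_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    return df


def write_catalog_tsv(catalog: pd.DataFrame, path, config: SimConfig | None = None):
    catalog[["variant_id", "phenotype", "p"]].to_csv(path, sep="\t", index=False)
    if config is not None:
        write_config_sidecar(config, str(path) + ".config.json")


def read_catalog_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# dosage formats
# ---------------------------------------------------------------------------

def write_panel_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel as an uncompressed VCF with a DS dosage FORMAT field."""
    import pysam
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(panel.variants["chrom"]):
        header.contigs.add(str(chrom))
    header.formats.add("DS", 1, "Float", "Effect-allele dosage")
    for person in panel.people:
        header.add_sample(person)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, row in panel.variants.iterrows():
            rec = vcf.new_record(
                contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                stop=int(row["pos"]), id=row["variant_id"],
                alleles=(row["other_allele"], row["effect_allele"]))
            for i, person in enumerate(panel.people):
                rec.samples[person]["DS"] = float(panel.dosages[i, j])
            vcf.write(rec)


def read_panel_vcf(path) -> GenotypePanel:
    """Read a dosage VCF (ALT = effect allele, DS FORMAT field)."""
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    people = list(vcf.samples)
    meta, cols = [], []
    for var in vcf:
        meta.append({"variant_id": var.ID, "chrom": str(var.CHROM),
                     "pos": int(var.POS), "effect_allele": var.ALT[0],
                     "other_allele": var.REF})
        cols.append(np.asarray(var.format("DS"), dtype=float).ravel())
    variants = pd.DataFrame(meta)
    dosages = np.column_stack(cols) if cols else np.zeros((len(people), 0))
    return GenotypePanel(people=people, variants=variants, dosages=dosages)


def write_panel_tsv(panel: GenotypePanel, path) -> None:
    """Plain matrix TSV: variant metadata columns then one column per person."""
    mat = pd.DataFrame(panel.dosages.T.astype(float), columns=panel.people)
    out = pd.concat([panel.variants[["variant_id", "chrom", "pos",
                                     "effect_allele", "other_allele"]]
                     .reset_index(drop=True), mat], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
    people = [c for c in df.columns if c not in meta_cols]
    return GenotypePanel(people=people, variants=df[meta_cols].copy(),
                         dosages=df[people].to_numpy(dtype=float).T)


# ---------------------------------------------------------------------------
# model artefacts
# ---------------------------------------------------------------------------

def write_scoring_file(model: PgsModel, path) -> None:
    """PGS-Catalog-style scoring file: rsID, effect_allele, effect_weight."""
    out = model.variants.rename(columns={"variant_id": "rsID",
                                         "weight": "effect_weight"})
    out[["rsID", "effect_allele", "effect_weight"]].to_csv(
        path, sep="\t", index=False)


def read_scoring_file(path) -> PgsModel:
    df = pd.read_csv(path, sep="\t").rename(
        columns={"rsID": "variant_id", "effect_weight": "weight"})
    return PgsModel(variants=df[["variant_id", "effect_allele", "weight"]])


def write_exclusion_log(model: PgsModel, path) -> None:
    payload = {
        "threshold": model.threshold,
        "standardization": {"mean": model.mean, "sd": model.sd},
        "n_retained": model.n_variants,
        "exclusions": model.exclusions.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
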