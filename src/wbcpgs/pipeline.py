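"""End-to-end orchestration of the synthetic analysis pipeline.

``run_pipeline`` executes the stages in dependency order — synthetic
data, score construction (with threshold selection), quintile
diagnostics, genotype-informed reference ranges, and the clinical
association stages — from one seeded configuration, and writes every
stage output plus a run manifest (seed, configuration echo, input
digests, exclusion tallies) under an output directory.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, pgs, quintiles, refrange, clinassoc, synthdata
from .config import SimConfig
from .errors import WbcPgsError


@dataclass
class RunConfig:
    """Structured configuration for one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "results/pipeline"
    thresholds: tuple = (5e-8, 5e-7, 5e-6)
    clump_r2: float = 0.01
    catalog_r2: float = 0.5
    catalog_p_max: float = 5e-7
    mhc: str = "6:25500000-33500000"
    half_width: float = 0.2
    percentile: float = 2.5
    min_window_n: int = 20
    n_perm: int = 200
    n_phenotypes: int = 15
    run_quintiles: bool = True
    run_refrange: bool = True
    run_clinassoc: bool = True
    use_catalog: bool = True

    def validate(self) -> "RunConfig":
        self.sim.validate()
        if not (0 < self.clump_r2 <= 1) or not (0 < self.catalog_r2 <= 1):
            raise WbcPgsError("LD thresholds must lie in (0, 1]")
        return self


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _null_phenotypes(n_people: int, n_pheno: int, rng) -> pd.DataFrame:
    return pd.DataFrame({f"pheno_{i:02d}": (rng.random(n_people) < 0.1).astype(int)
                         for i in range(n_pheno)})


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.sim.seed, "config": asdict(config),
                      "stages": {}, "inputs": {}, "exclusion_tallies": {}}
    import wbcpgs
    manifest["versions"] = {"wbcpgs": wbcpgs.__version__,
                            "numpy": np.__version__, "pandas": pd.__version__}

    def fail(stage, exc):
        record = {"stage": stage, "error": type(exc).__name__, "message": str(exc)}
        (out / "error.json").write_text(json.dumps(record, indent=2))
        raise

    # --- synthetic inputs -------------------------------------------------
    try:
        panel = synthdata.simulate_panel(config.sim)
        summary = synthdata.simulate_summary_stats(panel, config.sim)
        catalog = synthdata.simulate_catalog(summary, config.sim)
        raw_true = synthdata.true_raw_score(panel, config.sim)
        true_std, _, _ = pgs.standardize(raw_true)
        bundle = synthdata.simulate_cohorts(panel, true_std, config.sim)
    except WbcPgsError as exc:
        fail("synthdata", exc)
    io.write_summary_tsv(summary, out / "summary_stats.tsv", config.sim)
    io.write_catalog_tsv(catalog, out / "catalog.tsv")
    for name in ("summary_stats.tsv", "catalog.tsv"):
        manifest["inputs"][name] = _digest(out / name)

    # --- score construction ----------------------------------------------
    try:
        persons, _dropped = refrange.person_summary(bundle.wbc_observations)
        persons = bundle.wbc_persons.merge(persons, on="person_id")
        chosen, thr_table = pgs.select_threshold(
            summary, panel, persons, thresholds=config.thresholds,
            catalog=catalog if config.use_catalog else None,
            clump_r2=config.clump_r2, catalog_p_max=config.catalog_p_max,
            catalog_r2=config.catalog_r2,
            mhc=pgs.GenomicRegion.parse(config.mhc))
        model = pgs.build_pgs_model(
            summary, panel, catalog=catalog if config.use_catalog else None,
            p_max=chosen, clump_r2=config.clump_r2,
            mhc=pgs.GenomicRegion.parse(config.mhc),
            catalog_p_max=config.catalog_p_max, catalog_r2=config.catalog_r2)
        raw = pgs.score(panel, model)
        z, model.mean, model.sd = pgs.standardize(raw)
        pgs_by_person = pd.Series(z, index=panel.people)
        persons["pgs"] = persons["person_id"].map(pgs_by_person).to_numpy()
    except WbcPgsError as exc:
        fail("pgs_builder", exc)
    io.write_scoring_file(model, out / "scoring_file.tsv")
    io.write_exclusion_log(model, out / "exclusion_log.json")
    thr_table.to_csv(out / "threshold_selection.tsv", sep="\t", index=False)
    tallies = model.exclusions.groupby("step").size().to_dict()
    manifest["exclusion_tallies"] = {k: int(v) for k, v in tallies.items()}
    cov_cols = ["age", "sex"] + [f"pc{i+1}" for i in range(config.sim.n_pcs)]
    manifest["stages"]["pgs_builder"] = {
        "threshold": chosen, "n_retained": model.n_variants,
        "partial_r": float(
            thr_table.loc[thr_table["threshold"] == chosen, "partial_r"].iloc[0]),
    }

    # --- quintile diagnostics --------------------------------------------
    if config.run_quintiles and model.n_variants >= 5:
        rng = np.random.default_rng([99, config.sim.seed])
        phen = _null_phenotypes(panel.n_people, config.n_phenotypes, rng)
        quints = quintiles.quintile_split(model)
        scan_cov = bundle.wbc_persons[cov_cols]  # full panel, aligned with z
        scan = quintiles.phenome_scan(z, phen, scan_cov)
        scan.to_csv(out / "phenome_scan.tsv", sep="\t", index=False)
        perm_rows = []
        for q in quints:
            res = quintiles.permutation_count_test(
                model, q, panel, phen, scan_cov,
                n_perm=config.n_perm, seed=config.sim.seed,
                direction="positive")
            perm_rows.append({"quintile": q.index, "n_variants": q.n_variants,
                              "observed": res.observed_count,
                              "empiric_p": res.empiric_p})
        pd.DataFrame(perm_rows).to_csv(out / "quintile_permutation.tsv",
                                       sep="\t", index=False)
        manifest["stages"]["quintile_diag"] = {
            "n_nominal_scan": int(scan["nominal"].sum()),
            "min_empiric_p": float(min(r["empiric_p"] for r in perm_rows))}

    # --- reference ranges -------------------------------------------------
    if config.run_refrange:
        curves = refrange.window_percentiles(
            persons["pgs"].to_numpy(), persons["median_wbc"].to_numpy(),
            half_width=config.half_width, min_n=config.min_window_n)
        curves.to_csv(out / "percentile_curves.tsv", sep="\t", index=False)
        classified = refrange.classify_within_range(
            bundle.biopsy, persons["pgs"].to_numpy(),
            persons["min_wbc"].to_numpy(), half_width=config.half_width,
            percentile=config.percentile, min_n=config.min_window_n)
        merged = bundle.biopsy.merge(classified, on="person_id")
        strat = refrange.stratified_summary(merged)
        strat.to_csv(out / "stratified_summary.tsv", sep="\t", index=False)
        manifest["stages"]["refrange"] = {
            "n_grid": len(curves),
            "n_classifiable": int(classified["classifiable"].sum())}

    # --- clinical associations --------------------------------------------
    if config.run_clinassoc:
        flags = refrange.outlier_flag(bundle.wbc_observations)
        persons = persons.merge(flags.rename("outlier"), on="person_id")
        covar = persons[cov_cols].copy()
        covar["age2"] = covar["age"] ** 2
        fit = clinassoc.logistic_fit(persons["outlier"].astype(int),
                                     persons["pgs"], covar)
        hl = clinassoc.hosmer_lemeshow(fit.diagnostics["fitted"],
                                       persons["outlier"].astype(int))
        tax_records, _excl = clinassoc.build_exposure_cohort(
            bundle.taxane_persons, bundle.taxane_measures,
            clinassoc.CensoringRules())
        tax_records["pgs"] = tax_records["score"]  # generative score stands in
        cox = clinassoc.cox_fit(tax_records, score_col="pgs",
                                covariate_cols=("age", "sex", "dose", "duration"))
        lin = clinassoc.linear_log_fit(
            np.log(bundle.taxane_persons["baseline_wbc"]),
            bundle.taxane_persons["score"],
            bundle.taxane_persons[["age", "sex"]])
        _labels, _curves = clinassoc.km_strata(tax_records["pgs"], tax_records)
        manifest["stages"]["clinassoc"] = {
            "outlier_or": fit.estimate, "outlier_events": fit.events,
            "hosmer_lemeshow_p": hl.p,
            "taxane_hr": cox.estimate, "taxane_events": cox.events,
            "baseline_slope": lin.estimate,
        }
        pd.DataFrame([manifest["stages"]["clinassoc"]]).to_csv(
            out / "clinical_associations.tsv", sep="\t", index=False)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str) + "\n")
    return manifest
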