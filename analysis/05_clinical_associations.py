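"""Clinical association stages on the simulated cohorts.

Fits the assay-outlier logistic stage (with Hosmer-Lemeshow check), the
baseline log-WBC linear stage, the taxane time-to-leukopenia Cox stage
(with Kaplan-Meier strata), and the azathioprine discontinuation Cox
stage, and prints each estimate against its generative value.
"""
import argparse
import math
from pathlib import Path

import numpy as np
import pandas as pd

from wbcpgs import clinassoc, refrange, synthdata

from common import analysis_config


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--score", default="results/score")
    ap.add_argument("--out", default="results/clinassoc")
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    data = Path(args.data)
    persons = pd.read_csv(data / "wbc_persons.csv")
    obs = pd.read_csv(data / "wbc_observations.csv")
    scores = pd.read_csv(Path(args.score) / "scores.csv")
    persons = persons.merge(scores, on="person_id")

    flags = refrange.outlier_flag(obs).rename("outlier")
    persons = persons.merge(flags, on="person_id")
    cov = persons[["age", "sex"] + [c for c in persons if c.startswith("pc")]]
    cov = cov.assign(age2=cov["age"] ** 2)
    fit = clinassoc.logistic_fit(persons["outlier"].astype(int),
                                 persons["pgs"], cov)
    hl = clinassoc.hosmer_lemeshow(fit.diagnostics["fitted"],
                                   persons["outlier"].astype(int))
    print(f"assay outlier stage: OR = {fit.estimate:.2f} "
          f"[{fit.ci_low:.2f}-{fit.ci_high:.2f}] per s.d., p = {fit.p:.2g}, "
          f"{fit.events} events; Hosmer-Lemeshow p = {hl.p:.2f} ({hl.n_bins} bins)")

    tax_p = pd.read_csv(data / "taxane_persons.csv")
    tax_m = pd.read_csv(data / "taxane_measures.csv")
    rec, excl = clinassoc.build_exposure_cohort(tax_p, tax_m)
    cox = clinassoc.cox_fit(rec, covariate_cols=("age", "sex", "dose",
                                                 "duration"))
    print(f"taxane leukopenia stage: HR = {cox.estimate:.2f} "
          f"[{cox.ci_low:.2f}-{cox.ci_high:.2f}] per s.d. "
          f"(generative 0.78), {cox.events}/{cox.n} events "
          f"({100 * cox.events / cox.n:.0f}%), {len(excl)} excluded at baseline")
    labels, curves = clinassoc.km_strata(rec["score"], rec)
    km = pd.concat(curves.values(), axis=1)
    km.to_csv(out / "km_strata.tsv", sep="\t")
    print("  KM strata sizes:", labels.value_counts().to_dict())

    lin = clinassoc.linear_log_fit(np.log(tax_p["baseline_wbc"]),
                                   tax_p["score"], tax_p[["age", "sex"]])
    print(f"baseline log-WBC stage: slope = {lin.estimate:.3f} "
          f"[{lin.ci_low:.3f}-{lin.ci_high:.3f}] per s.d.")

    cfg = analysis_config(args.seed)
    rng = np.random.default_rng([66, args.seed])
    aza = synthdata.simulate_exposure_records(
        rng.normal(size=cfg.n_azathioprine), cfg, rng=rng,
        kind="azathioprine")
    aza_cox = clinassoc.cox_fit(aza)
    print(f"azathioprine discontinuation stage: HR = {aza_cox.estimate:.2f} "
          f"[{aza_cox.ci_low:.2f}-{aza_cox.ci_high:.2f}] per s.d. "
          f"(generative {math.exp(cfg.aza_loghr_per_sd):.2f}), "
          f"{aza_cox.events}/{aza_cox.n} events")

    pd.DataFrame([{
        "outlier_or": fit.estimate, "outlier_hl_p": hl.p,
        "taxane_hr": cox.estimate, "taxane_events": cox.events,
        "baseline_slope": lin.estimate, "aza_hr": aza_cox.estimate,
    }]).to_csv(out / "clinical_associations.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
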