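"""Build the benign WBC polygenic score from the written inputs.

Reads the summary statistics, catalog and dosage panel emitted by
01_simulate_inputs.py, selects the association threshold by partial
correlation with median WBC, runs the full exclusion chain, and writes
the scoring file, exclusion log and threshold table.
"""
import argparse
from pathlib import Path

import pandas as pd

from wbcpgs import io, pgs, refrange


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/score")
    args = ap.parse_args()
    data, out = Path(args.data), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    summary = io.read_summary_tsv(data / "summary_stats.tsv")
    catalog = io.read_catalog_tsv(data / "catalog.tsv")
    panel = io.read_panel_tsv(data / "panel.tsv")
    persons = pd.read_csv(data / "wbc_persons.csv")
    obs = pd.read_csv(data / "wbc_observations.csv")
    medians, _ = refrange.person_summary(obs)
    persons = persons.merge(medians, on="person_id")

    chosen, table = pgs.select_threshold(summary, panel, persons,
                                         catalog=catalog)
    model = pgs.build_pgs_model(summary, panel, catalog=catalog, p_max=chosen)
    raw = pgs.score(panel, model)
    z, model.mean, model.sd = pgs.standardize(raw)

    io.write_scoring_file(model, out / "scoring_file.tsv")
    io.write_exclusion_log(model, out / "exclusion_log.json")
    table.to_csv(out / "threshold_selection.tsv", sep="\t", index=False)
    pd.DataFrame({"person_id": panel.people, "pgs": z}).to_csv(
        out / "scores.csv", index=False)

    print("threshold selection (partial correlation with median WBC):")
    print(table.to_string(index=False))
    print(f"chosen threshold: {chosen:g}; retained {model.n_variants} variants")
    print("exclusion tallies:",
          model.exclusions.groupby("step").size().to_dict())


if __name__ == "__main__":
    main()
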