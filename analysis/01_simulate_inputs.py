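"""Generate the synthetic study inputs and write them under results/data/.

Emits GWAS summary statistics, the disease catalog, a dosage panel
(matrix TSV plus a VCF excerpt), and the cohort tables, all derived from
one seed.  Sizes are kept modest so the whole analysis replays in
seconds; the package defaults carry the full study-scale conditions.
"""
import argparse
import json
from pathlib import Path

from wbcpgs import io, pgs, synthdata

from common import analysis_config


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", default="results/data")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    cfg = analysis_config(args.seed)
    panel = synthdata.simulate_panel(cfg)
    summary = synthdata.simulate_summary_stats(panel, cfg)
    catalog = synthdata.simulate_catalog(summary, cfg)
    true_std, _, _ = pgs.standardize(synthdata.true_raw_score(panel, cfg))
    bundle = synthdata.simulate_cohorts(panel, true_std, cfg)

    io.write_summary_tsv(summary, out / "summary_stats.tsv", config=cfg)
    io.write_catalog_tsv(catalog, out / "catalog.tsv")
    io.write_panel_tsv(panel, out / "panel.tsv")
    # VCF excerpt (first 30 variants, 50 people) as a format illustration
    excerpt = synthdata.GenotypePanel(
        people=panel.people[:50],
        variants=panel.variants.head(30).reset_index(drop=True),
        dosages=panel.dosages[:50, :30])
    io.write_panel_vcf(excerpt, out / "panel_excerpt.vcf")
    bundle.wbc_persons.to_csv(out / "wbc_persons.csv", index=False)
    bundle.wbc_observations.to_csv(out / "wbc_observations.csv", index=False)
    bundle.biopsy.to_csv(out / "biopsy.csv", index=False)
    bundle.taxane_persons.to_csv(out / "taxane_persons.csv", index=False)
    bundle.taxane_measures.to_csv(out / "taxane_measures.csv", index=False)

    n_sig = int((summary["p"] < 5e-6).sum())
    print(f"panel: {panel.n_people} people x {panel.n_variants} variants "
          f"in {cfg.n_blocks} LD blocks")
    print(f"summary statistics: {n_sig} variants reach p < 5e-6 "
          f"({cfg.n_causal} causal simulated)")
    print(f"catalog: {len(catalog)} disease loci, all p < 5e-7")
    print(f"cohorts: WBC n={len(bundle.wbc_persons)}, "
          f"biopsy n={len(bundle.biopsy)}, taxane n={len(bundle.taxane_persons)}")
    (out / "run.json").write_text(json.dumps({"seed": args.seed}) + "\n")


if __name__ == "__main__":
    main()
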