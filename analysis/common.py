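"""Shared study configuration for the numbered analysis scripts.

Sizes are reduced from the package defaults so the whole analysis
replays in seconds; the generative effect sizes are unchanged.
"""
from wbcpgs import SimConfig


def analysis_config(seed: int) -> SimConfig:
    return SimConfig(seed=seed, n_variants=600, n_blocks=150,
                     n_people_panel=3000, gwas_n=12_000, n_causal=120,
                     effect_sd=0.08, n_disease_loci=24,
                     n_taxane=1000, n_azathioprine=700, n_biopsy=117)
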