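import numpy as np
import pandas as pd
import pytest

from wbcpgs import SimConfig, pgs, synthdata


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=7, n_variants=300, n_blocks=100, block_ld=0.8,
                     n_people_panel=1000, gwas_n=8000, n_causal=80,
                     effect_sd=0.08, n_disease_loci=20, n_taxane=400,
                     n_azathioprine=300, n_biopsy=60)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return synthdata.simulate_panel(small_config)


@pytest.fixture(scope="session")
def small_summary(small_panel, small_config):
    return synthdata.simulate_summary_stats(small_panel, small_config)


@pytest.fixture(scope="session")
def small_catalog(small_summary, small_config):
    return synthdata.simulate_catalog(small_summary, small_config)


@pytest.fixture(scope="session")
def small_model(small_summary, small_panel):
    return pgs.build_pgs_model(small_summary, small_panel)


def make_toy_panel(dosages: np.ndarray, chrom="1") -> synthdata.GenotypePanel:
    """Panel from an explicit people-by-variants dosage matrix."""
    n, m = dosages.shape
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chrom": chrom, "pos": 1000 + 10 * np.arange(m),
        "effect_allele": "A", "other_allele": "G",
        "block": 0, "freq": dosages.mean(axis=0) / 2.0,
    })
    return synthdata.GenotypePanel(
        people=[f"p{i}" for i in range(n)], variants=variants,
        dosages=np.asarray(dosages))


@pytest.fixture
def toy_panel():
    rng = np.random.default_rng(42)
    return make_toy_panel(rng.integers(0, 3, size=(10, 6)).astype(np.int8))
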