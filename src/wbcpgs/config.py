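"""Simulation configuration for the synthetic cohort generator.

The defaults encode the study conditions the pipeline is exercised under:
a WBC distribution with mean 8200 and s.d. 3900 cells/uL, an assay lower
bound of 3900 cells/uL, a WBC cohort of 11,694 people (6931 female, mean
age 57 [s.d. 17]), a taxane exposure cohort of 1724 people with a ~16%
leukopenia event rate and a generative hazard ratio of 0.78 per score
s.d., and an azathioprine discontinuation cohort of 1180 people with a
generative hazard ratio of 0.62.  The source GWAS is scaled down to
20,000 participants (see docs/methods.md).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

from .errors import ConfigError

# log-normal with mean 8200 and s.d. 3900 cells/uL:
# sigma^2 = ln(1 + (3900/8200)^2) = 0.2039, mu = ln(8200) - sigma^2/2
_WBC_LOG_MEAN = math.log(8200.0) - 0.5 * math.log(1.0 + (3900.0 / 8200.0) ** 2)


@dataclass
class SimConfig:
    """Seeded configuration for every synthetic-data generator.

    All random streams are derived deterministically from ``seed``; the
    same seed and configuration reproduce every output bit-for-bit.
    """

    seed: int = 0

    # genotype panel
    n_variants: int = 1200
    n_blocks: int = 300
    block_ld: float = 0.8          # target pairwise dosage correlation within a block
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_people_panel: int = 11_694
    palindromic_frac: float = 0.05

    # source GWAS
    n_causal: int = 120
    effect_sd: float = 0.06        # per-allele effect s.d. on log-WBC
    gwas_n: int = 20_000

    # disease catalog
    n_disease_loci: int = 30
    catalog_p_max: float = 5e-7

    # WBC phenotype (log cells/uL)
    wbc_log_mean: float = _WBC_LOG_MEAN
    wbc_log_sd_between: float = 0.392
    wbc_log_sd_within: float = 0.18
    score_effect: float = 0.133    # log-WBC shift per s.d. of the true score
    mean_extra_measures: float = 2.0
    assay_lower: float = 3900.0
    assay_upper: float = 10_800.0

    # demographics
    age_mean: float = 57.0
    age_sd: float = 17.0
    age_bounds: tuple[float, float] = (18.0, 90.0)
    female_frac: float = 0.55
    n_pcs: int = 5
    beta_age: float = -0.002       # log-WBC per year of age
    beta_female: float = 0.03      # log-WBC shift for females

    # bone marrow biopsy cohort
    n_biopsy: int = 117
    biopsy_abnormal_frac: float = 0.30
    biopsy_score_mean: float = -0.8
    biopsy_score_sd: float = 0.9

    # drug exposure cohorts
    n_taxane: int = 1724
    n_azathioprine: int = 1180
    hazard_baseline: float = 0.25        # leukopenia events per person-month at score 0
    hazard_loghr_per_sd: float = math.log(0.78)
    second_cycle_mean_day: float = 21.0
    horizon_days: float = 30.0           # taxane first-cycle window
    aza_hazard_baseline: float = 0.0025  # discontinuation events per person-month
    aza_loghr_per_sd: float = math.log(0.62)
    aza_horizon_days: float = 730.0

    def validate(self) -> "SimConfig":
        positive = {
            "n_variants": self.n_variants,
            "n_blocks": self.n_blocks,
            "n_people_panel": self.n_people_panel,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if not (0.0 <= self.block_ld < 1.0):
            raise ConfigError(f"block_ld must lie in [0, 1), got {self.block_ld}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_blocks > self.n_variants:
            raise ConfigError("n_blocks cannot exceed n_variants")
        if self.n_causal < 0 or self.n_causal > self.n_variants:
            raise ConfigError("n_causal must lie in [0, n_variants]")
        if self.gwas_n < 2:
            raise ConfigError(f"gwas_n must be at least 2, got {self.gwas_n}")
        if self.n_disease_loci < 0 or self.n_disease_loci > self.n_variants:
            raise ConfigError("n_disease_loci must lie in [0, n_variants]")
        if not (0.0 <= self.palindromic_frac <= 1.0):
            raise ConfigError("palindromic_frac must lie in [0, 1]")
        if self.assay_lower >= self.assay_upper:
            raise ConfigError("assay_lower must be below assay_upper")
        return self

    def to_dict(self) -> dict:
        return asdict(self)
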