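"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the statistical structure the downstream stages
assume: LD-block-structured genotypes, GWAS summary statistics computed
on a simulated discovery cohort, a disease-association catalog with
ground-truth linkage tags, a log-normal WBC phenotype partly driven by
the true genetic score (with repeated measures and per-assay reference
bounds), a bone marrow biopsy cohort whose pathology outcome is
independent of the benign score, and proportional-hazards event times
for drug-induced leukopenia and drug discontinuation.

LD model
--------
Variants are partitioned into contiguous blocks.  Within a block every
variant shares the block's allele frequency, and each haplotype copy
equals a block-level "lead" allele with probability sqrt(block_ld),
otherwise an independent draw at the same frequency.  Two variants in a
block then have dosage correlation exactly block_ld (so r-squared is
block_ld squared); variants in different blocks are independent.  This
is the simplest structure that exercises clumping and catalog-LD
exclusion with an analytically known correlation target.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import ConfigError

_NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

# stream labels -> fixed sub-seeds so partial re-runs stay reproducible
_STREAMS = {
    "panel": 1, "gwas_panel": 2, "gwas_pheno": 3, "alleles": 4,
    "effects": 5, "info": 6, "catalog": 7, "covariates": 8,
    "wbc": 9, "biopsy": 10, "taxane": 11, "azathioprine": 12,
}


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], config.seed])


@dataclass
class GenotypePanel:
    """Effect-allele dosages for a set of people at a set of variants.

    ``dosages`` is people-by-variants with integer entries in {0, 1, 2};
    column order matches ``variants`` row order.
    """

    people: list[str]
    variants: pd.DataFrame  # variant_id, chrom, pos, effect_allele, other_allele, block, freq
    dosages: np.ndarray

    def __post_init__(self):
        self._index = {v: i for i, v in enumerate(self.variants["variant_id"])}
        if self.dosages.shape != (len(self.people), len(self.variants)):
            raise ConfigError("dosage matrix shape does not match people x variants")

    @property
    def n_people(self) -> int:
        return len(self.people)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def column_index(self, variant_ids) -> np.ndarray:
        from .errors import LookupFailure
        idx = []
        for v in variant_ids:
            if v not in self._index:
                raise LookupFailure(f"variant {v!r} absent from panel")
            idx.append(self._index[v])
        return np.asarray(idx, dtype=int)

    def dosage_matrix(self, variant_ids) -> np.ndarray:
        """Float dosage columns for the requested variants, in order."""
        return self.dosages[:, self.column_index(variant_ids)].astype(float)


def _block_sizes(n_variants: int, n_blocks: int) -> np.ndarray:
    base = np.full(n_blocks, n_variants // n_blocks, dtype=int)
    base[: n_variants % n_blocks] += 1
    return base


def _block_positions(n_blocks: int):
    """Deterministic chrom/pos layout: blocks cycle through chromosomes 1-22.

    Chromosome-6 blocks advance in 3 Mb steps from 10 Mb, so some land
    inside the MHC interval (25.5-33.5 Mb) and exercise that exclusion.
    """
    chroms, starts = [], []
    for b in range(n_blocks):
        chroms.append(str(1 + b % 22))
        starts.append(10_000_000 + (b // 22) * 3_000_000)
    return chroms, starts


def _simulate_dosages(rng, n_people: int, sizes: np.ndarray,
                      freqs: np.ndarray, copy_prob: float) -> np.ndarray:
    """Two haplotype copies of the lead-copy LD construction per block."""
    out = np.empty((n_people, int(sizes.sum())), dtype=np.int8)
    col = 0
    for size, p in zip(sizes, freqs):
        geno = np.zeros((n_people, size), dtype=np.int8)
        for _copy in range(2):
            lead = rng.random((n_people, 1)) < p
            indep = rng.random((n_people, size)) < p
            take_lead = rng.random((n_people, size)) < copy_prob
            geno += np.where(take_lead, lead, indep).astype(np.int8)
        out[:, col: col + size] = geno
        col += size
    return out


def _draw_alleles(rng, n: int, palindromic_frac: float) -> tuple[list, list]:
    eff, oth = [], []
    pal = rng.random(n) < palindromic_frac
    pick_np = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=n)
    pick_p = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)
    for i in range(n):
        a, b = (_PALINDROMIC_PAIRS[pick_p[i]] if pal[i]
                else _NON_PALINDROMIC_PAIRS[pick_np[i]])
        eff.append(a)
        oth.append(b)
    return eff, oth


def simulate_panel(config: SimConfig) -> GenotypePanel:
    """Generate an LD-block-structured genotype panel.

    Within-block pairwise dosage correlation targets ``config.block_ld``;
    blocks are mutually independent; each block's allele frequency is
    drawn uniformly from ``config.maf_range``.
    """
    config.validate()
    sizes = _block_sizes(config.n_variants, config.n_blocks)
    rng = _rng(config, "panel")
    freqs = rng.uniform(*config.maf_range, size=config.n_blocks)
    copy_prob = float(np.sqrt(config.block_ld))
    dosages = _simulate_dosages(rng, config.n_people_panel, sizes, freqs, copy_prob)

    allele_rng = _rng(config, "alleles")
    eff, oth = _draw_alleles(allele_rng, config.n_variants, config.palindromic_frac)
    chroms, starts = _block_positions(config.n_blocks)
    block_of = np.repeat(np.arange(config.n_blocks), sizes)
    offsets = np.concatenate([np.arange(s) for s in sizes])
    variants = pd.DataFrame({
        "variant_id": [f"rs{i:06d}" for i in range(config.n_variants)],
        "chrom": [chroms[b] for b in block_of],
        "pos": [starts[b] + 10_000 * int(o) for b, o in zip(block_of, offsets)],
        "effect_allele": eff,
        "other_allele": oth,
        "block": block_of,
        "freq": [float(freqs[b]) for b in block_of],
    })
    people = [f"P{i:06d}" for i in range(config.n_people_panel)]
    return GenotypePanel(people=people, variants=variants, dosages=dosages)


def true_effects(config: SimConfig) -> np.ndarray:
    """Per-variant true effects on log-WBC: n_causal draws from N(0, effect_sd^2)."""
    rng = _rng(config, "effects")
    beta = np.zeros(config.n_variants)
    causal = rng.choice(config.n_variants, size=config.n_causal, replace=False)
    beta[causal] = rng.normal(0.0, config.effect_sd, size=config.n_causal)
    return beta


def simulate_summary_stats(panel: GenotypePanel, config: SimConfig) -> pd.DataFrame:
    """Single-variant least-squares summary statistics from a simulated GWAS.

    A fresh discovery cohort of ``config.gwas_n`` people is generated with
    the same LD structure; the phenotype is the true genetic value plus
    unit-variance noise.  Ground-truth columns (``true_beta``, ``block``)
    are retained for testing and stripped by the TSV writer.
    """
    if config.gwas_n < 2:
        raise ConfigError("gwas_n must be at least 2")
    sizes = _block_sizes(config.n_variants, config.n_blocks)
    freqs = panel.variants.groupby("block")["freq"].first().to_numpy()
    copy_prob = float(np.sqrt(config.block_ld))
    g_rng = _rng(config, "gwas_panel")
    G = _simulate_dosages(g_rng, config.gwas_n, sizes, freqs, copy_prob)

    beta_true = true_effects(config)
    p_rng = _rng(config, "gwas_pheno")
    y = G.astype(float) @ beta_true + p_rng.normal(0.0, 1.0, size=config.gwas_n)

    n = config.gwas_n
    y_c = y - y.mean()
    yy = float(y_c @ y_c)
    beta_hat = np.empty(config.n_variants)
    se = np.empty(config.n_variants)
    eaf = np.empty(config.n_variants)
    chunk = 512
    for lo in range(0, config.n_variants, chunk):
        hi = min(lo + chunk, config.n_variants)
        Gc = G[:, lo:hi].astype(float)
        means = Gc.mean(axis=0)
        eaf[lo:hi] = means / 2.0
        Gc -= means
        gg = np.einsum("ij,ij->j", Gc, Gc)
        gy = y_c @ Gc
        gg_safe = np.where(gg > 0, gg, np.nan)
        b = gy / gg_safe
        resid_ss = yy - b * gy
        sigma2 = resid_ss / (n - 2)
        beta_hat[lo:hi] = b
        se[lo:hi] = np.sqrt(sigma2 / gg_safe)
    from scipy import stats as _st
    with np.errstate(invalid="ignore", divide="ignore"):
        tval = beta_hat / se
    pval = 2.0 * _st.t.sf(np.abs(tval), df=n - 2)
    # monomorphic columns carry no evidence
    pval = np.where(np.isnan(pval), 1.0, pval)
    beta_hat = np.where(np.isnan(beta_hat), 0.0, beta_hat)

    info = _rng(config, "info").uniform(0.3, 1.0, size=config.n_variants)
    out = panel.variants[["variant_id", "chrom", "pos",
                          "effect_allele", "other_allele", "block"]].copy()
    out["beta"] = beta_hat
    out["p"] = np.clip(pval, np.finfo(float).tiny, 1.0)
    out["eaf"] = np.clip(eaf, 1e-6, 1.0 - 1e-6)
    out["info"] = info
    out["true_beta"] = beta_true
    return out[["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                "beta", "p", "eaf", "info", "true_beta", "block"]]


_PHENOTYPE_NAMES = [
    "lymphoid_malignancy", "myeloid_malignancy", "plasma_cell_malignancy",
    "systemic_lupus_erythematosus", "chronic_leukemia", "acute_leukemia",
]


def simulate_catalog(summary: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Disease-association catalog with ground-truth block tags.

    ``config.n_disease_loci`` variants are labeled with synthetic disease
    phenotype names and p-values below ``config.catalog_p_max``; half are
    drawn (where possible) from LD blocks that contain a WBC-significant
    variant, the rest from other blocks.  The ``block`` column is the
    ground-truth tag used by tests; the TSV writer strips it.
    """
    if config.n_disease_loci > len(summary):
        raise ConfigError("n_disease_loci cannot exceed the number of variants")
    if config.n_disease_loci == 0:
        return pd.DataFrame(columns=["variant_id", "phenotype", "p", "block"])
    rng = _rng(config, "catalog")
    wbc_blocks = set(summary.loc[summary["p"] < 5e-6, "block"])
    in_blocks = summary.index[summary["block"].isin(wbc_blocks)].to_numpy()
    out_blocks = summary.index[~summary["block"].isin(wbc_blocks)].to_numpy()
    n_linked = min(config.n_disease_loci // 2, len(in_blocks))
    n_other = config.n_disease_loci - n_linked
    chosen = []
    if n_linked:
        chosen.append(rng.choice(in_blocks, size=n_linked, replace=False))
    chosen.append(rng.choice(out_blocks, size=min(n_other, len(out_blocks)),
                             replace=False))
    idx = np.concatenate(chosen)
    rows = summary.loc[idx]
    pvals = config.catalog_p_max * 10.0 ** (-rng.uniform(0.5, 8.0, size=len(idx)))
    names = [f"{_PHENOTYPE_NAMES[i % len(_PHENOTYPE_NAMES)]}_{i % 7:02d}"
             for i in range(len(idx))]
    return pd.DataFrame({
        "variant_id": rows["variant_id"].to_numpy(),
        "phenotype": names,
        "p": pvals,
        "block": rows["block"].to_numpy(),
    }).reset_index(drop=True)


def true_raw_score(panel: GenotypePanel, config: SimConfig) -> np.ndarray:
    """Raw true genetic value per panel person (dosage times true effect)."""
    return panel.dosages.astype(float) @ true_effects(config)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def simulate_covariates(n: int, config: SimConfig, rng) -> pd.DataFrame:
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    age = np.clip(age, *config.age_bounds)
    sex = (rng.random(n) < config.female_frac).astype(int)  # 1 = female
    cov = {"age": age, "sex": sex}
    for k in range(config.n_pcs):
        cov[f"pc{k + 1}"] = rng.normal(0.0, 1.0, size=n)
    return pd.DataFrame(cov)


def _round_count(x: np.ndarray) -> np.ndarray:
    """Clinical assays report WBC counts in multiples of 100 cells/uL."""
    return np.maximum(np.round(x / 100.0) * 100.0, 100.0)


def simulate_wbc_cohort(scores: np.ndarray, config: SimConfig,
                        rng=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated WBC measures driven partly by the standardized score.

    Per person ``i``: baseline log-WBC = wbc_log_mean + score_effect*score_i
    + age/sex terms + between-person noise; each of 1+Poisson measures adds
    within-person noise.  Returns ``(persons, observations)``.
    """
    if rng is None:
        rng = _rng(config, "wbc")
    n = len(scores)
    persons = simulate_covariates(n, config, rng)
    persons.insert(0, "person_id", [f"P{i:06d}" for i in range(n)])
    persons["score_true"] = scores
    base = (config.wbc_log_mean
            + config.score_effect * np.asarray(scores)
            + config.beta_age * (persons["age"].to_numpy() - config.age_mean)
            + config.beta_female * persons["sex"].to_numpy()
            + rng.normal(0.0, config.wbc_log_sd_between, size=n))
    n_meas = 1 + rng.poisson(config.mean_extra_measures, size=n)
    pid = np.repeat(persons["person_id"].to_numpy(), n_meas)
    base_rep = np.repeat(base, n_meas)
    total = int(n_meas.sum())
    logw = base_rep + rng.normal(0.0, config.wbc_log_sd_within, size=total)
    counts = _round_count(np.exp(logw))
    dates = np.concatenate([736_000 + np.sort(rng.integers(0, 3650, size=m))
                            for m in n_meas])
    obs = pd.DataFrame({
        "person_id": pid,
        "date": dates,
        "count": counts,
        "assay_lower": config.assay_lower,
        "assay_upper": config.assay_upper,
    })
    return persons, obs


def simulate_outlier_outcome(scores: np.ndarray, log_or: float,
                             base_rate: float, rng) -> np.ndarray:
    """Binary outcome with a specified log odds-ratio per score s.d.

    The intercept is solved so the marginal event rate matches
    ``base_rate`` given the empirical score distribution.  Used by
    parameter-recovery studies for the logistic stages.
    """
    from scipy.optimize import brentq
    s = np.asarray(scores, dtype=float)

    def rate(b0):
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + log_or * s))))) - base_rate

    b0 = brentq(rate, -30.0, 30.0)
    prob = 1.0 / (1.0 + np.exp(-(b0 + log_or * s)))
    return (rng.random(len(s)) < prob).astype(int)


def simulate_biopsy_cohort(config: SimConfig, rng=None,
                           scores: np.ndarray | None = None) -> pd.DataFrame:
    """Bone marrow biopsy cohort; pathology is independent of the score.

    Normal-outcome biopsy WBC tracks the person's genetic expectation
    (low tail, since the biopsy indication was a low count); abnormal
    outcome WBC is disease-driven and independent of the score.
    """
    if rng is None:
        rng = _rng(config, "biopsy")
    n = config.n_biopsy
    if scores is None:
        scores = rng.normal(config.biopsy_score_mean, config.biopsy_score_sd, size=n)
    abnormal = rng.random(n) < config.biopsy_abnormal_frac
    logw = np.where(
        abnormal,
        rng.normal(7.90, 0.35, size=n),
        8.10 + config.score_effect * np.asarray(scores) + rng.normal(0.0, 0.25, size=n),
    )
    comorbid = np.where(abnormal, rng.random(n) < 0.83, rng.random(n) < 0.45)
    cov = simulate_covariates(n, config, rng)
    out = pd.DataFrame({
        "person_id": [f"B{i:04d}" for i in range(n)],
        "score": scores,
        "wbc_at_biopsy": _round_count(np.exp(logw)),
        "other_heme_comorbidity": comorbid.astype(int),
        "outcome": np.where(abnormal, "abnormal", "normal"),
    })
    return pd.concat([out, cov], axis=1)


def simulate_exposure_timelines(scores: np.ndarray, config: SimConfig,
                                rng=None, kind: str = "taxane"
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drug-exposure timelines with proportional-hazards event times.

    The latent event day is exponential with rate
    ``hazard_baseline/30 * exp(loghr * score)``; the measurement stream
    contains routine counts above the outcome threshold plus, if the
    event occurs in the observation window, one sub-threshold count on
    the event day.  Returns ``(persons, measures)`` for
    :func:`wbcpgs.clinassoc.build_exposure_cohort`.
    """
    if rng is None:
        rng = _rng(config, kind)
    if kind == "taxane":
        rate_day = config.hazard_baseline / 30.0
        loghr = config.hazard_loghr_per_sd
        horizon = config.horizon_days
    elif kind == "azathioprine":
        rate_day = config.aza_hazard_baseline / 30.0
        loghr = config.aza_loghr_per_sd
        horizon = config.aza_horizon_days
    else:
        raise ConfigError(f"unknown exposure kind {kind!r}")
    n = len(scores)
    cov = simulate_covariates(n, config, rng)
    baseline = _round_count(np.exp(
        config.wbc_log_mean + config.score_effect * np.asarray(scores)
        + rng.normal(0.0, config.wbc_log_sd_between, size=n)))
    dose = np.round(rng.normal(100.0, 15.0, size=n), 1)
    duration = np.round(rng.uniform(1.0, 5.0, size=n), 1)
    rates = rate_day * np.exp(loghr * np.asarray(scores))
    event_day = rng.exponential(1.0 / rates)
    if kind == "taxane":
        second_cycle = np.round(rng.normal(config.second_cycle_mean_day, 3.0, size=n))
        second_cycle = np.clip(second_cycle, 7.0, None)
        last_enc = np.full(n, np.inf)
    else:
        second_cycle = np.full(n, np.inf)
        last_enc = np.ceil(rng.uniform(60.0, horizon, size=n))
    persons = pd.DataFrame({
        "person_id": [f"X{i:05d}" for i in range(n)],
        "score": scores,
        "baseline_wbc": baseline,
        "dose": dose,
        "duration": duration,
        "second_cycle_day": second_cycle,
        "last_encounter_day": last_enc,
    })
    persons = pd.concat([persons, cov], axis=1)

    threshold = 3000.0
    rows = []
    for i in range(n):
        censor = min(second_cycle[i], last_enc[i], horizon)
        rows.append((persons.at[i, "person_id"], 0, baseline[i]))
        step = 7 if kind == "taxane" else 30
        for day in range(step, int(min(censor, horizon)) + 1, step):
            c = max(_round_count(np.exp(np.log(max(baseline[i], 200.0))
                                        + rng.normal(-0.05, 0.1)))[()],
                    threshold + 100.0)
            rows.append((persons.at[i, "person_id"], day, c))
        ev = int(np.ceil(event_day[i]))
        if ev <= censor:
            rows.append((persons.at[i, "person_id"], ev,
                         _round_count(np.array([threshold * rng.uniform(0.5, 0.96)]))[0]))
    measures = pd.DataFrame(rows, columns=["person_id", "day", "count"])
    return persons, measures


def simulate_exposure_records(scores: np.ndarray, config: SimConfig,
                              rng=None, kind: str = "taxane") -> pd.DataFrame:
    """Time-to-event records drawn directly from the hazard model.

    Same generative law as :func:`simulate_exposure_timelines` but
    skipping the measurement stream — the event day is exponential with
    rate ``hazard_baseline/30 * exp(loghr * score)`` and censoring is
    administrative (second cycle / horizon for taxane, last encounter
    for azathioprine).  Used by parameter-recovery studies that fit the
    survival stage many times.
    """
    if rng is None:
        rng = _rng(config, kind)
    if kind == "taxane":
        rate_day = config.hazard_baseline / 30.0
        loghr = config.hazard_loghr_per_sd
        horizon = config.horizon_days
    elif kind == "azathioprine":
        rate_day = config.aza_hazard_baseline / 30.0
        loghr = config.aza_loghr_per_sd
        horizon = config.aza_horizon_days
    else:
        raise ConfigError(f"unknown exposure kind {kind!r}")
    s = np.asarray(scores, dtype=float)
    n = len(s)
    cov = simulate_covariates(n, config, rng)
    rates = rate_day * np.exp(loghr * s)
    event_day = np.ceil(rng.exponential(1.0 / rates))
    if kind == "taxane":
        censor = np.minimum(
            np.clip(np.round(rng.normal(config.second_cycle_mean_day, 3.0, n)),
                    7.0, None), horizon)
    else:
        censor = np.minimum(np.ceil(rng.uniform(60.0, horizon, n)), horizon)
    event = event_day <= censor
    out = pd.DataFrame({
        "person_id": [f"R{i:05d}" for i in range(n)],
        "score": s,
        "time": np.where(event, event_day, censor),
        "event": event,
        "censor_reason": np.where(event, "event",
                                  "second_cycle" if kind == "taxane"
                                  else "last_encounter"),
        "dose": np.round(rng.normal(100.0, 15.0, n), 1),
        "duration": np.round(rng.uniform(1.0, 5.0, n), 1),
    })
    return pd.concat([out, cov], axis=1)


@dataclass
class CohortBundle:
    """All simulated analysis cohorts for one configuration."""

    wbc_persons: pd.DataFrame
    wbc_observations: pd.DataFrame
    biopsy: pd.DataFrame
    taxane_persons: pd.DataFrame
    taxane_measures: pd.DataFrame
    azathioprine_persons: pd.DataFrame
    azathioprine_measures: pd.DataFrame


def simulate_cohorts(panel: GenotypePanel, model_true_score: np.ndarray,
                     config: SimConfig) -> CohortBundle:
    """Generate every analysis cohort from the panel's true score vector.

    ``model_true_score`` must be standardized; the WBC cohort covers all
    panel people, the exposure cohorts re-use the first ``n_taxane`` /
    ``n_azathioprine`` people's scores, and the biopsy cohort draws its
    own score distribution (enriched for low values, as biopsies for a
    low count are).
    """
    s = np.asarray(model_true_score, dtype=float)
    if len(s) != panel.n_people:
        raise ConfigError("score vector length must match the panel")
    persons, obs = simulate_wbc_cohort(s, config)
    biopsy = simulate_biopsy_cohort(config)
    n_tax = min(config.n_taxane, panel.n_people)
    n_aza = min(config.n_azathioprine, panel.n_people)
    tax_p, tax_m = simulate_exposure_timelines(s[:n_tax], config, kind="taxane")
    aza_p, aza_m = simulate_exposure_timelines(s[:n_aza], config, kind="azathioprine")
    return CohortBundle(persons, obs, biopsy, tax_p, tax_m, aza_p, aza_m)


# ---------------------------------------------------------------------------
# deterministic worked-example fixture
# ---------------------------------------------------------------------------

_WORKED_EXAMPLE_SPEC = [
    # (outcome, stratum_lo, stratum_hi, n_total, n_within)
    ("normal", 3500.0, 4000.0, 10, 10),
    ("normal", 3000.0, 3500.0, 13, 9),
    ("normal", 2500.0, 3000.0, 18, 1),
    ("normal", 0.0, 2500.0, 18, 0),
    ("abnormal", 3500.0, 4000.0, 3, 3),
    ("abnormal", 3000.0, 3500.0, 6, 0),
    ("abnormal", 2500.0, 3000.0, 20, 0),
    ("abnormal", 0.0, 2500.0, 10, 0),
]


def worked_example_fixture(window_size: int = 40
                   ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Deterministic biopsy cohort reproducing the study's stratified worked-example tallies.

    Each biopsied person is placed at an isolated score value with its own
    ``window_size``-member reference-cohort window (scores exactly equal,
    neighbouring windows more than the +/-0.2 s.d. half-width apart).  A
    within-range person's window values all equal their biopsy count (the
    2.5th-percentile threshold then sits exactly at the count, exercising
    the "at or above" boundary); an outside-range person's window values
    sit 100 cells/uL higher.  Returns ``(biopsy, cohort_scores,
    cohort_lowest_wbc)``.
    """
    rows, scores, lowest = [], [], []
    i = 0
    for outcome, lo, hi, n_total, n_within in _WORKED_EXAMPLE_SPEC:
        span = hi - lo
        for k in range(n_total):
            # strictly inside (lo, hi]; spread deterministically, 100-multiples
            wbc = lo + max(100.0, round(span * (k + 1) / (n_total + 1) / 100) * 100)
            wbc = min(wbc, hi)
            score = float(i)  # 1.0 spacing >> 2 * 0.2 half-width
            within = k < n_within
            rows.append({
                "person_id": f"T1_{i:03d}",
                "score": score,
                "wbc_at_biopsy": wbc,
                "other_heme_comorbidity": 0,
                "outcome": outcome,
            })
            member_value = wbc if within else wbc + 100.0
            scores.extend([score] * window_size)
            lowest.extend([member_value] * window_size)
            i += 1
    return (pd.DataFrame(rows), np.asarray(scores, dtype=float),
            np.asarray(lowest, dtype=float))
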