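"""Residual-disease-signal diagnostics on the score.

The score's variants are split into five quintiles of effect-size
magnitude, a sub-score is built per quintile, and each sub-score is
scanned against a panel of binary phenotypes.  Two enrichment tests
probe whether a quintile carries more nominal associations than chance:

* a permutation test that rebuilds same-size sub-scores from random
  variant subsets of the full model and compares nominal-association
  counts (empiric p with the add-one rule, so 0 exceedances out of 1000
  permutations prints 0.001);
* a per-SNP binomial test that counts single-variant nominal
  associations per phenotype against an exact Binomial(n, 0.05) tail.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _glm
from .errors import ConfigError, FitError, InsufficientDataError
from .pgs import PgsModel, score as pgs_score, standardize
from .synthdata import GenotypePanel


@dataclass
class QuintileModel:
    """One effect-size quintile of a score model (index 1 = smallest |weight|)."""

    index: int
    variants: pd.DataFrame  # variant_id, effect_allele, weight
    bounds: tuple[float, float]  # |weight| range covered (closed)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def quintile_split(model: PgsModel) -> list[QuintileModel]:
    """Partition the model's variants into five |weight| quintiles.

    Variants are ranked by effect-size magnitude (ties broken by variant
    id, assigned to the lower quintile); rank cuts at the 20/40/60/80th
    percentiles give sizes differing by at most one.  Quintile 4 spans
    the 60-80th percentile ranks.
    """
    n = model.n_variants
    if n < 5:
        raise InsufficientDataError("quintile split needs at least 5 variants")
    df = model.variants.copy()
    df["_mag"] = df["weight"].abs()
    df = df.sort_values(["_mag", "variant_id"], kind="mergesort").reset_index(drop=True)
    ranks = np.arange(n)
    q_of = (ranks * 5) // n  # lower quintile wins on boundaries
    out = []
    for q in range(5):
        member = df.loc[q_of == q].drop(columns="_mag").reset_index(drop=True)
        mags = df.loc[q_of == q, "_mag"]
        out.append(QuintileModel(index=q + 1, variants=member,
                                 bounds=(float(mags.min()), float(mags.max()))))
    return out


def quintile_score(panel: GenotypePanel, quintile: QuintileModel) -> np.ndarray:
    """Raw sub-score for one quintile (same dosage/weight convention)."""
    sub = PgsModel(variants=quintile.variants)
    return pgs_score(panel, sub)


def phenome_scan(scores: np.ndarray, phenotypes: pd.DataFrame,
                 covariates: pd.DataFrame | None = None,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Logistic scan of one standardized score against binary phenotypes.

    One maximum-likelihood logistic fit per phenotype column (via
    :func:`wbcpgs.clinassoc.logistic_fit`); phenotypes that fail to fit
    (separation, a single outcome class) are marked unestimable rather
    than dropped.  Returns one row per phenotype with the odds ratio per
    s.d., Wald CI, p, direction and nominal flag.
    """
    from .clinassoc import logistic_fit
    rows = []
    for name in phenotypes.columns:
        y = phenotypes[name].to_numpy()
        try:
            fit = logistic_fit(y, scores, covariates)
            rows.append({"phenotype": name, "or_per_sd": fit.estimate,
                         "ci_low": fit.ci_low, "ci_high": fit.ci_high,
                         "p": fit.p,
                         "direction": "positive" if fit.estimate >= 1.0 else "inverse",
                         "nominal": fit.p < alpha, "estimable": True,
                         "error": ""})
        except (FitError, InsufficientDataError, ValueError) as exc:
            rows.append({"phenotype": name, "or_per_sd": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                         "direction": "", "nominal": False,
                         "estimable": False, "error": str(exc)})
    return pd.DataFrame(rows)


@dataclass
class PermutationResult:
    observed_count: int
    perm_counts: np.ndarray
    empiric_p: float
    n_perm: int
    per_phenotype: pd.DataFrame


def _design(covariates, n) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(n), C])


def _standardize_columns(S: np.ndarray) -> np.ndarray:
    m = S.mean(axis=0)
    sd = S.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (S - m) / sd


def _nominal_counts(Z, phenotypes, S, alpha, direction):
    """Per-column counts of nominal phenotype associations (score test)."""
    counts = np.zeros(S.shape[1], dtype=int)
    per_pheno = []
    for name in phenotypes.columns:
        y = phenotypes[name].to_numpy(dtype=float)
        _, p, sign = _glm.score_test_columns(Z, y, S)
        hit = p < alpha
        if direction == "positive":
            hit &= sign > 0
        elif direction == "inverse":
            hit &= sign < 0
        counts += hit.astype(int)
        per_pheno.append((name, p[0], sign[0]))
    return counts, pd.DataFrame(per_pheno, columns=["phenotype", "p", "sign"])


def permutation_count_test(model: PgsModel, quintile: QuintileModel,
                           panel: GenotypePanel, phenotypes: pd.DataFrame,
                           covariates: pd.DataFrame | None = None,
                           n_perm: int = 1000, seed: int = 0,
                           direction: str = "positive", alpha: float = 0.05,
                           mode: str = "variant",
                           max_cells: float = 2e7) -> PermutationResult:
    """Permutation null for a quintile's nominal-association count.

    Observed statistic: number of phenotypes nominally associated
    (p < alpha, direction per ``direction``: positive-only by default)
    with the quintile sub-score.  Null draws rebuild same-size sub-scores
    from random variant subsets of the full model (``mode='variant'``) or
    permute person labels of the quintile score (``mode='person'``).
    Empiric p uses the add-one rule (k+1)/(n_perm+1).

    Associations (observed and permuted alike) are assessed with the Rao
    score test from a covariate-only logistic null fit; see
    docs/methods.md for why this engine is used here.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be at least 1")
    n_cells = float(n_perm) * len(phenotypes.columns)
    if n_cells > max_cells:
        raise ConfigError(
            f"n_perm x n_phenotypes = {n_cells:.3g} exceeds max_cells="
            f"{max_cells:.3g}; lower n_perm or raise max_cells explicitly")
    rng = np.random.default_rng(seed)
    n_people = panel.n_people
    obs_raw = quintile_score(panel, quintile)

    if mode == "variant":
        D = panel.dosage_matrix(model.variants["variant_id"])
        w = model.weights()
        m, k = len(w), quintile.n_variants
        W = np.zeros((m, n_perm))
        for b in range(n_perm):
            pick = rng.choice(m, size=k, replace=False)
            W[pick, b] = w[pick]
        S = np.column_stack([obs_raw, D @ W])
    elif mode == "person":
        perms = np.column_stack([rng.permutation(obs_raw) for _ in range(n_perm)])
        S = np.column_stack([obs_raw, perms])
    else:
        raise ConfigError(f"unknown permutation mode {mode!r}")

    S = _standardize_columns(S)
    Z = _design(covariates, n_people if mode == "variant" else len(obs_raw))
    counts, per_pheno = _nominal_counts(Z, phenotypes, S, alpha, direction)
    observed, perm_counts = int(counts[0]), counts[1:]
    k_exceed = int(np.sum(perm_counts >= observed))
    empiric_p = (1 + k_exceed) / (n_perm + 1)
    return PermutationResult(observed, perm_counts, empiric_p, n_perm, per_pheno)


def binomial_tail(k: int, n: int, rate: float = 0.05) -> float:
    """Exact upper tail P(X >= k), X ~ Binomial(n, rate)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, rate))


def per_snp_binomial(quintile: QuintileModel, panel: GenotypePanel,
                     phenotypes: pd.DataFrame,
                     covariates: pd.DataFrame | None = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-phenotype count of nominal single-SNP associations in a quintile,
    with exact binomial enrichment tails.

    For each phenotype, k = number of the quintile's SNPs individually
    associated at p < alpha (score test with the same covariates);
    ``binom_p`` = P(X >= k) for X ~ Binomial(n_q, alpha).  ``enriched``
    flags tail p < 0.05.
    """
    D = panel.dosage_matrix(quintile.variants["variant_id"])
    Z = _design(covariates, panel.n_people)
    n_q = quintile.n_variants
    rows = []
    for name in phenotypes.columns:
        y = phenotypes[name].to_numpy(dtype=float)
        _, p, _ = _glm.score_test_columns(Z, y, D)
        k = int(np.sum(p < alpha))
        tail = binomial_tail(k, n_q, alpha)
        rows.append({"phenotype": name, "n_snps": n_q, "k_nominal": k,
                     "binom_p": tail, "enriched": tail < 0.05})
    return pd.DataFrame(rows)
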