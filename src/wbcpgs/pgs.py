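"""Construction of the benign WBC polygenic score.

The score is a weighted allele-dosage sum built from GWAS summary
statistics in five steps: quality-control filtering (association p,
minor allele frequency, imputation quality, non-palindromic alleles),
greedy LD clumping against a genotype reference panel, exclusion of the
MHC region, exclusion of variants in LD with disease-catalog loci, and
an optional sensitivity re-scoring that drops variants nominally
associated with hematological malignancy.  Every excluded variant is
logged with the step that removed it, so the pipeline conserves
variants: input = retained + excluded.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (DegenerateInputError, InsufficientDataError,
                     LookupFailure, ValidationError)
from .synthdata import GenotypePanel

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}
_BASES = {"A", "C", "G", "T"}

#: Major histocompatibility complex, 1-based inclusive.
MHC_REGION = None  # set below once GenomicRegion is defined


@dataclass(frozen=True)
class GenomicRegion:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"region start {self.start} > end {self.end}")

    @classmethod
    def parse(cls, text: str) -> "GenomicRegion":
        m = re.fullmatch(r"(\w+):(\d+)-(\d+)", text)
        if not m:
            raise ValidationError(f"cannot parse region {text!r}")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)))

    def contains(self, chrom, pos) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end


MHC_REGION = GenomicRegion("6", 25_500_000, 33_500_000)


@dataclass
class PgsModel:
    """Retained variants/weights plus the provenance of every exclusion.

    ``variants`` columns: variant_id, effect_allele, weight.
    ``exclusions`` columns: variant_id, step, detail — ``step`` is one of
    qc, clump, mhc, catalog_ld, sensitivity.
    """

    variants: pd.DataFrame
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "step", "detail"]))
    threshold: float | None = None
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self):
        ids = pd.concat([self.variants["variant_id"],
                         self.exclusions["variant_id"]]) if len(self.exclusions) \
            else self.variants["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].tolist()
            raise ValidationError("variant appears twice in model/exclusion log",
                                  rows=dup)
        if self.sd is not None and self.sd <= 0:
            raise DegenerateInputError("standardization s.d. must be positive")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def weights(self) -> np.ndarray:
        return self.variants["weight"].to_numpy(dtype=float)


def _excl(df: pd.DataFrame, step: str, detail) -> pd.DataFrame:
    if isinstance(detail, str):
        detail = [detail] * len(df)
    return pd.DataFrame({"variant_id": df["variant_id"].to_numpy(),
                         "step": step, "detail": detail})


def is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _PALINDROMIC


def validate_alleles(summary: pd.DataFrame) -> None:
    bad = ~(summary["effect_allele"].isin(_BASES)
            & summary["other_allele"].isin(_BASES))
    if bad.any():
        raise ValidationError(
            f"{int(bad.sum())} records with malformed alleles",
            rows=summary.loc[bad, "variant_id"].tolist())


def qc_filter(summary: pd.DataFrame, p_max: float = 5e-6,
              maf_min: float = 0.01, info_min: float = 0.7
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain non-palindromic variants passing p, MAF and imputation filters.

    Retained iff ``p < p_max`` and ``min(eaf, 1-eaf) > maf_min`` and
    ``info >= info_min`` and the allele pair is not A/T or C/G.
    Returns ``(retained, exclusion_log)``.
    """
    if len(summary) == 0:
        raise InsufficientDataError("empty summary table")
    validate_alleles(summary)
    maf = np.minimum(summary["eaf"], 1.0 - summary["eaf"])
    pal = np.array([is_palindromic(a, b) for a, b in
                    zip(summary["effect_allele"], summary["other_allele"])])
    keep = ((summary["p"].to_numpy() < p_max)
            & (maf.to_numpy() > maf_min)
            & (summary["info"].to_numpy() >= info_min)
            & ~pal)
    reasons = np.select(
        [pal, summary["p"].to_numpy() >= p_max, maf.to_numpy() <= maf_min],
        ["palindromic", "p", "maf"], default="info")
    return (summary.loc[keep].reset_index(drop=True),
            _excl(summary.loc[~keep], "qc", list(reasons[~keep])))


def _corr_matrix(D: np.ndarray) -> np.ndarray:
    """Pearson correlation of dosage columns; zero-variance columns -> 0."""
    Dc = D - D.mean(axis=0)
    sd = Dc.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    C = (Dc / sd_safe).T @ (Dc / sd_safe) / D.shape[0]
    C[sd == 0, :] = 0.0
    C[:, sd == 0] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def ld_clump(candidates: pd.DataFrame, panel: GenotypePanel,
             r2_max: float = 0.01) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy p-value-ordered clumping.

    Repeatedly retain the remaining variant with the smallest p (ties
    broken by variant id) and drop every remaining variant whose squared
    dosage correlation with it is >= ``r2_max``.  All retained pairs then
    have r-squared below ``r2_max``.  Returns ``(retained, exclusion_log)``.
    """
    if len(candidates) == 0:
        return candidates.copy(), _excl(candidates, "clump", "")
    base = candidates.reset_index(drop=True)
    D = panel.dosage_matrix(base["variant_id"])
    order = base.sort_values(["p", "variant_id"], kind="mergesort")
    r2 = _corr_matrix(D) ** 2
    alive = np.ones(len(base), dtype=bool)
    kept_rows, dropped = [], []
    for idx in order.index:
        if not alive[idx]:
            continue
        kept_rows.append(idx)
        alive[idx] = False
        lead = base.at[idx, "variant_id"]
        for j in np.flatnonzero(alive & (r2[idx] >= r2_max)):
            dropped.append((j, lead))
            alive[j] = False
    kept = base.iloc[sorted(kept_rows)].reset_index(drop=True)
    drop_df = base.iloc[[j for j, _ in dropped]]
    detail = [f"r2>={r2_max} with {lead}" for _, lead in dropped]
    return kept, _excl(drop_df, "clump", detail)


def exclude_region(variants: pd.DataFrame, region: GenomicRegion = MHC_REGION
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop variants inside a genomic interval (1-based inclusive)."""
    inside = np.array([region.contains(c, p) for c, p in
                       zip(variants["chrom"], variants["pos"])])
    return (variants.loc[~inside].reset_index(drop=True),
            _excl(variants.loc[inside], "mhc",
                  f"{region.chrom}:{region.start}-{region.end}"))


def exclude_catalog_ld(variants: pd.DataFrame, catalog: pd.DataFrame,
                       panel: GenotypePanel, catalog_p_max: float = 5e-7,
                       r2_min: float = 0.5
                       ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Drop variants in LD (r-squared strictly above ``r2_min``) with a
    disease-catalog variant reported at ``p < catalog_p_max``.

    Catalog variants absent from the panel are skipped and returned as
    warnings.  Returns ``(retained, exclusion_log, warnings)``.
    """
    if panel.n_variants == 0:
        raise LookupFailure("empty genotype panel")
    warnings: list[str] = []
    if len(variants) == 0 or len(catalog) == 0:
        return variants.copy(), _excl(variants.iloc[0:0], "catalog_ld", ""), warnings
    cat = catalog.loc[catalog["p"].to_numpy() < catalog_p_max]
    present = []
    for _, row in cat.iterrows():
        try:
            panel.column_index([row["variant_id"]])
            present.append(row)
        except LookupFailure:
            warnings.append(f"catalog variant {row['variant_id']} absent from panel")
    if not present:
        return variants.copy(), _excl(variants.iloc[0:0], "catalog_ld", ""), warnings
    cat = pd.DataFrame(present)
    Dc = panel.dosage_matrix(variants["variant_id"])
    Dk = panel.dosage_matrix(cat["variant_id"])

    def _std(M):
        Mc = M - M.mean(axis=0)
        sd = Mc.std(axis=0)
        return Mc / np.where(sd > 0, sd, 1.0), sd

    Zc, sd_c = _std(Dc)
    Zk, sd_k = _std(Dk)
    R = Zc.T @ Zk / len(Zc)
    R[sd_c == 0, :] = 0.0
    R[:, sd_k == 0] = 0.0
    r2 = R ** 2
    hit = r2 > r2_min
    drop_mask = hit.any(axis=1)
    detail = []
    for i in np.flatnonzero(drop_mask):
        j = int(np.argmax(r2[i]))
        detail.append(f"r2={r2[i, j]:.3f} with {cat.iloc[j]['variant_id']} "
                      f"({cat.iloc[j]['phenotype']})")
    return (variants.loc[~drop_mask].reset_index(drop=True),
            _excl(variants.loc[drop_mask], "catalog_ld", detail),
            warnings)


def score(panel: GenotypePanel, model: PgsModel) -> np.ndarray:
    """Raw score per person: sum of allele dosage times SNP weight.

    A model variant whose effect allele matches the panel's other allele
    has its dosage flipped to ``2 - d``; a variant matching neither
    allele, or absent from the panel, raises :class:`LookupFailure`.
    Missing (NaN) dosages are mean-imputed per variant.
    """
    if model.n_variants == 0:
        return np.zeros(panel.n_people)
    idx = panel.column_index(model.variants["variant_id"])
    D = panel.dosages[:, idx].astype(float)
    pan_eff = panel.variants["effect_allele"].to_numpy()[idx]
    pan_oth = panel.variants["other_allele"].to_numpy()[idx]
    for j, (_, row) in enumerate(model.variants.iterrows()):
        if row["effect_allele"] == pan_eff[j]:
            continue
        if row["effect_allele"] == pan_oth[j]:
            D[:, j] = 2.0 - D[:, j]
        else:
            raise LookupFailure(
                f"variant {row['variant_id']}: model effect allele "
                f"{row['effect_allele']} matches neither panel allele")
    if np.isnan(D).any():
        col_mean = np.nanmean(D, axis=0)
        nan_at = np.where(np.isnan(D))
        D[nan_at] = col_mean[nan_at[1]]
    return D @ model.weights()


def standardize(raw: np.ndarray, reference: np.ndarray | None = None
                ) -> tuple[np.ndarray, float, float]:
    """Standardize raw scores against a reference cohort's moments.

    Uses the sample standard deviation (ddof=1) of ``reference`` (the
    scored cohort itself when omitted).  Returns ``(z, mean, sd)``.
    """
    raw = np.asarray(raw, dtype=float)
    ref = raw if reference is None else np.asarray(reference, dtype=float)
    if len(np.unique(ref)) < 2:
        raise DegenerateInputError("reference cohort has zero score variance")
    m = float(ref.mean())
    s = float(ref.std(ddof=1))
    return (raw - m) / s, m, s


def sensitivity_exclude(model: PgsModel, per_variant_assoc: pd.DataFrame,
                        p_cut: float) -> PgsModel:
    """Drop model variants with any listed disease association ``p < p_cut``."""
    if not (0.0 < p_cut < 1.0):
        raise ValidationError(f"p_cut must lie in (0, 1), got {p_cut}")
    if len(per_variant_assoc) == 0:
        return model
    flagged = per_variant_assoc.loc[per_variant_assoc["p"].to_numpy() < p_cut]
    worst = flagged.sort_values("p").drop_duplicates("variant_id")
    drop = model.variants["variant_id"].isin(set(worst["variant_id"]))
    detail = {r["variant_id"]: f"{r['phenotype']} p={r['p']:.3g}"
              for _, r in worst.iterrows()}
    dropped = model.variants.loc[drop]
    log = _excl(dropped, "sensitivity",
                [detail[v] for v in dropped["variant_id"]])
    return PgsModel(
        variants=model.variants.loc[~drop].reset_index(drop=True),
        exclusions=pd.concat([model.exclusions, log], ignore_index=True),
        threshold=model.threshold, mean=None, sd=None)


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: np.ndarray | None) -> float:
    """Correlation of residuals after least-squares adjustment of both
    variables on the covariates (intercept always included)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        Z = np.ones((n, 1))
    else:
        Z = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise DegenerateInputError("zero residual variance in partial correlation")
    return float(rx @ ry / denom)


def build_pgs_model(summary: pd.DataFrame, panel: GenotypePanel,
                    catalog: pd.DataFrame | None = None,
                    p_max: float = 5e-6, maf_min: float = 0.01,
                    info_min: float = 0.7, clump_r2: float = 0.01,
                    mhc: GenomicRegion | None = MHC_REGION,
                    catalog_p_max: float = 5e-7, catalog_r2: float = 0.5
                    ) -> PgsModel:
    """Run the full construction chain and assemble a :class:`PgsModel`.

    Order: QC filter -> LD clump -> MHC exclusion -> catalog-LD exclusion.
    The summary table's ``beta`` column provides the weights.
    """
    logs = []
    kept, log = qc_filter(summary, p_max=p_max, maf_min=maf_min, info_min=info_min)
    logs.append(log)
    kept, log = ld_clump(kept, panel, r2_max=clump_r2)
    logs.append(log)
    if mhc is not None:
        kept, log = exclude_region(kept, mhc)
        logs.append(log)
    if catalog is not None:
        kept, log, _warn = exclude_catalog_ld(kept, catalog, panel,
                                              catalog_p_max=catalog_p_max,
                                              r2_min=catalog_r2)
        logs.append(log)
    variants = kept[["variant_id", "effect_allele", "beta"]].rename(
        columns={"beta": "weight"}).reset_index(drop=True)
    model = PgsModel(variants=variants,
                     exclusions=pd.concat(logs, ignore_index=True),
                     threshold=p_max)
    assert model.n_variants + len(model.exclusions) == len(summary)
    return model


def select_threshold(summary: pd.DataFrame, panel: GenotypePanel,
                     wbc_persons: pd.DataFrame,
                     thresholds=(5e-8, 5e-7, 5e-6),
                     covariate_cols=("age", "sex"),
                     wbc_col: str = "median_wbc",
                     catalog: pd.DataFrame | None = None,
                     **build_kwargs) -> tuple[float, pd.DataFrame]:
    """Pick the association p-value threshold with the highest partial
    correlation between the standardized score and median WBC.

    For each threshold the full construction chain is rebuilt, the panel
    is scored and standardized, and the partial correlation with
    ``wbc_persons[wbc_col]`` (adjusting for ``covariate_cols``) is
    computed.  Ties break toward the most stringent threshold.
    Returns ``(chosen_threshold, per_threshold_table)``.
    """
    needed = [wbc_col, *covariate_cols]
    complete = wbc_persons.dropna(subset=[c for c in needed
                                          if c in wbc_persons.columns])
    if len(complete) < 3:
        raise InsufficientDataError("fewer than 3 complete cases")
    cov = (complete[list(covariate_cols)].to_numpy(dtype=float)
           if covariate_cols else None)
    y = complete[wbc_col].to_numpy(dtype=float)
    rows = []
    for t in sorted(thresholds):  # ascending = most stringent first
        model = build_pgs_model(summary, panel, catalog=catalog,
                                p_max=t, **build_kwargs)
        if model.n_variants == 0:
            rows.append({"threshold": t, "n_variants": 0, "partial_r": -np.inf})
            continue
        raw = score(panel, model)
        sub = raw[complete.index.to_numpy()]
        try:
            z, _, _ = standardize(sub)
            r = partial_correlation(z, y, cov)
        except DegenerateInputError:
            r = -np.inf
        rows.append({"threshold": t, "n_variants": model.n_variants,
                     "partial_r": r})
    table = pd.DataFrame(rows)
    best = table.loc[table["partial_r"].idxmax(), "threshold"]  # first max: stringent
    return float(best), table
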