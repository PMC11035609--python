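"""Genotype-informed WBC reference-range machinery.

Per-person summaries (median and lowest count, with a 35,000 cells/uL
cap on plausibly healthy values), assay-outlier flags, sliding-window
percentile curves across the score range (+/-0.2 s.d. windows), the
2.5th-percentile genotype-informed classification of biopsy-time counts,
and the stratified within-range summary table.

Quantile convention: linear interpolation between order statistics
(numpy's default), used identically by every operation here and by the
brute-force oracles in the tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientDataError, ValidationError

DEFAULT_CAP = 35_000.0
DEFAULT_STRATA = ((0.0, 2500.0), (2500.0, 3000.0), (3000.0, 3500.0), (3500.0, 4000.0))


def person_summary(observations: pd.DataFrame, cap: float = DEFAULT_CAP
                   ) -> tuple[pd.DataFrame, list]:
    """Per-person median and minimum WBC over counts surviving the cap.

    Counts above ``cap`` are excluded as likely active disease; a person
    with no surviving observation is dropped and returned in the log.
    """
    surv = observations.loc[observations["count"].to_numpy() <= cap]
    dropped = sorted(set(observations["person_id"]) - set(surv["person_id"]))
    g = surv.groupby("person_id")["count"]
    out = pd.DataFrame({
        "person_id": g.median().index,
        "median_wbc": g.median().to_numpy(),
        "min_wbc": g.min().to_numpy(),
        "n_obs": g.size().to_numpy(),
    }).reset_index(drop=True)
    return out, dropped


def outlier_flag(observations: pd.DataFrame, cap: float = DEFAULT_CAP) -> pd.Series:
    """Per-person flag: any surviving count strictly below its assay's
    lower reference bound."""
    if observations["assay_lower"].isna().any():
        bad = observations.loc[observations["assay_lower"].isna(), "person_id"]
        raise ValidationError("missing assay lower bound", rows=bad.tolist())
    surv = observations.loc[observations["count"].to_numpy() <= cap].copy()
    surv["below"] = surv["count"].to_numpy() < surv["assay_lower"].to_numpy()
    return surv.groupby("person_id")["below"].any()


@dataclass
class WindowPercentile:
    score: float
    p5: float
    p50: float
    p95: float
    n_in_window: int


def window_percentiles(scores: np.ndarray, values: np.ndarray,
                       half_width: float = 0.2,
                       grid: np.ndarray | None = None, min_n: int = 20,
                       percentiles=(5.0, 50.0, 95.0)) -> pd.DataFrame:
    """Percentile curves of ``values`` within +/-``half_width`` score windows.

    At each grid point g the persons with ``|score - g| <= half_width``
    contribute; grid points with fewer than ``min_n`` members are
    omitted.  Returns columns score, p5, p50, p95, n_in_window.
    """
    scores = np.asarray(scores, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(scores) == 0:
        raise InsufficientDataError("no observations for percentile curves")
    if grid is None:
        grid = np.arange(np.floor(scores.min() * 10) / 10,
                         np.ceil(scores.max() * 10) / 10 + 1e-9, 0.1)
    rows = []
    for g in np.asarray(grid, dtype=float):
        member = np.abs(scores - g) <= half_width
        n = int(member.sum())
        if n < min_n:
            continue
        p = np.percentile(values[member], percentiles)
        rows.append({"score": g, "p5": p[0], "p50": p[1], "p95": p[2],
                     "n_in_window": n})
    return pd.DataFrame(rows, columns=["score", "p5", "p50", "p95", "n_in_window"])


def classify_within_range(biopsy: pd.DataFrame, cohort_scores: np.ndarray,
                          cohort_lowest_wbc: np.ndarray,
                          half_width: float = 0.2, percentile: float = 2.5,
                          min_n: int = 20,
                          boundary: str = "at_or_above") -> pd.DataFrame:
    """Genotype-informed range classification of biopsy-time WBC counts.

    For each biopsied person, the threshold is the ``percentile``-th
    percentile of the lowest-observed-WBC distribution among reference
    cohort members whose score lies within ``half_width`` of theirs.
    ``within_range`` is count >= threshold (``boundary='at_or_above'``,
    the default) or strictly above (``boundary='above'``).  Windows with
    fewer than ``min_n`` members are surfaced as unclassifiable.
    """
    if boundary not in ("at_or_above", "above"):
        raise ConfigError(f"unknown boundary rule {boundary!r}")
    cohort_scores = np.asarray(cohort_scores, dtype=float)
    cohort_lowest_wbc = np.asarray(cohort_lowest_wbc, dtype=float)
    rows = []
    for _, rec in biopsy.iterrows():
        member = np.abs(cohort_scores - rec["score"]) <= half_width
        n = int(member.sum())
        if n < min_n:
            rows.append({"person_id": rec["person_id"], "threshold": np.nan,
                         "n_in_window": n, "within_range": pd.NA,
                         "classifiable": False})
            continue
        thr = float(np.percentile(cohort_lowest_wbc[member], percentile))
        w = rec["wbc_at_biopsy"]
        within = (w >= thr) if boundary == "at_or_above" else (w > thr)
        rows.append({"person_id": rec["person_id"], "threshold": thr,
                     "n_in_window": n, "within_range": bool(within),
                     "classifiable": True})
    return pd.DataFrame(rows)


def stratified_summary(classified: pd.DataFrame,
                       strata=DEFAULT_STRATA) -> pd.DataFrame:
    """Per-stratum, per-outcome within-range tallies and percentages.

    ``classified`` needs columns outcome, wbc_at_biopsy, within_range and
    classifiable.  Strata are half-open intervals (lo, hi], must be
    disjoint and ordered.  Percentages are within/total x 100 rounded to
    one decimal; empty cells report n=0 and an undefined (NaN) percentage.
    """
    strata = [tuple(map(float, s)) for s in strata]
    for (a_lo, a_hi), (b_lo, b_hi) in zip(strata, strata[1:]):
        if b_lo < a_hi:
            raise ConfigError("strata must be disjoint and ordered")
    usable = classified.loc[classified["classifiable"].astype(bool)]
    rows = []
    for outcome in sorted(usable["outcome"].unique()):
        sub = usable.loc[usable["outcome"] == outcome]
        wbc = sub["wbc_at_biopsy"].to_numpy(dtype=float)
        for lo, hi in strata:
            member = (wbc > lo) & (wbc <= hi)
            n = int(member.sum())
            n_within = int(sub.loc[member, "within_range"].astype(bool).sum())
            pct = round(100.0 * n_within / n, 1) if n else np.nan
            rows.append({"outcome": outcome, "stratum_lo": lo, "stratum_hi": hi,
                         "n": n, "n_within": n_within, "pct_within": pct})
    return pd.DataFrame(rows)
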