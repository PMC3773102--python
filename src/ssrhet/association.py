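"""Correlation of parental genetic distance with hybrid performance.

Per trait and ploidy group the module correlates the Nei distance between a
hybrid's parents with the hybrid's heterobeltiosis (Pearson r, two-sided p
from ``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2 df), and correlates
yield heterobeltiosis with every other trait's heterobeltiosis.  Stars
follow the usual convention: ``*`` at p < 0.05, ``**`` at p < 0.01.

Missing values are handled by pairwise-complete deletion with the n used
reported per cell.  No multiple-testing correction is applied by default;
Benjamini-Hochberg adjusted p-values are available as an option.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .panel_io import CrossPlan

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float
    p: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


def significance_stars(p: float) -> str:
    if math.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson r with a two-sided p, after pairwise-complete filtering.

    Raises ``ValueError`` with fewer than 3 complete pairs or zero variance
    in either variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(n=n, r=float(r), p=float(p))


def simple_linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares y on x; R^2 equals the squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("zero x-variance; regression undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


def _safe_pearson(x, y) -> CorrelationResult:
    try:
        return pearson_correlation(x, y)
    except ValueError as exc:
        logger.warning("correlation undefined: %s", exc)
        n = int(np.sum(~(np.isnan(np.asarray(x, float)) | np.isnan(np.asarray(y, float)))))
        return CorrelationResult(n=n, r=math.nan, p=math.nan)


def parental_distances(
    dm: DistanceMatrix, plan: CrossPlan, ploidy: int
) -> pd.Series:
    """Nei distance between the parents of each cross at one ploidy.

    Crosses whose parents are absent from the matrix are dropped with a
    warning.
    """
    ids = set(dm.ids)
    out = {}
    for cross in plan.by_ploidy(ploidy):
        if cross.female not in ids or cross.male not in ids:
            logger.warning(
                "cross %s: parent missing from distance matrix; dropped",
                cross.hybrid_id,
            )
            continue
        out[cross.hybrid_id] = float(dm[cross.female, cross.male])
    return pd.Series(out, name="gd", dtype=float)


def gd_heterosis_table(
    dm: DistanceMatrix,
    records: pd.DataFrame,
    plan: CrossPlan,
    adjust: bool = False,
) -> pd.DataFrame:
    """Correlation of parental genetic distance with per-cross heterobeltiosis.

    One row per (trait, ploidy) with n, r, p and stars.  ``adjust=True``
    appends Benjamini-Hochberg adjusted p-values per ploidy group.
    """
    rows = []
    for ploidy in (2, 4):
        gd = parental_distances(dm, plan, ploidy)
        sub = records[records["ploidy"] == ploidy]
        if gd.empty or sub.empty:
            continue
        hb = sub.pivot_table(index="hybrid_id", columns="trait", values="hb")
        hb = hb.reindex(gd.index)
        for trait in hb.columns:
            res = _safe_pearson(gd.to_numpy(), hb[trait].to_numpy())
            rows.append(
                {
                    "trait": trait,
                    "ploidy": ploidy,
                    "n": res.n,
                    "r": res.r,
                    "p": res.p,
                    "stars": res.stars,
                }
            )
    out = pd.DataFrame(rows)
    if adjust:
        out["p_bh"] = np.nan
        for ploidy in (2, 4):
            mask = (out["ploidy"] == ploidy) & out["p"].notna()
            if mask.any():
                out.loc[mask, "p_bh"] = stats.false_discovery_control(
                    out.loc[mask, "p"].to_numpy()
                )
    return out


def yield_trait_correlation_table(
    records: pd.DataFrame, yield_trait: str = "GY"
) -> pd.DataFrame:
    """Correlation of yield heterobeltiosis with every other trait's HB."""
    rows = []
    for ploidy in (2, 4):
        sub = records[records["ploidy"] == ploidy]
        if sub.empty:
            continue
        hb = sub.pivot_table(index="hybrid_id", columns="trait", values="hb")
        if yield_trait not in hb.columns:
            raise KeyError(f"yield trait {yield_trait!r} absent from records")
        gy = hb[yield_trait].to_numpy()
        for trait in hb.columns:
            if trait == yield_trait:
                continue
            res = _safe_pearson(gy, hb[trait].to_numpy())
            rows.append(
                {
                    "trait": trait,
                    "ploidy": ploidy,
                    "n": res.n,
                    "r": res.r,
                    "p": res.p,
                    "stars": res.stars,
                }
            )
    return pd.DataFrame(rows)


def gd_yield_regression(
    dm: DistanceMatrix,
    records: pd.DataFrame,
    plan: CrossPlan,
    yield_trait: str = "GY",
) -> dict[int, RegressionResult]:
    """Per-ploidy OLS of yield heterobeltiosis on parental genetic distance."""
    out = {}
    for ploidy in (2, 4):
        gd = parental_distances(dm, plan, ploidy)
        if gd.empty:
            continue
        sub = records[(records["ploidy"] == ploidy) & (records["trait"] == yield_trait)]
        hb = sub.set_index("hybrid_id")["hb"].reindex(gd.index)
        out[ploidy] = simple_linear_regression(gd.to_numpy(), hb.to_numpy())
    return out
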