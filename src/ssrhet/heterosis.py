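"""Heterosis statistics for diallel hybrids and paired trait-variation summaries.

Three per-cross statistics, all on entity means (replicate averages):

* heterobeltiosis      HB = 100 * (F1 - BP) / BP, BP the better parent
  (larger mean by default; per-trait direction flags can flip it);
* mid-parent heterosis MP = 100 * (F1 - MPV) / MPV, MPV = (P1 + P2) / 2;
* competitive heterosis CH = 100 * (F1_4x - F1_2x) / F1_2x, comparing a
  tetraploid hybrid with the diploid hybrid of the same cultivar pair.

Zero or near-zero denominators yield NaN (with a logged warning) rather
than exceptions so one degenerate trait cannot abort a batch run.
Per-cross significance uses a two-sided Welch t on replicates; the paired
diploid/tetraploid trait comparison uses a paired t on per-cultivar means.
"""
from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import CrossPlan, TraitTable

logger = logging.getLogger(__name__)

_DENOM_TOL = 1e-12


def seed_set_ratio(filled: float, total: float) -> float:
    """Seed set percentage: 100 * filled grains / total grains."""
    if total <= 0:
        raise ValueError(f"total grain count must be positive, got {total}")
    if not 0 <= filled <= total:
        raise ValueError(f"filled count {filled} outside [0, {total}]")
    return 100.0 * filled / total


def heterobeltiosis(
    f1_mean: float, p1_mean: float, p2_mean: float, larger_is_better: bool = True
) -> float:
    """Percent superiority of the F1 over its better parent.

    Positive values mean superiority in the preferred direction regardless
    of the direction flag.
    """
    pick = max if larger_is_better else min
    bp = pick(p1_mean, p2_mean)
    if abs(bp) < _DENOM_TOL:
        logger.warning("better-parent mean is 0; heterobeltiosis undefined")
        return math.nan
    hb = 100.0 * (f1_mean - bp) / bp
    return hb if larger_is_better else -hb


def midparent_heterosis(f1_mean: float, p1_mean: float, p2_mean: float) -> float:
    """Percent deviation of the F1 from the parental average."""
    mp = (p1_mean + p2_mean) / 2.0
    if abs(mp) < _DENOM_TOL:
        logger.warning("mid-parent mean is 0; mid-parent heterosis undefined")
        return math.nan
    return 100.0 * (f1_mean - mp) / mp


def competitive_heterosis(f1_4x_mean: float, f1_2x_mean: float) -> float:
    """Percent superiority of a 4x hybrid over its counterpart 2x hybrid."""
    if abs(f1_2x_mean) < _DENOM_TOL:
        logger.warning("2x hybrid mean is 0; competitive heterosis undefined")
        return math.nan
    return 100.0 * (f1_4x_mean - f1_2x_mean) / f1_2x_mean


def per_cross_significance(
    f1_reps: Sequence[float], bp_reps: Sequence[float], alpha: float = 0.05
) -> bool | None:
    """Welch two-sample t on replicates; None when either side has < 2 values."""
    f1_reps = np.asarray(f1_reps, dtype=float)
    bp_reps = np.asarray(bp_reps, dtype=float)
    if len(f1_reps) < 2 or len(bp_reps) < 2:
        return None
    if np.ptp(f1_reps) == 0 and np.ptp(bp_reps) == 0:
        # zero variance on both sides: the Welch statistic is undefined
        return bool(f1_reps[0] != bp_reps[0])
    t, p = stats.ttest_ind(f1_reps, bp_reps, equal_var=False)
    return bool(p < alpha)


# ---------------------------------------------------------------------------
# batch computation over a cross plan
# ---------------------------------------------------------------------------

def compute_heterosis(
    traits: TraitTable, plan: CrossPlan, with_significance: bool = True
) -> pd.DataFrame:
    """Per-cross, per-trait heterosis records.

    Columns: hybrid_id, ploidy, trait, f1, p1, p2, hb, mp, ch, significant.
    CH is defined only for 4x crosses with a counterpart 2x hybrid in the
    plan; elsewhere it is NaN.
    """
    means = traits.data.groupby(["entity", "trait"])["value"].mean()
    if with_significance:
        reps = {k: g.to_numpy() for k, g in traits.data.groupby(["entity", "trait"])["value"]}

    def mean_of(entity: str, trait: str) -> float:
        return float(means.get((entity, trait), math.nan))

    rows = []
    for cross in plan.crosses:
        for trait in traits.traits:
            f1 = mean_of(cross.hybrid_id, trait)
            p1 = mean_of(cross.female, trait)
            p2 = mean_of(cross.male, trait)
            if any(math.isnan(v) for v in (f1, p1, p2)):
                logger.warning(
                    "cross %s trait %s: missing entity means; skipped",
                    cross.hybrid_id, trait,
                )
                continue
            direction = traits.directions.get(trait, True)
            hb = heterobeltiosis(f1, p1, p2, larger_is_better=direction)
            mp = midparent_heterosis(f1, p1, p2)
            ch = math.nan
            if cross.ploidy == 4 and cross.hybrid_id in plan.counterpart:
                f1_2x = mean_of(plan.counterpart[cross.hybrid_id], trait)
                if not math.isnan(f1_2x):
                    ch = competitive_heterosis(f1, f1_2x)
            sig = None
            if with_significance:
                pick = max if direction else min
                bp_entity = cross.female if pick(p1, p2) == p1 else cross.male
                sig = per_cross_significance(
                    reps.get((cross.hybrid_id, trait), ()),
                    reps.get((bp_entity, trait), ()),
                )
            rows.append(
                {
                    "hybrid_id": cross.hybrid_id,
                    "ploidy": cross.ploidy,
                    "trait": trait,
                    "f1": f1,
                    "p1": p1,
                    "p2": p2,
                    "hb": hb,
                    "mp": mp,
                    "ch": ch,
                    "significant": sig,
                }
            )
    return pd.DataFrame(rows)


def heterosis_summary_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-trait min/max/mean and +/- counts for HB (each ploidy) and CH.

    Mirrors the layout of a heterobeltiosis/competitive-heterosis summary:
    one row per (trait, statistic-group) with n, minimum, maximum, mean and
    the counts of crosses with positive, negative and zero effects.
    """
    blocks = []
    for label, mask, col in (
        ("HB_2x", records["ploidy"] == 2, "hb"),
        ("HB_4x", records["ploidy"] == 4, "hb"),
        ("CH", records["ploidy"] == 4, "ch"),
    ):
        sub = records.loc[mask, ["trait", col]].dropna()
        for trait, grp in sub.groupby("trait", sort=True):
            v = grp[col].to_numpy()
            blocks.append(
                {
                    "trait": trait,
                    "statistic": label,
                    "n": len(v),
                    "minimum": float(v.min()),
                    "maximum": float(v.max()),
                    "mean": float(v.mean()),
                    "n_positive": int((v > 0).sum()),
                    "n_negative": int((v < 0).sum()),
                    "n_zero": int((v == 0).sum()),
                }
            )
    return pd.DataFrame(blocks)


def paired_t(diffs: np.ndarray) -> tuple[float, float]:
    """Paired t statistic and two-sided p for a vector of paired differences.

    Degenerate cases: all-zero differences give (0, 1); nonzero constant
    differences have zero variance and give (nan, nan) with a warning.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    if n < 2:
        return math.nan, math.nan
    sd = diffs.std(ddof=1)
    if sd == 0:
        if np.all(diffs == 0):
            return 0.0, 1.0
        logger.warning("constant nonzero paired differences; t undefined")
        return math.nan, math.nan
    t = diffs.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def trait_variation_table(
    traits: TraitTable, pairing: Mapping[str, str]
) -> pd.DataFrame:
    """Group summaries plus the paired diploid/tetraploid t test per trait.

    ``pairing`` maps each diploid cultivar id to its tetraploid derivative.
    Per trait and group: mean, min, max and CV% = 100 * sample sd / mean of
    the per-cultivar means; t and two-sided p come from the paired t on the
    pair-matched means (df = n_pairs - 1).
    """
    rows = []
    pairs = sorted(pairing.items())
    for trait in traits.traits:
        m2 = np.array([traits.entity_mean(a, trait) for a, _ in pairs])
        m4 = np.array([traits.entity_mean(b, trait) for _, b in pairs])
        ok = ~(np.isnan(m2) | np.isnan(m4))
        m2, m4 = m2[ok], m4[ok]
        if len(m2) < 2:
            t = p = math.nan
            logger.warning("trait %s: fewer than 2 matched pairs; t/p missing", trait)
        else:
            t, p = paired_t(m4 - m2)
        row = {"trait": trait, "n_pairs": int(len(m2)), "t": t, "p": p}
        for label, vals in (("2x", m2), ("4x", m4)):
            if len(vals) == 0:
                row.update({f"mean_{label}": math.nan})
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else math.nan
            row.update(
                {
                    f"mean_{label}": mean,
                    f"min_{label}": float(vals.min()),
                    f"max_{label}": float(vals.max()),
                    f"cv_{label}": 100.0 * sd / mean if mean else math.nan,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
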