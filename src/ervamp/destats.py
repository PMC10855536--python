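"""Group-comparison statistics for per-locus amplicon counts.

Two complementary layers:

* Descriptive fold-change statistics on relative frequencies: the fold
  change ``x`` is the ratio of group median percentages (case over
  control), and the *relative fold change* is its symmetric
  deviation-from-1 transform (``x - 1`` above 1, ``1/x - 1`` below 1, and
  0 at ``x`` of 0 or 1), so a doubling and a halving are the same distance
  from "no change".

* A negative-binomial Wald test on raw counts: median-of-ratios size
  factors, per-locus method-of-moments dispersion with a floor, and a Wald
  statistic on the log2 ratio of group mean normalized counts, with
  Benjamini-Hochberg FDR across loci. This is a deliberately transparent
  count model — no empirical-Bayes dispersion shrinkage, no outlier
  refitting — whose calibration is checked by simulation instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


# ---------------------------------------------------- fold-change statistics

def fold_change(case_freqs: Sequence[float], control_freqs: Sequence[float],
                ) -> float:
    """Ratio of group medians, case over control.

    Conventions for zero medians: both zero -> 0 (feeds the rfc(0) = 0
    rule); control zero with nonzero case -> +inf sentinel.
    """
    case = np.asarray(case_freqs, dtype=float)
    control = np.asarray(control_freqs, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("fold_change requires non-empty groups")
    mc, mk = float(np.median(case)), float(np.median(control))
    if mc == 0.0:
        return 0.0
    if mk == 0.0:
        return math.inf
    return mc / mk


def relative_fold_change(x: float) -> float:
    """Symmetric deviation from a 1-fold change.

    ``x > 1 -> x - 1``; ``0 < x < 1 -> 1/x - 1``; ``x in {0, 1} -> 0``.
    An infinite fold change propagates as inf (callers exclude it from
    summaries).
    """
    if x < 0 or math.isnan(x):
        raise ValueError(f"fold change must be >= 0, got {x}")
    if x == 0.0 or x == 1.0:
        return 0.0
    if x > 1.0:
        return x - 1.0
    return 1.0 / x - 1.0


def summarize_rfc(comparisons: pd.DataFrame, subset: str = "all",
                  unchanged_window: tuple[float, float] = (0.8, 1.2),
                  ) -> dict[str, float]:
    """Cohort-level summary of per-locus relative fold changes.

    ``comparisons`` needs columns ``fold_change`` and ``rfc``. With
    ``subset="changed_only"`` loci whose fold change lies strictly inside
    ``unchanged_window`` are dropped first. Loci with infinite fold change
    are excluded from the numbers and counted in ``n_infinite``. The signed
    relative change takes its sign from the direction of ``x`` (positive
    above 1, negative below); both signed and absolute centers are
    reported because either aggregation is a defensible reading of a
    "median fold change over loci".
    """
    df = comparisons.copy()
    if subset == "changed_only":
        lo, hi = unchanged_window
        df = df[~((df["fold_change"] > lo) & (df["fold_change"] < hi))]
    elif subset != "all":
        raise ValueError("subset must be 'all' or 'changed_only'")
    infinite = ~np.isfinite(df["fold_change"])
    n_inf = int(infinite.sum())
    if n_inf:
        logger.info("excluding %d loci with infinite fold change from the "
                    "rfc summary", n_inf)
    df = df[~infinite]
    sign = np.sign(df["fold_change"] - 1.0)
    signed = sign * df["rfc"]
    return {
        "n": int(len(df)),
        "n_infinite": n_inf,
        "median_signed_rfc": float(np.median(signed)) if len(df) else math.nan,
        "mean_signed_rfc": float(np.mean(signed)) if len(df) else math.nan,
        "sd_signed_rfc": float(np.std(signed, ddof=1)) if len(df) > 1 else math.nan,
        "median_abs_rfc": float(np.median(df["rfc"])) if len(df) else math.nan,
    }


# ----------------------------------------------------------- count modelling

@dataclass
class NbFitParams:
    """Inputs of the NB Wald test that a caller may want to pin.

    ``size_factors`` default to median-of-ratios estimates; ``dispersion``
    (per-locus NB alpha, variance = mu + alpha*mu^2) defaults to a pooled
    within-group method-of-moments estimate floored at
    ``dispersion_floor``.
    """

    size_factors: pd.Series | None = None
    dispersion: pd.Series | None = None
    dispersion_floor: float = 1e-8


def size_factors(counts: pd.DataFrame, allow_fallback: bool = True,
                 ) -> pd.Series:
    """Median-of-ratios size factors (loci x samples), normalized to
    geometric mean 1.

    Only loci with nonzero counts in every sample enter the median; if no
    such locus exists, total counts are used instead (logged) unless
    ``allow_fallback`` is false.
    """
    arr = counts.to_numpy(dtype=float)
    everywhere = (arr > 0).all(axis=1)
    if everywhere.any():
        sub = arr[everywhere]
        log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
        ratios = np.log(sub) - log_geo
        log_sf = np.median(ratios, axis=0)
    else:
        if not allow_fallback:
            raise ValueError("no locus with nonzero counts in all samples")
        logger.warning("no locus nonzero in all samples; falling back to "
                       "total-count size factors")
        totals = arr.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total counts")
        log_sf = np.log(totals)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns)


def _group_arrays(counts: pd.DataFrame, groups: Mapping[str, str],
                  case: str, control: str,
                  ) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    g = pd.Series(dict(groups))
    case_samples = [s for s in counts.columns if g.get(s) == case]
    control_samples = [s for s in counts.columns if g.get(s) == control]
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise ValueError("each group needs at least 2 samples")
    return (counts[case_samples].to_numpy(dtype=float),
            counts[control_samples].to_numpy(dtype=float),
            case_samples, control_samples)


def nb_wald_test(counts: pd.DataFrame, groups: Mapping[str, str],
                 case: str, control: str,
                 params: NbFitParams | None = None) -> pd.DataFrame:
    """Per-locus NB Wald test of case vs control on raw counts.

    Counts are size-factor normalized; per group the mean normalized count
    is the NB mean estimate. The per-locus dispersion alpha is a pooled
    within-group method-of-moments estimate (floored), and the Wald
    statistic is log2FC divided by its delta-method standard error, with a
    Student-t reference on the pooled within-group degrees of freedom to
    account for the dispersion and mean being estimated from few samples.
    A +0.5 pseudocount is applied to both group means when either is zero.

    Returns a DataFrame indexed by locus with columns
    ``base_mean, log2_fc, se, stat, p``.
    """
    params = params or NbFitParams()
    ka, kc, case_s, control_s = _group_arrays(counts, groups, case, control)
    sf = params.size_factors if params.size_factors is not None \
        else size_factors(counts)
    sa = sf[case_s].to_numpy(dtype=float)
    sc = sf[control_s].to_numpy(dtype=float)
    ya, yc = ka / sa, kc / sc
    na, nc = ya.shape[1], yc.shape[1]

    ma, mc = ya.mean(axis=1), yc.mean(axis=1)
    base_mean = np.concatenate([ya, yc], axis=1).mean(axis=1)

    if params.dispersion is not None:
        alpha = params.dispersion.reindex(counts.index).to_numpy(dtype=float)
    else:
        # pooled within-group moment estimate of alpha:
        # Var(y_ij) = mu_g * xi_g + alpha * mu_g^2  with xi_g = mean(1/s_j)
        rss = (((ya - ma[:, None]) ** 2).sum(axis=1)
               + ((yc - mc[:, None]) ** 2).sum(axis=1))
        dof = na + nc - 2
        s2 = rss / dof
        xia, xic = np.mean(1.0 / sa), np.mean(1.0 / sc)
        w = na + nc
        mean_term = (na * ma * xia + nc * mc * xic) / w
        mu2_term = (na * ma ** 2 + nc * mc ** 2) / w
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = (s2 - mean_term) / mu2_term
        alpha = np.where(np.isfinite(alpha), alpha, params.dispersion_floor)
    alpha = np.maximum(alpha, params.dispersion_floor)

    # pseudocount when a group mean is zero (applied to both, symmetric)
    zero = (ma == 0) | (mc == 0)
    ma_adj = np.where(zero, ma + 0.5, ma)
    mc_adj = np.where(zero, mc + 0.5, mc)
    log2_fc = np.log2(ma_adj) - np.log2(mc_adj)

    xia, xic = np.mean(1.0 / sa), np.mean(1.0 / sc)
    var_ln_a = xia / (na * ma_adj) + alpha / na
    var_ln_c = xic / (nc * mc_adj) + alpha / nc
    se = np.sqrt(var_ln_a + var_ln_c) / math.log(2)

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2_fc / se, 0.0)
    df_t = na + nc - 2
    p = 2.0 * sps.t.sf(np.abs(stat), df=df_t)
    p = np.where(log2_fc == 0.0, 1.0, p)

    return pd.DataFrame(
        {"base_mean": base_mean, "log2_fc": log2_fc, "se": se,
         "stat": stat, "p": np.clip(p, 0.0, 1.0)},
        index=counts.index)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    # guard the p_adj >= p invariant against 1-ulp rounding in p*m/rank
    return np.maximum(out, p)


# -------------------------------------------------------------- orchestration

def compare_groups(counts: pd.DataFrame, frequencies: pd.DataFrame,
                   groups: Mapping[str, str], case: str, control: str,
                   params: NbFitParams | None = None) -> pd.DataFrame:
    """Full per-locus comparison table: frequency fold change, relative
    fold change, NB log2FC, Wald p and BH-adjusted p."""
    g = pd.Series(dict(groups))
    case_s = [s for s in counts.columns if g.get(s) == case]
    control_s = [s for s in counts.columns if g.get(s) == control]
    x = frequencies.apply(
        lambda row: fold_change(row[case_s], row[control_s]), axis=1)
    rfc = x.map(relative_fold_change)
    nb = nb_wald_test(counts, groups, case, control, params)
    out = nb.copy()
    out.insert(0, "fold_change", x)
    out.insert(1, "rfc", rfc)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def write_comparison_tsv(comparison: pd.DataFrame, path: str | Path) -> None:
    comparison.rename_axis("locus_id").to_csv(path, sep="\t",
                                              float_format="%.6g")
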