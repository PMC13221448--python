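"""Tertile stratification and moderated differential abundance.

The differential engine follows the spectral-count-aware empirical-Bayes
scheme used for DIA protein matrices: per-protein two-group statistics
are moderated by shrinking each protein's pooled variance toward a
variance trend fitted against the protein's median precursor count
(proteins quantified from few precursors are noisier), with the prior
degrees of freedom estimated by moment matching on the scaled-F
distribution of variance ratios. Benjamini-Hochberg adjustment is
implemented here as well, since it is part of the reported statistic.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from scipy.special import polygamma

from .errors import InsufficientDataError

logger = logging.getLogger(__name__)

TERTILE_LABELS = ("high", "mid", "low")

D0_BOUNDS = (0.5, 500.0)
MIN_PROTEINS_FOR_TREND = 50
TREND_MIN_BINS = 10


def stratify_tertiles(values: pd.Series) -> pd.Series:
    """Split samples into high/mid/low tertiles of a marker's level.

    Samples are ranked descending; ties are broken by sample id so the
    assignment is deterministic. Group sizes: for n divisible by 3 each
    group gets n/3; for n % 3 == 2 the extremes get the extra samples
    (e.g. 68 -> 23/22/23); for n % 3 == 1 the middle gets it.
    """
    clean = values.dropna()
    n = len(clean)
    if n < 3:
        raise InsufficientDataError("tertile stratification needs >= 3 samples")
    base, rem = divmod(n, 3)
    if rem == 0:
        sizes = (base, base, base)
    elif rem == 2:
        sizes = (base + 1, base, base + 1)
    else:
        sizes = (base, base + 1, base)
    order = clean.to_frame("v").assign(sid=clean.index.astype(str))
    order = order.sort_values(["v", "sid"], ascending=[False, True]).index
    labels = pd.Series(index=values.index, dtype=object, name="tertile")
    labels.loc[order[: sizes[0]]] = "high"
    labels.loc[order[sizes[0] : sizes[0] + sizes[1]]] = "mid"
    labels.loc[order[sizes[0] + sizes[1] :]] = "low"
    return labels


def tertile_sizes(labels: pd.Series) -> dict[str, int]:
    return {k: int((labels == k).sum()) for k in TERTILE_LABELS}


def median_precursor_counts(precursors: pd.DataFrame) -> pd.Series:
    """Median over samples of each protein's per-sample precursor count."""
    per = precursors.groupby(["protein", "sample_id"], observed=True).size()
    return per.groupby("protein").median().rename("precursor_count")


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries propagate as missing and do not count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[mask] = res
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve polygamma(1, y) = x for y (Newton iteration, limma-style)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _variance_trend(log_s2: np.ndarray, counts: np.ndarray, d: float) -> np.ndarray:
    """Prior variance s0^2(count) from a smoothed count-vs-variance trend.

    Binned medians of log s^2 against log count (unique small counts act
    as their own bins), interpolated by a smoothing spline; the median
    of log chi2_d/d is subtracted so the trend estimates log sigma^2
    rather than the median of the noisy log s^2.
    """
    logc = np.log(np.maximum(counts, 1.0))
    uniq = np.unique(logc)
    bias = np.log(stats.chi2.median(d) / d)
    if uniq.size == 1:
        return np.full(log_s2.shape, np.exp(np.median(log_s2) - bias))
    if uniq.size <= TREND_MIN_BINS:
        edges_vals = uniq
        med = np.array([np.median(log_s2[logc == u]) for u in uniq])
    else:
        qs = np.linspace(0, 1, TREND_MIN_BINS + 1)
        edges = np.unique(np.quantile(logc, qs))
        which = np.clip(np.searchsorted(edges, logc, side="right") - 1, 0, edges.size - 2)
        edges_vals = np.array(
            [np.median(logc[which == b]) for b in range(edges.size - 1)]
        )
        med = np.array([np.median(log_s2[which == b]) for b in range(edges.size - 1)])
        keep = np.isfinite(edges_vals) & np.isfinite(med)
        edges_vals, med = edges_vals[keep], med[keep]
    k = min(2, edges_vals.size - 1)
    spl = interpolate.UnivariateSpline(edges_vals, med, k=k, s=float(edges_vals.size))
    fitted = spl(np.clip(logc, edges_vals.min(), edges_vals.max()))
    return np.exp(fitted - bias)


def _estimate_d0(log_ratio: np.ndarray, d: float) -> float:
    """Prior df by moment matching var(log(s^2/s0^2)) on log-F(d, d0)."""
    evar = float(np.var(log_ratio, ddof=1)) - float(polygamma(1, d / 2.0))
    if evar <= 1e-8:
        return D0_BOUNDS[1]
    d0 = 2.0 * _trigamma_inverse(evar)
    return float(np.clip(d0, *D0_BOUNDS))


def moderated_test(
    matrix: pd.DataFrame,
    groups: pd.Series,
    precursor_counts: pd.Series,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Count-moderated two-group differential abundance on a log2 matrix.

    ``groups`` maps sample ids to ``high``/``low`` (other labels are
    ignored, matching a tertile contrast that drops the middle group).
    ``precursor_counts`` gives each protein's median precursor count;
    proteins absent from it get count 1 (maximal shrinkage uncertainty).

    Returns a per-protein frame with log2 fold change (high - low),
    ordinary and moderated t, p, BH-adjusted p, the prior variance at
    the protein's count, residual df d, prior df d0, and group means/ns.
    ``d0_override`` pins the prior df (0 recovers the ordinary t).
    """
    groups = groups.dropna()
    high = [s for s in matrix.columns if groups.get(s) == "high"]
    low = [s for s in matrix.columns if groups.get(s) == "low"]
    n1, n2 = len(high), len(low)
    if min(n1, n2) < 2:
        raise InsufficientDataError("need >= 2 samples per group")
    if len(matrix) < MIN_PROTEINS_FOR_TREND and d0_override is None:
        raise InsufficientDataError(
            f"variance trend unreliable with {len(matrix)} proteins (< {MIN_PROTEINS_FOR_TREND})"
        )

    a = matrix[high].to_numpy(float)
    b = matrix[low].to_numpy(float)
    mean1, mean2 = a.mean(axis=1), b.mean(axis=1)
    logfc = mean1 - mean2
    ss = ((a - mean1[:, None]) ** 2).sum(axis=1) + ((b - mean2[:, None]) ** 2).sum(axis=1)
    d = float(n1 + n2 - 2)
    s2 = ss / d
    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)

    zero_var = s2 <= 0
    if zero_var.any():
        logger.warning("moderated_test: %d protein(s) with zero variance", zero_var.sum())
    s2_safe = np.where(zero_var, np.nan, s2)

    counts = precursor_counts.reindex(matrix.index).fillna(1.0).to_numpy(float)
    valid = np.isfinite(s2_safe)
    log_s2 = np.log(s2_safe[valid])
    s0_sq = np.full(len(matrix), np.nan)
    s0_sq[valid] = _variance_trend(log_s2, counts[valid], d)

    if d0_override is not None:
        d0 = float(d0_override)
    else:
        d0 = _estimate_d0(np.log(s2_safe[valid] / s0_sq[valid]), d)

    if d0 == 0:
        post_var = s2_safe
        df_total = d
    else:
        post_var = (d0 * s0_sq + d * s2_safe) / (d0 + d)
        df_total = d0 + d
    with np.errstate(invalid="ignore", divide="ignore"):
        t_ord = logfc / np.sqrt(s2_safe) / se_factor
        t_mod = logfc / np.sqrt(post_var) / se_factor
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p[~np.isfinite(t_mod)] = np.nan

    result = pd.DataFrame(
        {
            "logFC": logfc,
            "t_ordinary": t_ord,
            "t_moderated": t_mod,
            "p_value": p,
            "adj_p_value": bh_adjust(p),
            "df_residual": d,
            "df_prior": d0,
            "prior_var": s0_sq,
            "posterior_var": post_var,
            "precursor_count": counts,
            "mean_high": mean1,
            "mean_low": mean2,
            "n_high": n1,
            "n_low": n2,
        },
        index=matrix.index,
    )
    result.index.name = "protein"
    return result
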