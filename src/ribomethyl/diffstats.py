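"""Differential statistics for two-group feature-intensity tables.

Implements the screen statistics used throughout the study: a
fold-change-moderated t-like statistic with a constant s0 added to the
pooled standard error, thresholded by a permutation-estimated FDR curve (the
curved cutoff of a volcano plot); left-tail imputation of censored missing
values; the intensity-binned robust outlier test ("significance B"); and
Benjamini-Hochberg adjustment (delegated to statsmodels).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class DiffStatsResult:
    """Per-feature statistics plus the global threshold curve.

    ``table`` columns: diff (log2 mean difference), se (pooled standard
    error), d (s0 statistic), significant.  ``fdr_curve`` columns:
    threshold, fdr_hat, n_observed, mean_null.
    """

    table: pd.DataFrame
    fdr_curve: pd.DataFrame
    threshold: float
    s0: float
    fdr_target: float
    n_permutations: int
    seed: int
    null_abs: np.ndarray | None = None  # pooled |d| under label permutation


def impute_lower_tail(table: pd.DataFrame, downshift: float = 1.8, width: float = 0.3,
                      seed: int = 0) -> pd.DataFrame:
    """Fill missing cells from a down-shifted narrow normal, per sample.

    Each missing value in sample s is drawn from
    Normal(mean_s - downshift * sd_s, (width * sd_s)^2) computed over that
    sample's observed values — the standard treatment of left-censored
    label-free intensities.  Observed cells are never altered.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col in out.columns:
        observed = out[col].dropna()
        if len(observed) < 3:
            raise ValueError(f"sample {col!r} has {len(observed)} observed values; need >= 3")
        n_missing = int(out[col].isna().sum())
        if n_missing == 0:
            continue
        mu, sd = observed.mean(), observed.std(ddof=1)
        out.loc[out[col].isna(), col] = rng.normal(mu - downshift * sd, width * sd, size=n_missing)
    return out


def s0_statistic(x: np.ndarray, y: np.ndarray, s0: float = 0.1) -> np.ndarray:
    """Moderated statistic d = (mean(x) - mean(y)) / (se_pooled + s0).

    x, y: features-by-samples arrays (one row per feature).  With s0 = 0
    this is exactly the pooled-variance Student t statistic.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    diff = x.mean(axis=1) - y.mean(axis=1)
    sp2 = ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1)) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    denom = se + s0
    if s0 == 0 and np.any(denom == 0):
        raise ValueError("zero variance in both groups with s0 = 0: statistic undefined")
    return diff / denom


def _assignments(n_total: int, n_group1: int, n_perm: int, seed: int,
                 min_assignments: int = 20) -> list[tuple[int, ...]]:
    """Label permutations as index tuples for group 1, excluding the observed
    assignment and its complement (they reproduce the observed statistics)."""
    total = comb(n_total, n_group1)
    if total < min_assignments:
        raise ValueError(
            f"only {total} distinct label assignments (< {min_assignments}); "
            "use larger groups or exact enumeration on a bigger design")
    observed = tuple(range(n_group1))
    complement = tuple(range(n_total - n_group1, n_total)) if 2 * n_group1 == n_total else None
    all_assignments = [a for a in combinations(range(n_total), n_group1)
                       if a != observed and a != complement]
    if len(all_assignments) <= n_perm:
        return all_assignments
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(all_assignments), size=n_perm, replace=False)
    return [all_assignments[i] for i in sorted(chosen)]


def permutation_fdr(table: pd.DataFrame, groups: pd.Series | dict, s0: float = 0.1,
                    fdr_target: float = 0.01, n_perm: int = 250, seed: int = 0) -> DiffStatsResult:
    """s0 statistic with a permutation-estimated FDR significance threshold.

    ``groups`` maps sample (column) names to two group labels; group order
    follows first appearance (difference = first minus second).  For each
    candidate cutoff c (the observed |d| values),
    FDRhat(c) = mean over permutations of #{|d_perm| >= c} / #{|d_obs| >= c};
    the significance threshold is the smallest c with FDRhat <= fdr_target
    and ties at the threshold are called significant.  Label permutations
    are enumerated exactly when few, sampled without replacement otherwise;
    the observed assignment (and its mirror) is excluded from the null.
    """
    groups = pd.Series(groups)
    labels = list(dict.fromkeys(groups[c] for c in table.columns))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    cols1 = [c for c in table.columns if groups[c] == labels[0]]
    cols2 = [c for c in table.columns if groups[c] == labels[1]]
    if table[cols1 + cols2].isna().any().any():
        raise ValueError("table contains missing values; impute first")
    data = table[cols1 + cols2].to_numpy(dtype=float)
    n1 = len(cols1)
    n_total = n1 + len(cols2)

    d_obs = s0_statistic(data[:, :n1], data[:, n1:], s0)
    assignments = _assignments(n_total, n1, n_perm, seed)
    abs_obs = np.abs(d_obs)
    null_stats = np.empty((len(assignments), len(d_obs)))
    for k, idx1 in enumerate(assignments):
        idx2 = [j for j in range(n_total) if j not in idx1]
        null_stats[k] = s0_statistic(data[:, list(idx1)], data[:, idx2], s0)
    abs_null = np.abs(null_stats)

    candidates = np.unique(abs_obs)[::-1]
    sorted_obs = np.sort(abs_obs)
    sorted_null = np.sort(abs_null.ravel())
    n_obs_ge = len(abs_obs) - np.searchsorted(sorted_obs, candidates, side="left")
    mean_null_ge = (len(sorted_null) - np.searchsorted(sorted_null, candidates, side="left")) \
        / len(assignments)
    fdr_hat = np.minimum(mean_null_ge / n_obs_ge, 1.0)
    curve = pd.DataFrame({"threshold": candidates, "fdr_hat": fdr_hat,
                          "n_observed": n_obs_ge, "mean_null": mean_null_ge})
    passing = curve[curve["fdr_hat"] <= fdr_target]
    threshold = float(passing["threshold"].min()) if not passing.empty else np.inf

    n1_arr, n2_arr = data[:, :n1], data[:, n1:]
    diff = n1_arr.mean(axis=1) - n2_arr.mean(axis=1)
    sp2 = ((n1 - 1) * n1_arr.var(axis=1, ddof=1)
           + (n2_arr.shape[1] - 1) * n2_arr.var(axis=1, ddof=1)) / (n_total - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2_arr.shape[1]))
    result = pd.DataFrame({"diff": diff, "se": se, "d": d_obs,
                           "significant": abs_obs >= threshold}, index=table.index)
    return DiffStatsResult(table=result, fdr_curve=curve, threshold=threshold, s0=s0,
                           fdr_target=fdr_target, n_permutations=len(assignments), seed=seed,
                           null_abs=sorted_null)


def significance_b(log_ratios: np.ndarray | pd.Series, intensities: np.ndarray | pd.Series,
                   bin_size: int = 300) -> np.ndarray:
    """Intensity-binned robust outlier test for abundance ratios.

    Features are ordered by intensity and split into bins of ``bin_size``
    (remainder merged into the last bin).  Within each bin the ratio's
    robust z-score uses the median as centre and half the 15.87-84.13
    percentile spread as scale; p-values are two-sided standard-normal
    tails.  Bin membership depends on intensity ranks only.
    """
    if bin_size < 30:
        raise ValueError("bin_size must be >= 30 for a stable robust scale")
    ratios = np.asarray(log_ratios, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    if ratios.shape != inten.shape:
        raise ValueError("ratios and intensities must be aligned")
    order = np.argsort(inten, kind="mergesort")
    n = len(ratios)
    n_bins = max(1, n // bin_size)
    p = np.empty(n)
    for b in range(n_bins):
        start = b * bin_size
        stop = n if b == n_bins - 1 else (b + 1) * bin_size
        members = order[start:stop]
        r = ratios[members]
        centre = np.median(r)
        lo, hi = np.percentile(r, [15.87, 84.13])
        scale = (hi - lo) / 2
        if scale == 0:
            raise ValueError(f"zero robust scale in intensity bin {b}")
        z = (r - centre) / scale
        p[members] = 2 * stats.norm.sf(np.abs(z))
    return p


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
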