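"""Cohort-level statistics.

Z-scores against the young cognitively unimpaired reference group, one-way
ANOVA with Tukey HSD pairwise tests and Benjamini-Hochberg FDR across the
pairwise family, Spearman rank correlations, and standardized multivariable
OLS with covariates.  Standard fits go through scipy / statsmodels; this
module fixes the conventions (reference-group Z-scoring, FDR family, the
treatment of binary covariates) used throughout the pipeline.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "zscores_vs_reference",
    "oneway_anova_tukey",
    "bh_fdr",
    "spearman",
    "ols_standardized",
    "GroupComparison",
    "RegressionResult",
    "COVARIATE_PROFILES",
]

#: Covariate profiles used across the analyses: COV1 = demographics,
#: COV2 adds head size, COV3 additionally controls for atrophy.
COVARIATE_PROFILES = {
    "COV1": ("age", "sex", "apoe4"),
    "COV2": ("age", "sex", "apoe4", "icv"),
    "COV3": ("age", "sex", "apoe4", "icv", "gm_volume"),
}


def zscores_vs_reference(values, is_reference) -> np.ndarray:
    """Z-scores normalized by the mean and SD of the reference subset.

    Inputs should already be ICV-residualized where applicable; the reference
    subset then has mean 0 and SD 1 by construction.
    """
    x = np.asarray(values, dtype=float)
    ref = np.asarray(is_reference, dtype=bool)
    if x.shape != ref.shape:
        raise ValueError("values and is_reference must have the same length")
    if ref.sum() < 2:
        raise ValueError("need at least two reference members")
    mu = x[ref].mean()
    sd = x[ref].std(ddof=1)
    if sd == 0:
        raise ValueError("reference subset has zero spread")
    return (x - mu) / sd


@dataclass(frozen=True)
class GroupComparison:
    f_stat: float
    df: tuple[int, int]
    p: float
    #: (groupA, groupB, mean_diff, tukey_p, fdr_adjusted_p, reject)
    pairwise: tuple[tuple, ...]
    dropped_groups: tuple[str, ...] = ()


def oneway_anova_tukey(values, groups, q: float = 0.05, low_n_warn: int = 5) -> GroupComparison:
    """One-way ANOVA with Tukey HSD post hoc tests and BH-FDR correction.

    Tukey pairwise p-values come from the studentized-range distribution;
    Benjamini-Hochberg step-up is then applied across the whole pairwise
    family at level ``q`` (reporting both the Tukey and the adjusted values).
    Groups with fewer than 2 members are dropped with a warning; very small
    groups (n < ``low_n_warn``) trigger a low-n warning but are kept.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    names = [n for n in pd.unique(g)]
    samples, kept, dropped = [], [], []
    for n in names:
        xs = x[g == n]
        if len(xs) < 2:
            dropped.append(str(n))
            continue
        if len(xs) < low_n_warn:
            warnings.warn(f"group {n!r} has only n={len(xs)}; its pairwise tests are fragile",
                          stacklevel=2)
        samples.append(xs)
        kept.append(str(n))
    if dropped:
        warnings.warn(f"dropping groups with n<2 from comparison: {dropped}", stacklevel=2)
    if len(samples) < 2:
        raise ValueError("need at least two groups with n >= 2")
    if np.ptp(np.concatenate(samples)) == 0:
        raise ValueError("all values identical; F statistic undefined")

    f_stat, p = sps.f_oneway(*samples)
    k = len(samples)
    n_tot = sum(len(s) for s in samples)
    tuk = sps.tukey_hsd(*samples)
    pairs, tukey_p = [], []
    for i, j in itertools.combinations(range(k), 2):
        pairs.append((kept[i], kept[j], float(samples[i].mean() - samples[j].mean())))
        tukey_p.append(float(tuk.pvalue[i, j]))
    adj_p, reject = bh_fdr(tukey_p, q=q)
    pairwise = tuple(
        (a, b, d, tp, float(ap), bool(r))
        for (a, b, d), tp, ap, r in zip(pairs, tukey_p, adj_p, reject)
    )
    return GroupComparison(
        f_stat=float(f_stat),
        df=(k - 1, n_tot - k),
        p=float(p),
        pairwise=pairwise,
        dropped_groups=tuple(dropped),
    )


def bh_fdr(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up: returns (adjusted p-values, reject flags)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return adj, reject


def spearman(x, y):
    """Spearman rank correlation (average ranks for ties) with the
    large-sample p-value.  Returns (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length vectors of length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class RegressionResult:
    beta_std: dict
    ci95: dict
    p: dict
    r2: float
    n: int
    predictors: tuple[str, ...]
    covariates: tuple[str, ...]


def _is_binary(x: np.ndarray) -> bool:
    u = np.unique(x)
    return len(u) <= 2


def _standardize_columns(df: pd.DataFrame, cols) -> tuple[np.ndarray, list[str]]:
    out, bad = [], []
    for c in cols:
        x = df[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            bad.append(c)
            out.append(x - x.mean())
        elif _is_binary(x):
            out.append(x - x.mean())  # centred only: beta is per category
        else:
            out.append((x - x.mean()) / sd)
    return np.column_stack(out) if out else np.empty((len(df), 0)), bad


def ols_standardized(
    data: pd.DataFrame,
    outcome: str,
    predictors,
    covariates=("age", "sex", "apoe4", "icv"),
) -> RegressionResult:
    """Standardized multivariable OLS.

    All continuous variables (outcome included) are scaled to mean 0 / SD 1
    before fitting; binary covariates are centred but not variance-scaled, so
    their coefficients are per-category effects.  Covariates are always
    included in the fit but reported separately from the predictors of
    interest.
    """
    predictors = tuple(predictors)
    covariates = tuple(covariates)
    n = len(data)
    p_tot = 1 + len(predictors) + len(covariates)
    if n <= p_tot + 2:
        raise ValueError(f"n={n} too small for {p_tot} parameters")
    y = data[outcome].to_numpy(dtype=float)
    y = (y - y.mean()) / y.std(ddof=1)
    X, bad = _standardize_columns(data, predictors + covariates)
    if bad:
        raise ValueError(f"constant columns in design: {bad}")
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by leave-one-out rank
        names = ("const",) + predictors + covariates
        offending = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"design is rank-deficient (collinear columns: {offending})")
    fit = sm.OLS(y, X).fit()
    names = predictors + covariates
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        beta_std={nm: float(fit.params[i + 1]) for i, nm in enumerate(names)},
        ci95={nm: (float(ci[i + 1][0]), float(ci[i + 1][1])) for i, nm in enumerate(names)},
        p={nm: float(fit.pvalues[i + 1]) for i, nm in enumerate(names)},
        r2=float(fit.rsquared),
        n=n,
        predictors=predictors,
        covariates=covariates,
    )
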