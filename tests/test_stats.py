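"""Cohort statistics against closed-form and brute-force oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from ventricsf import stats as S
from ventricsf.volumetrics import residualize


# --- Z-scores -------------------------------------------------------------

def test_zscores_reference_mean_zero_sd_one():
    rng = np.random.default_rng(0)
    x = rng.normal(5, 2, 100)
    ref = np.zeros(100, bool)
    ref[:40] = True
    z = S.zscores_vs_reference(x, ref)
    assert z[ref].mean() == pytest.approx(0.0, abs=1e-10)
    assert z[ref].std(ddof=1) == pytest.approx(1.0, abs=1e-10)
    # formula oracle
    mu, sd = x[:40].mean(), x[:40].std(ddof=1)
    assert np.allclose(z, (x - mu) / sd, atol=1e-12)
    # value at the reference mean scores zero
    assert S.zscores_vs_reference(np.r_[x, mu], np.r_[ref, False])[-1] == pytest.approx(0.0)


def test_zscores_affine_invariance():
    rng = np.random.default_rng(1)
    x = rng.normal(size=50)
    ref = rng.random(50) < 0.5
    z1 = S.zscores_vs_reference(x, ref)
    z2 = S.zscores_vs_reference(7.0 + 3.0 * x, ref)
    assert np.allclose(z1, z2, atol=1e-10)


def test_zscores_degenerate_reference():
    with pytest.raises(ValueError):
        S.zscores_vs_reference(np.r_[np.ones(5), 2.0], np.r_[np.ones(5, bool), False])


# --- ANOVA / Tukey --------------------------------------------------------

def test_anova_identical_groups_no_rejections():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 90)
    g = np.repeat(["a", "b", "c"], 30)
    res = S.oneway_anova_tukey(x, g)
    assert all(p[4] > 0.05 for p in res.pairwise) or not any(p[5] for p in res.pairwise)


def test_tukey_two_groups_equals_t_test():
    """With two groups the studentized range gives p = two-sided equal-variance
    comparison at q = sqrt(2)|t|."""
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, 25)
    b = rng.normal(0.8, 1, 30)
    res = S.oneway_anova_tukey(np.r_[a, b], np.r_[["a"] * 25, ["b"] * 30])
    t, _ = sps.ttest_ind(a, b)
    df = 25 + 30 - 2
    p_oracle = sps.studentized_range.sf(np.sqrt(2) * abs(t), 2, df)
    assert res.pairwise[0][3] == pytest.approx(p_oracle, abs=1e-8)


def test_anova_separated_group_rejected():
    rng = np.random.default_rng(4)
    x = np.r_[rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(10, 1, 30)]
    g = np.repeat(["a", "b", "c"], 30)
    res = S.oneway_anova_tukey(x, g)
    rejected_pairs = {frozenset((p[0], p[1])) for p in res.pairwise if p[5]}
    assert frozenset(("a", "c")) in rejected_pairs
    assert frozenset(("b", "c")) in rejected_pairs


def test_anova_drops_tiny_groups_with_warning():
    x = np.r_[np.random.default_rng(5).normal(size=40), [1.0]]
    g = np.r_[np.repeat(["a", "b"], 20), ["tiny"]]
    with pytest.warns(UserWarning, match="n<2"):
        res = S.oneway_anova_tukey(x, g)
    assert res.dropped_groups == ("tiny",)


def test_anova_identical_values_error():
    with pytest.raises(ValueError):
        S.oneway_anova_tukey(np.ones(20), np.repeat(["a", "b"], 10))


def test_anova_null_p_is_uniform():
    """Under a global null with the cohort's group sizes, the ANOVA p-value
    is uniform and BH keeps the family-wise false-rejection rate near q."""
    rng = np.random.default_rng(6)
    sizes = {"CU(Y)": 52, "A-T-": 166, "A+T-": 64, "A+T+": 92}  # n>=2 groups
    g = np.concatenate([[k] * v for k, v in sizes.items()])
    pvals, any_false = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(500):
            x = rng.standard_normal(len(g))
            res = S.oneway_anova_tukey(x, g, q=0.05)
            pvals.append(res.p)
            any_false.append(any(p[5] for p in res.pairwise))
    assert sps.kstest(pvals, "uniform").pvalue > 0.01
    fwer = np.mean(any_false)
    mc_se = np.sqrt(0.05 * 0.95 / 500)
    assert fwer <= 0.05 + 3 * mc_se


# --- BH FDR ---------------------------------------------------------------

def test_bh_enumerated_vectors():
    adj, rej = S.bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
    assert rej.all()  # p(i) <= i q / m for all i
    adj, rej = S.bh_fdr([1.0, 1.0, 1.0], q=0.05)
    assert not rej.any() and (adj == 1.0).all()
    _, rej = S.bh_fdr([0.04], q=0.05)
    assert rej[0]
    _, rej = S.bh_fdr([0.06], q=0.05)
    assert not rej[0]
    with pytest.raises(ValueError):
        S.bh_fdr([0.5, 1.5])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30), st.floats(0.001, 0.2))
def test_bonferroni_rejections_subset_of_bh(ps, q):
    ps = np.asarray(ps)
    _, bh = S.bh_fdr(ps, q=q)
    bonf = ps <= q / len(ps)
    assert not np.any(bonf & ~bh)


# --- Spearman -------------------------------------------------------------

def test_spearman_monotone_limits():
    x = np.arange(10.0)
    assert S.spearman(x, np.exp(x))[0] == pytest.approx(1.0)
    assert S.spearman(x, -(x**3))[0] == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        S.spearman(np.ones(10), x)


def test_spearman_ties_match_rank_then_pearson_oracle():
    rng = np.random.default_rng(7)
    x = rng.integers(0, 4, 50).astype(float)  # heavy ties
    y = rng.integers(0, 4, 50).astype(float) + 0.3 * x
    rho, _ = S.spearman(x, y)
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    oracle = sps.pearsonr(rx, ry).statistic
    assert rho == pytest.approx(oracle, abs=1e-12)


# --- standardized OLS -----------------------------------------------------

def _random_table(n=200, seed=8):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "y": rng.standard_normal(n),
            "x1": rng.standard_normal(n),
            "x2": rng.standard_normal(n),
            "age": rng.normal(70, 8, n),
            "sex": rng.integers(0, 2, n),
        }
    )
    df["y"] += 0.5 * df["x1"]
    return df


def test_ols_identity_predictor():
    df = _random_table()
    df["y"] = df["x1"]
    res = S.ols_standardized(df, "y", ["x1"], covariates=())
    assert res.beta_std["x1"] == pytest.approx(1.0, abs=1e-10)
    assert res.r2 == pytest.approx(1.0, abs=1e-10)


def test_ols_independent_predictors_near_zero():
    rng = np.random.default_rng(9)
    df = _random_table(n=2000, seed=10)
    df["y"] = rng.standard_normal(2000)
    res = S.ols_standardized(df, "y", ["x1", "x2"], covariates=("age", "sex"))
    assert all(abs(b) < 0.1 for b in res.beta_std.values())
    assert res.r2 < 0.02


def test_ols_matches_normal_equations_oracle():
    df = _random_table()
    res = S.ols_standardized(df, "y", ["x1", "x2"], covariates=("age", "sex"))

    def std(c):
        v = df[c].to_numpy(float)
        u = np.unique(v)
        return v - v.mean() if len(u) <= 2 else (v - v.mean()) / v.std(ddof=1)

    X = np.column_stack([np.ones(len(df)), std("x1"), std("x2"), std("age"), std("sex")])
    y = std("y") / 1.0
    y = (df["y"] - df["y"].mean()).to_numpy() / df["y"].std(ddof=1)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert res.beta_std["x1"] == pytest.approx(beta[1], abs=1e-10)
    assert res.beta_std["x2"] == pytest.approx(beta[2], abs=1e-10)
    resid = y - X @ beta
    r2 = 1 - resid @ resid / (y @ y)
    assert res.r2 == pytest.approx(r2, abs=1e-10)
    assert res.ci95["x1"][0] < res.beta_std["x1"] < res.ci95["x1"][1]


def test_ols_collinearity_names_columns():
    df = _random_table()
    df["dup"] = df["x1"]
    with pytest.raises(ValueError, match="collinear"):
        S.ols_standardized(df, "y", ["x1", "dup"], covariates=())


# --- cohort-level pattern -------------------------------------------------

def test_vv_zscore_increases_across_stages(default_cohort):
    """Mean ICV-residualized ventricular-volume Z-score rises along the
    amyloid/tau staging axis, reaching about 4 in the A+T+ group."""
    df = default_cohort
    res = residualize(df["latent_vv"].to_numpy(), df["icv"].to_numpy())
    z = S.zscores_vs_reference(res, (df["stage"] == "CU(Y)").to_numpy())
    means = {s: z[(df["stage"] == s).to_numpy()].mean() for s in ("A-T-", "A+T-", "A+T+")}
    assert means["A-T-"] < means["A+T-"] < means["A+T+"]
    assert means["A+T+"] > 3.0
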