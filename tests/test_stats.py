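"""Statistical machinery against closed-form and library oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from weanbiome.stats import (
    ModelFit,
    ModelSpec,
    StatsError,
    build_association_matrix,
    candidate_screen,
    chi_squared_test,
    fit_lmm,
    fit_mixed_glm,
    gamma_gof,
    nudge_zeros,
    p_bin,
    permanova,
    select_top_abundant,
    welch_test,
)

from conftest import random_table


# ---------------------------------------------------------------------------
# Simple comparisons
# ---------------------------------------------------------------------------

def test_welch_worked_example():
    t, df, p = welch_test(24.1, 4.16, 15, 20.5, 1.97, 7)
    assert t == pytest.approx(2.7545, abs=1e-3)
    assert df == pytest.approx(19.94, abs=0.05)
    assert 0.01 < p < 0.02


def test_welch_matches_scipy():
    res = scipy.stats.ttest_ind_from_stats(
        24.1, 4.16, 15, 20.5, 1.97, 7, equal_var=False
    )
    t, _, p = welch_test(24.1, 4.16, 15, 20.5, 1.97, 7)
    assert t == pytest.approx(res.statistic, abs=1e-12)
    assert p == pytest.approx(res.pvalue, abs=1e-12)


def test_welch_input_validation():
    with pytest.raises(StatsError):
        welch_test(1, 1, 1, 2, 1, 5)
    with pytest.raises(StatsError):
        welch_test(1, 0, 5, 2, 1, 5)


def test_chi_squared_matches_scipy():
    table = [[12, 3], [5, 9]]
    chi2, dof, p = chi_squared_test(table)
    ref = scipy.stats.chi2_contingency(np.array(table), correction=False)
    assert chi2 == pytest.approx(ref.statistic, abs=1e-12)
    assert dof == 1
    assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_chi_squared_rejects_zero_margin():
    with pytest.raises(StatsError):
        chi_squared_test([[0, 0], [5, 9]])


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _euclid_dm(points, ids):
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(squareform(pdist(points)), ids)


def test_permanova_single_factor_matches_skbio():
    rng = np.random.default_rng(21)
    pts = rng.normal(size=(14, 3))
    ids = [f"s{i}" for i in range(14)]
    dm = _euclid_dm(pts, ids)
    groups = ["x"] * 7 + ["y"] * 7
    data = pd.DataFrame({"group": groups}, index=ids)
    ours = permanova(dm, data, ["group"], n_perm=99, seed=1)
    ref = skbio_permanova(dm, grouping=np.array(groups), permutations=99)
    assert ours.table.loc["group", "pseudo_F"] == pytest.approx(
        ref["test statistic"], abs=1e-10
    )


def test_permanova_exact_enumeration_matches_bruteforce():
    rng = np.random.default_rng(22)
    pts = rng.normal(size=(5, 2))
    ids = [f"s{i}" for i in range(5)]
    dm = _euclid_dm(pts, ids)
    groups = np.array(["x", "x", "x", "y", "y"])
    data = pd.DataFrame({"group": groups}, index=ids)
    ours = permanova(dm, data, ["group"], exact=True)

    # independent one-way pseudo-F from the classic distance decomposition
    d2 = dm.data**2

    def f_of(lab):
        n = len(lab)
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in np.unique(lab):
            idx = np.flatnonzero(lab == g)
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_between = ss_total - ss_within
        return (ss_between / 1) / (ss_within / (n - 2))

    f_obs = f_of(groups)
    count = total = 0
    for perm in itertools.permutations(range(5)):
        total += 1
        if f_of(groups[list(perm)]) >= f_obs - 1e-10:
            count += 1
    assert ours.table.loc["group", "pseudo_F"] == pytest.approx(f_obs, abs=1e-10)
    assert ours.table.loc["group", "p_value"] == pytest.approx(count / total, abs=1e-12)


def test_permanova_sequential_r2_sums_to_one():
    rng = np.random.default_rng(23)
    table = random_table(rng, n_samples=16)
    from weanbiome.community import bray_curtis

    dm = bray_curtis(table)
    meta = table.metadata
    res = permanova(dm, meta, ["cohort", "participant_id", "period"],
                    n_perm=49, seed=3)
    assert res.table["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-10)
    assert res.table.loc["Total", "R2"] == pytest.approx(1.0)


def test_permanova_collinear_term_rejected():
    rng = np.random.default_rng(24)
    pts = rng.normal(size=(8, 2))
    ids = [f"s{i}" for i in range(8)]
    dm = _euclid_dm(pts, ids)
    data = pd.DataFrame(
        {"a": ["x"] * 4 + ["y"] * 4, "b": ["x"] * 4 + ["y"] * 4}, index=ids
    )
    with pytest.raises(StatsError):
        permanova(dm, data, ["a", "b"], n_perm=9, seed=0)


def test_permanova_strata_restricts_permutations():
    rng = np.random.default_rng(25)
    pts = rng.normal(size=(12, 2))
    ids = [f"s{i}" for i in range(12)]
    dm = _euclid_dm(pts, ids)
    data = pd.DataFrame(
        {
            "treat": ["t", "c"] * 6,
            "block": np.repeat([f"b{i}" for i in range(3)], 4),
        },
        index=ids,
    )
    res = permanova(dm, data, ["treat"], n_perm=99, seed=4, strata="block")
    assert 0 < res.table.loc["treat", "p_value"] <= 1


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------

def _grouped_gaussian(rng, n_groups=12, per=8, sd_b=0.0):
    g = np.repeat([f"g{i}" for i in range(n_groups)], per)
    x = rng.normal(size=n_groups * per)
    b = dict(zip(np.unique(g), rng.normal(0, sd_b, n_groups)))
    y = 1.0 + 0.5 * x + np.array([b[k] for k in g]) + rng.normal(0, 0.3, len(g))
    return pd.DataFrame({"y": y, "x": x, "participant_id": g})


def test_lmm_degenerate_matches_ols():
    rng = np.random.default_rng(31)
    d = _grouped_gaussian(rng, sd_b=0.0)
    fit = fit_lmm(d, ModelSpec("y", ["x"]))
    ols = sm.OLS(d["y"], sm.add_constant(d["x"])).fit()
    assert fit.converged
    assert fit.coef("x") == pytest.approx(ols.params["x"], abs=1e-4)


def test_lmm_recovers_slope_with_random_intercepts():
    rng = np.random.default_rng(32)
    d = _grouped_gaussian(rng, n_groups=30, per=10, sd_b=1.0)
    fit = fit_lmm(d, ModelSpec("y", ["x"]))
    assert fit.converged
    assert fit.coef("x") == pytest.approx(0.5, abs=0.1)
    assert fit.re_sd == pytest.approx(1.0, abs=0.4)


def test_gamma_glmm_degenerate_matches_glm():
    rng = np.random.default_rng(33)
    n = 400
    x = rng.uniform(0, 2, n)
    shape = 5.0
    mu = np.exp(0.3 - 0.6 * x)
    y = rng.gamma(shape, mu / shape)
    d = pd.DataFrame(
        {"y": y, "x": x, "participant_id": np.repeat([f"g{i}" for i in range(20)], 20)}
    )
    fit = fit_mixed_glm(d, ModelSpec("y", ["x"], family="gamma_log"))
    glm = sm.GLM(y, sm.add_constant(x),
                 family=sm.families.Gamma(sm.families.links.Log())).fit()
    assert fit.converged
    assert fit.coef("x") == pytest.approx(glm.params[1], abs=0.02)
    assert fit.re_sd < 0.1  # no real group effect in the data


def test_nb_glmm_offset_invariance():
    rng = np.random.default_rng(34)
    n = 200
    g = np.repeat([f"g{i}" for i in range(20)], 10)
    x = rng.uniform(0, 10, n)
    expo = rng.uniform(5000, 20000, n)
    b = dict(zip(np.unique(g), rng.normal(0, 0.3, 20)))
    mu = expo * np.exp(-6 + 0.1 * x + np.array([b[k] for k in g]))
    y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
    d = pd.DataFrame({"y": y, "x": x, "participant_id": g,
                      "off": np.log(expo)})
    d2 = d.assign(off=np.log(expo * 37.0))
    spec = ModelSpec("y", ["x"], family="negative_binomial", offset="off")
    f1 = fit_mixed_glm(d, spec)
    f2 = fit_mixed_glm(d2, spec)
    assert f1.converged and f2.converged
    assert abs(f1.coef("x") - f2.coef("x")) < 1e-6
    assert f1.coef("const") - f2.coef("const") == pytest.approx(np.log(37.0), abs=1e-5)


def test_gamma_glmm_requires_positive_response():
    d = pd.DataFrame({"y": [0.0, 1.0, 2.0, 1.0],
                      "x": [0, 1, 0, 1],
                      "participant_id": ["a", "a", "b", "b"]})
    with pytest.raises(StatsError):
        fit_mixed_glm(d, ModelSpec("y", ["x"], family="gamma_log"))


def test_offset_only_for_negative_binomial():
    with pytest.raises(StatsError):
        ModelSpec("y", ["x"], family="gamma_log", offset="off")


# ---------------------------------------------------------------------------
# Helpers around the models
# ---------------------------------------------------------------------------

def test_nudge_zeros():
    vals, n = nudge_zeros(np.array([0.0, 0.4, 0.2, 0.0]))
    assert n == 2
    assert vals.min() == pytest.approx(0.1)
    with pytest.raises(StatsError):
        nudge_zeros(np.zeros(3))


def test_gamma_gof_recovers_parameters():
    rng = np.random.default_rng(35)
    y = rng.gamma(3.0, 1 / 2.0, size=4000)
    shape, rate, ks, ks_p = gamma_gof(y)
    assert shape == pytest.approx(3.0, rel=0.1)
    assert rate == pytest.approx(2.0, rel=0.1)
    assert ks_p > 0.01


def test_p_bin_boundaries():
    assert p_bin(0.0005) == "<0.001"
    assert p_bin(0.005) == "<0.01"
    assert p_bin(0.03) == "<0.05"
    assert p_bin(0.07) == "<0.1"
    assert p_bin(0.5) == "ns"
    assert p_bin(0.05) == "<0.1"  # strict inequality at each threshold


def test_select_top_abundant_deterministic():
    rng = np.random.default_rng(36)
    table = random_table(rng)
    top = select_top_abundant(table, k=5)
    rel = table.counts.div(table.counts.sum(axis=1), axis=0)
    means = rel.mean(axis=0).sort_values(ascending=False)
    assert set(top) == set(means.index[:5])


def test_association_matrix_duplicate_cell_rejected():
    fit = ModelFit(
        family="negative_binomial",
        params=pd.Series({"const": 0.0, "fiber": 0.2}),
        bse=pd.Series({"const": 0.1, "fiber": 0.1}),
        pvalues=pd.Series({"const": 0.9, "fiber": 0.03}),
        converged=True, n_obs=10, n_groups=4,
        extra={"asv_id": "ASV1", "diet_var": "fiber", "tier": "unadjusted"},
    )
    mat = build_association_matrix([fit])
    assert mat.cells.iloc[0]["p_bin"] == "<0.05"
    with pytest.raises(StatsError):
        build_association_matrix([fit, fit])


def test_association_matrix_nonconverged_is_missing():
    fit = ModelFit(
        family="negative_binomial",
        params=pd.Series({"const": 0.0, "fiber": 0.2}),
        bse=pd.Series({"const": 0.1, "fiber": 0.1}),
        pvalues=pd.Series({"const": 0.9, "fiber": 0.03}),
        converged=False, n_obs=10, n_groups=4,
        extra={"asv_id": "ASV1", "diet_var": "fiber", "tier": "unadjusted"},
    )
    mat = build_association_matrix([fit])
    assert mat.cells.iloc[0]["p_bin"] == "missing"


def test_candidate_screen_needs_six_infants():
    rng = np.random.default_rng(37)
    table = random_table(rng, n_samples=8, n_participants=4)
    diet = pd.Series(1.0, index=table.metadata["participant_id"].unique())
    with pytest.raises(StatsError):
        candidate_screen(table, diet)
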