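"""Inferential layer: cohort comparisons, PERMANOVA, mixed models.

Covers the association analyses relating diet to the infant gut microbiome:

* Welch / chi-squared cohort comparisons,
* sequential (Type-I) multi-term PERMANOVA on Bray-Curtis distance
  matrices with seeded permutations,
* Gaussian linear mixed models for alpha diversity (statsmodels MixedLM),
* gamma-family random-intercept GLMMs (log link) for sample-to-sample
  Bray-Curtis change, with a gamma goodness-of-fit check,
* negative-binomial random-intercept regressions of ASV counts with a
  log-total-count offset, in three adjustment tiers,
* a cross-sectional NB Wald screen ranking candidate ASVs by log2 fold
  difference, and signed-significance association matrices.

The gamma and negative-binomial mixed models are fit by maximum likelihood
with the random intercept integrated out by Gauss-Hermite quadrature;
standard errors are Wald, from the numerical Hessian at the optimum.
No multiplicity corrections are applied anywhere, by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from scipy.special import gammaln, logsumexp
from skbio import DistanceMatrix

import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess1

P_BINS = ((0.001, "<0.001"), (0.01, "<0.01"), (0.05, "<0.05"), (0.1, "<0.1"))

#: optimizer settings shared by the mixed-model fitters
OPTIM_TOL = 1e-8
OPTIM_MAXITER = 500


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Simple cohort comparisons
# ---------------------------------------------------------------------------

def welch_test(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from summary statistics.

    Returns ``(t, welch_df, two_sided_p)`` with the Welch-Satterthwaite
    degrees of freedom.
    """
    if n_a < 2 or n_b < 2:
        raise StatsError("Welch test needs n >= 2 in each group")
    if sd_a <= 0 or sd_b <= 0:
        raise StatsError("Welch test needs positive standard deviations")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2 * scipy.stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi_squared_test(table) -> tuple[float, int, float]:
    """Pearson chi-squared on a contingency table, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any():
        raise StatsError("negative cell counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise StatsError("all-zero margin in contingency table")
    chi2, p, dof, _ = scipy.stats.chi2_contingency(arr, correction=False)
    return float(chi2), int(dof), float(p)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Sequential PERMANOVA partition: one row per term plus residual/total."""

    table: pd.DataFrame
    n_permutations: int
    seed: int | None = None

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p_value"])


def _design_columns(data: pd.DataFrame, term: str) -> np.ndarray:
    col = data[term]
    if col.nunique() < 2:
        raise StatsError(f"term {term!r} is constant")
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
        return pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)[:, None]


def _hat(x: np.ndarray) -> np.ndarray:
    # projection onto the column space via pseudoinverse (rank-safe)
    return x @ np.linalg.pinv(x)


def permanova(
    dm: DistanceMatrix,
    data: pd.DataFrame,
    terms: list[str],
    n_perm: int = 9999,
    seed: int | None = None,
    strata: str | None = None,
    exact: bool = False,
) -> PermanovaResult:
    """Sequential (Type-I) multi-term PERMANOVA with a permutation test.

    Partitions the Gower-centered squared-distance matrix over the terms in
    caller order; each term's pseudo-F is tested by permuting sample rows
    (within ``strata`` groups when given).  The permutation p-value is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``; with ``exact=True`` all
    ``n!`` row permutations are enumerated instead (small n only) and the
    p-value is the exact exceedance fraction.  Ties are counted with a
    small relative tolerance so permutations equivalent to the identity
    are not lost to roundoff.
    """
    ids = list(dm.ids)
    if not set(ids).issubset(set(data.index)):
        raise StatsError("covariate table does not cover all distance-matrix samples")
    data = data.loc[ids]
    if n_perm < 1:
        raise StatsError("n_perm must be >= 1")
    n = len(ids)
    d2 = dm.data**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    ss_total = np.trace(g)

    # cumulative designs: intercept, then +term1, +term1+term2, ...
    x = np.ones((n, 1))
    hats, ranks = [_hat(x)], [1]
    for term in terms:
        x = np.hstack([x, _design_columns(data, term)])
        hats.append(_hat(x))
        ranks.append(np.linalg.matrix_rank(x))
    df_terms = np.diff(ranks)
    if (df_terms == 0).any():
        bad = [t for t, d in zip(terms, df_terms) if d == 0]
        raise StatsError(f"terms add no rank (collinear): {bad}")
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise StatsError("no residual degrees of freedom")

    def f_stats(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tr = np.array([np.sum(h * gmat) for h in hats])
        ss = np.diff(tr)
        ss_res = np.trace(gmat) - tr[-1]
        f = (ss / df_terms) / (ss_res / df_res)
        return ss, f

    ss_obs, f_obs = f_stats(g)
    ss_res = ss_total - ss_obs.sum()
    tie_tol = 1e-8 * np.maximum(np.abs(f_obs), 1.0)

    if exact:
        import itertools

        if strata is not None:
            raise StatsError("exact enumeration does not support strata")
        exceed = np.zeros(len(terms))
        total = 0
        for perm in itertools.permutations(range(n)):
            _, f_perm = f_stats(g[np.ix_(perm, perm)])
            exceed += f_perm >= f_obs - tie_tol
            total += 1
        pvals = exceed / total
        n_perm = total
    else:
        rng = np.random.default_rng(seed)
        if strata is not None:
            if strata not in data.columns:
                raise StatsError(f"strata column {strata!r} missing")
            groups = data[strata].to_numpy()
            idx_by_group = [
                np.flatnonzero(groups == gval) for gval in pd.unique(groups)
            ]
        exceed = np.zeros(len(terms))
        base = np.arange(n)
        for _ in range(n_perm):
            if strata is None:
                perm = rng.permutation(n)
            else:
                perm = base.copy()
                for idx in idx_by_group:
                    perm[idx] = idx[rng.permutation(len(idx))]
            _, f_perm = f_stats(g[np.ix_(perm, perm)])
            exceed += f_perm >= f_obs - tie_tol
        pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, term in enumerate(terms):
        rows.append(
            {
                "term": term,
                "df": int(df_terms[i]),
                "SS": ss_obs[i],
                "R2": ss_obs[i] / ss_total,
                "pseudo_F": f_obs[i],
                "p_value": pvals[i],
            }
        )
    rows.append(
        {"term": "Residual", "df": int(df_res), "SS": ss_res,
         "R2": ss_res / ss_total, "pseudo_F": np.nan, "p_value": np.nan}
    )
    rows.append(
        {"term": "Total", "df": n - 1, "SS": ss_total, "R2": 1.0,
         "pseudo_F": np.nan, "p_value": np.nan}
    )
    return PermanovaResult(
        pd.DataFrame(rows).set_index("term"), n_permutations=n_perm, seed=seed
    )


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Declarative model description shared by the mixed-model fitters."""

    response: str
    fixed_effects: list[str]
    random_intercept: str = "participant_id"
    family: str = "gaussian"  # gaussian | gamma_log | negative_binomial
    offset: str | None = None

    def __post_init__(self):
        if self.offset is not None and self.family != "negative_binomial":
            raise StatsError("offset only supported for negative_binomial family")


@dataclass
class ModelFit:
    """Coefficient table plus fit metadata for one model."""

    family: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    converged: bool
    n_obs: int
    n_groups: int
    dispersion: float | None = None
    re_sd: float | None = None
    loglike: float | None = None
    extra: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.params[term])

    def p(self, term: str) -> float:
        return float(self.pvalues[term])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "p_value": self.pvalues}
        )


def _prepare_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None, list[str]]:
    cols = ["const"] + list(spec.fixed_effects)
    d = data.dropna(subset=[spec.response, *spec.fixed_effects, spec.random_intercept])
    y = d[spec.response].to_numpy(dtype=float)
    x = np.column_stack(
        [np.ones(len(d))] + [d[c].to_numpy(dtype=float) for c in spec.fixed_effects]
    )
    groups = pd.factorize(d[spec.random_intercept])[0]
    offset = d[spec.offset].to_numpy(dtype=float) if spec.offset else None
    return y, x, groups, offset, cols


# ---------------------------------------------------------------------------
# Gaussian LMM (alpha diversity)
# ---------------------------------------------------------------------------

def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Random-intercept Gaussian linear mixed model by maximum likelihood."""
    if spec.family != "gaussian":
        raise StatsError("fit_lmm requires a gaussian ModelSpec")
    y, x, groups, _, cols = _prepare_design(data, spec)
    if len(np.unique(groups)) < 2:
        raise StatsError("need at least 2 groups for a mixed model")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, x, groups=groups)
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=OPTIM_MAXITER)
            converged = bool(res.converged)
        except Exception:
            return ModelFit(
                "gaussian", pd.Series(dtype=float), pd.Series(dtype=float),
                pd.Series(dtype=float), False, len(y), len(np.unique(groups)),
            )
    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore")
        params = pd.Series(res.fe_params, index=cols)
        bse = pd.Series(res.bse_fe, index=cols)
        pvals = pd.Series(
            2 * scipy.stats.norm.sf(np.abs(res.fe_params / res.bse_fe)), index=cols
        )
        if not np.all(np.isfinite(bse.to_numpy())):
            converged = False
    return ModelFit(
        "gaussian", params, bse, pvals, converged, len(y),
        len(np.unique(groups)),
        dispersion=float(res.scale),
        re_sd=float(np.sqrt(np.asarray(res.cov_re)[0, 0])),
        loglike=float(res.llf),
    )


# ---------------------------------------------------------------------------
# Gauss-Hermite mixed GLM (gamma, negative binomial)
# ---------------------------------------------------------------------------

def _family_loglik(family: str, y: np.ndarray, mu: np.ndarray, disp: float):
    if family == "gamma_log":
        a = disp  # shape
        return (
            a * (np.log(a) - np.log(mu))
            + (a - 1.0) * np.log(y)[:, None]
            - a * y[:, None] / mu
            - gammaln(a)
        )
    if family == "negative_binomial":
        r = 1.0 / disp  # NB2: Var = mu + disp * mu^2
        return (
            gammaln(y[:, None] + r)
            - gammaln(r)
            - gammaln(y + 1.0)[:, None]
            + r * np.log(r / (r + mu))
            + y[:, None] * np.log(mu / (r + mu))
        )
    raise StatsError(f"unknown family {family!r}")


def _glmm_loglik(
    theta: np.ndarray,
    y: np.ndarray,
    x: np.ndarray,
    groups: np.ndarray,
    offset: np.ndarray | None,
    family: str,
    nodes: np.ndarray,
    logweights: np.ndarray,
    n_groups: int,
) -> float:
    p = x.shape[1]
    beta = theta[:p]
    # line searches may probe extreme log-scale values; treat any resulting
    # overflow as a very bad (non-finite) objective rather than warning
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        disp = np.exp(np.clip(theta[p], -300, 300))
        sigma = np.exp(np.clip(theta[p + 1], -300, 300))
        eta0 = x @ beta
        if offset is not None:
            eta0 = eta0 + offset
        b = np.sqrt(2.0) * sigma * nodes  # (K,)
        mu = np.exp(np.clip(eta0[:, None] + b[None, :], -300, 300))
        ll = _family_loglik(family, y, mu, disp)  # (n, K)
        s = np.zeros((n_groups, ll.shape[1]))
        np.add.at(s, groups, ll)
        return float(logsumexp(s + logweights[None, :], axis=1).sum())


def fit_mixed_glm(
    data: pd.DataFrame,
    spec: ModelSpec,
    n_quad: int = 21,
) -> ModelFit:
    """Random-intercept GLMM (log link) by Gauss-Hermite quadrature ML.

    Families: ``gamma_log`` (shape-parametrized gamma) and
    ``negative_binomial`` (NB2 with dispersion alpha, optional log-exposure
    offset).  The marginal likelihood integrates the per-group normal
    random intercept on ``n_quad`` Hermite nodes; parameters are the fixed
    effects, log dispersion, and log random-intercept SD.  Wald standard
    errors come from the numerical Hessian at the optimum.

    The offset is mean-centered internally (the intercept is shifted back
    afterwards) so a global rescaling of exposures cannot perturb the
    optimizer path for the slope coefficients.
    """
    y, x, groups, offset, cols = _prepare_design(data, spec)
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        raise StatsError("need at least 2 groups for a mixed model")
    if spec.family == "gamma_log" and (y <= 0).any():
        raise StatsError("gamma family requires strictly positive responses")

    offset_mean = 0.0
    if offset is not None:
        offset_mean = float(offset.mean())
        offset = offset - offset_mean

    # starting values from the corresponding fixed-effects-only GLM
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if spec.family == "gamma_log":
                g0 = sm.GLM(y, x, family=sm.families.Gamma(sm.families.links.Log()))
                r0 = g0.fit()
                disp0 = max(1.0 / r0.scale, 1e-3)  # scale ~ 1/shape
            else:
                g0 = sm.GLM(y, x, family=sm.families.Poisson(), offset=offset)
                r0 = g0.fit()
                mu0 = r0.fittedvalues
                excess = np.mean(((y - mu0) ** 2 - mu0) / np.maximum(mu0**2, 1e-8))
                disp0 = float(np.clip(excess, 0.05, 10.0))
            beta0 = np.asarray(r0.params)
        except Exception:
            beta0 = np.zeros(x.shape[1])
            beta0[0] = np.log(max(y.mean(), 1e-8))
            disp0 = 1.0

    theta0 = np.concatenate([beta0, [np.log(disp0)], [np.log(0.3)]])
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    logweights = np.log(weights) - 0.5 * np.log(np.pi)

    args = (y, x, groups, offset, spec.family, nodes, logweights, n_groups)

    def nll(theta):
        val = _glmm_loglik(theta, *args)
        return -val if np.isfinite(val) else 1e12

    res = scipy.optimize.minimize(
        nll, theta0, method="BFGS",
        options={"gtol": OPTIM_TOL, "maxiter": OPTIM_MAXITER},
    )
    converged = bool(np.isfinite(res.fun))
    theta = res.x
    p = x.shape[1]
    try:
        hess = approx_hess1(theta, nll)
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        if not np.all(np.isfinite(se_all[:p])) or np.any(se_all[:p] == 0):
            converged = False
    except np.linalg.LinAlgError:
        converged = False
        se_all = np.full(len(theta), np.nan)

    beta = theta[:p].copy()
    beta_report = beta.copy()
    if spec.offset:
        # undo the internal offset centering: eta = X beta' + (offset - m)
        # implies the original-scale intercept is beta0' - m
        beta_report[0] = beta[0] - offset_mean

    params = pd.Series(beta_report, index=cols)
    bse = pd.Series(se_all[:p], index=cols)
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = pd.Series(
            2 * scipy.stats.norm.sf(np.abs(beta / se_all[:p])), index=cols
        )
    return ModelFit(
        spec.family, params, bse, pvals, converged, len(y), n_groups,
        dispersion=float(np.exp(np.clip(theta[p], -300, 300))),
        re_sd=float(np.exp(np.clip(theta[p + 1], -300, 300))),
        loglike=float(-res.fun),
    )


# ---------------------------------------------------------------------------
# Stability model (gamma GLMM) and gamma goodness of fit
# ---------------------------------------------------------------------------

def nudge_zeros(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Replace zero responses by half the smallest positive value.

    Identical consecutive samples give a Bray-Curtis change of exactly 0,
    which a gamma response cannot represent; the number of nudges is
    reported so callers can log it.
    """
    values = np.asarray(values, dtype=float).copy()
    zeros = values == 0
    if zeros.any():
        positive = values[values > 0]
        if positive.size == 0:
            raise StatsError("all responses are zero; gamma model impossible")
        values[zeros] = positive.min() / 2.0
    return values, int(zeros.sum())


def fit_stability_model(
    pooled: pd.DataFrame,
    diet_var: str,
    adjust_for: str | None = "energy_total",
    response: str = "bray_curtis_change",
    group_col: str = "participant_id",
) -> dict[str, ModelFit]:
    """Univariable and caloric-adjusted gamma GLMMs for one diet variable.

    Fits the sample-to-sample Bray-Curtis change (gamma, log link, random
    intercept per infant) against ``diet_var``, unadjusted and adjusted for
    total energy from solids.  Returns ``{"univariable": fit,
    "multivariable": fit}`` (multivariable omitted when ``diet_var`` is the
    adjustment variable itself).
    """
    d = pooled.dropna(subset=[diet_var, response]).copy()
    d[response], n_nudged = nudge_zeros(d[response].to_numpy())
    fits = {}
    uni = fit_mixed_glm(
        d, ModelSpec(response, [diet_var], group_col, family="gamma_log")
    )
    uni.extra["n_zero_nudged"] = n_nudged
    fits["univariable"] = uni
    if adjust_for and diet_var != adjust_for:
        d2 = d.dropna(subset=[adjust_for])
        multi = fit_mixed_glm(
            d2, ModelSpec(response, [diet_var, adjust_for], group_col,
                          family="gamma_log")
        )
        multi.extra["n_zero_nudged"] = n_nudged
        fits["multivariable"] = multi
    return fits


def stability_model_table(
    pooled: pd.DataFrame,
    diet_vars: list[str],
    adjust_for: str = "energy_total",
) -> pd.DataFrame:
    """Model-summary table: per variable, univariable and adjusted tiers."""
    rows = []
    for var in diet_vars:
        fits = fit_stability_model(pooled, var, adjust_for)
        uni = fits["univariable"]
        row = {
            "term": var,
            "univariable_estimate": uni.coef(var) if uni.converged else np.nan,
            "univariable_p": uni.p(var) if uni.converged else np.nan,
            "univariable_converged": uni.converged,
        }
        if "multivariable" in fits:
            m = fits["multivariable"]
            row.update(
                multivariable_estimate=m.coef(var) if m.converged else np.nan,
                multivariable_p=m.p(var) if m.converged else np.nan,
                multivariable_converged=m.converged,
            )
        else:
            row.update(
                multivariable_estimate=np.nan, multivariable_p=np.nan,
                multivariable_converged=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("term")


def gamma_gof(responses) -> tuple[float, float, float, float]:
    """ML gamma fit plus one-sample Kolmogorov-Smirnov test.

    Returns ``(shape, rate, ks_statistic, ks_p)``; location fixed at zero.
    """
    y = np.asarray(responses, dtype=float)
    if y.size < 5:
        raise StatsError("need at least 5 observations")
    if (y <= 0).any():
        raise StatsError("gamma fit requires strictly positive values")
    shape, _, scale = scipy.stats.gamma.fit(y, floc=0)
    ks = scipy.stats.kstest(y, "gamma", args=(shape, 0, scale))
    return float(shape), float(1.0 / scale), float(ks.statistic), float(ks.pvalue)


# ---------------------------------------------------------------------------
# Negative-binomial ASV regressions
# ---------------------------------------------------------------------------

NB_TIERS = ("unadjusted", "multivariate_I", "multivariate_II")


def _tier_covariates(tier: str, diet_var: str) -> list[str]:
    if tier == "unadjusted":
        return [diet_var]
    if tier == "multivariate_I":
        return [diet_var, "energy_total"]
    if tier == "multivariate_II":
        return [diet_var, "energy_total", "age_at_intro_weeks"]
    raise StatsError(f"unknown tier {tier!r}")


def fit_nb_asv(
    table,
    asv_id: str,
    diet_data: pd.DataFrame,
    diet_var: str,
    tier: str = "multivariate_II",
) -> ModelFit:
    """NB2 random-intercept regression of one ASV's counts on a diet variable.

    ``diet_data`` is indexed by sample id and must carry ``diet_var``,
    ``participant_id`` and the tier's adjustment columns (``energy_total``,
    ``age_at_intro_weeks``).  The offset is the log of each sample's total
    count, so coefficients act on relative abundance.
    """
    if asv_id not in table.counts.columns:
        raise StatsError(f"ASV {asv_id!r} absent from table")
    y = table.counts[asv_id]
    if (y == 0).all():
        raise StatsError(f"ASV {asv_id!r} has all-zero counts")
    covars = _tier_covariates(tier, diet_var)
    d = diet_data.loc[table.counts.index].copy()
    d["_count"] = y.values
    d["_log_total"] = np.log(table.counts.sum(axis=1).values)
    spec = ModelSpec(
        "_count", covars, "participant_id",
        family="negative_binomial", offset="_log_total",
    )
    fit = fit_mixed_glm(d, spec)
    fit.extra.update(asv_id=asv_id, diet_var=diet_var, tier=tier)
    return fit


def candidate_screen(
    table,
    diet_by_participant: pd.Series,
    diet_name: str = "diet",
    top_n: int = 5,
    min_prevalence: int = 2,
) -> pd.DataFrame:
    """Cross-sectional NB Wald screen on each infant's last sample.

    A simplified differential-abundance screen: per ASV, a plain NB
    regression of the last-sample count on the participant's diet value
    with a log-total-count offset, ranked by absolute log2 fold difference
    per diet unit (``|estimate| / ln 2``).  Returns the ``top_n`` ranked
    ASVs; if fewer converge a warning is issued and all are returned.
    """
    meta = table.metadata
    last = meta.sort_values("study_day").groupby("participant_id").tail(1)
    if len(last) < 6:
        raise StatsError("candidate screen needs at least 6 infants")
    diet = diet_by_participant.reindex(last["participant_id"]).to_numpy(dtype=float)
    if np.nanstd(diet) == 0:
        raise StatsError(f"diet variable {diet_name!r} constant across infants")
    sub = table.counts.loc[last.index]
    log_total = np.log(sub.sum(axis=1).to_numpy(dtype=float))
    x = np.column_stack([np.ones(len(sub)), diet])
    rows = []
    for asv in sub.columns:
        y = sub[asv].to_numpy(dtype=float)
        if (y > 0).sum() < min_prevalence:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = sm.NegativeBinomial(y, x, offset=log_total)
                res = model.fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", False):
                    continue
                est = float(res.params[1])
                pval = float(res.pvalues[1])
            except Exception:
                continue
        if not np.isfinite(est) or not np.isfinite(pval):
            continue
        rows.append(
            {
                "asv_id": asv,
                "estimate": est,
                "log2_fold_per_unit": est / np.log(2),
                "p_value": pval,
                "sign": int(np.sign(est)),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        warnings.warn("no ASVs converged in candidate screen")
        return out
    out = out.reindex(
        out["log2_fold_per_unit"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
    if len(out) < top_n:
        warnings.warn(
            f"only {len(out)} converged ASVs in candidate screen (wanted {top_n})"
        )
        return out
    return out.head(top_n)


def select_top_abundant(table, k: int = 10) -> list[str]:
    """Top-k ASVs by mean relative abundance; ties broken by ASV id."""
    from .community import relative_abundance

    mean_rel = relative_abundance(table).mean(axis=0)
    order = sorted(mean_rel.index, key=lambda a: (-mean_rel[a], a))
    return order[: min(k, len(order))]


# ---------------------------------------------------------------------------
# Association matrix
# ---------------------------------------------------------------------------

def p_bin(p: float) -> str:
    """Bin a p-value by the strict-< thresholds 0.001/0.01/0.05/0.1."""
    for cut, label in P_BINS:
        if p < cut:
            return label
    return "ns"


@dataclass
class AssociationMatrix:
    """Taxa x diet-variable grid of signed significance for one model tier."""

    tier: str
    cells: pd.DataFrame  # columns: taxon, diet_var, sign, p_bin, estimate, p_value

    def to_frame(self) -> pd.DataFrame:
        def fmt(row):
            if row["p_bin"] == "missing":
                return "missing"
            sig = row["p_bin"]
            return f"{'+' if row['sign'] > 0 else '-' if row['sign'] < 0 else '0'}{sig}"

        wide = self.cells.assign(cell=self.cells.apply(fmt, axis=1)).pivot(
            index="taxon", columns="diet_var", values="cell"
        )
        return wide

    def to_records(self) -> list[dict]:
        return self.cells.to_dict(orient="records")


def build_association_matrix(fits: list[ModelFit]) -> AssociationMatrix:
    """Assemble signed significance bins from NB fits sharing one tier.

    Non-converged fits become explicit ``missing`` cells; a duplicate
    (taxon, diet variable) cell is an error.  Boundary values follow the
    strict-< convention (p = 0.05 is "ns" at the 0.05 bin).
    """
    if not fits:
        raise StatsError("no fits given")
    tiers = {f.extra.get("tier") for f in fits}
    if len(tiers) != 1:
        raise StatsError(f"fits span multiple tiers: {tiers}")
    rows, seen = [], set()
    for f in fits:
        key = (f.extra["asv_id"], f.extra["diet_var"])
        if key in seen:
            raise StatsError(f"duplicate association cell {key}")
        seen.add(key)
        if not f.converged:
            rows.append(
                {"taxon": key[0], "diet_var": key[1], "sign": 0,
                 "p_bin": "missing", "estimate": np.nan, "p_value": np.nan}
            )
            continue
        est = f.coef(f.extra["diet_var"])
        pv = f.p(f.extra["diet_var"])
        rows.append(
            {"taxon": key[0], "diet_var": key[1], "sign": int(np.sign(est)),
             "p_bin": p_bin(pv), "estimate": est, "p_value": pv}
        )
    return AssociationMatrix(tiers.pop(), pd.DataFrame(rows))
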