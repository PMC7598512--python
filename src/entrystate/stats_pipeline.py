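"""Variable screening and random-intercept mixed-model workflow.

The analysis mirrors the sequence used to relate the entry state to start
performance: (1) for every candidate entry variable, three simple
pooled-OLS regressions (responses TTO15, z-score15m, outcome5m) plus the
pairwise Pearson correlation matrix; (2) candidate selection -- a variable
is excluded if any of its three slope p-values exceeds 0.3, and among
surviving variables with absolute pairwise correlation >= 0.75 only the
one with the highest average bearing (mean r^2 across the three screening
responses, by default) is kept per correlated cluster; (3) a linear mixed
model with the survivors as fixed effects and a per-swimmer random
intercept, reduced by step-down elimination of the highest-p fixed effect
until all remaining effects are significant; (4) a sex confounder check
(>= 10% coefficient change on augmentation); (5) validation: variance
inflation factors, Shapiro-Wilk on the estimated random intercepts,
likelihood-ratio tests, and two variance-explained measures.

Mixed models are fit with statsmodels' ``MixedLM`` (REML estimates for
coefficients and standard errors; an ML refit supplies log-likelihoods
for LR tests).  Fixed-effect p-values are Wald tests against a normal
reference.  No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "SCREENING_RESPONSES",
    "ScreeningResult",
    "MixedModelFit",
    "ValidationReport",
    "screen_variables",
    "select_candidates",
    "fit_mixed_model",
    "step_down",
    "confounder_check",
    "likelihood_ratio_test",
    "validate_model",
]

SCREENING_RESPONSES = ("outcome5m", "tto15", "zscore15m")


@dataclass
class ScreeningResult:
    """r^2 and slope p per candidate x response, plus predictor correlations."""

    r2: pd.DataFrame          # index: candidates, columns: responses
    p: pd.DataFrame
    correlations: pd.DataFrame

    @property
    def candidates(self) -> list[str]:
        return list(self.r2.index)


@dataclass
class MixedModelFit:
    """Random-intercept mixed model summary for one response."""

    response: str
    predictors: tuple[str, ...]
    params: pd.Series            # fixed effects incl. intercept (REML)
    bse: pd.Series
    pvalues: pd.Series
    random_intercept_sd: float
    residual_sd: float
    llf_ml: float
    llf_reml: float
    n_obs: int
    n_groups: int
    singular: bool
    random_effects: pd.Series    # estimated per-group intercepts (BLUPs)
    fitted_fixed: np.ndarray
    groups: np.ndarray

    @property
    def fitted_conditional(self) -> np.ndarray:
        """Fixed-effect prediction plus the group's estimated intercept."""
        re = self.random_effects.reindex(self.groups).to_numpy()
        return self.fitted_fixed + re


@dataclass
class ValidationReport:
    vif: pd.Series
    shapiro_w: float
    shapiro_p: float
    lr_final_vs_null: tuple[float, int, float]
    lr_full_vs_final: tuple[float, int, float] | None
    residual_sd_null: float
    residual_sd_final: float
    response_variance: float
    fraction_explained_simple: float
    conditional_r2: float
    mean_predicted_minus_observed: float
    predicted_vs_observed: pd.DataFrame = field(repr=False)


def screen_variables(
    df: pd.DataFrame,
    candidates: list[str],
    responses: tuple[str, ...] = SCREENING_RESPONSES,
) -> ScreeningResult:
    """Simple pooled regressions of each response on each candidate.

    Constant predictors get r^2 = 0 with the p-value flagged NaN.
    """
    if len(df) < 3:
        raise ValueError("need at least 3 starts for screening")
    missing = [c for c in candidates if c not in df.columns]
    if missing:
        raise KeyError(f"candidates absent from the table: {missing}")
    r2 = pd.DataFrame(index=candidates, columns=responses, dtype=float)
    pv = pd.DataFrame(index=candidates, columns=responses, dtype=float)
    for c in candidates:
        x = df[c].to_numpy(dtype=float)
        for resp in responses:
            y = df[resp].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                r2.loc[c, resp] = 0.0
                pv.loc[c, resp] = np.nan
                continue
            res = sps.linregress(x, y)
            r2.loc[c, resp] = res.rvalue**2
            pv.loc[c, resp] = res.pvalue
    corr = df[candidates].corr(method="pearson")
    return ScreeningResult(r2=r2, p=pv, correlations=corr)


def select_candidates(
    screening: ScreeningResult,
    p_max: float = 0.3,
    r_max: float = 0.75,
    strategy: str = "mean_r2",
) -> list[str]:
    """Two-stage candidate selection.

    Stage 1 drops any variable with one or more screening p-values above
    ``p_max`` (or undefined).  Stage 2 builds the graph of survivors with
    ``|r| >= r_max`` and keeps one variable per connected component: the
    one with the highest mean r^2 across the screening responses
    (``strategy='mean_r2'``) or the smallest minimum p (``'min_p'``).
    """
    survivors = [
        c
        for c in screening.candidates
        if screening.p.loc[c].notna().all() and (screening.p.loc[c] <= p_max).all()
    ]
    if not survivors:
        raise ValueError("no candidate survived the screening p-value filter")

    parent = {c: c for c in survivors}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(survivors):
        for b in survivors[i + 1:]:
            if abs(screening.correlations.loc[a, b]) >= r_max:
                parent[find(a)] = find(b)

    clusters: dict[str, list[str]] = {}
    for c in survivors:
        clusters.setdefault(find(c), []).append(c)

    if strategy == "mean_r2":
        score = lambda c: screening.r2.loc[c].mean()
    elif strategy == "min_p":
        score = lambda c: -screening.p.loc[c].min()
    else:
        raise ValueError(f"unknown selection strategy {strategy!r}")

    kept = [max(members, key=score) for members in clusters.values()]
    return [c for c in screening.candidates if c in kept]


def _fit_mixedlm(endog, exog, groups, reml):
    model = MixedLM(endog, exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=reml)
        if not getattr(fit, "converged", True) or not np.isfinite(fit.llf):
            for method in ("powell", "cg"):
                retry = model.fit(reml=reml, method=method)
                if getattr(retry, "converged", True) and np.isfinite(retry.llf):
                    fit = retry
                    break
    return fit


def fit_mixed_model(
    df: pd.DataFrame,
    predictors: list[str],
    response: str,
    group: str = "swimmer_id",
) -> MixedModelFit:
    """Random-intercept linear mixed model of ``response`` on ``predictors``.

    Requires at least two groups with two starts each.  A vanishing
    random-intercept variance is returned with ``singular=True`` rather
    than raised.
    """
    groups = df[group].to_numpy()
    counts = pd.Series(groups).value_counts()
    if len(counts) < 2 or (counts < 2).all():
        raise ValueError("need >= 2 participants with >= 2 starts each")

    endog = df[response].to_numpy(dtype=float)
    exog = sm.add_constant(df[list(predictors)].astype(float), has_constant="add")
    exog = exog.rename(columns={"const": "intercept"})

    fit_reml = _fit_mixedlm(endog, exog, groups, reml=True)
    fit_ml = _fit_mixedlm(endog, exog, groups, reml=False)

    names = list(exog.columns)
    params = pd.Series(np.asarray(fit_reml.fe_params), index=names)
    bse = pd.Series(np.asarray(fit_reml.bse_fe), index=names)
    pvals = pd.Series(np.asarray(fit_reml.pvalues)[: len(names)], index=names)
    re_var = float(np.asarray(fit_reml.cov_re)[0, 0])
    resid_sd = float(np.sqrt(fit_reml.scale))
    try:
        re = pd.Series(
            {g: float(np.asarray(v)[0]) for g, v in fit_reml.random_effects.items()}
        )
    except (ValueError, np.linalg.LinAlgError):
        # vanishing random-effect variance: BLUPs are identically zero
        re = pd.Series({g: 0.0 for g in counts.index})
    fitted_fixed = exog.to_numpy() @ params.to_numpy()
    return MixedModelFit(
        response=response,
        predictors=tuple(predictors),
        params=params,
        bse=bse,
        pvalues=pvals,
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
        residual_sd=resid_sd,
        llf_ml=float(fit_ml.llf),
        llf_reml=float(fit_reml.llf),
        n_obs=len(endog),
        n_groups=len(counts),
        singular=bool(re_var < 1e-10 * max(np.var(endog), 1e-12)),
        random_effects=re,
        fitted_fixed=fitted_fixed,
        groups=groups,
    )


def step_down(
    df: pd.DataFrame,
    predictors: list[str],
    response: str,
    alpha: float = 0.05,
    group: str = "swimmer_id",
):
    """Backward elimination of fixed effects.

    Starting from the full model, the predictor with the highest Wald
    p-value is removed (the intercept never is) and the model refit until
    every remaining predictor has p < ``alpha`` or none remain.  Ties on p
    remove the later variable in the declared order.  Returns the final
    fit and the removal trace ``[(name, p), ...]``.
    """
    current = list(predictors)
    trace: list[tuple[str, float]] = []
    fit = fit_mixed_model(df, current, response, group=group)
    while current:
        pv = fit.pvalues.drop("intercept")
        worst_p = pv.max()
        if worst_p < alpha:
            break
        # tie-break: the later variable in declared order among maxima
        worst = [n for n in current if np.isclose(pv[n], worst_p)][-1]
        current.remove(worst)
        trace.append((worst, float(worst_p)))
        fit = fit_mixed_model(df, current, response, group=group)
    return fit, trace


def confounder_check(
    df: pd.DataFrame,
    final_fit: MixedModelFit,
    covariate: str = "sex",
    threshold: float = 0.10,
    group: str = "swimmer_id",
):
    """Coefficient-change confounder rule.

    The final model is refit with ``covariate`` added (categorical
    covariates are dummy-coded).  If any original predictor coefficient
    changes by at least ``threshold`` (relative), the covariate is deemed
    a confounder and retained.  Returns ``(retained, augmented_fit,
    relative_changes)``; a constant covariate is skipped with a warning.
    """
    if covariate not in df.columns:
        raise KeyError(f"covariate {covariate!r} absent from the table")
    col = df[covariate]
    if col.nunique() < 2:
        warnings.warn(f"covariate {covariate!r} is constant; confounder check skipped")
        return False, None, pd.Series(dtype=float)

    work = df.copy()
    if not pd.api.types.is_numeric_dtype(col):
        codes, _ = pd.factorize(col)
        cov_col = f"{covariate}_code"
        work[cov_col] = codes.astype(float)
    else:
        cov_col = covariate

    aug = fit_mixed_model(
        work, list(final_fit.predictors) + [cov_col], final_fit.response, group=group
    )
    old = final_fit.params.drop("intercept")
    new = aug.params.reindex(old.index)
    diff = (new - old).abs()
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = pd.Series(
            np.where(old.abs() > 0, diff / old.abs(),
                     np.where(diff > 0, np.inf, 0.0)),
            index=old.index,
        )
    retained = bool((rel >= threshold).any()) if len(rel) else False
    return retained, aug, rel


def likelihood_ratio_test(nested_fit: MixedModelFit, fuller_fit: MixedModelFit):
    """LR test of two nested fixed-effect structures (ML log-likelihoods).

    Returns (chi2, df, p).  The chi-square statistic is clipped at zero.
    """
    if nested_fit.response != fuller_fit.response:
        raise ValueError("fits have different responses")
    if not set(nested_fit.predictors) <= set(fuller_fit.predictors):
        raise ValueError("fixed-effect sets are not nested")
    df = len(fuller_fit.predictors) - len(nested_fit.predictors)
    chi2 = max(2.0 * (fuller_fit.llf_ml - nested_fit.llf_ml), 0.0)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    if df == 0:
        chi2 = 0.0
    return chi2, df, p


def validate_model(
    fit: MixedModelFit,
    df: pd.DataFrame,
    full_fit: MixedModelFit | None = None,
    group: str = "swimmer_id",
) -> ValidationReport:
    """Validation battery for a fitted mixed model.

    VIF_j = 1 / (1 - R_j^2) from regressing predictor j on the other
    predictors (infinite under perfect collinearity); Shapiro-Wilk on the
    estimated per-participant random intercepts; LR tests of the final
    model against the intercept-plus-random-intercept null (and against
    the full model when given); and two variance-explained measures:
    1 - sigma_resid^2 / var(response) and the conditional R^2 (variance of
    fixed-plus-random fitted values over the response variance).
    """
    preds = list(fit.predictors)
    vif = {}
    if len(preds) >= 2:
        X = df[preds].to_numpy(dtype=float)
        for j, name in enumerate(preds):
            others = np.delete(X, j, axis=1)
            r2 = sm.OLS(X[:, j], sm.add_constant(others)).fit().rsquared
            vif[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    elif preds:
        vif[preds[0]] = 1.0
    vif = pd.Series(vif, dtype=float)

    re = fit.random_effects.to_numpy()
    if len(re) >= 3:
        w, p_sw = sps.shapiro(re)
    else:  # pragma: no cover - degenerate group count
        w, p_sw = np.nan, np.nan

    null_fit = fit_mixed_model(df, [], fit.response, group=group)
    lr_null = likelihood_ratio_test(null_fit, fit)
    lr_full = likelihood_ratio_test(fit, full_fit) if full_fit is not None else None

    y = df[fit.response].to_numpy(dtype=float)
    var_y = float(np.var(y, ddof=1))
    frac_simple = 1.0 - fit.residual_sd**2 / var_y
    cond = fit.fitted_conditional
    conditional_r2 = float(np.var(cond, ddof=1) / var_y)

    pvo = pd.DataFrame(
        {
            "observed": y,
            "predicted": cond,
            "predicted_fixed_only": fit.fitted_fixed,
            "swimmer_id": fit.groups,
        }
    )
    return ValidationReport(
        vif=vif,
        shapiro_w=float(w),
        shapiro_p=float(p_sw),
        lr_final_vs_null=lr_null,
        lr_full_vs_final=lr_full,
        residual_sd_null=null_fit.residual_sd,
        residual_sd_final=fit.residual_sd,
        response_variance=var_y,
        fraction_explained_simple=float(frac_simple),
        conditional_r2=conditional_r2,
        mean_predicted_minus_observed=float(np.mean(cond - y)),
        predicted_vs_observed=pvo,
    )
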