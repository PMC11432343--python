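"""Model-selection ladder on the per-video metrics table.

For each response the ladder fits a simple linear regression and,
when random intercept terms are given, a mixed model with crossed random
intercepts.  The mixed model is kept only when its AIC beats the simple
model's and the fit is not singular.  Residuals of the selected model are
checked for normality (Shapiro-Wilk) and homoscedasticity
(Goldfeld-Quandt); heteroscedastic simple models are reported with
HC3 robust standard errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.diagnostic import het_goldfeldquandt
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from beeforage.errors import DesignError, ParameterError, TransformationDomainError

__all__ = [
    "Transformation",
    "IDENTITY",
    "SQRT",
    "CBRT",
    "power_transform",
    "apply_transformation",
    "ModelSpec",
    "FitReport",
    "fit_ladder",
    "significance_code",
]


@dataclass(frozen=True)
class Transformation:
    """Invertible response transformation."""

    name: str
    forward: Callable[[np.ndarray], np.ndarray]
    inverse: Callable[[np.ndarray], np.ndarray]
    domain_ok: Callable[[np.ndarray], np.ndarray]

    def __call__(self, y: np.ndarray) -> np.ndarray:
        return apply_transformation(y, self)


IDENTITY = Transformation(
    "identity", lambda y: y, lambda y: y, lambda y: np.ones_like(y, dtype=bool)
)
SQRT = Transformation(
    "sqrt", np.sqrt, lambda y: y**2, lambda y: y >= 0
)
CBRT = Transformation(
    "cbrt", np.cbrt, lambda y: y**3, lambda y: np.ones_like(y, dtype=bool)
)


def power_transform(p: float) -> Transformation:
    """General power transform y -> y**p (p != 0); negative p excludes zero."""
    if p == 0:
        raise ParameterError("power must be non-zero")
    domain = (lambda y: y != 0) if p < 0 else (lambda y: np.ones_like(y, dtype=bool))
    return Transformation(
        f"power({p:g})",
        lambda y: np.power(y, p),
        lambda y: np.power(y, 1.0 / p),
        domain,
    )


def apply_transformation(y: Sequence[float], t: Transformation) -> np.ndarray:
    """Element-wise transform with an explicit domain check."""
    arr = np.asarray(y, dtype=np.float64)
    ok = t.domain_ok(arr)
    if not np.all(ok):
        bad = np.flatnonzero(~ok)
        raise TransformationDomainError(
            f"{t.name} undefined at indices {bad.tolist()}", offending_indices=bad
        )
    return t.forward(arr)


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, transformation, fixed RHS, random intercepts.

    ``fixed`` is a patsy right-hand side (e.g. ``"C(species) * flower_cover_pct"``);
    ``random`` lists columns that become crossed random intercepts in the
    mixed alternative (empty: simple regression only).
    """

    response: str
    fixed: str
    transformation: Transformation = IDENTITY
    random: Tuple[str, ...] = ()


@dataclass
class FitReport:
    """Selected model's coefficients, selection path and diagnostics."""

    spec: ModelSpec
    model_kind: str  # "ols" | "mixed"
    params: pd.DataFrame  # term, estimate, se, t, p, significance
    aic: float
    aic_simple: float
    aic_mixed: Optional[float]
    singular: bool
    normality_p: float
    heteroscedasticity_p: float
    robust: bool
    selection_log: List[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "fixed": self.spec.fixed,
            "transformation": self.spec.transformation.name,
            "random": list(self.spec.random),
            "model_kind": self.model_kind,
            "aic": self.aic,
            "aic_simple": self.aic_simple,
            "aic_mixed": self.aic_mixed,
            "singular": self.singular,
            "normality_p": self.normality_p,
            "heteroscedasticity_p": self.heteroscedasticity_p,
            "robust": self.robust,
            "selection_log": self.selection_log,
            "coefficients": self.params.to_dict(orient="records"),
        }


def significance_code(p: float) -> str:
    """Significance stars in the conventional coding."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _coef_table(names, est, se, tvals, pvals) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": list(names),
            "estimate": np.asarray(est, dtype=float),
            "se": np.asarray(se, dtype=float),
            "t": np.asarray(tvals, dtype=float),
            "p": np.asarray(pvals, dtype=float),
            "significance": [significance_code(p) for p in np.asarray(pvals, dtype=float)],
        }
    )


def _validate_design(data: pd.DataFrame, spec: ModelSpec) -> None:
    if "species" in spec.fixed and "species" in data.columns:
        if data["species"].nunique() < 2:
            raise DesignError("design needs at least two species levels")
    for col in data.columns:
        if col in spec.fixed and pd.api.types.is_numeric_dtype(data[col]):
            if np.isclose(data[col].std(ddof=0), 0.0):
                raise DesignError(f"covariate {col!r} is constant")


def _fit_mixed(data: pd.DataFrame, formula: str, random: Tuple[str, ...]):
    """Crossed random intercepts via variance components on a single group."""
    df = data.copy()
    df["_one_group"] = 1
    vc = {term: f"0 + C({term})" for term in random}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, df, groups="_one_group", vc_formula=vc)
        # ML (not REML) so the AIC is comparable with the OLS fit.
        result = model.fit(reml=False)
        convergence_issue = any(
            issubclass(w.category, (ConvergenceWarning, RuntimeWarning)) for w in caught
        )
    return result, convergence_issue


def _mixed_is_singular(result, resid_var: float, convergence_issue: bool) -> bool:
    """Singular when any variance component collapses to (near) zero."""
    vcomp = np.asarray(result.vcomp, dtype=float)
    scale = max(resid_var, float(result.scale), 1e-12)
    return bool(convergence_issue or vcomp.size == 0 or np.any(vcomp < 1e-6 * scale))


def fit_ladder(data: pd.DataFrame, spec: ModelSpec, alpha: float = 0.05) -> FitReport:
    """Fit simple and (optionally) mixed models and select per the AIC rule.

    The mixed model is selected iff its AIC is lower than the simple
    model's and the fit is not singular.  Shapiro-Wilk (normality) and
    Goldfeld-Quandt (homoscedasticity) are run on the selected model's
    residuals; a heteroscedastic simple model is re-reported with HC3
    robust standard errors.
    """
    if spec.response not in data.columns:
        raise ParameterError(f"response {spec.response!r} not in data")
    _validate_design(data, spec)

    df = data.copy().reset_index(drop=True)
    df["_y"] = apply_transformation(df[spec.response].to_numpy(), spec.transformation)
    formula = f"_y ~ {spec.fixed}"
    log: List[str] = [f"response transformed with {spec.transformation.name}"]

    ols_fit = smf.ols(formula, df).fit()
    aic_simple = float(ols_fit.aic)
    log.append(f"simple model AIC = {aic_simple:.3f}")

    aic_mixed: Optional[float] = None
    singular = False
    use_mixed = False
    mixed_fit = None
    if spec.random:
        try:
            mixed_fit, convergence_issue = _fit_mixed(df, formula, spec.random)
            aic_mixed = float(mixed_fit.aic)
            singular = _mixed_is_singular(
                mixed_fit, float(np.var(ols_fit.resid)), convergence_issue
            )
            log.append(f"mixed model AIC = {aic_mixed:.3f}, singular = {singular}")
            use_mixed = (aic_mixed < aic_simple) and not singular
        except Exception as exc:  # mixed fit can fail outright on tiny designs
            log.append(f"mixed model failed to fit: {exc!r}; falling back to simple model")
            singular = True
    log.append("selected: mixed model" if use_mixed else "selected: simple linear model")

    if use_mixed:
        assert mixed_fit is not None
        resid = np.asarray(mixed_fit.resid, dtype=float)
        fe = mixed_fit.fe_params
        names = list(fe.index)
        params = _coef_table(
            names,
            fe.to_numpy(),
            mixed_fit.bse_fe.to_numpy(),
            mixed_fit.tvalues[: len(names)].to_numpy(),
            mixed_fit.pvalues[: len(names)].to_numpy(),
        )
        aic = float(aic_mixed)
        kind = "mixed"
    else:
        resid = np.asarray(ols_fit.resid, dtype=float)
        params = _coef_table(
            ols_fit.params.index, ols_fit.params, ols_fit.bse, ols_fit.tvalues, ols_fit.pvalues
        )
        aic = aic_simple
        kind = "ols"

    normality_p = float(stats.shapiro(resid).pvalue) if 3 <= resid.size <= 5000 else math.nan
    exog = ols_fit.model.exog
    try:
        _, het_p, _ = het_goldfeldquandt(df["_y"].to_numpy(), exog)
        het_p = float(het_p)
    except Exception:
        het_p = math.nan
    log.append(f"Shapiro-Wilk p = {normality_p:.4f}, Goldfeld-Quandt p = {het_p:.4f}")

    robust = bool(not math.isnan(het_p) and het_p < alpha)
    if robust and kind == "ols":
        robust_fit = ols_fit.get_robustcov_results(cov_type="HC3")
        params = _coef_table(
            ols_fit.params.index,
            robust_fit.params,
            robust_fit.bse,
            robust_fit.tvalues,
            robust_fit.pvalues,
        )
        log.append("heteroscedastic residuals: reporting HC3 robust standard errors")
    elif robust:
        log.append("heteroscedastic residuals under mixed model: robust SEs unavailable")

    return FitReport(
        spec=spec,
        model_kind=kind,
        params=params,
        aic=aic,
        aic_simple=aic_simple,
        aic_mixed=aic_mixed,
        singular=singular,
        normality_p=normality_p,
        heteroscedasticity_p=het_p,
        robust=robust,
        selection_log=log,
    )
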