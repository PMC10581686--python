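"""Fitting and validating the interest count models.

Workflow mirrored here: fit a Poisson mixed model first, check for
overdispersion via the Pearson dispersion ratio, escalate to NB2; check the
societal model for zero under-fitting (observed vs. predicted zeros),
escalate to zero-inflated NB2; confirm no multicollinearity (all VIF < 3)
and rank candidate models by AIC.  Significance uses a conservative
alpha = 0.01 Wald convention.

The heavy lifting lives in :mod:`biointerest.glmm`; this module provides the
procedure-level operations and report containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import CountGLMM, CountGLMMResults, FAMILIES

__all__ = [
    "CountModelSpec",
    "DiagnosticsReport",
    "ZeroCheck",
    "fit_count_model",
    "overdispersion_check",
    "zero_check",
    "vif",
    "compare_fits",
    "significance_flags",
    "influence_report",
]


@dataclass(frozen=True)
class CountModelSpec:
    """What to fit: response, conditional family, fixed and random terms."""

    response: str = "papers"            # "papers" (scientific) | "views" (societal)
    family: str = "nb2"
    fixed_terms: tuple[str, ...] = ()
    random_terms: tuple[str, ...] = ()
    zi_structure: str = "none"          # "none" | "intercept_only"

    def __post_init__(self):
        if self.response not in ("papers", "views"):
            raise ValueError(f"response must be 'papers' or 'views', got {self.response!r}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not self.fixed_terms:
            raise ValueError("fixed_terms must be nonempty")
        if self.family == "zinb2" and self.zi_structure != "intercept_only":
            raise ValueError("zinb2 requires zi_structure='intercept_only'")
        if self.family != "zinb2" and self.zi_structure != "none":
            raise ValueError("zi_structure is only meaningful for zinb2")


def fit_count_model(
    design: pd.DataFrame,
    y,
    spec: CountModelSpec,
    group_labels: dict | None = None,
    **fit_kwargs,
) -> CountGLMMResults:
    """Fit the model described by ``spec`` on a prepared design.

    ``design`` must contain every column in ``spec.fixed_terms`` (plus
    ``const``); ``group_labels`` maps each name in ``spec.random_terms`` to
    per-observation labels.
    """
    cols = list(spec.fixed_terms)
    if "const" in design.columns and "const" not in cols:
        cols = ["const"] + cols
    missing = [c for c in cols if c not in design.columns]
    if missing:
        raise ValueError(f"design is missing fixed terms: {missing}")
    groups = None
    if spec.random_terms:
        group_labels = group_labels or {}
        absent = [g for g in spec.random_terms if g not in group_labels]
        if absent:
            raise ValueError(f"no group labels supplied for random terms: {absent}")
        groups = {g: group_labels[g] for g in spec.random_terms}
    model = CountGLMM(np.asarray(y), design[cols], groups=groups, family=spec.family)
    return model.fit(**fit_kwargs)


@dataclass
class DiagnosticsReport:
    """Overdispersion / zero-fit / collinearity numbers for one fit."""

    dispersion_ratio: float
    pearson_chi2: float
    df: int
    p_overdispersion: float
    observed_zeros: int | None = None
    predicted_zeros: float | None = None
    zero_ratio: float | None = None
    vif: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dispersion_ratio": self.dispersion_ratio,
            "pearson_chi2": self.pearson_chi2,
            "df": self.df,
            "p_overdispersion": self.p_overdispersion,
            "observed_zeros": self.observed_zeros,
            "predicted_zeros": self.predicted_zeros,
            "zero_ratio": self.zero_ratio,
            "vif": {k: float(v) for k, v in self.vif.items()},
        }


def overdispersion_check(fit: CountGLMMResults) -> DiagnosticsReport:
    """Pearson dispersion ratio: sum of squared Pearson residuals over df.

    df = n_obs - number of fixed-effect parameters.  A ratio well above 1
    under a Poisson fit indicates overdispersion (chi-square upper-tail
    p-value reported); a correctly specified family gives a ratio near 1.
    """
    if not fit.converged:
        raise ValueError("overdispersion check requires a converged fit")
    df = fit.df_resid
    if df <= 0:
        raise ValueError("nonpositive residual degrees of freedom")
    chi2 = float(np.sum(fit.pearson_resid() ** 2))
    ratio = chi2 / df
    p = float(stats.chi2.sf(chi2, df))
    return DiagnosticsReport(
        dispersion_ratio=ratio, pearson_chi2=chi2, df=int(df), p_overdispersion=p
    )


@dataclass
class ZeroCheck:
    observed: int
    predicted: float
    ratio: float  # predicted / observed; NaN when no zeros observed
    note: str = ""


def zero_check(fit: CountGLMMResults) -> ZeroCheck:
    """Observed vs. model-predicted zero counts.

    predicted = sum_i P(y_i = 0 | fitted model); ratio = predicted/observed.
    A ratio well below 1 means the model under-fits zeros — the signature of
    zero inflation.  With no observed zeros the ratio is NaN with a note.
    """
    if not fit.converged:
        raise ValueError("zero check requires a converged fit")
    observed = int(np.sum(fit.model.y == 0))
    predicted = float(np.sum(fit.predict_zero_prob()))
    if observed == 0:
        return ZeroCheck(observed, predicted, float("nan"),
                         note="no zeros observed; ratio undefined")
    return ZeroCheck(observed, predicted, predicted / observed)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, per non-constant design column.

    VIF_j = 1 / (1 - R^2_j) from an intercept-included OLS of column j on the
    other columns.  Perfectly collinear columns give +inf with a warning.
    The convention is all VIF < 3 for an acceptable design.
    """
    cols = [c for c in design.columns if c != "const"]
    if len(cols) < 2:
        raise ValueError("VIF needs at least two covariate columns")
    Xall = design[cols].to_numpy(float)
    if np.any(np.std(Xall, axis=0) < 1e-12):
        bad = [c for c in cols if design[c].std() < 1e-12]
        raise ValueError(f"constant column(s) in design: {bad}")
    out = {}
    n = len(design)
    ones = np.ones((n, 1))
    for j, cj in enumerate(cols):
        yj = Xall[:, j]
        Xo = np.hstack([ones, np.delete(Xall, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        if r2 > 1.0 - 1e-10:
            warnings.warn(f"column {cj!r} is perfectly collinear; VIF = inf",
                          stacklevel=2)
            out[cj] = float("inf")
        else:
            out[cj] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def compare_fits(fits: list[CountGLMMResults]) -> pd.DataFrame:
    """Rank candidate fits of the same data by AIC (ascending), with dAIC."""
    if not fits:
        raise ValueError("no fits to compare")
    n0 = fits[0].nobs
    if any(f.nobs != n0 for f in fits):
        raise ValueError("fits compare different data (n_obs mismatch)")
    rows = [
        {"family": f.model.family, "k_params": f.k_params,
         "loglik": f.llf, "aic": f.aic}
        for f in fits
    ]
    out = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    return out


def significance_flags(fit: CountGLMMResults, alpha: float = 0.01) -> pd.Series:
    """Per-coefficient Wald flags at the conservative default alpha = 0.01."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return fit.significant(alpha)


def influence_report(fit: CountGLMMResults, k: int = 10,
                     **fit_kwargs) -> pd.DataFrame:
    """Leave-one-out sensitivity for the k largest-|Pearson-residual| points.

    Each flagged observation is dropped and the model refit; the report gives
    the largest absolute coefficient change per refit.  Observations are
    reported, never auto-removed — removal is an analyst's decision.
    """
    model = fit.model
    resid = np.abs(fit.pearson_resid())
    worst = np.argsort(resid)[::-1][:k]
    rows = []
    for i in worst:
        keep = np.ones(model.nobs, bool)
        keep[i] = False
        groups = {
            g: model.group_levels[f][model.group_codes[f][keep]]
            for f, g in enumerate(model.group_names)
        } or None
        sub = CountGLMM(model.y[keep], model.X[keep], groups=groups,
                        family=model.family, exog_names=model.exog_names)
        refit = sub.fit(compute_se=False, **fit_kwargs)
        delta = (refit.beta - fit.beta).abs()
        rows.append({
            "obs": int(i),
            "pearson_resid": float(resid[i]),
            "max_abs_coef_change": float(delta.max()),
            "most_changed_term": str(delta.idxmax()),
        })
    return pd.DataFrame(rows)
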