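"""Scientific-vs-societal imbalance scores and the residual trait model.

Species that attract much more public attention than research effort (or the
reverse) are identified by smoothing societal interest against scientific
interest and taking residuals:

1. transform both counts, x = log10(1 + papers), y = log10(1 + pageviews);
2. fit a Gaussian penalized cubic B-spline (P-spline: second-difference
   penalty, smoothing parameter chosen by GCV on a log grid) of y on x;
3. the imbalance score of a species is its residual y - fitted:
   positive = more societal than scientific interest.

The scores are then regressed on the same trait design as the count models
with a Gaussian identity-link mixed model (REML; nested taxonomic + crossed
realm random intercepts), exposed with the same reporting surface as the
count fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from .glmm import nested_group_labels
from .traits_geo import prepare_design

__all__ = [
    "PSplineResults",
    "fit_pspline",
    "ImbalanceResult",
    "imbalance_scores",
    "ResidualLMMResults",
    "fit_residual_lmm",
]


# ---------------------------------------------------------------------------
# penalized spline smoother
# ---------------------------------------------------------------------------

DEFAULT_LAMBDA_GRID = np.logspace(-6, 6, 61)


def _bspline_basis(x: np.ndarray, xmin: float, xmax: float, nb: int) -> np.ndarray:
    # cubic basis on equally spaced (unclamped) knots extending past the data
    # range, so the second-difference penalty null space is exactly the
    # straight lines; len(t) = nb + 4
    nseg = nb - 3
    dx = (xmax - xmin) / nseg
    t = xmin + dx * np.arange(-3, nseg + 4)
    return BSpline.design_matrix(np.clip(x, xmin, xmax), t, 3).toarray()


@dataclass
class PSplineResults:
    """A fitted P-spline: coefficients, smoothing parameter, fit summaries."""

    coef: np.ndarray
    lam: float
    edf: float
    gcv: float
    fitted: np.ndarray
    basis_size: int
    xmin: float
    xmax: float
    gcv_path: pd.DataFrame = field(repr=False, default=None)

    def predict(self, xnew) -> np.ndarray:
        B = _bspline_basis(np.asarray(xnew, float), self.xmin, self.xmax,
                           self.basis_size)
        return B @ self.coef

    def to_dict(self) -> dict:
        return {
            "lambda": float(self.lam),
            "edf": float(self.edf),
            "gcv": float(self.gcv),
            "basis_size": int(self.basis_size),
            "x_range": [float(self.xmin), float(self.xmax)],
        }


def fit_pspline(x, y, basis_size: int = 10, lambda_grid=None) -> PSplineResults:
    """Gaussian penalized-spline smooth of y on x.

    Cubic B-spline basis (``basis_size`` functions, uniform knots over the
    data range) with a second-difference coefficient penalty; the penalty
    null space is exactly the straight lines, so lambda -> inf recovers the
    OLS line.  lambda is selected by generalized cross-validation,
    GCV(lambda) = n RSS / (n - edf)^2, over a 61-point log grid spanning
    1e-6..1e6 by default.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) <= basis_size:
        raise ValueError(f"need n > basis_size ({basis_size}), got n={len(x)}")
    xmin, xmax = float(x.min()), float(x.max())
    if xmax - xmin < 1e-12:
        raise ValueError("degenerate x: all values (nearly) equal")
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID

    B = _bspline_basis(x, xmin, xmax, basis_size)
    D = np.diff(np.eye(basis_size), n=2, axis=0)
    P = D.T @ D
    BtB = B.T @ B
    Bty = B.T @ y
    n = len(x)

    best = None
    path = []
    for lam in np.asarray(lambda_grid, float):
        A = BtB + lam * P
        coef = np.linalg.solve(A, Bty)
        fitted = B @ coef
        rss = float(np.sum((y - fitted) ** 2))
        edf = float(np.trace(np.linalg.solve(A, BtB)))
        gcv = n * rss / (n - edf) ** 2
        path.append({"lambda": lam, "edf": edf, "gcv": gcv})
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef, fitted, edf)
    gcv, lam, coef, fitted, edf = best
    return PSplineResults(
        coef=coef, lam=float(lam), edf=edf, gcv=float(gcv), fitted=fitted,
        basis_size=basis_size, xmin=xmin, xmax=xmax,
        gcv_path=pd.DataFrame(path),
    )


# ---------------------------------------------------------------------------
# imbalance scores
# ---------------------------------------------------------------------------

MIN_SPECIES_FOR_SMOOTH = 30


@dataclass
class ImbalanceResult:
    """Per-species imbalance residuals plus the smoother they come from."""

    scores: pd.DataFrame  # columns: species_id, residual
    smoother: PSplineResults
    transform: str = "log10p1"

    def top(self, k: int = 10) -> pd.DataFrame:
        out = self.scores.reindex(
            self.scores["residual"].abs().sort_values(ascending=False).index
        )
        return out.head(k).reset_index(drop=True)


def imbalance_scores(profiles: pd.DataFrame, basis_size: int = 10,
                     log_base: float = 10.0) -> ImbalanceResult:
    """Residual of societal interest given scientific interest, per species.

    Both axes are log(1 + count) transformed (base 10 by default, natural
    log via ``log_base=np.e``) before the P-spline smooth; the residual is
    taken on that transformed scale.  Positive residual = societal excess.
    """
    for col in ("species_id", "n_papers", "n_views"):
        if col not in profiles.columns:
            raise ValueError(f"profiles missing column {col!r}")
    if len(profiles) < MIN_SPECIES_FOR_SMOOTH:
        raise ValueError("insufficient data for smooth: need >= "
                         f"{MIN_SPECIES_FOR_SMOOTH} species, got {len(profiles)}")
    x = np.log1p(profiles["n_papers"].to_numpy(float)) / np.log(log_base)
    y = np.log1p(profiles["n_views"].to_numpy(float)) / np.log(log_base)
    sm_fit = fit_pspline(x, y, basis_size=basis_size)
    scores = pd.DataFrame({
        "species_id": profiles["species_id"].to_numpy(),
        "residual": y - sm_fit.fitted,
    })
    return ImbalanceResult(scores=scores, smoother=sm_fit)


# ---------------------------------------------------------------------------
# Gaussian residual mixed model
# ---------------------------------------------------------------------------

class _GaussianShim:
    """Minimal model-attribute surface shared with the count fits."""

    family = "gaussian"

    def __init__(self, y, X, exog_names):
        self.y = y
        self.X = X
        self.exog_names = exog_names


class ResidualLMMResults:
    """Gaussian mixed-model fit of imbalance scores on traits (REML).

    Thin adapter over a statsmodels MixedLM result giving the same
    reporting surface (beta/bse/conf_int/significant/sigma2/aic/summary/
    forest frame) as :class:`biointerest.glmm.CountGLMMResults`.
    """

    def __init__(self, sm_results, exog_names, vc_names, y, X):
        self._res = sm_results
        self.model = _GaussianShim(y, X, exog_names)
        self.beta = pd.Series(np.asarray(sm_results.fe_params, float),
                              index=exog_names, name="estimate")
        self.bse = pd.Series(
            np.asarray(sm_results.bse_fe, float), index=exog_names)
        self.sigma2 = {
            name: float(v) for name, v in zip(vc_names, np.asarray(sm_results.vcomp))
        }
        self.resid_var = float(sm_results.scale)
        self.llf = float(sm_results.llf)
        self.nobs = int(sm_results.nobs)
        self.k_params = len(exog_names) + len(vc_names) + 1  # + residual var
        self.aic = 2.0 * self.k_params - 2.0 * self.llf
        self.converged = bool(getattr(sm_results, "converged", True))
        self.df_resid = self.nobs - len(exog_names)
        self.theta = None
        self.zi_prob = None

    @property
    def fixed_linear_predictor(self) -> np.ndarray:
        return self.model.X @ self.beta.to_numpy()

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({"lower": self.beta - z * self.bse,
                             "upper": self.beta + z * self.bse})

    @property
    def zvalues(self) -> pd.Series:
        return self.beta / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.beta.index)

    def significant(self, alpha: float = 0.01) -> pd.Series:
        return self.pvalues < alpha

    def to_forest_frame(self, alpha_ci: float = 0.05,
                        alpha_sig: float = 0.01) -> pd.DataFrame:
        ci = self.conf_int(alpha_ci)
        return pd.DataFrame({
            "term": self.beta.index,
            "estimate": self.beta.to_numpy(),
            "lo95": ci["lower"].to_numpy(),
            "hi95": ci["upper"].to_numpy(),
            "significant": self.significant(alpha_sig).to_numpy(),
        })

    def summary(self) -> str:
        lines = [
            "Gaussian residual mixed model (REML, identity link)",
            f"  n_obs: {self.nobs}   loglik: {self.llf:.1f}   AIC: {self.aic:.1f}"
            f"   converged: {self.converged}",
            f"  residual variance: {self.resid_var:.4f}",
        ]
        for g, s2 in self.sigma2.items():
            lines.append(f"  random intercept var ({g}): {s2:.4f}")
        for t in self.beta.index:
            lines.append(f"  {t:<22}{self.beta[t]:>10.4f}{self.bse[t]:>10.4f}")
        return "\n".join(lines)


def fit_residual_lmm(
    scores: pd.DataFrame,
    profiles: pd.DataFrame,
    variant: str = "eq1",
    design: pd.DataFrame | None = None,
) -> ResidualLMMResults:
    """REML Gaussian mixed model of imbalance residuals on the trait design.

    Uses the same fixed-effect design and nested taxonomic + crossed realm
    random intercepts as the count models; for the Gaussian case REML is
    exact (no Laplace error).  Random intercepts whose variance estimate is
    driven to ~0 are simply reported at ~0.
    """
    import warnings

    from statsmodels.regression.mixed_linear_model import MixedLM

    merged = profiles.merge(scores, on="species_id", how="inner")
    if len(merged) != len(scores):
        raise ValueError("scores and profiles do not match one-to-one")
    if design is None:
        design, _ = prepare_design(merged, variant)
    groups = nested_group_labels(merged, variant)

    data = design.drop(columns=["const"]).copy()
    fixed_cols = list(data.columns)
    data["resid_score"] = merged["residual"].to_numpy(float)
    data["_one"] = 1
    vc_formula = {}
    vc_names = []
    for i, (name, labels) in enumerate(groups.items()):
        col = f"vc{i}"
        data[col] = labels
        vc_formula[col] = f"0 + C({col})"
        vc_names.append(name)
    md = MixedLM.from_formula(
        "resid_score ~ " + " + ".join(fixed_cols),
        groups="_one", vc_formula=vc_formula, re_formula="0", data=data,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = md.fit(reml=True, method=["lbfgs"])
    exog_names = ["const"] + fixed_cols  # patsy puts the intercept first
    # statsmodels orders vc alphabetically by the formula key (vc0, vc1, ...)
    ordered = sorted(range(len(vc_names)), key=lambda i: f"vc{i}")
    vc_ordered = [vc_names[i] for i in ordered]
    X = design.to_numpy(float)
    y = data["resid_score"].to_numpy(float)
    return ResidualLMMResults(res, exog_names, vc_ordered, y, X)
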