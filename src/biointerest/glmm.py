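"""Count mixed models with nested + crossed random intercepts (Laplace ML).

The interest models regress a per-species count (papers indexed for the
species' scientific name, or total Wikipedia pageviews) on standardized
traits with a log link, Gaussian random intercepts for taxonomic relatedness
(nested Phylum / Phylum:Class / Phylum:Class:Order) and geographic provenance
(crossed biogeographic realm), and one of three conditional families:

* ``poisson`` — variance mu;
* ``nb2`` — negative binomial, variance mu + mu^2/theta;
* ``zinb2`` — zero-inflated NB2 with an intercept-only mixing probability pi:
  P(y=0) = pi + (1-pi) NB2(0 | mu, theta).

The marginal likelihood integrates the random intercepts out with a Laplace
approximation: for each candidate (beta, theta, pi, sigma_g) the joint
log-density is maximised over the stacked intercepts b by damped Newton
iterations, and

    log L ~= l(y | b_hat) - b_hat' D^-1 b_hat / 2 - [logdet H + logdet D] / 2

with D = blockdiag(sigma_g^2 I) and H the negative Hessian of the penalised
log-likelihood at b_hat.  With no random terms this reduces exactly to the
fixed-effects likelihood.  The outer maximisation runs L-BFGS-B on
(beta, log theta, logit pi, log sigma_g); standard errors come from the
numerical Hessian of the Laplace log-likelihood at the optimum (Wald).

:class:`CountGLMM` is the model object; :meth:`CountGLMM.fit` returns a
:class:`CountGLMMResults` carrying estimates, standard errors, confidence
intervals, dispersion/zero-inflation parameters, random-intercept variances,
log-likelihood and AIC, with ``summary()`` / forest-frame / plotting helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .traits_geo import prepare_design

__all__ = ["CountGLMM", "CountGLMMResults", "FAMILIES", "nested_group_labels"]

FAMILIES = ("poisson", "nb2", "zinb2")

_SIGMA_LOG_FLOOR = -5.0  # below exp(-5) a variance is reported as pinned at ~0


# ---------------------------------------------------------------------------
# conditional families: per-observation loglik and eta-derivatives
# ---------------------------------------------------------------------------

_ETA_MAX = 300.0  # keeps exp(eta) finite in doubles; never binds in practice


def _poisson_terms(y, eta):
    eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
    mu = np.exp(eta)
    ll = y * eta - mu - special.gammaln(y + 1.0)
    return ll, y - mu, -mu


def _nb2_terms(y, eta, theta):
    eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
    mu = np.exp(eta)
    denom = theta + mu
    ll = (
        special.gammaln(y + theta) - special.gammaln(theta) - special.gammaln(y + 1.0)
        + theta * (np.log(theta) - np.log(denom))
        + y * (eta - np.log(denom))
    )
    dl = y - (y + theta) * mu / denom
    d2l = -(y + theta) * theta * mu / denom**2
    return ll, dl, d2l


def _zinb2_terms(y, eta, theta, pi):
    eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
    mu = np.exp(eta)
    denom = theta + mu
    ll_nb, dl_nb, d2l_nb = _nb2_terms(y, eta, theta)
    is0 = y == 0
    # zeros: l = log(pi + (1-pi) p0), p0 = (theta/(theta+mu))^theta
    logp0 = theta * (np.log(theta) - np.log(denom))
    p0 = np.exp(logp0)
    f0 = pi + (1.0 - pi) * p0
    a = theta * mu / denom                    # -d log p0 / d eta
    da = theta**2 * mu / denom**2
    g = (1.0 - pi) * p0 / f0
    ll = np.where(is0, np.log(f0), ll_nb + np.log1p(-pi))
    dl = np.where(is0, -g * a, dl_nb)
    d2l = np.where(is0, g * a**2 * pi / f0 - g * da, d2l_nb)
    return ll, dl, d2l


def _zero_prob(family, eta, theta=None, pi=None):
    """P(y=0) per observation under the fitted family."""
    mu = np.exp(eta)
    if family == "poisson":
        return np.exp(-mu)
    p0 = np.exp(theta * (np.log(theta) - np.log(theta + mu)))
    if family == "nb2":
        return p0
    return pi + (1.0 - pi) * p0


def _mean_var(family, eta, theta=None, pi=None):
    """Marginal mean and variance of y per observation (for Pearson residuals)."""
    mu = np.exp(eta)
    if family == "poisson":
        return mu, mu
    if family == "nb2":
        return mu, mu + mu**2 / theta
    m = (1.0 - pi) * mu
    v = (1.0 - pi) * mu * (1.0 + mu / theta + pi * mu)
    return m, v


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def nested_group_labels(df: pd.DataFrame, variant: str = "eq1",
                        region_col: str = "region") -> dict[str, np.ndarray]:
    """Random-intercept grouping labels for the interest models.

    ``eq1`` expands the nested taxonomic intercept (1 | Phylum/Class/Order)
    into three composite-key factors plus the crossed realm factor; ``eq2``
    (within-phylum models) starts the nesting at class.
    """
    phyl = df["phylum"].astype(str)
    cls = df["class_"].astype(str)
    order = df["order"].astype(str)
    if variant == "eq1":
        labels = {
            "phylum": phyl,
            "phylum:class": phyl + "/" + cls,
            "phylum:class:order": phyl + "/" + cls + "/" + order,
        }
    else:
        labels = {"class": cls, "class:order": cls + "/" + order}
    labels["region"] = df[region_col].astype(str)
    return {k: np.asarray(v) for k, v in labels.items()}


class CountGLMM:
    """Count regression with log link and Gaussian random intercepts.

    Parameters
    ----------
    y : array of counts
    X : DataFrame or array, fixed-effects design (include a ``const`` column)
    groups : mapping factor name -> per-observation labels, or None
        Each factor contributes an independent random intercept per level;
        nested structures are expressed by composite keys
        (see :func:`nested_group_labels`).
    family : "poisson" | "nb2" | "zinb2"
    """

    def __init__(self, y, X, groups=None, family="nb2", exog_names=None):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        self.family = family
        self.y = np.asarray(y, dtype=float)
        if np.any(self.y < 0) or np.any(self.y != np.floor(self.y)):
            raise ValueError("y must be nonnegative integer counts")
        if isinstance(X, pd.DataFrame):
            self.exog_names = list(X.columns)
            self.X = X.to_numpy(float)
        else:
            self.X = np.asarray(X, dtype=float)
            self.exog_names = list(exog_names) if exog_names is not None else [
                f"x{j}" for j in range(self.X.shape[1])
            ]
        if self.X.shape[0] != len(self.y):
            raise ValueError("X rows must match y length")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("missing values in y or X")
        self.nobs = len(self.y)

        self.group_names: list[str] = []
        self.group_codes: list[np.ndarray] = []
        self.group_levels: list[np.ndarray] = []
        if groups:
            for name, labels in groups.items():
                codes, levels = pd.factorize(np.asarray(labels), sort=True)
                if len(labels) != self.nobs:
                    raise ValueError(f"group {name!r} length mismatch")
                self.group_names.append(name)
                self.group_codes.append(codes.astype(np.int64))
                self.group_levels.append(levels)
        self._sizes = [len(lv) for lv in self.group_levels]
        self._offsets = np.concatenate([[0], np.cumsum(self._sizes)]).astype(int)
        self.q = int(self._offsets[-1])
        self._b_cache = np.zeros(self.q)

    # -- parameter packing ---------------------------------------------------

    @property
    def k_extra(self) -> int:
        return {"poisson": 0, "nb2": 1, "zinb2": 2}[self.family]

    @property
    def k_params(self) -> int:
        """All estimated parameters: beta, theta, pi, random variances."""
        return len(self.exog_names) + self.k_extra + len(self.group_names)

    @property
    def param_names(self) -> list[str]:
        names = list(self.exog_names)
        if self.family in ("nb2", "zinb2"):
            names.append("log_theta")
        if self.family == "zinb2":
            names.append("logit_pi")
        names += [f"log_sigma[{g}]" for g in self.group_names]
        return names

    def _unpack(self, params):
        p = len(self.exog_names)
        beta = params[:p]
        i = p
        theta = pi = None
        if self.family in ("nb2", "zinb2"):
            theta = np.exp(params[i]); i += 1
        if self.family == "zinb2":
            pi = special.expit(params[i]); i += 1
        sig2 = np.exp(2.0 * params[i:])
        return beta, theta, pi, sig2

    def _terms(self, eta, theta, pi):
        # extreme eta during line search may overflow; the search backtracks
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            if self.family == "poisson":
                return _poisson_terms(self.y, eta)
            if self.family == "nb2":
                return _nb2_terms(self.y, eta, theta)
            return _zinb2_terms(self.y, eta, theta, pi)

    # -- Laplace machinery ---------------------------------------------------

    def _eta(self, beta, b):
        eta = self.X @ beta
        for f, codes in enumerate(self.group_codes):
            eta = eta + b[self._offsets[f]:self._offsets[f + 1]][codes]
        return eta

    def _inner_mode(self, beta, theta, pi, sig2, tol=1e-8, maxiter=60):
        """Maximise the penalised loglik over stacked intercepts b (Newton).

        Damped Newton with backtracking; the gradient tolerance is relative
        to the objective magnitude (an absolute tolerance is unattainable in
        double precision when counts are large).
        """
        dinv = np.concatenate(
            [np.full(m, 1.0 / s2) for m, s2 in zip(self._sizes, sig2)]
        ) if self.q else np.zeros(0)
        b = self._b_cache.copy()

        def penalised(bvec):
            ll = self._terms(self._eta(beta, bvec), theta, pi)[0].sum()
            return ll - 0.5 * np.sum(bvec**2 * dinv)

        pen = penalised(b)
        if not np.isfinite(pen):
            b = np.zeros(self.q)
            pen = penalised(b)
        scale = 1.0 + abs(pen)
        W = None
        for _ in range(maxiter):
            eta = self._eta(beta, b)
            _, dl, d2l = self._terms(eta, theta, pi)
            grad = np.empty(self.q)
            for f, codes in enumerate(self.group_codes):
                sl = slice(self._offsets[f], self._offsets[f + 1])
                grad[sl] = np.bincount(codes, weights=dl, minlength=self._sizes[f])
            grad -= dinv * b
            if np.max(np.abs(grad), initial=0.0) < tol * scale:
                W = -d2l
                break
            H = self._zwz(-d2l)
            H[np.diag_indices(self.q)] += dinv
            step = self._solve_pd(H, grad)
            slope = float(grad @ step)
            t = 1.0
            improved = False
            for _ in range(25):
                cand = b + t * step
                pen_c = penalised(cand)
                # Armijo-style ascent test, with arithmetic-noise allowance
                if np.isfinite(pen_c) and pen_c >= pen + 1e-4 * t * slope - 1e-13 * scale:
                    improved = pen_c > pen + 1e-12 * scale
                    b, pen = cand, pen_c
                    break
                t *= 0.5
            if not improved:  # converged as far as arithmetic allows
                _, _, d2l = self._terms(self._eta(beta, b), theta, pi)
                W = -d2l
                break
        if W is None:
            _, _, d2l = self._terms(self._eta(beta, b), theta, pi)
            W = -d2l
        self._b_cache = b.copy()
        return b, pen, W, dinv

    def _zwz(self, w):
        """Z' diag(w) Z over all random factors (q x q, dense; q is small)."""
        H = np.zeros((self.q, self.q))
        for fa in range(len(self.group_codes)):
            ca = self.group_codes[fa]
            oa, ma = self._offsets[fa], self._sizes[fa]
            for fb in range(fa, len(self.group_codes)):
                cb = self.group_codes[fb]
                ob, mb = self._offsets[fb], self._sizes[fb]
                block = np.zeros((ma, mb))
                np.add.at(block, (ca, cb), w)
                H[oa:oa + ma, ob:ob + mb] += block
                if fb != fa:
                    H[ob:ob + mb, oa:oa + ma] += block.T
        return H

    @staticmethod
    def _solve_pd(H, g):
        """Solve H x = g, ridging H up if it is not positive definite."""
        tau = 0.0
        eye = np.eye(H.shape[0])
        for _ in range(30):
            try:
                L = np.linalg.cholesky(H + tau * eye)
                x = np.linalg.solve(L, g)
                return np.linalg.solve(L.T, x)
            except np.linalg.LinAlgError:
                tau = max(2.0 * tau, 1e-6 * (1.0 + np.abs(np.diag(H)).max()))
        return np.linalg.lstsq(H, g, rcond=None)[0]

    def loglike(self, params) -> float:
        """Laplace-approximate marginal log-likelihood at packed ``params``.

        Packing: beta, then log(theta) (nb2/zinb2), logit(pi) (zinb2), then
        one log(sigma) per random factor.  With no random factors this is the
        exact fixed-effects log-likelihood.
        """
        params = np.asarray(params, dtype=float)
        beta, theta, pi, sig2 = self._unpack(params)
        if self.q == 0:
            ll = self._terms(self.X @ beta, theta, pi)[0].sum()
            return float(ll)
        b, pen, W, dinv = self._inner_mode(beta, theta, pi, sig2)
        if not (np.isfinite(pen) and np.all(np.isfinite(W))):
            return -np.inf
        H = self._zwz(W)
        H[np.diag_indices(self.q)] += dinv
        # diagonal scaling keeps the determinant computable when the trial
        # parameters give H a huge dynamic range
        d = np.sqrt(np.abs(np.diag(H)))
        d[d == 0] = 1.0
        Hs = H / d[:, None] / d[None, :]
        sign, logdet_s = np.linalg.slogdet(Hs)
        if sign <= 0:  # saddle-ish mode; fall back to a ridged determinant
            logdet_s = np.linalg.slogdet(Hs + 1e-8 * np.eye(self.q))[1]
        logdet_h = logdet_s + 2.0 * float(np.sum(np.log(d)))
        logdet_d = float(np.sum([m * np.log(s2) for m, s2 in zip(self._sizes, sig2)]))
        return float(pen - 0.5 * (logdet_h + logdet_d))

    # -- fitting -------------------------------------------------------------

    def _start_params(self):
        import statsmodels.api as sm

        p = len(self.exog_names)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                glm = sm.GLM(self.y, self.X, family=sm.families.Poisson()).fit()
            beta0 = np.asarray(glm.params, dtype=float)
            mu = np.asarray(glm.fittedvalues, dtype=float)
        except Exception:
            beta0 = np.zeros(p)
            if "const" in self.exog_names:
                beta0[self.exog_names.index("const")] = np.log(self.y.mean() + 0.5)
            mu = np.full(self.nobs, self.y.mean() + 0.5)
        x0 = list(beta0)
        if self.family in ("nb2", "zinb2"):
            # method-of-moments dispersion from the Poisson fit
            alpha = np.mean(((self.y - mu) ** 2 - mu) / mu**2)
            theta0 = 1.0 / alpha if alpha > 1e-3 else 100.0
            x0.append(np.log(np.clip(theta0, 0.05, 100.0)))
        if self.family == "zinb2":
            p0 = np.mean(_zero_prob("nb2", np.log(mu), theta=np.exp(x0[-1])))
            excess = np.mean(self.y == 0) - p0
            x0.append(special.logit(np.clip(excess, 0.02, 0.6)))
        x0 += [np.log(np.sqrt(0.1))] * len(self.group_names)
        return np.array(x0)

    def _bounds(self):
        p = len(self.exog_names)
        bounds: list[tuple] = [(-30.0, 30.0)] * p
        if self.family in ("nb2", "zinb2"):
            bounds.append((-7.0, 12.0))       # log theta
        if self.family == "zinb2":
            bounds.append((-15.0, 8.0))       # logit pi
        # sigma capped at e^1.5 ~ 4.5 (variance ~20): far above any plausible
        # intercept spread on the log scale, but small enough to keep the
        # joint mode finite when a quasi-Poisson fit tries to absorb
        # overdispersion into the intercepts
        bounds += [(_SIGMA_LOG_FLOOR, 1.5)] * len(self.group_names)
        return bounds

    def fit(self, start_params=None, maxiter=300, gtol=1e-6,
            compute_se=True) -> "CountGLMMResults":
        """Maximise the (Laplace) marginal likelihood; Wald inference."""
        x0 = np.asarray(start_params, float) if start_params is not None \
            else self._start_params()
        self._b_cache = np.zeros(self.q)

        def neg(params):
            val = self.loglike(params)
            # large finite penalty keeps finite-difference gradients usable
            return 1e10 if not np.isfinite(val) else -val

        opt = optimize.minimize(
            neg, x0, method="L-BFGS-B", bounds=self._bounds(),
            options={"maxiter": maxiter, "maxfun": 10 * maxiter * max(len(x0), 1),
                     "ftol": 1e-11, "gtol": gtol, "eps": 1e-6},
        )
        params = opt.x
        # re-evaluate at the returned point: opt.fun can be a stale trial
        # value when the final line search failed
        self._b_cache = np.zeros(self.q)
        llf = self.loglike(params)
        cov = None
        if compute_se:
            cov = _num_cov(neg, params)
        beta, theta, pi, sig2 = self._unpack(params)
        pinned = [g for g, s2 in zip(self.group_names, sig2)
                  if np.log(s2) / 2.0 <= _SIGMA_LOG_FLOOR + 1e-6]
        if pinned:
            warnings.warn(
                f"random-effect variance(s) pinned at ~0: {pinned}", stacklevel=2
            )
        return CountGLMMResults(self, params, llf, bool(opt.success), cov,
                                message=str(opt.message))


def _num_cov(negloglike, params, h0=5e-4):
    """Covariance = inverse numerical Hessian (central differences)."""
    k = len(params)
    h = h0 * (1.0 + np.abs(params))
    H = np.zeros((k, k))
    f0 = negloglike(params)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        fpp = negloglike(params + ei)
        fmm = negloglike(params - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                negloglike(params + ei + ej) - negloglike(params + ei - ej)
                - negloglike(params - ei + ej) + negloglike(params - ei - ej)
            ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    d = np.diag(cov).copy()
    if np.any(d <= 0):  # boundary parameters can produce non-PD curvature
        cov[np.diag_indices(k)] = np.where(d <= 0, np.nan, d)
    return cov


class CountGLMMResults:
    """Fitted count mixed model: estimates, uncertainty, diagnostics hooks."""

    def __init__(self, model, params, llf, converged, cov=None, message=""):
        self.model = model
        self._params = np.asarray(params, float)
        self.llf = float(llf)
        self.converged = converged
        self.message = message
        self._cov = cov
        beta, theta, pi, sig2 = model._unpack(self._params)
        self.beta = pd.Series(beta, index=model.exog_names, name="estimate")
        self.theta = None if theta is None else float(theta)
        self.zi_prob = None if pi is None else float(pi)
        self.sigma2 = {g: float(s2) for g, s2 in zip(model.group_names, sig2)}
        self.nobs = model.nobs
        self.k_params = model.k_params
        self.aic = 2.0 * self.k_params - 2.0 * self.llf
        self.df_resid = self.nobs - len(model.exog_names)
        if model.q:
            bhat = model._inner_mode(beta, theta, pi, sig2)[0]
            self.random_effects = {
                g: pd.Series(
                    bhat[model._offsets[f]:model._offsets[f + 1]],
                    index=model.group_levels[f],
                )
                for f, g in enumerate(model.group_names)
            }
            self._eta_hat = model._eta(beta, bhat)
        else:
            self.random_effects = {}
            self._eta_hat = model.X @ beta
        self._eta_fixed = model.X @ beta

    # -- inference -----------------------------------------------------------

    @property
    def params(self) -> pd.Series:
        """All packed parameters (beta, log theta, logit pi, log sigmas)."""
        return pd.Series(self._params, index=self.model.param_names)

    @property
    def bse(self) -> pd.Series:
        p = len(self.beta)
        if self._cov is None:
            return pd.Series(np.nan, index=self.beta.index)
        return pd.Series(np.sqrt(np.diag(self._cov)[:p]), index=self.beta.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        se = self.bse
        return pd.DataFrame(
            {"lower": self.beta - z * se, "upper": self.beta + z * se}
        )

    @property
    def zvalues(self) -> pd.Series:
        return self.beta / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues)), index=self.beta.index
        )

    def significant(self, alpha: float = 0.01) -> pd.Series:
        """Wald significance flags at the (conservative) default alpha=0.01."""
        return self.pvalues < alpha

    # -- fitted quantities ---------------------------------------------------

    @property
    def fittedvalues(self) -> np.ndarray:
        """Conditional mean mu (or (1-pi)mu for zinb2) with plug-in intercepts."""
        m, _ = _mean_var(self.model.family, self._eta_hat, self.theta, self.zi_prob)
        return m

    def predict_zero_prob(self) -> np.ndarray:
        return _zero_prob(self.model.family, self._eta_hat, self.theta, self.zi_prob)

    def pearson_resid(self) -> np.ndarray:
        m, v = _mean_var(self.model.family, self._eta_hat, self.theta, self.zi_prob)
        return (self.model.y - m) / np.sqrt(v)

    @property
    def fixed_linear_predictor(self) -> np.ndarray:
        return self._eta_fixed

    # -- reporting -----------------------------------------------------------

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
            f"Count mixed model ({self.model.family}), log link",
            f"  n_obs: {self.nobs}   loglik: {self.llf:.1f}   AIC: {self.aic:.1f}"
            f"   converged: {self.converged}",
        ]
        if self.theta is not None:
            lines.append(f"  dispersion theta: {self.theta:.4f}")
        if self.zi_prob is not None:
            lines.append(f"  zero-inflation pi: {self.zi_prob:.4f}")
        for g, s2 in self.sigma2.items():
            lines.append(f"  random intercept var ({g}): {s2:.4f}")
        lines.append(f"  {'term':<22}{'coef':>10}{'se':>10}{'z':>8}{'p':>10}")
        se, z, p = self.bse, self.zvalues, self.pvalues
        for t in self.beta.index:
            lines.append(
                f"  {t:<22}{self.beta[t]:>10.4f}{se[t]:>10.4f}"
                f"{z[t]:>8.2f}{p[t]:>10.3g}"
            )
        return "\n".join(lines)

    def plot_forest(self, ax=None):
        """Forest plot of coefficients with 95% Wald intervals."""
        import matplotlib.pyplot as plt

        frame = self.to_forest_frame()
        frame = frame[frame["term"] != "const"]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * len(frame) + 1))
        ypos = np.arange(len(frame))[::-1]
        ax.errorbar(
            frame["estimate"], ypos,
            xerr=[frame["estimate"] - frame["lo95"], frame["hi95"] - frame["estimate"]],
            fmt="o", color="k", ecolor="gray", capsize=2,
        )
        ax.axvline(0.0, color="r", lw=0.8, ls="--")
        ax.set_yticks(ypos)
        ax.set_yticklabels(frame["term"])
        ax.set_xlabel("coefficient (log scale)")
        return ax

    def to_dict(self) -> dict:
        """JSON-serialisable record of the fit."""
        ci = self.conf_int()
        return {
            "family": self.model.family,
            "n_obs": int(self.nobs),
            "loglik": self.llf,
            "aic": self.aic,
            "converged": self.converged,
            "theta": self.theta,
            "zi_prob": self.zi_prob,
            "sigma2": self.sigma2,
            "coefficients": {
                t: {
                    "estimate": float(self.beta[t]),
                    "se": float(self.bse[t]),
                    "lo95": float(ci.loc[t, "lower"]),
                    "hi95": float(ci.loc[t, "upper"]),
                }
                for t in self.beta.index
            },
        }


def from_profiles(profiles: pd.DataFrame, response: str = "n_papers",
                  variant: str = "eq1", family: str = "nb2",
                  design=None, transform=None):
    """Build a :class:`CountGLMM` for a species-profile table.

    Convenience constructor: builds the standardized design for the requested
    formula variant and the nested+crossed grouping labels, then assembles
    the model.  Returns ``(model, design, transform)``.
    """
    if design is None:
        design, transform = prepare_design(profiles, variant, transform)
    groups = nested_group_labels(profiles, variant)
    model = CountGLMM(profiles[response].to_numpy(), design, groups=groups,
                      family=family)
    return model, design, transform
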