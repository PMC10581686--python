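"""Count-model fitting, likelihood correctness and validation diagnostics."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import special

import biointerest as bi
from biointerest.count_models import (CountModelSpec, compare_fits,
                                      fit_count_model, overdispersion_check,
                                      significance_flags, vif, zero_check)
from biointerest.glmm import CountGLMM, from_profiles


def _sim_design(rng, n, p=3):
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p)])
    names = ["const"] + [f"x{j}" for j in range(1, p + 1)]
    return pd.DataFrame(X, columns=names)


def _nb_draw(rng, mu, theta):
    return rng.negative_binomial(theta, theta / (theta + mu))


# ---------------------------------------------------------------------------
# likelihood / fitting correctness against independent oracles
# ---------------------------------------------------------------------------

class TestFixedEffectsOracles:
    def test_poisson_fit_matches_hand_irls(self):
        """A 10-row Poisson regression against a from-scratch IRLS solver."""
        X = np.column_stack([np.ones(10), np.arange(10) / 5.0])
        y = np.array([1, 0, 2, 1, 3, 2, 4, 6, 5, 9], dtype=float)
        # independent IRLS (textbook scoring iterations)
        beta = np.zeros(2)
        for _ in range(50):
            eta = X @ beta
            mu = np.exp(eta)
            z = eta + (y - mu) / mu
            W = mu
            beta_new = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
            if np.max(np.abs(beta_new - beta)) < 1e-12:
                beta = beta_new
                break
            beta = beta_new
        res = CountGLMM(y, X, family="poisson", exog_names=["const", "x"]).fit()
        assert np.allclose(res.beta.to_numpy(), beta, atol=1e-6)

    def test_nb2_fit_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        design = _sim_design(rng, 600)
        beta = np.array([1.0, 0.5, -0.3, 0.2])
        y = _nb_draw(rng, np.exp(design.to_numpy() @ beta), theta=0.8)
        ours = CountGLMM(y, design, family="nb2").fit()
        ref = sm.NegativeBinomial(y, design).fit(disp=0, maxiter=200)
        ref_params = np.asarray(ref.params)
        assert np.allclose(ours.beta.to_numpy(), ref_params[:-1], atol=1e-3)
        assert ours.theta == pytest.approx(1.0 / ref_params[-1], rel=1e-3)
        assert ours.llf == pytest.approx(ref.llf, abs=1e-4)

    def test_nb2_loglik_approaches_poisson_as_theta_grows(self, rng):
        design = _sim_design(rng, 200)
        y = rng.poisson(np.exp(design.to_numpy() @ np.array([1.0, 0.3, 0.1, -0.2])))
        beta = np.array([1.0, 0.3, 0.1, -0.2])
        pois = CountGLMM(y, design, family="poisson")
        nb = CountGLMM(y, design, family="nb2")
        ll_p = pois.loglike(beta)
        ll_nb = nb.loglike(np.r_[beta, np.log(1e6)])
        assert abs(ll_p - ll_nb) / len(y) < 1e-3

    def test_zinb2_with_no_inflation_degenerates_to_nb2(self, rng):
        design = _sim_design(rng, 1500)
        beta = np.array([1.2, 0.4, -0.2, 0.3])
        y = _nb_draw(rng, np.exp(design.to_numpy() @ beta), theta=1.0)  # pi = 0
        nb = CountGLMM(y, design, family="nb2").fit(compute_se=False)
        zi = CountGLMM(y, design, family="zinb2").fit(compute_se=False)
        assert zi.zi_prob < 0.03
        assert np.allclose(zi.beta.to_numpy(), nb.beta.to_numpy(), atol=0.02)


class TestLaplaceApproximation:
    def _gh_marginal_ll(self, y, X, codes, beta, sigma, family, theta=None,
                        nodes=60):
        """Independent marginal loglik via Gauss-Hermite quadrature over the
        single random intercept, group by group."""
        xk, wk = np.polynomial.hermite.hermgauss(nodes)
        eta0 = X @ beta
        total = 0.0
        for g in range(codes.max() + 1):
            idx = codes == g
            lls = []
            for b in np.sqrt(2.0) * sigma * xk:
                e = eta0[idx] + b
                mu = np.exp(e)
                if family == "poisson":
                    ll = np.sum(y[idx] * e - mu - special.gammaln(y[idx] + 1))
                else:
                    ll = np.sum(
                        special.gammaln(y[idx] + theta) - special.gammaln(theta)
                        - special.gammaln(y[idx] + 1)
                        + theta * np.log(theta / (theta + mu))
                        + y[idx] * np.log(mu / (theta + mu)))
                lls.append(ll)
            total += special.logsumexp(np.array(lls) + np.log(wk)) \
                - 0.5 * np.log(np.pi)
        return total

    @pytest.mark.parametrize("family", ["poisson", "nb2"])
    def test_laplace_close_to_quadrature(self, family, rng):
        n_groups, per = 8, 12
        codes = np.repeat(np.arange(n_groups), per)
        X = np.column_stack([np.ones(n_groups * per),
                             rng.normal(size=n_groups * per)])
        beta = np.array([1.0, 0.4])
        sigma, theta = 0.6, 1.2
        eta = X @ beta + rng.normal(0, sigma, n_groups)[codes]
        if family == "poisson":
            y = rng.poisson(np.exp(eta))
            params = np.r_[beta, np.log(sigma)]
        else:
            y = _nb_draw(rng, np.exp(eta), theta)
            params = np.r_[beta, np.log(theta), np.log(sigma)]
        m = CountGLMM(y, X, groups={"g": codes}, family=family,
                      exog_names=["const", "x"])
        lap = m.loglike(params)
        exact = self._gh_marginal_ll(y, X, codes, beta, sigma, family,
                                     theta=theta)
        assert lap == pytest.approx(exact, abs=0.1)

    def test_vanishing_variances_recover_fixed_likelihood(self, rng):
        design = _sim_design(rng, 150)
        codes = rng.integers(0, 5, 150)
        beta = np.array([0.8, 0.2, -0.1, 0.1])
        y = rng.poisson(np.exp(design.to_numpy() @ beta))
        fixed = CountGLMM(y, design, family="poisson")
        mixed = CountGLMM(y, design, groups={"g": codes}, family="poisson")
        ll_fixed = fixed.loglike(beta)
        ll_sigma0 = mixed.loglike(np.r_[beta, np.log(1e-8)])
        assert ll_sigma0 == pytest.approx(ll_fixed, abs=1e-6)

    def test_mixed_nb2_matches_glmmtmb(self, tmp_path, small_cfg):
        """Cross-check the full nested+crossed NB2 mixed model against
        glmmTMB (the field-standard TMB Laplace implementation) on one
        synthetic dataset."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        cfg = small_cfg.replace(seed=9, n_phyla=4, classes_per_phylum=2,
                                orders_per_class=2)
        prof, _ = bi.gen_profiles(bi.gen_species_frame(cfg, 400), cfg)
        model, design, _ = from_profiles(prof, "n_papers", "eq1", "nb2")
        ours = model.fit(compute_se=False)

        df = design.drop(columns=["const"]).copy()
        df["y"] = prof["n_papers"].to_numpy()
        for col in ("phylum", "region"):
            df[col] = prof[col].to_numpy()
        df["klass"] = prof["class_"].to_numpy()
        df["ord"] = prof["order"].to_numpy()
        data_csv = tmp_path / "d.csv"
        df.to_csv(data_csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(f"""
suppressMessages(library(glmmTMB))
d <- read.csv("{data_csv}")
f <- y ~ {' + '.join(c for c in design.columns if c != 'const')} +
  (1 | phylum / klass / ord) + (1 | region)
fit <- glmmTMB(f, data = d, family = nbinom2)
co <- fixef(fit)$cond
cat(jsonlite::toJSON(list(beta = as.numeric(co), theta = sigma(fit),
  loglik = as.numeric(logLik(fit))), auto_unbox = TRUE))
""")
        out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, timeout=300)
        payload = json.loads(out.stdout[out.stdout.index("{"):])
        assert ours.llf == pytest.approx(payload["loglik"], abs=0.5)
        assert ours.theta == pytest.approx(payload["theta"], rel=0.05)
        assert np.allclose(ours.beta.to_numpy(), np.asarray(payload["beta"]),
                           atol=0.05)

    def test_wald_ci_coverage_fixed_effects(self, rng):
        """~95% of Wald intervals cover the generating coefficients."""
        beta = np.array([1.0, 0.4, -0.3, 0.2])
        hits = total = 0
        for _ in range(40):
            design = _sim_design(rng, 300)
            y = _nb_draw(rng, np.exp(design.to_numpy() @ beta), theta=0.8)
            res = CountGLMM(y, design, family="nb2").fit()
            ci = res.conf_int()
            hits += int(((beta >= ci["lower"].to_numpy())
                         & (beta <= ci["upper"].to_numpy())).sum())
            total += len(beta)
        assert 0.88 <= hits / total <= 0.99

    def test_aic_counts_all_parameters(self, profiles_small):
        prof, _ = profiles_small
        model, _, _ = from_profiles(prof.head(300), "n_papers", "eq1", "nb2")
        res = model.fit(compute_se=False)
        k = len(res.beta) + 1 + len(res.sigma2)  # beta + theta + variances
        assert res.k_params == k
        assert res.aic == pytest.approx(2 * k - 2 * res.llf)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

class TestOverdispersionCheck:
    def test_poisson_data_ratio_near_one(self, rng):
        design = _sim_design(rng, 2000)
        beta = np.array([1.0, 0.3, -0.2, 0.1])
        y = rng.poisson(np.exp(design.to_numpy() @ beta))
        fit = CountGLMM(y, design, family="poisson").fit(compute_se=False)
        rep = overdispersion_check(fit)
        assert 0.8 <= rep.dispersion_ratio <= 1.2
        assert rep.df == 2000 - 4

    def test_nb_data_overdisperses_poisson_fit(self, rng):
        design = _sim_design(rng, 1000)
        beta = np.array([1.0, 0.3, -0.2, 0.1])
        y = _nb_draw(rng, np.exp(design.to_numpy() @ beta), theta=0.5)
        fit = CountGLMM(y, design, family="poisson").fit(compute_se=False)
        rep = overdispersion_check(fit)
        assert rep.dispersion_ratio > 1.5
        assert rep.p_overdispersion < 0.001


class TestZeroCheck:
    def test_correct_nb2_model_is_calibrated(self, rng):
        design = _sim_design(rng, 2000)
        beta = np.array([0.5, 0.3, -0.2, 0.1])
        y = _nb_draw(rng, np.exp(design.to_numpy() @ beta), theta=0.7)
        fit = CountGLMM(y, design, family="nb2").fit(compute_se=False)
        zc = zero_check(fit)
        assert 0.9 <= zc.ratio <= 1.1

    def test_zero_inflation_underfits_nb2(self, rng):
        design = _sim_design(rng, 2000)
        beta = np.array([1.5, 0.3, -0.2, 0.1])
        y = _nb_draw(rng, np.exp(design.to_numpy() @ beta), theta=1.0)
        y[rng.random(2000) < 0.3] = 0
        fit = CountGLMM(y, design, family="nb2").fit(compute_se=False)
        zc = zero_check(fit)
        assert zc.ratio < 1.0

    def test_no_observed_zeros(self, rng):
        design = _sim_design(rng, 200)
        y = 1 + rng.poisson(3.0, 200)
        fit = CountGLMM(y, design, family="poisson").fit(compute_se=False)
        zc = zero_check(fit)
        assert zc.observed == 0
        assert np.isnan(zc.ratio)
        assert "undefined" in zc.note


class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        n = 64
        X = np.zeros((n, 3))
        X[:, 0] = np.tile([1, -1], n // 2)
        X[:, 1] = np.tile([1, 1, -1, -1], n // 4)
        X[:, 2] = np.tile([1, 1, 1, 1, -1, -1, -1, -1], n // 8)
        out = vif(pd.DataFrame(X, columns=["a", "b", "c"]))
        assert np.allclose(out.to_numpy(), 1.0, atol=1e-10)

    def test_correlation_09_gives_5point26(self, rng):
        # construct columns with empirical correlation exactly 0.9
        z1 = rng.normal(size=500)
        z2 = rng.normal(size=500)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = z2 - z2.mean()
        z2 -= z1 * (z1 @ z2) / (z1 @ z1)  # orthogonalize
        z2 /= z2.std()
        x2 = 0.9 * z1 + np.sqrt(1 - 0.81) * z2
        out = vif(pd.DataFrame({"a": z1, "b": x2}))
        assert out["a"] == pytest.approx(1.0 / (1.0 - 0.81), rel=1e-9)
        assert out["b"] == pytest.approx(5.263, abs=1e-3)

    def test_duplicated_column_infinite(self, rng):
        x = rng.normal(size=100)
        with pytest.warns(UserWarning, match="collinear"):
            out = vif(pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)}))
        assert np.isinf(out["a"]) and np.isinf(out["b"])


class TestModelComparison:
    def test_identical_fits_zero_delta(self, rng):
        design = _sim_design(rng, 300)
        y = rng.poisson(np.exp(design.to_numpy() @ np.array([1.0, 0.2, 0.1, 0.0])))
        fit = CountGLMM(y, design, family="poisson").fit(compute_se=False)
        out = compare_fits([fit, fit])
        assert (out["delta_aic"] == 0).all()

    def test_zinb_wins_on_inflated_data_and_order_invariance(self, rng):
        design = _sim_design(rng, 2000)
        beta = np.array([1.5, 0.3, -0.2, 0.1])
        y = _nb_draw(rng, np.exp(design.to_numpy() @ beta), theta=1.0)
        y[rng.random(2000) < 0.3] = 0
        nb = CountGLMM(y, design, family="nb2").fit(compute_se=False)
        zi = CountGLMM(y, design, family="zinb2").fit(compute_se=False)
        a = compare_fits([nb, zi])
        b = compare_fits([zi, nb])
        assert a["family"].iloc[0] == "zinb2"
        pd.testing.assert_frame_equal(a, b)

    def test_mismatched_data_rejected(self, rng):
        d1, d2 = _sim_design(rng, 100), _sim_design(rng, 120)
        f1 = CountGLMM(rng.poisson(2, 100), d1, family="poisson").fit(compute_se=False)
        f2 = CountGLMM(rng.poisson(2, 120), d2, family="poisson").fit(compute_se=False)
        with pytest.raises(ValueError, match="n_obs"):
            compare_fits([f1, f2])


class TestSignificanceFlags:
    @staticmethod
    def _stub_fit(beta, se, rng):
        design = _sim_design(rng, 100, p=len(beta) - 1)
        y = rng.poisson(2.0, 100)
        res = CountGLMM(y, design, family="poisson").fit(compute_se=False)
        res.beta = pd.Series(beta, index=res.beta.index[:len(beta)])
        res._cov = np.diag(np.asarray(se) ** 2)
        return res

    def test_threshold_behaviour(self, rng):
        res = self._stub_fit([3.0, 0.0], [1.0, 1.0], rng)
        flags = significance_flags(res, alpha=0.01)
        assert bool(flags.iloc[0]) is True      # |z| = 3 > 2.576
        assert bool(flags.iloc[1]) is False     # z = 0

    def test_alpha_monotonicity(self, rng):
        res = self._stub_fit([2.2, 1.0, 0.1], [1.0, 1.0, 1.0], rng)
        at_05 = significance_flags(res, alpha=0.05)
        at_01 = significance_flags(res, alpha=0.01)
        assert (at_01 <= at_05).all()  # 0.01 flags are a subset


class TestFitCountModelSurface:
    def test_spec_validation(self):
        with pytest.raises(ValueError, match="zinb2 requires"):
            CountModelSpec(family="zinb2", fixed_terms=("x",), zi_structure="none")
        with pytest.raises(ValueError, match="nonempty"):
            CountModelSpec(fixed_terms=())

    def test_fit_through_spec(self, profiles_small):
        prof, _ = profiles_small
        design, _ = bi.prepare_design(prof.head(300), "eq1")
        spec = CountModelSpec(response="papers", family="nb2",
                              fixed_terms=("size", "colorful", "range"),
                              random_terms=("region",))
        labels = {"region": prof.head(300)["region"].to_numpy()}
        res = fit_count_model(design, prof.head(300)["n_papers"].to_numpy(),
                              spec, labels, compute_se=False)
        assert res.converged
        assert set(res.sigma2) == {"region"}
        assert list(res.beta.index) == ["const", "size", "colorful", "range"]
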