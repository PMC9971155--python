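"""Mixed-model fitting checked against independent routes: statsmodels'
fixed-effects beta regression for the sigma=0 case, dense Gauss-Hermite
quadrature for the Laplace integral, and the analytic chi-square reference
for the likelihood-ratio statistic."""
import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

import dyadnet._glmm_core as core
from dyadnet.association import dyad_table
from dyadnet.inference import (
    FULL_TERMS,
    REDUCED_TERMS,
    ConvergenceError,
    FitOptions,
    ModelSpec,
    build_design,
    fit_full_reduced,
    fit_glmm,
    group_contrasts,
    likelihood_ratio,
    marginal_loglik,
    squeeze_unit_interval,
    _prepare_response,
)
from dyadnet.synthetic import GeneratorConfig, GroupSpec, generate_focal_stream, generate_roster


class TestSqueeze:
    def test_boundary_values(self):
        assert squeeze_unit_interval(np.array([0.0]), 100)[0] == pytest.approx(0.005)
        assert squeeze_unit_interval(np.array([1.0]), 100)[0] == pytest.approx(0.995)

    def test_midpoint_fixed(self):
        assert squeeze_unit_interval(np.array([0.5]), 17)[0] == pytest.approx(0.5)

    def test_order_preserved(self):
        y = np.array([0.0, 0.2, 0.21, 0.9, 1.0])
        out = squeeze_unit_interval(y, 50)
        assert (np.diff(out) > 0).all()

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            squeeze_unit_interval(np.array([0.5]), 1)


class TestSpecValidation:
    def test_interaction_requires_mains(self):
        with pytest.raises(ValueError, match="main"):
            ModelSpec("party_sri", ("intercept", "sex_type:group"))

    def test_family_must_match_response(self):
        with pytest.raises(ValueError, match="family"):
            ModelSpec("occurrence", FULL_TERMS, family="beta_logit")


class TestBetaDensity:
    def test_integrates_to_one(self):
        # the compiled beta log-density, integrated numerically over (0,1)
        for mu, phi in [(0.2, 5.0), (0.5, 30.0), (0.8, 12.0)]:
            eta = np.log(mu / (1 - mu))

            def dens(y):
                ll, _, _ = core._derivs(core.FAM_BETA, np.array([y]), np.array([eta]), phi, False)
                return np.exp(ll)

            val, _ = integrate.quad(dens, 1e-9, 1 - 1e-9)
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_special_functions_match_scipy(self):
        xs = np.array([0.02, 0.3, 1.0, 2.7, 5.99, 6.01, 40.0, 300.0])
        dg = np.array([core._digamma(x) for x in xs])
        tg = np.array([core._trigamma(x) for x in xs])
        np.testing.assert_allclose(dg, special.digamma(xs), atol=1e-9)
        np.testing.assert_allclose(tg, special.polygamma(1, xs), atol=1e-9)


@pytest.fixture(scope="module")
def fitted_table(two_group_data_module):
    _, roster, records = two_group_data_module
    return dyad_table(records, roster)


@pytest.fixture(scope="module")
def two_group_data_module():
    cfg = GeneratorConfig(
        seed=101,
        groups=(GroupSpec("g1", 5, 5, 7), GroupSpec("g2", 5, 5, 7)),
        n_days=25,
        target_focals_per_individual=20,
        p_close_given_party=0.25,
    )
    roster = generate_roster(cfg)
    return cfg, roster, generate_focal_stream(roster, cfg)


class TestFixedEffectsOracle:
    def test_sigma_zero_matches_statsmodels_beta_regression(self, fitted_table):
        from statsmodels.othermod.betareg import BetaModel

        spec = ModelSpec("party_sri", FULL_TERMS)
        fit = fit_glmm(fitted_table, spec, FitOptions(fix_sigma_zero=True))
        sub, y, _, _ = _prepare_response(fitted_table, "party_sri")
        X, names, _ = build_design(sub, FULL_TERMS)
        oracle = BetaModel(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.beta_hat, oracle.params[: len(names)], atol=1e-3)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-4)

    def test_binomial_intercept_closed_form(self, fitted_table):
        spec = ModelSpec("occurrence", ("intercept",), family="binomial_logit")
        fit = fit_glmm(fitted_table, spec, FitOptions(fix_sigma_zero=True))
        p = (fitted_table.sri_direct > 0).mean()
        assert fit.beta_hat[0] == pytest.approx(np.log(p / (1 - p)), abs=1e-6)

    def test_sigma_zero_simulated_data_recovers_truth(self):
        rng = np.random.default_rng(8)
        n = 400
        df = pd.DataFrame(
            {
                "sex_type": rng.choice(["FF", "MF", "MM"], n),
                "group_id": rng.choice(["g1", "g2"], n),
                "kin": rng.random(n) < 0.15,
                "age_diff": rng.uniform(0, 20, n),
                "member_a": [f"a{i % 9}" for i in range(n)],
                "member_b": [f"b{i % 9}" for i in range(n)],
            }
        )
        eta = -1.0 + 0.8 * df.kin.to_numpy()
        mu = special.expit(eta)
        phi = 25.0
        df["sri_party"] = rng.beta(mu * phi, (1 - mu) * phi)
        fit = fit_glmm(df, ModelSpec("party_sri", ("intercept", "kin")), FitOptions(fix_sigma_zero=True))
        assert fit.beta_hat[0] == pytest.approx(-1.0, abs=3 * fit.se[0])
        assert fit.beta_hat[1] == pytest.approx(0.8, abs=3 * fit.se[1])
        assert fit.phi_hat == pytest.approx(25.0, rel=0.25)


class TestLaplaceVsQuadrature:
    """The Laplace integral against dense tensor-product Gauss-Hermite."""

    # 3 individuals -> 3 dyads, member-A roles {A,B}, member-B roles {B,C}: q = 4
    ia = np.array([0, 0, 1])
    ib = np.array([0, 1, 1])
    X = np.ones((3, 1))
    beta = np.array([-0.8])
    y = np.array([0.2, 0.35, 0.15])

    @pytest.mark.parametrize("phi,sigma", [(8.0, 0.3), (15.0, 0.4), (30.0, 0.5)])
    def test_beta_family_crossed(self, phi, sigma):
        lap = marginal_loglik(self.y, self.X, self.beta, self.ia, self.ib, 2, 2,
                              "beta_logit", phi, sigma, sigma, method="laplace")
        gh = marginal_loglik(self.y, self.X, self.beta, self.ia, self.ib, 2, 2,
                             "beta_logit", phi, sigma, sigma, method="gh", gh_nodes=25)
        assert lap == pytest.approx(gh, abs=0.05)

    @pytest.mark.parametrize("sigma", [0.3, 0.5])
    def test_binomial_family_crossed(self, sigma):
        yb = np.array([1.0, 0.0, 1.0])
        lap = marginal_loglik(yb, self.X, self.beta, self.ia, self.ib, 2, 2,
                              "binomial_logit", 1.0, sigma, sigma, method="laplace")
        gh = marginal_loglik(yb, self.X, self.beta, self.ia, self.ib, 2, 2,
                             "binomial_logit", 1.0, sigma, sigma, method="gh", gh_nodes=25)
        assert lap == pytest.approx(gh, abs=0.05)

    def test_multi_membership_four_individuals(self):
        ia = np.array([0, 0, 0, 1, 1, 2])
        ib = np.array([1, 2, 3, 2, 3, 3])
        X = np.ones((6, 1))
        y = np.array([0.2, 0.35, 0.15, 0.3, 0.22, 0.12])
        lap = marginal_loglik(y, X, np.array([-1.2]), ia, ib, 4, 0, "beta_logit",
                              15.0, 0.4, 0.4, multi_membership=True, method="laplace")
        gh = marginal_loglik(y, X, np.array([-1.2]), ia, ib, 4, 0, "beta_logit",
                             15.0, 0.4, 0.4, multi_membership=True, method="gh", gh_nodes=25)
        assert lap == pytest.approx(gh, abs=0.05)


class TestGLMMFitting:
    def test_full_fit_converges_and_reports(self, fitted_table):
        full, reduced = fit_full_reduced(
            fitted_table, ModelSpec("party_sri", FULL_TERMS), ModelSpec("party_sri", REDUCED_TERMS)
        )
        assert full.converged and reduced.converged
        assert full.deviance == pytest.approx(-2 * full.loglik)
        assert full.sigma2_a >= 0 and full.sigma2_b >= 0
        assert np.all(np.isfinite(full.se))
        # vcov symmetric PSD
        w = np.linalg.eigvalsh(full.vcov_fixed)
        assert w.min() > -1e-10

    def test_model_ladder_loglik_monotone(self, fitted_table):
        ladder = [
            ("intercept",),
            ("intercept", "sex_type"),
            ("intercept", "sex_type", "group"),
            ("intercept", "sex_type", "group", "kin"),
            ("intercept", "sex_type", "group", "kin", "age_diff"),
            FULL_TERMS,
        ]
        logliks = []
        for terms in ladder:
            fit = fit_glmm(fitted_table, ModelSpec("party_sri", tuple(terms)))
            logliks.append(fit.loglik)
        assert all(b >= a - 1e-6 for a, b in zip(logliks, logliks[1:]))

    def test_multi_membership_structure_fits(self, fitted_table):
        spec = ModelSpec("party_sri", FULL_TERMS, re_structure="multi_membership")
        fit = fit_glmm(fitted_table, spec)
        assert fit.converged
        assert fit.sigma2_a == fit.sigma2_b

    def test_magnitude_model_uses_nonzero_subset(self, fitted_table):
        fit = fit_glmm(fitted_table, ModelSpec("magnitude_sri", REDUCED_TERMS))
        assert fit.n_obs == int((fitted_table.sri_direct > 0).sum())


class TestLikelihoodRatio:
    def test_identity_comparison(self, fitted_table):
        fit = fit_glmm(fitted_table, ModelSpec("party_sri", REDUCED_TERMS))
        res = likelihood_ratio(fit, fit)
        assert res.chi2 == 0.0 and res.df == 0 and res.p_analytic == 1.0

    def test_interaction_df_is_two(self, fitted_table):
        full, reduced = fit_full_reduced(
            fitted_table, ModelSpec("party_sri", FULL_TERMS), ModelSpec("party_sri", REDUCED_TERMS)
        )
        res = likelihood_ratio(full, reduced)
        assert res.df == 2
        assert res.chi2 >= 0

    def test_non_nested_rejected(self, fitted_table):
        f1 = fit_glmm(fitted_table, ModelSpec("party_sri", ("intercept", "kin")))
        f2 = fit_glmm(fitted_table, ModelSpec("party_sri", ("intercept", "age_diff")))
        with pytest.raises(ValueError):
            likelihood_ratio(f2, f1)

    def test_null_distribution_matches_chi2(self):
        """Deviance differences under a true null follow chi-square with 2 df."""
        rng = np.random.default_rng(42)
        chi2s = []
        opts = FitOptions(fix_sigma_zero=True)
        for _ in range(400):
            n = 60
            df = pd.DataFrame(
                {
                    "sex_type": np.tile(["FF", "MF", "MM"], n // 3),
                    "group_id": np.repeat(["g1", "g2"], n // 2),
                    "kin": rng.random(n) < 0.1,
                    "age_diff": rng.uniform(0, 20, n),
                    "member_a": [f"a{i % 7}" for i in range(n)],
                    "member_b": [f"b{i % 7}" for i in range(n)],
                }
            )
            eta = df.sex_type.map({"FF": -1.2, "MF": -1.5, "MM": -1.0}).to_numpy() + 0.5 * df.kin.to_numpy()
            mu = special.expit(eta)
            phi = 20.0
            df["sri_party"] = rng.beta(mu * phi, (1 - mu) * phi)
            full, red = fit_full_reduced(
                df, ModelSpec("party_sri", FULL_TERMS), ModelSpec("party_sri", REDUCED_TERMS), opts
            )
            chi2s.append(likelihood_ratio(full, red).chi2)
        ks = stats.kstest(np.array(chi2s), "chi2", args=(2,))
        assert ks.pvalue > 0.01


class TestContrasts:
    def test_zero_interaction_reduces_to_group_effect(self, fitted_table):
        full = fit_glmm(fitted_table, ModelSpec("party_sri", FULL_TERMS))
        # force the interaction coefficients to zero and recompute
        import copy

        fit0 = copy.deepcopy(full)
        for j, t in enumerate(fit0.terms):
            if ":" in t:
                fit0.beta_hat[j] = 0.0
        cons = group_contrasts(fit0)
        gcol = [t for t in fit0.terms if t.startswith("group[")][0]
        expected = -fit0.beta_hat[fit0.terms.index(gcol)]
        assert all(c.estimate == pytest.approx(expected, abs=1e-12) for c in cons)

    def test_statistic_consistency(self, fitted_table):
        full = fit_glmm(fitted_table, ModelSpec("party_sri", FULL_TERMS))
        for c in group_contrasts(full):
            assert c.statistic * c.se == pytest.approx(c.estimate, rel=1e-9)
            assert 0.0 <= c.p <= 1.0

    def test_requires_interaction(self, fitted_table):
        red = fit_glmm(fitted_table, ModelSpec("party_sri", REDUCED_TERMS))
        with pytest.raises(ValueError):
            group_contrasts(red)

    def test_null_contrasts_moderate(self):
        # groups generated identically: contrast statistics should be unremarkable
        cfg = GeneratorConfig(
            seed=55, groups=(GroupSpec("g1", 5, 5, 7), GroupSpec("g2", 5, 5, 7)),
            n_days=30, target_focals_per_individual=24, sigma_indiv=0.0,
        )
        roster = generate_roster(cfg)
        tab = dyad_table(generate_focal_stream(roster, cfg), roster)
        full = fit_glmm(tab, ModelSpec("party_sri", FULL_TERMS))
        assert all(abs(c.statistic) < 3.5 for c in group_contrasts(full))


class TestParameterRecovery:
    def test_kin_effect_recovered_with_coverage(self):
        """Generating values inside +/-2 SE and positive kin effect detected."""
        hits_kin = 0
        covered = 0
        reps = 5
        for rep in range(reps):
            cfg = GeneratorConfig(
                seed=300 + rep,
                groups=(GroupSpec("g1", 5, 5, 6), GroupSpec("g2", 5, 5, 6)),
                n_days=40,
                target_focals_per_individual=30,
                beta_kin=1.2,
                sigma_indiv=0.3,
            )
            roster = generate_roster(cfg)
            tab = dyad_table(generate_focal_stream(roster, cfg), roster)
            full, red = fit_full_reduced(
                tab,
                ModelSpec("party_sri", FULL_TERMS),
                ModelSpec("party_sri", ("intercept", "sex_type", "group", "age_diff")),
            )
            k = full.terms.index("kin")
            if full.beta_hat[k] > 0:
                hits_kin += 1
            # daily binarization (<= 2 samples per dyad-day) shifts the
            # per-sample coefficient; generous coverage window
            if abs(full.beta_hat[k] - 1.2) < 4 * full.se[k]:
                covered += 1
        assert hits_kin == reps
        assert covered >= reps - 1
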