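"""REML core: likelihood correctness, covariance assembly, fit behaviour."""

import numpy as np
import pandas as pd
import pytest

from bivarlmm import (
    BivariateLMM,
    ModelSpec,
    SimulationConfig,
    VarianceComponents,
    compare_aic,
    fit_univariate,
    marginal_covariance,
    ou_covariance,
    simulate_cohort,
)
from bivarlmm.errors import IncomparableModelsError, InvalidParameterError

from conftest import dense_reml_loglik


def _vc_bivariate(g_scale=1.0):
    G = np.array(
        [
            [16.0, 1.0, 8.0, 0.5],
            [1.0, 0.25, 0.4, 0.05],
            [8.0, 0.4, 25.0, 1.0],
            [0.5, 0.05, 1.0, 0.16],
        ]
    ) * g_scale
    return VarianceComponents(G=G, sigma2=np.array([36.0, 49.0]))


class TestOuCovariance:
    def test_zero_lag_returns_c(self):
        C = np.array([[4.0, 1.0], [1.0, 1.0]])
        np.testing.assert_allclose(ou_covariance(C, (0.5, 0.8), 2.0, 2.0), C)

    def test_equal_decay_scalar_factor(self):
        C = np.array([[4.0, 1.0], [1.0, 1.0]])
        np.testing.assert_allclose(
            ou_covariance(C, (0.5, 0.5), 0.0, 2.0), np.exp(-1.0) * C
        )

    def test_zero_cross_term_stays_zero(self):
        C = np.diag([4.0, 1.0])
        R = ou_covariance(C, (0.3, 0.9), 0.0, 3.0)
        assert R[0, 1] == 0.0 and R[1, 0] == 0.0

    def test_invalid_inputs_rejected(self):
        C = np.array([[1.0, 2.0], [2.0, 1.0]])  # not PSD
        with pytest.raises(InvalidParameterError):
            ou_covariance(C, (0.5, 0.5), 0.0, 1.0)
        with pytest.raises(InvalidParameterError):
            ou_covariance(np.eye(2), (0.5, -0.5), 0.0, 1.0)


class TestMarginalCovariance:
    def test_pure_noise_identity(self):
        vc = VarianceComponents(G=np.zeros((4, 4)), sigma2=np.array([1.0, 1.0]))
        Z = np.zeros((4, 4))
        V = marginal_covariance(vc, Z, np.array([0.0, 1.0, 0.0, 1.0]),
                                [0, 0, 1, 1])
        np.testing.assert_allclose(V, np.eye(4))

    def test_trait_specific_residuals(self):
        vc = VarianceComponents(G=np.zeros((4, 4)), sigma2=np.array([4.0, 1.0]))
        V = marginal_covariance(vc, np.zeros((4, 4)), np.zeros(4), [0, 0, 1, 1])
        np.testing.assert_allclose(V, np.diag([4.0, 4.0, 1.0, 1.0]))

    def test_cross_trait_intercept_covariance(self):
        g12 = 3.0
        G = np.array([[5.0, g12], [g12, 7.0]])
        vc = VarianceComponents(G=G, sigma2=np.array([1.0, 1.0]))
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])  # one visit, both traits
        V = marginal_covariance(vc, Z, np.zeros(2), [0, 1])
        assert V[0, 1] == pytest.approx(g12)
        np.testing.assert_allclose(np.diag(V), [6.0, 8.0])


class TestRemlLoglik:
    def test_intercept_only_iid_classical_reml(self):
        # REML on y = mu + eps recovers the (n-1)-divisor variance
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        ph = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(5)],
                "exam": 1, "time": 0.0, "sbp": y, "dbp": np.nan,
                "baseline_age": 0.0, "sex": 0.0, "medication": 0.0, "smoking": 0.0,
            }
        )
        spec = ModelSpec(fixed_effects=("intercept",), random_effects=())
        res = fit_univariate(ph, None, spec=spec, trait="sbp", gtol=1e-10)
        assert res.params["sbp:intercept"] == pytest.approx(3.0, abs=1e-6)
        assert res.vc.sigma2[0] == pytest.approx(2.5, rel=1e-5)

    def test_translation_invariance(self, small_cohort):
        pheno, gm = small_cohort
        dos = gm.dosage_series("snp1")
        vc = _vc_bivariate()
        m1 = BivariateLMM(pheno, dosages=dos)
        shifted = pheno.copy()
        shifted["sbp"] = shifted["sbp"] + 500.0  # shift along the intercept column
        shifted["dbp"] = shifted["dbp"] - 200.0
        m2 = BivariateLMM(shifted, dosages=dos)
        assert m1.loglike(vc) == pytest.approx(m2.loglike(vc), abs=1e-7)

    @pytest.mark.parametrize("family,ou,ar1", [
        ("UN_RE", None, None),
        ("UN_RE_OU", {"C": np.array([[9.0, 2.0], [2.0, 4.0]]),
                      "decay": np.array([0.4, 0.7])}, None),
        ("AR1_VISIT", None, {"sigma2_w": np.array([10.0, 6.0]),
                             "rho": np.array([0.4, 0.2])}),
    ])
    def test_matches_dense_formula_oracle(self, tiny_cohort, family, ou, ar1):
        pheno, gm = tiny_cohort
        pheno = pheno.copy()
        pheno.loc[3, "dbp"] = np.nan  # unbalanced rows too
        spec = ModelSpec(covariance_family=family)
        m = BivariateLMM(pheno, dosages=gm.dosage_series("snp1"), spec=spec)
        vc = _vc_bivariate()
        vc.ou, vc.ar1 = ou, ar1
        assert m.loglike(vc) == pytest.approx(
            dense_reml_loglik(m.design, vc), abs=1e-8
        )


class TestAnalyticGradient:
    def test_matches_central_differences(self, tiny_cohort):
        pheno, gm = tiny_cohort
        model = BivariateLMM(pheno, dosages=gm.dosage_series("snp1"))
        pm, eng = model.pmap, model.engine
        from bivarlmm.model import _mom_start

        theta = pm.pack(_mom_start(model.design))
        theta += 0.1 * np.sin(np.arange(theta.size))  # move off the start
        got = eng.evaluate(pm.unpack(theta), need_grad=True, pmap=pm,
                           theta=theta).grad
        h = 1e-6
        num = np.empty_like(theta)
        for i in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            num[i] = (
                eng.evaluate(pm.unpack(tp)).loglik
                - eng.evaluate(pm.unpack(tm)).loglik
            ) / (2 * h)
        np.testing.assert_allclose(got, num, rtol=1e-5, atol=1e-7)


class TestFit:
    def test_recovers_truth_within_3_se(self):
        cfg = SimulationConfig(n_subjects=400, seed=17)
        pheno, gm = simulate_cohort(cfg)
        res = BivariateLMM(pheno, dosages=gm.dosage_series("snp1")).fit()
        assert res.converged
        truth = {
            "sbp:genotype": cfg.beta_snp[0], "dbp:genotype": cfg.beta_snp[1],
            "sbp:time": 0.45, "dbp:baseline_age": 0.12,
            "sbp:intercept": 118.0, "dbp:intercept": 72.0,
        }
        for name, true_val in truth.items():
            z = (res.params[name] - true_val) / res.bse[name]
            assert abs(z) < 3, f"{name}: {res.params[name]} vs {true_val}"

    def test_warm_start_is_fixed_point(self, small_cohort):
        pheno, gm = small_cohort
        model = BivariateLMM(pheno, dosages=gm.dosage_series("snp1"))
        first = model.fit()
        again = model.fit(start=first.vc)
        assert again.n_iter <= 2
        assert again.llf == pytest.approx(first.llf, abs=1e-6)

    def test_response_rescaling_equivariance(self, small_cohort):
        pheno, gm = small_cohort
        dos = gm.dosage_series("snp1")
        c = 2.0
        scaled = pheno.copy()
        scaled[["sbp", "dbp"]] = scaled[["sbp", "dbp"]] * c
        r1 = BivariateLMM(pheno, dosages=dos).fit(gtol=1e-9)
        scaled_vc = VarianceComponents(G=c**2 * r1.vc.G, sigma2=c**2 * r1.vc.sigma2)
        r2 = BivariateLMM(scaled, dosages=dos).fit(start=scaled_vc, gtol=1e-9)
        np.testing.assert_allclose(r2.params, c * r1.params, rtol=1e-4)
        np.testing.assert_allclose(r2.vc.sigma2, c**2 * r1.vc.sigma2, rtol=1e-3)
        np.testing.assert_allclose(r2.vc.G, c**2 * r1.vc.G, rtol=1e-3, atol=1e-2)
        p1 = r1.joint_genotype_test().p_f
        p2 = r2.joint_genotype_test().p_f
        assert p2 == pytest.approx(p1, rel=1e-4)

    def test_subject_permutation_invariance(self, small_cohort):
        pheno, gm = small_cohort
        dos = gm.dosage_series("snp1")
        perm = pheno.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r1 = BivariateLMM(pheno, dosages=dos).fit()
        r2 = BivariateLMM(perm, dosages=dos).fit()
        assert r1.llf == pytest.approx(r2.llf, abs=1e-6)
        np.testing.assert_allclose(r1.params, r2.params, rtol=1e-5, atol=1e-6)

    def test_optimum_beats_truth_loglik(self, small_cohort):
        pheno, gm = small_cohort
        cfg = SimulationConfig()
        truth = VarianceComponents(G=cfg.G, sigma2=np.asarray(cfg.sigma_resid) ** 2)
        model = BivariateLMM(pheno, dosages=gm.dosage_series("snp1"))
        res = model.fit()
        assert res.llf >= model.loglike(truth) - 1e-6

    def test_cov_beta_symmetric_psd(self, small_cohort):
        pheno, gm = small_cohort
        res = BivariateLMM(pheno, dosages=gm.dosage_series("snp1")).fit()
        C = res.cov_params.to_numpy()
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        assert np.linalg.eigvalsh(C).min() > 0

    def test_univariate_bad_trait_rejected(self, small_cohort):
        pheno, gm = small_cohort
        with pytest.raises(InvalidParameterError):
            fit_univariate(pheno, gm.dosage_series("snp1"), trait="pulse")

    def test_summary_mentions_key_quantities(self, small_cohort):
        pheno, gm = small_cohort
        res = BivariateLMM(pheno, dosages=gm.dosage_series("snp1")).fit()
        s = res.summary()
        assert "REML log-likelihood" in s and "sbp:genotype" in s and "AIC" in s

    def test_json_roundtrip(self, small_cohort, tmp_path):
        import json

        pheno, gm = small_cohort
        res = BivariateLMM(pheno, dosages=gm.dosage_series("snp1")).fit()
        res.to_json(tmp_path / "fit.json")
        d = json.loads((tmp_path / "fit.json").read_text())
        assert d["converged"]
        assert d["params"]["sbp:genotype"] == pytest.approx(res.params["sbp:genotype"])


class TestSerialFamilies:
    def test_ou_fit_improves_on_nested_un_re(self):
        cfg = SimulationConfig(
            n_subjects=30, seed=13,
            ou_params={"C": np.array([[6.0, 2.0], [2.0, 5.0]]),
                       "decay": (0.4, 0.6)},
        )
        pheno, gm = simulate_cohort(cfg)
        dos = gm.dosage_series("snp1")
        r_un = BivariateLMM(pheno, dosages=dos).fit()
        r_ou = BivariateLMM(
            pheno, dosages=dos, spec=ModelSpec(covariance_family="UN_RE_OU")
        ).fit(maxiter=300)
        # the OU family nests UN_RE (C -> 0), so its optimum cannot be worse
        assert r_ou.llf >= r_un.llf - 1e-3
        assert r_ou.vc.ou is not None
        C = np.asarray(r_ou.vc.ou["C"])
        assert np.linalg.eigvalsh(C).min() >= -1e-8


class TestUnivariateCalibration:
    def test_null_snp_rejection_rate_near_nominal(self):
        # null SNP, n=141: the 1-df univariate test rejects at ~5%
        n_reps = 150
        seeds = np.random.SeedSequence(99).generate_state(n_reps) % (2**31)
        rej = 0
        for s in seeds:
            cfg = SimulationConfig(beta_snp=(0.0, 0.0), seed=int(s))
            pheno, gm = simulate_cohort(cfg)
            fit = fit_univariate(pheno, gm.dosage_series("snp1"), trait="sbp")
            rej += fit.genotype_test("sbp").p_chi2 < 0.05
        rate = rej / n_reps
        # binomial 99% CI around 0.05 at 150 replicates
        half = 2.58 * np.sqrt(0.05 * 0.95 / n_reps)
        assert 0.05 - half <= rate <= 0.05 + half, rate


class TestCompareAic:
    def test_aic_definition_and_ranking(self, small_cohort):
        pheno, gm = small_cohort
        dos = gm.dosage_series("snp1")
        r_un = BivariateLMM(pheno, dosages=dos).fit()
        r_ar = BivariateLMM(pheno, dosages=dos,
                            spec=ModelSpec(covariance_family="AR1_VISIT")).fit()
        assert r_un.aic == pytest.approx(-2 * r_un.llf + 2 * r_un.n_vc_params)
        tbl = compare_aic([r_un, r_ar])
        assert list(tbl["rank"]) == [1, 2]
        assert tbl.iloc[0]["aic"] == min(r_un.aic, r_ar.aic)

    def test_single_fit_ranked_first(self, small_cohort):
        pheno, gm = small_cohort
        r = BivariateLMM(pheno, dosages=gm.dosage_series("snp1")).fit()
        tbl = compare_aic([r])
        assert list(tbl["rank"]) == [1]

    def test_different_responses_incomparable(self, small_cohort, tiny_cohort):
        p1, g1 = small_cohort
        p2, g2 = tiny_cohort
        r1 = BivariateLMM(p1, dosages=g1.dosage_series("snp1")).fit()
        r2 = BivariateLMM(p2, dosages=g2.dosage_series("snp1")).fit()
        with pytest.raises(IncomparableModelsError):
            compare_aic([r1, r2])

    def test_un_re_preferred_under_un_re_truth(self):
        # strong random slopes: visit-index AR(1) cannot track the
        # time-increasing variance, so the UN_RE family should win on AIC
        G = np.array(
            [
                [13.0, 0.0, 10.0, 0.0],
                [0.0, 1.0, 0.0, 0.3],
                [10.0, 0.0, 34.0, 0.0],
                [0.0, 0.3, 0.0, 1.0],
            ]
        )
        wins = 0
        n_reps = 12
        for s in range(n_reps):
            pheno, gm = simulate_cohort(
                SimulationConfig(n_subjects=120, G=G, seed=1000 + s)
            )
            dos = gm.dosage_series("snp1")
            r_un = BivariateLMM(pheno, dosages=dos).fit()
            r_ar = BivariateLMM(pheno, dosages=dos,
                                spec=ModelSpec(covariance_family="AR1_VISIT")).fit()
            tbl = compare_aic([r_un, r_ar])
            if tbl.iloc[0]["family"] == "UN_RE":
                wins += 1
        assert wins >= int(0.75 * n_reps)
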