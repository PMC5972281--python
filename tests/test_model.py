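import numpy as np
import pytest

from cfasim import (OneFactorCFA, PopulationModel, compute_moments,
                    generate_sample, implied_sigma)
from cfasim.exceptions import EstimationInputError
from cfasim.model import ModelSpec

TRIAD_HEYWOOD = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.2], [0.8, 0.2, 1.0]])


class TestModelSpec:
    @pytest.mark.parametrize("p,df", [(4, 2), (5, 5), (6, 9), (7, 14), (15, 90)])
    def test_degrees_of_freedom(self, p, df):
        assert ModelSpec(p=p).df == df


class TestZeroResidualRecovery:
    @pytest.mark.parametrize("method", ["ml", "uls"])
    @pytest.mark.parametrize("lam", [0.2, 0.3, 0.4])
    @pytest.mark.parametrize("p", [4, 5, 6, 7, 15])
    def test_fitting_implied_sigma_recovers_population(self, method, lam, p):
        sigma = implied_sigma(PopulationModel.equal_loading(lam, p))
        res = OneFactorCFA(sigma, n=500).fit(method, input_kind="S")
        assert res.status == "proper"
        assert res.f_min < 1e-10
        assert np.allclose(res.loadings_hat, lam, atol=1e-5)
        assert np.allclose(res.unique_variances_hat, 1 - lam**2, atol=1e-5)


class TestTriadClosedForm:
    @pytest.mark.parametrize("method", ["ml", "uls"])
    def test_planted_heywood_matrix(self, method):
        res = OneFactorCFA(TRIAD_HEYWOOD, n=100).fit(method, input_kind="S")
        assert res.status == "heywood"
        assert res.loadings_hat[0] == pytest.approx(np.sqrt(0.9 * 0.8 / 0.2), abs=1e-6)
        assert res.unique_variances_hat[0] == pytest.approx(-2.6, abs=1e-6)
        assert res.f_min < 1e-10

    @pytest.mark.parametrize("method", ["ml", "uls"])
    def test_positive_triad_interpolates(self, method, rng):
        r = implied_sigma(PopulationModel(loadings=[0.5, 0.6, 0.7]))
        res = OneFactorCFA(r, n=200).fit(method)
        assert res.status == "proper"
        assert np.allclose(res.loadings_hat, [0.5, 0.6, 0.7], atol=1e-6)
        assert res.loadings_hat[0] == pytest.approx(
            np.sqrt(r[0, 1] * r[0, 2] / r[1, 2]), abs=1e-6
        )


class TestEstimatesAgainstOracles:
    def test_ml_matches_independent_sem_implementation(self, clean_fit_moments):
        statsmodels = pytest.importorskip("statsmodels.multivariate.factor")
        ours = OneFactorCFA(clean_fit_moments).fit_ml()
        sm = statsmodels.Factor(
            corr=clean_fit_moments.correlation, n_factor=1, method="ml",
            nobs=clean_fit_moments.n,
        ).fit()
        ref = np.asarray(sm.loadings).ravel()
        if ref.sum() < 0:
            ref = -ref
        assert np.allclose(ours.standardized_loadings, ref, atol=1e-4)

    def test_uls_f_min_is_sum_of_squared_residuals(self, clean_fit_moments):
        res = OneFactorCFA(clean_fit_moments).fit_uls()
        p = clean_fit_moments.p
        sigma = np.outer(res.loadings_hat, res.loadings_hat)
        sigma[np.diag_indices(p)] += res.unique_variances_hat
        e = sigma - clean_fit_moments.correlation
        ssq = float(sum(e[i, j] ** 2 for i in range(p) for j in range(i + 1)))
        assert res.f_min == pytest.approx(ssq, abs=1e-10)

    def test_ml_and_uls_agree_on_large_unit_variance_samples(self):
        mo = compute_moments(
            generate_sample(PopulationModel.equal_loading(0.3, 5), 10_000, 21)
        )
        ml = OneFactorCFA(mo).fit_ml()
        uls = OneFactorCFA(mo).fit_uls()
        assert np.allclose(ml.standardized_loadings, uls.standardized_loadings,
                           atol=1e-3)


class TestStandardization:
    def test_unit_variance_input_standardized_equals_unstandardized(self):
        r = implied_sigma(PopulationModel.equal_loading(0.4, 4))
        res = OneFactorCFA(r, n=300).fit_ml()
        assert np.allclose(res.standardized_loadings, res.loadings_hat)

    def test_scale_invariance_of_standardized_loadings(self, rng):
        x = generate_sample(PopulationModel.equal_loading(0.4, 5), 400, rng).data
        base = OneFactorCFA.from_data(x).fit_ml()
        scaled = OneFactorCFA.from_data(x * np.array([2.0, 0.5, 3.0, 1.0, 10.0])).fit_ml()
        assert np.allclose(
            base.standardized_loadings, scaled.standardized_loadings, atol=1e-6
        )

    def test_standardized_solution_matches_ml_on_correlation(self, clean_fit_moments):
        on_s = OneFactorCFA(clean_fit_moments).fit_ml()
        on_r = OneFactorCFA(clean_fit_moments).fit("ml", input_kind="R")
        assert np.allclose(
            on_s.standardized_loadings, on_r.loadings_hat, atol=1e-6
        )

    def test_sign_convention_nonnegative_sum(self, clean_fit_moments):
        res = OneFactorCFA(clean_fit_moments).fit_ml()
        assert res.loadings_hat.sum() >= 0


class TestStandardErrorsAndTTests:
    def test_ses_positive_for_proper_solution(self, clean_fit_moments):
        res = OneFactorCFA(clean_fit_moments).fit_ml()
        assert res.is_proper and res.bse_available
        assert np.all(res.bse > 0)

    def test_ses_shrink_as_root_n(self):
        model = PopulationModel.equal_loading(0.4, 5)
        rng = np.random.default_rng(3)

        def mean_se(n, reps=60):
            out = []
            for _ in range(reps):
                f = OneFactorCFA(compute_moments(generate_sample(model, n, rng))).fit_ml()
                if f.is_proper and f.bse_available:
                    out.append(f.bse.mean())
            return np.mean(out)

        ratio = mean_se(500) / mean_se(200)
        assert abs(ratio - np.sqrt(200 / 500)) < 0.2 * np.sqrt(200 / 500)

    def test_t_statistics_are_loading_over_se(self, clean_fit_moments):
        res = OneFactorCFA(clean_fit_moments).fit_ml()
        assert np.allclose(res.tvalues, res.loadings_hat / res.bse)

    def test_t_test_power_under_strong_signal(self):
        model = PopulationModel.equal_loading(0.4, 6)
        rng = np.random.default_rng(5)
        sig = tot = 0
        for _ in range(150):
            f = OneFactorCFA(compute_moments(generate_sample(model, 500, rng))).fit_ml()
            if f.is_proper and f.bse_available:
                sig += int(np.all(np.abs(f.tvalues) > 1.96))
                tot += 1
        assert sig / tot > 0.99

    def test_uls_has_no_standard_errors(self, clean_fit_moments):
        res = OneFactorCFA(clean_fit_moments).fit_uls()
        assert not res.bse_available
        assert np.all(np.isnan(res.bse))


class TestSolutionClassification:
    def test_proper_heywood_nonconvergent_statuses_all_occur(self):
        # weak loadings, few indicators, small N: the condition the study
        # flags as improper-prone
        model = PopulationModel.equal_loading(0.2, 4)
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(300):
            f = OneFactorCFA(compute_moments(generate_sample(model, 200, rng))).fit_ml()
            seen.add(f.status)
            if f.status == "heywood":
                assert f.converged and f.unique_variances_hat.min() < 0
            if f.status == "nonconvergent":
                assert not f.converged
        assert seen == {"proper", "heywood", "nonconvergent"}

    def test_singular_input_rejected(self):
        s = np.ones((4, 4))
        with pytest.raises(EstimationInputError):
            OneFactorCFA(s, n=100).fit_ml()

    def test_asymmetric_input_rejected(self):
        m = np.eye(4)
        m[0, 1] = 0.5
        with pytest.raises(EstimationInputError):
            OneFactorCFA(m, n=100)


class TestSummary:
    def test_summary_prints_estimates_and_fit(self, clean_fit_moments):
        text = OneFactorCFA(clean_fit_moments).fit_ml().summary()
        assert "Status: proper" in text
        assert "RMSEA" in text and "CFI" in text
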