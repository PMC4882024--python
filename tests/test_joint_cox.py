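import numpy as np
import pandas as pd
import pytest

from stemspat.inhom_null import LogLinearIntensityModel, fit_loglinear, simulate_ipp
from stemspat.joint_cox import (
    CoxModel, DecompositionResult, MaternParams, fit_cox_twostep,
    lgcp_theoretical_K, matern_cov, pve_increments, select_cox_model,
    simulate_cox, simulate_gaussian_field, variance_decomposition,
)
from stemspat.plot_io import PlotWindow, RasterSurface
from tests.conftest import csr


def truth_cox(env, window, beta=1.0, variance=1.0, scale=10.0,
              expected_n=700.0):
    pc1 = env.components[0].values
    lam = np.exp(beta * pc1)
    lam *= expected_n / (lam.sum() * env.components[0].cell_size ** 2)
    surf = RasterSurface(lam, env.components[0].cell_size, name="lam")
    im = LogLinearIntensityModel(
        intercept=float(np.log(lam.mean())), coefficients=np.array([beta]),
        terms=[(0, 1)], surface=surf, window=window)
    return CoxModel(im, MaternParams(variance, scale, 0.5))


class TestMaternCov:
    def test_value_at_zero(self):
        assert matern_cov(0.0, MaternParams(2.5, 7.0, 0.75)) == 2.5

    def test_nu_half_equals_exponential(self):
        # known special case: exact closed form
        p = MaternParams(1.7, 9.0, 0.5)
        r = np.linspace(0.0, 60.0, 121)
        np.testing.assert_allclose(matern_cov(r, p), 1.7 * np.exp(-r / 9.0),
                                   atol=1e-12)

    @pytest.mark.parametrize("nu", [0.25, 0.5, 1.0, 2.0])
    def test_strictly_decreasing(self, nu):
        p = MaternParams(1.0, 8.0, nu)
        r = np.linspace(0.0, 5 * p.scale, 200)
        vals = matern_cov(r, p)
        assert np.all(np.diff(vals) < 0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            MaternParams(0.0, 1.0, 0.5)


class TestGaussianField:
    def test_marginal_variance_and_covariance(self, rng):
        p = MaternParams(1.5, 15.0, 0.5)
        fields = [simulate_gaussian_field((40, 40), 5.0, p, rng)
                  for _ in range(60)]
        arr = np.array(fields)
        assert arr.var() == pytest.approx(1.5, rel=0.08)
        lag2 = np.mean([np.mean(f[:, :-2] * f[:, 2:]) for f in fields])
        assert lag2 == pytest.approx(1.5 * np.exp(-10.0 / 15.0), rel=0.15)

    def test_deterministic_by_seed(self):
        p = MaternParams(1.0, 10.0, 0.5)
        a = simulate_gaussian_field((20, 20), 5.0, p, rng=3)
        b = simulate_gaussian_field((20, 20), 5.0, p, rng=3)
        np.testing.assert_array_equal(a, b)


class TestSimulateCox:
    def test_no_field_reduces_to_ipp_same_seed(self, small_env, small_window, rng):
        p = csr(300, small_window, rng)
        m = fit_loglinear(p, small_env, [(0, 1)])
        cox = CoxModel(m, matern=None)
        a = simulate_cox(cox, rng=11)
        b = simulate_ipp(m, rng=11)
        np.testing.assert_array_equal(a.x, b.x)

    def test_mean_count_unit_mean_field(self, small_env, small_window, rng):
        truth = truth_cox(small_env, small_window, expected_n=300.0)
        counts = [simulate_cox(truth, rng).n for _ in range(150)]
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 300.0) < 3 * se + 1e-9

    def test_pcf_matches_lgcp_closed_form(self, small_env, small_window, rng):
        # g(r) = exp(C(r)) at r = scale, beta = 0
        from stemspat.sumstats import pair_correlation

        phi = 10.0
        surf = RasterSurface(np.full((40, 40), 0.02), 5.0, name="lam")
        im = LogLinearIntensityModel(intercept=np.log(0.02),
                                     coefficients=np.empty(0), terms=[],
                                     surface=surf, window=small_window)
        truth = CoxModel(im, MaternParams(0.8, phi, 0.5))
        vals = []
        for _ in range(120):
            p = simulate_cox(truth, rng)
            if p.n > 20:
                vals.append(pair_correlation(p, [0.0, phi],
                                             bandwidth=2.5).values[1])
        expected = np.exp(0.8 * np.exp(-1.0))
        assert np.mean(vals) == pytest.approx(expected, rel=0.1)


class TestLgcpTheoreticalK:
    def test_zero_variance_gives_csr(self):
        r = np.linspace(0, 50, 11)
        k = lgcp_theoretical_K(r, MaternParams(1e-12, 10.0, 0.5))
        np.testing.assert_allclose(k, np.pi * r ** 2, rtol=1e-4)

    def test_positive_variance_exceeds_csr(self):
        r = np.array([0.0, 10.0, 30.0])
        k = lgcp_theoretical_K(r, MaternParams(1.0, 10.0, 0.5))
        assert np.all(k[1:] > np.pi * r[1:] ** 2)


class TestTwoStep:
    def test_step1_equals_fit_loglinear(self, small_env, small_window, rng):
        truth = truth_cox(small_env, small_window)
        p = simulate_cox(truth, rng)
        cox = fit_cox_twostep(p, small_env, terms=[(0, 1)])
        direct = fit_loglinear(p, small_env, [(0, 1)])
        np.testing.assert_allclose(cox.intensity_model.coefficients,
                                   direct.coefficients, atol=1e-10)

    def test_parameter_recovery(self, small_env, small_window, rng):
        truth = truth_cox(small_env, small_window, beta=1.0, variance=1.0,
                          scale=10.0)
        betas, var_list, scale_list = [], [], []
        for _ in range(10):
            p = simulate_cox(truth, rng)
            fit = fit_cox_twostep(p, small_env, terms=[(0, 1)])
            betas.append(fit.intensity_model.coefficients[0])
            var_list.append(fit.matern.variance)
            scale_list.append(fit.matern.scale)
        assert abs(np.median(betas) - 1.0) < 0.3
        assert 0.5 <= np.median(var_list) <= 2.0
        assert 5.0 <= np.median(scale_list) <= 20.0

    def test_hpp_data_fit_small_variance(self, small_env, small_window, rng):
        p = csr(500, small_window, rng)
        fit = fit_cox_twostep(p, small_env, terms=[(0, 1)])
        assert fit.matern.variance < 0.25


class TestSelectCoxModel:
    def test_cox_data_retains_field(self, small_env, small_window, rng):
        truth = truth_cox(small_env, small_window)
        retained = sum(
            select_cox_model(simulate_cox(truth, rng), small_env, n_sim=39,
                             rng=rng).d_retained
            for _ in range(5))
        assert retained >= 4

    def test_hpp_data_drops_field(self, small_env, small_window, rng):
        dropped = 0
        for _ in range(5):
            p = csr(400, small_window, rng)
            m = select_cox_model(p, small_env, n_sim=39, rng=rng)
            dropped += not m.d_retained
        assert dropped >= 4

    def test_deterministic_given_seed(self, small_env, small_window, rng):
        truth = truth_cox(small_env, small_window)
        p = simulate_cox(truth, rng)
        a = select_cox_model(p, small_env, n_sim=19, rng=7)
        b = select_cox_model(p, small_env, n_sim=19, rng=7)
        assert a.d_retained == b.d_retained
        assert a.intensity_model.terms == b.intensity_model.terms


class TestVarianceDecomposition:
    def make_model(self, env, window, terms, coefs, matern):
        surf = RasterSurface(np.full(env.components[0].shape, 0.01), 5.0,
                             name="lam")
        im = LogLinearIntensityModel(intercept=0.0,
                                     coefficients=np.asarray(coefs, float),
                                     terms=terms, surface=surf, window=window)
        return CoxModel(im, matern)

    def test_no_field_gives_pve_one(self, small_env, small_window):
        m = self.make_model(small_env, small_window, [(0, 1)], [0.8], None)
        dec = variance_decomposition(m, small_env)
        assert dec.pve == 1.0 and dec.pvd == 0.0

    def test_no_env_gives_pve_zero(self, small_env, small_window):
        m = self.make_model(small_env, small_window, [], [],
                            MaternParams(1.0, 10.0, 0.5))
        dec = variance_decomposition(m, small_env)
        assert dec.pve == 0.0 and dec.pvd == 1.0

    def test_equal_split_gives_half(self, small_env, small_window):
        pc1 = small_env.components[0].values
        v_env = float(np.var(1.0 * pc1))
        m = self.make_model(small_env, small_window, [(0, 1)], [1.0],
                            MaternParams(v_env, 10.0, 0.5))
        dec = variance_decomposition(m, small_env)
        assert dec.pve == pytest.approx(0.5, abs=1e-12)
        assert dec.pve + dec.pvd == 1.0

    def test_undefined_flags_error(self, small_env, small_window):
        m = self.make_model(small_env, small_window, [], [], None)
        with pytest.raises(ValueError, match="undefined"):
            variance_decomposition(m, small_env)

    def test_result_invariants(self):
        with pytest.raises(ValueError):
            DecompositionResult(pve=1.2, pvd=-0.2)
        with pytest.raises(ValueError):
            DecompositionResult(pve=0.5, pvd=0.4)


class TestPveIncrements:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["sp", "stage", "pve"])

    def test_simple_increment(self):
        t = self.table([("A", "sapling", 0.2), ("A", "adult", 0.5),
                        ("A", "juvenile", 0.3)])
        inc = pve_increments(t, ["sapling", "juvenile", "adult"], {"A": "wind"})
        juv = inc[(inc.from_stage == "juvenile")].iloc[0]
        assert juv.delta_pve == pytest.approx(0.2)
        sap = inc[(inc.from_stage == "sapling")].iloc[0]
        assert sap.delta_pve == pytest.approx(0.1)

    def test_identical_pve_zero_increments(self):
        t = self.table([("A", s, 0.4) for s in ("sapling", "juvenile", "adult")])
        inc = pve_increments(t, ["sapling", "juvenile", "adult"], {})
        assert np.allclose(inc["delta_pve"], 0.0)

    def test_missing_stage_excluded(self):
        t = self.table([("A", "sapling", 0.2), ("A", "adult", 0.5)])
        inc = pve_increments(t, ["sapling", "juvenile", "adult"], {"A": "animal"})
        assert inc.empty
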