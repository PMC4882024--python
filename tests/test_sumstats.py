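import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemspat.cluster_null import ThomasParams, simulate_csr, simulate_thomas
from stemspat.plot_io import PlotWindow, PointPattern, RasterSurface
from stemspat.sumstats import (
    SummaryCurve, default_r_grid, envelope, gof_loosmore, pair_correlation,
    pair_correlation_inhom, ripley_K, ripley_disc_fraction,
)
from tests.conftest import constant_surface, csr


def brute_force_K(pattern: PointPattern, r_grid) -> np.ndarray:
    """Independent O(n^2) oracle for the uncorrected K estimator."""
    n = pattern.n
    out = np.zeros(len(r_grid))
    for k, r in enumerate(r_grid):
        count = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = np.hypot(pattern.x[i] - pattern.x[j],
                             pattern.y[i] - pattern.y[j])
                if d <= r:
                    count += 1
        out[k] = pattern.window.area / (n * (n - 1)) * count
    return out


class TestRipleyK:
    def test_two_points_at_unit_distance(self):
        # |W| / (n (n-1)) * pairs = 100 / 2 * 2
        p = PointPattern([4.0, 5.0], [5.0, 5.0], PlotWindow(10, 10))
        k = ripley_K(p, [0.0, 1.0], correction="none")
        assert k.values[1] == pytest.approx(100.0, abs=1e-10)

    def test_two_points_no_pairs_below_distance(self):
        p = PointPattern([4.0, 5.0], [5.0, 5.0], PlotWindow(10, 10))
        assert ripley_K(p, [0.0, 0.5], correction="none").values[1] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        w = PlotWindow(50, 50)
        for _ in range(3):
            p = csr(40, w, rng)
            r = np.linspace(0, 20, 9)
            k = ripley_K(p, r, correction="none")
            np.testing.assert_allclose(k.values, brute_force_K(p, r),
                                       atol=1e-10)

    @pytest.mark.parametrize("correction", ["none", "isotropic", "translation"])
    def test_monotone_nondecreasing(self, rng, correction):
        p = csr(80, PlotWindow(60, 60), rng)
        k = ripley_K(p, default_r_grid(25), correction=correction)
        assert np.all(np.diff(k.values) >= -1e-12)

    def test_csr_calibration_isotropic(self, rng):
        # Monte-Carlo vs the closed form K(10) = 100 pi
        w = PlotWindow(100, 100)
        vals = [ripley_K(csr(500, w, rng), [0.0, 10.0]).values[1]
                for _ in range(60)]
        assert np.mean(vals) == pytest.approx(np.pi * 100.0, rel=0.02)

    def test_single_point_rejected(self):
        p = PointPattern([1.0], [1.0], PlotWindow(10, 10))
        with pytest.raises(ValueError):
            ripley_K(p, [0, 1])


class TestRipleyDiscFraction:
    def test_interior_point_full_circle(self):
        w = PlotWindow(100, 100)
        assert ripley_disc_fraction(50.0, 50.0, 10.0, w) == pytest.approx(1.0)

    def test_point_at_corner_quarter_circle(self):
        w = PlotWindow(100, 100)
        assert ripley_disc_fraction(0.0, 0.0, 10.0, w) == pytest.approx(0.25)

    def test_point_on_edge_half_circle(self):
        w = PlotWindow(100, 100)
        assert ripley_disc_fraction(50.0, 0.0, 10.0, w) == pytest.approx(0.5)

    @given(x=st.floats(1, 99), y=st.floats(1, 99), t=st.floats(0.5, 40))
    @settings(max_examples=60, deadline=None)
    def test_matches_numeric_arc_integration(self, x, y, t):
        w = PlotWindow(100, 100)
        theta = np.linspace(0, 2 * np.pi, 20001)[:-1]
        inside = w.contains(x + t * np.cos(theta), y + t * np.sin(theta))
        assert ripley_disc_fraction(x, y, t, w) == pytest.approx(
            inside.mean(), abs=2e-3)


class TestPairCorrelation:
    def test_csr_near_one(self, rng):
        w = PlotWindow(100, 100)
        r = default_r_grid(20)
        sel = (r >= 5) & (r <= 20)
        means = np.mean(
            [pair_correlation(csr(600, w, rng), r).values[sel]
             for _ in range(20)], axis=0)
        assert np.all(np.abs(means - 1.0) < 0.1)

    def test_thomas_clustered_at_short_range(self, rng):
        params = ThomasParams(kappa=3e-4, sigma=5.0, mu=12.0)
        p = simulate_thomas(params, PlotWindow(200, 200), rng)
        g = pair_correlation(p, [0.0, 2.0], bandwidth=1.0)
        assert g.values[1] > 1.5

    def test_hard_core_zero_below_spacing(self, rng):
        # grid pattern with 3 m minimum spacing has no pairs near r = 1
        xs, ys = np.meshgrid(np.arange(1.0, 59, 3.0), np.arange(1.0, 59, 3.0))
        p = PointPattern(xs.ravel(), ys.ravel(), PlotWindow(60, 60))
        g = pair_correlation(p, [0.0, 1.0], bandwidth=0.8)
        assert g.values[1] == pytest.approx(0.0, abs=1e-12)

    def test_bad_bandwidth_rejected(self, rng):
        p = csr(50, PlotWindow(50, 50), rng)
        with pytest.raises(ValueError):
            pair_correlation(p, [0.0, 1.0], bandwidth=0.0)


class TestPairCorrelationInhom:
    def test_reduces_to_homogeneous_for_constant_intensity(self, rng):
        w = PlotWindow(80, 80)
        p = csr(200, w, rng)
        surf = constant_surface(p.n / w.area, w)
        r = default_r_grid(15)
        g_h = pair_correlation(p, r, bandwidth=2.0)
        g_i = pair_correlation_inhom(p, surf, r, bandwidth=2.0)
        np.testing.assert_allclose(g_i.values, g_h.values, atol=1e-10)

    def test_known_trend_calibrates_to_one(self, rng):
        # pattern simulated from a log-linear intensity, truth supplied
        w = PlotWindow(100, 100)
        nx = ny = 20
        gx = (np.arange(nx) + 0.5) * 5.0
        lam = np.tile(np.exp(0.02 * gx) / np.exp(1.0), (ny, 1)) * 0.06
        surf = RasterSurface(lam, 5.0, name="lam")
        r = default_r_grid(20)
        sel = (r >= 5) & (r <= 20)
        curves = []
        for _ in range(25):
            counts = rng.poisson(lam * 25.0)
            iy, ix = np.nonzero(counts)
            reps = counts[iy, ix]
            x = np.repeat(ix * 5.0, reps) + rng.uniform(0, 5, reps.sum())
            y = np.repeat(iy * 5.0, reps) + rng.uniform(0, 5, reps.sum())
            p = PointPattern(x, y, w)
            curves.append(pair_correlation_inhom(p, surf, r, bandwidth=2.0).values)
        mean = np.mean(curves, axis=0)
        assert np.all(np.abs(mean[sel] - 1.0) < 0.12)

    def test_zero_intensity_at_point_raises(self, rng):
        w = PlotWindow(50, 50)
        p = csr(20, w, rng)
        surf = constant_surface(0.0, w)
        with pytest.raises(ValueError, match="intensity"):
            pair_correlation_inhom(p, surf, [0.0, 5.0], bandwidth=1.0)

    def test_trend_plus_cluster_keeps_residual_clustering(self, rng):
        w = PlotWindow(200, 200)
        p = simulate_thomas(ThomasParams(3e-4, 5.0, 12.0), w, rng)
        surf = constant_surface(p.n / w.area, w)
        g = pair_correlation_inhom(p, surf, [0.0, 2.0], bandwidth=1.0)
        assert g.values[1] > 1.5


def make_curves(rng, n_sim, base=0.0, spread=1.0, r=None):
    r = default_r_grid(10) if r is None else r
    return [SummaryCurve(r, base + spread * rng.normal(size=len(r)))
            for _ in range(n_sim)]


class TestEnvelope:
    def test_median_curve_not_significant(self, rng):
        sims = make_curves(rng, 199)
        med = SummaryCurve(sims[0].r,
                           np.median([c.values for c in sims], axis=0))
        res = envelope(med, sims, level=0.95, scale_range=(0, 10))
        assert not res.significant

    def test_curve_above_all_sims_significant(self, rng):
        sims = make_curves(rng, 199)
        top = SummaryCurve(sims[0].r,
                           np.max([c.values for c in sims], axis=0) + 1.0)
        res = envelope(top, sims, level=0.95, scale_range=(0, 10))
        assert res.significant and res.exceeds_above.sum() > 0

    def test_bound_orders(self, rng):
        sims = make_curves(rng, 199)
        res = envelope(sims[0], sims[1:] + sims[:1], level=0.95)
        assert np.all(res.lower <= res.upper)

    def test_rank_indices_199_at_95(self, rng):
        # 5th lowest / 5th highest for 199 sims at 95%
        r = np.array([0.0, 1.0])
        sims = [SummaryCurve(r, np.array([0.0, float(v)]))
                for v in range(1, 200)]
        res = envelope(SummaryCurve(r, np.array([0.0, 100.0])), sims,
                       level=0.95)
        assert res.lower[1] == 5.0 and res.upper[1] == 195.0

    def test_too_few_sims_rejected(self, rng):
        sims = make_curves(rng, 19)
        with pytest.raises(ValueError, match="too few"):
            envelope(sims[0], sims[1:], level=0.95)

    def test_mismatched_grids_rejected(self, rng):
        a = SummaryCurve(np.array([0.0, 1.0]), np.zeros(2))
        b = SummaryCurve(np.array([0.0, 2.0]), np.zeros(2))
        with pytest.raises(ValueError, match="grid"):
            envelope(a, [b], level=0.95)

    def test_exceedance_rate_calibrated(self, rng):
        # one-sided exceedance on one fixed r across replicates: the rank
        # bound with m = 5 of 199 gives a 2.5% one-sided level
        hits = 0
        n_rep = 250
        for _ in range(n_rep):
            vals = rng.normal(size=200)
            obs, sims = vals[0], np.sort(vals[1:])
            hits += obs > sims[-5]
        rate = hits / n_rep
        se = np.sqrt(0.025 * 0.975 / n_rep)
        assert abs(rate - 0.025) < 3 * se + 1e-9


class TestGof:
    def test_observed_at_mean_gives_p_near_one(self, rng):
        r = default_r_grid(10)
        sims = make_curves(rng, 99, r=r)
        mean = SummaryCurve(r, np.mean([c.values for c in sims], axis=0))
        res = gof_loosmore(mean, sims, (0.5, 10.0))
        assert res.u_obs < np.percentile(res.u_sims, 10)
        assert res.p_value > 0.9

    def test_extreme_observed_gives_min_p(self, rng):
        r = default_r_grid(10)
        sims = make_curves(rng, 99, r=r)
        far = SummaryCurve(r, np.full(len(r), 50.0))
        res = gof_loosmore(far, sims, (0.5, 10.0))
        assert res.p_value == pytest.approx(1.0 / 100.0)

    def test_p_value_formula(self, rng):
        r = default_r_grid(5)
        sims = make_curves(rng, 39, r=r)
        res = gof_loosmore(sims[0], sims[1:] + [sims[0]], (0.5, 5.0))
        expected = (1 + np.sum(res.u_sims >= res.u_obs)) / 40.0
        assert res.p_value == pytest.approx(expected)

    def test_null_p_values_roughly_uniform(self, rng):
        # calibration: p for a null observation is uniform on the achievable
        # grid; check the empirical CDF against uniform
        from scipy.stats import kstest

        pvals = []
        r = default_r_grid(5)
        for _ in range(150):
            curves = make_curves(rng, 40, r=r)
            res = gof_loosmore(curves[0], curves[1:], (0.5, 5.0))
            pvals.append(res.p_value)
        assert kstest(pvals, "uniform").statistic < 0.12

    def test_range_outside_grid_rejected(self, rng):
        sims = make_curves(rng, 39)
        with pytest.raises(ValueError, match="range"):
            gof_loosmore(sims[0], sims[1:], (0.0, 50.0))
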