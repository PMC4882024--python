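import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemspat.plot_io import PlotWindow, RasterSurface
from stemspat.terrain import (
    HABITATS, VariogramModel, classify_habitats, empirical_semivariogram,
    fit_variogram, krige_block, pca_environment, quadrat_topography,
)


def posts_from(f, nx, ny, spacing=20.0):
    x = np.arange(nx + 1) * spacing
    y = np.arange(ny + 1) * spacing
    gx, gy = np.meshgrid(x, y)
    return f(gx, gy)


class TestQuadratTopography:
    def test_horizontal_plane(self):
        topo = quadrat_topography(posts_from(lambda x, y: 0 * x + 42.0, 6, 4))
        assert np.allclose(topo["mean_elev"], 42.0)
        assert np.allclose(topo["slope"], 0.0)
        assert np.allclose(topo["convexity"], 0.0)

    def test_tilted_plane(self):
        # analytic plane geometry: z = 0.1 x has tilt arctan(0.1) everywhere
        topo = quadrat_topography(posts_from(lambda x, y: 0.1 * x, 6, 4))
        assert np.allclose(topo["slope"], np.degrees(np.arctan(0.1)), atol=1e-9)
        interior = topo[(topo.ix > 0) & (topo.ix < 5) & (topo.iy > 0) & (topo.iy < 3)]
        assert np.allclose(interior["convexity"], 0.0, atol=1e-9)

    def test_gaussian_hill_convexity_signs(self):
        # direct evaluation on a synthetic hill centred mid-plot
        def hill(x, y):
            return 50.0 * np.exp(-((x - 100) ** 2 + (y - 100) ** 2) / (2 * 40.0 ** 2))

        topo = quadrat_topography(posts_from(hill, 10, 10))
        apex = topo[(topo.ix == 4) & (topo.iy == 4)].iloc[0]
        assert apex.convexity > 0
        foot = topo[(topo.ix == 1) & (topo.iy == 4)].iloc[0]
        assert foot.convexity < 0

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            quadrat_topography(np.zeros(5))
        with pytest.raises(ValueError):
            quadrat_topography(np.zeros((1, 5)))


class TestClassifyHabitats:
    def topo_row(self, conv, elev):
        return pd.DataFrame({"ix": [0], "iy": [0], "mean_elev": [elev],
                             "convexity": [conv], "slope": [5.0]})

    @pytest.mark.parametrize("conv, elev, expected", [
        (-2.5, 430.0, "low_valley"),
        (-2.0, 500.0, "high_slope"),   # -2 boundary belongs to slope
        (1.99, 430.0, "low_slope"),
        (2.0, 430.0, "low_ridge"),     # 2 boundary belongs to ridge
        (3.0, 450.0, "high_ridge"),    # 450 boundary belongs to high
        (3.0, 449.99, "low_ridge"),
    ])
    def test_rules(self, conv, elev, expected):
        hmap = classify_habitats(self.topo_row(conv, elev))
        assert hmap.labels[0, 0] == expected

    def test_disturbed_mask_overrides(self):
        hmap = classify_habitats(self.topo_row(3.0, 600.0),
                                 disturbed_mask={(0, 0)})
        assert hmap.labels[0, 0] == "disturbed"

    @given(conv=st.floats(-10, 10), elev=st.floats(300, 600))
    @settings(max_examples=100, deadline=None)
    def test_total_and_idempotent(self, conv, elev):
        topo = self.topo_row(conv, elev)
        first = classify_habitats(topo).labels[0, 0]
        second = classify_habitats(topo).labels[0, 0]
        assert first == second and first in HABITATS

    def test_label_counts_sum_to_quadrat_count(self, small_habitat_map):
        assert sum(small_habitat_map.counts().values()) == (
            small_habitat_map.shape[0] * small_habitat_map.shape[1])


class TestSemivariogram:
    def test_constant_field_zero(self, rng):
        xy = rng.uniform(0, 100, (40, 2))
        emp = empirical_semivariogram(xy, np.full(40, 3.0),
                                      np.linspace(0, 100, 6))
        ok = emp[emp.n_pairs > 0]
        assert np.allclose(ok["gamma"], 0.0)

    def test_two_samples_single_bin(self):
        # derived: 0.5 * (2 - 0)^2 = 2
        emp = empirical_semivariogram(np.array([[0.0, 0.0], [10.0, 0.0]]),
                                      np.array([0.0, 2.0]),
                                      np.array([0.0, 20.0]))
        assert emp.loc[0, "gamma"] == pytest.approx(2.0)
        assert emp.loc[0, "n_pairs"] == 1

    def test_white_noise_flat_at_field_variance(self, rng):
        # Monte-Carlo: all bins should sit near the marginal variance
        xy = rng.uniform(0, 100, (400, 2))
        z = rng.normal(0, 2.0, 400)
        emp = empirical_semivariogram(xy, z, np.linspace(0, 80, 9))
        ok = emp[emp.n_pairs > 200]
        # pairs share samples, so allow a generous band around the variance
        assert np.all(np.abs(ok["gamma"] - 4.0) < 1.2)

    def test_empty_bins_reported(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0]])
        emp = empirical_semivariogram(xy, np.array([0.0, 1.0]),
                                      np.array([0.0, 0.5, 2.0]))
        assert emp.loc[0, "n_pairs"] == 0 and np.isnan(emp.loc[0, "gamma"])


class TestKriging:
    def make_model(self):
        return VariogramModel(nugget=0.0, psill=4.0, range=30.0)

    def test_constant_samples_give_constant_surface(self, rng):
        xy = rng.uniform(0, 50, (40, 2))
        surf = krige_block(xy, np.full(40, 5.5), self.make_model(),
                           PlotWindow(50, 50))
        np.testing.assert_allclose(surf.values, 5.5, atol=1e-8)

    def test_exact_interpolation_at_isolated_sample(self, rng):
        xy = np.vstack([rng.uniform(0, 20, (20, 2)),
                        [[42.5, 42.5]]])  # lone sample in its own cell
        vals = np.concatenate([np.zeros(20), [9.0]])
        # sub=1 evaluates the block at its centre, where the sample sits:
        # with zero nugget ordinary kriging interpolates exactly there
        surf = krige_block(xy, vals, self.make_model(), PlotWindow(50, 50),
                           sub=1)
        assert surf.value_at(42.5, 42.5) == pytest.approx(9.0, abs=1e-6)

    def test_leave_one_out_beats_field_sd(self, rng):
        # cross-validation oracle on a smooth synthetic field
        xy = rng.uniform(0, 100, (120, 2))
        z = np.sin(xy[:, 0] / 25.0) + np.cos(xy[:, 1] / 20.0)
        errs = []
        for i in range(0, 120, 6):
            keep = np.ones(120, bool)
            keep[i] = False
            surf = krige_block(xy[keep], z[keep], self.make_model(),
                               PlotWindow(100, 100))
            errs.append(surf.value_at(*xy[i]) - z[i])
        assert np.sqrt(np.mean(np.square(errs))) < z.std()

    def test_weights_sum_to_one_via_mean_shift(self, rng):
        # adding c to every sample shifts every prediction by exactly c
        xy = rng.uniform(0, 50, (30, 2))
        z = rng.normal(size=30)
        m = self.make_model()
        s1 = krige_block(xy, z, m, PlotWindow(50, 50))
        s2 = krige_block(xy, z + 10.0, m, PlotWindow(50, 50))
        np.testing.assert_allclose(s2.values - s1.values, 10.0, atol=1e-8)

    def test_fit_variogram_recovers_shape(self, rng):
        model = VariogramModel(nugget=0.5, psill=3.0, range=20.0)
        lags = np.linspace(0, 80, 17)
        mid = 0.5 * (lags[:-1] + lags[1:])
        emp = pd.DataFrame({"lag": mid, "gamma": model(mid),
                            "n_pairs": np.full(16, 200)})
        fitted = fit_variogram(emp)
        assert fitted.sill == pytest.approx(model.sill, rel=0.05)
        assert fitted.range == pytest.approx(20.0, rel=0.2)


class TestPCA:
    def test_uncorrelated_unit_fields_symmetric(self, rng):
        surfaces = [RasterSurface(rng.normal(size=(30, 30)), 5.0, name=f"v{i}")
                    for i in range(7)]
        env = pca_environment(surfaces)
        assert np.all(np.abs(env.explained_variance - 1.0) < 0.35)
        assert env.explained_variance.sum() == pytest.approx(7.0, abs=1e-8)

    def test_components_pairwise_uncorrelated(self, small_env):
        mat = small_env.component_matrix()
        corr = np.corrcoef(mat.T)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.all(np.abs(off) < 1e-8)

    def test_variance_conserved(self, small_env):
        assert small_env.explained_variance.sum() == pytest.approx(
            len(small_env.variable_names), abs=1e-8)

    def test_duplicated_variable_loads_equally(self, rng):
        # derived from the eigen-decomposition of the known correlation matrix
        base = rng.normal(size=(25, 25))
        surfaces = [
            RasterSurface(base, 5.0, name="A"),
            RasterSurface(base.copy(), 5.0, name="B"),
            RasterSurface(rng.normal(size=(25, 25)), 5.0, name="C"),
        ]
        env = pca_environment(surfaces)
        la, lb = env.loadings[0, 0], env.loadings[1, 0]
        assert abs(abs(la) - abs(lb)) < 1e-8
        assert env.explained_variance[0] >= 2.0 - 1e-8

    def test_constant_variable_dropped(self, rng):
        surfaces = [
            RasterSurface(rng.normal(size=(20, 20)), 5.0, name="A"),
            RasterSurface(np.full((20, 20), 3.0), 5.0, name="flat"),
        ]
        env = pca_environment(surfaces)
        assert env.variable_names == ["A"]
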