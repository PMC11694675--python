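"""Joint model of key ASVs vs temperature: transforms, augmentation, MCMC."""

import numpy as np
import pytest

from holomap.grid import EnvGridStack
from holomap.jsdm import (JSDMInput, JSDMFit, augment_locations,
                          convergence_psrf, cross_validate, dummy_transform,
                          explanatory_predictive_ratio, fit_jsdm,
                          optimal_temperature, spatial_predict, tjur_r2)


class TestDummyTransform:
    @pytest.mark.parametrize("rel,expected", [
        (0.235, 24), (0.0, 0), (0.005, 1), (1.0, 100),
    ])
    def test_rounding(self, rel, expected):
        assert dummy_transform(rel) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dummy_transform(1.2)

    def test_inverse_renormalization_bound(self, rng):
        comp = rng.dirichlet(np.ones(10))
        scale = 100
        dummy = dummy_transform(comp, scale)
        assert np.all(np.abs(dummy / scale - comp) <= 0.5 / scale + 1e-12)


def _temp_grid(temps_2d, cell=0.088):
    temps_2d = np.asarray(temps_2d, dtype=float)
    nlat, nlon = temps_2d.shape
    lat = 44.0 + np.arange(nlat) * cell
    lon = -62.0 + np.arange(nlon) * cell
    dyn_names = ("bottom_temperature", "bottom_salinity", "bottom_velocity",
                 "bottom_stress", "max_mld", "surface_temperature",
                 "surface_salinity")
    dynamic = {n: np.ones((1, nlat, nlon)) for n in dyn_names}
    dynamic["bottom_temperature"] = temps_2d[None]
    return EnvGridStack(lat=lat, lon=lon, timeframes=("t",),
                        static={"depth": np.full((nlat, nlon), 100.0),
                                "slope": np.zeros((nlat, nlon))},
                        dynamic=dynamic, cell_size=cell)


class TestAugmentation:
    def _sampled(self, grid, cells, temps):
        nlon = len(grid.lon)
        return JSDMInput(
            lat=grid.lat[np.asarray(cells) // nlon],
            lon=grid.lon[np.asarray(cells) % nlon],
            temperature=np.asarray(temps, dtype=float),
            counts=np.arange(len(cells) * 3).reshape(len(cells), 3),
            asvs=("ASV1", "ASV2", "ASV3"))

    def test_four_plus_eighteen_gives_22(self):
        # 4 sampled cells at two temperature categories; exactly 18 other
        # present cells carry a matching two-decimal temperature
        temps = np.full((5, 8), 3.0)
        temps[0, :4] = [7.31, 7.31, 7.52, 7.52]       # sampled cells
        temps.ravel()[8:8 + 10] = 7.31
        temps.ravel()[20:20 + 8] = 7.52
        grid = _temp_grid(temps)
        sampled = self._sampled(grid, [0, 1, 2, 3], temps.ravel()[:4])
        present = np.ones((5, 8))
        out = augment_locations(sampled, grid, "t", present)
        assert out.n_locations == 22
        assert (out.provenance == "augmented").sum() == 18

    def test_no_match_keeps_sampled_only(self):
        temps = np.full((3, 3), 3.0)
        temps[0, 0] = 7.31
        grid = _temp_grid(temps)
        sampled = self._sampled(grid, [0], [7.31])
        out = augment_locations(sampled, grid, "t", np.ones((3, 3)))
        assert out.n_locations == 1

    def test_augmented_rows_equal_category_mean_and_sampled_unchanged(self):
        temps = np.full((4, 4), 3.0)
        temps[0, 0] = temps[0, 1] = 7.31
        temps[2, 2] = temps[2, 3] = 7.31
        grid = _temp_grid(temps)
        sampled = self._sampled(grid, [0, 1], [7.31, 7.31])
        out = augment_locations(sampled, grid, "t", np.ones((4, 4)))
        np.testing.assert_array_equal(out.counts[:2], sampled.counts)
        cat_mean = np.rint(sampled.counts.mean(axis=0)).astype(int)
        for row in out.counts[2:]:
            np.testing.assert_array_equal(row, cat_mean)


class TestPsrf:
    def _fit_from_draws(self, draws):
        c, s, k = draws.shape
        return JSDMFit(beta=draws.reshape(c, s, k, 1),
                       loadings=np.zeros((c, s, 1)),
                       eta=np.zeros((c, s, 2)), asvs=("a",),
                       t_mean=0.0, t_sd=1.0, quadratic=False, input=None)

    def test_identical_chains_near_one(self, rng):
        one = rng.standard_normal((1, 400, 3))
        draws = np.concatenate([one, one], axis=0)
        psrf = convergence_psrf(self._fit_from_draws(draws))
        assert psrf["mean"] == pytest.approx(1.0, abs=0.02)

    def test_disjoint_chains_much_larger_than_one(self, rng):
        a = rng.standard_normal((1, 400, 3))
        b = rng.standard_normal((1, 400, 3)) + 50.0
        psrf = convergence_psrf(self._fit_from_draws(np.concatenate([a, b])))
        assert psrf["mean"] > 5.0

    def test_matches_arviz_on_stored_draws(self, rng):
        az = pytest.importorskip("arviz")
        draws = rng.standard_normal((2, 500, 4)) \
            + rng.standard_normal((2, 1, 4))  # chain-level offsets
        ours = convergence_psrf(self._fit_from_draws(draws))["per_parameter"]
        # arviz rank-normalizes by default; classic split-Rhat for parity
        ref = np.array([float(az.rhat(draws[:, :, k], method="split"))
                        for k in range(4)])
        np.testing.assert_allclose(ours, ref, atol=0.01)

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            convergence_psrf(self._fit_from_draws(
                rng.standard_normal((1, 100, 2))))


class TestTjur:
    def test_perfect_prediction(self):
        assert tjur_r2([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0

    def test_constant_prediction(self):
        assert tjur_r2([0.4] * 6, [1, 0, 1, 0, 1, 0]) == 0.0

    def test_equals_two_group_means(self, rng):
        p = rng.random(50)
        o = rng.integers(0, 2, 50)
        o[:2] = [0, 1]
        assert tjur_r2(p, o) == pytest.approx(p[o == 1].mean()
                                              - p[o == 0].mean())

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tjur_r2([0.5, 0.6], [1, 1])


class TestRatios:
    def test_printed_ratio_example(self):
        df = explanatory_predictive_ratio([0.6], [0.5], ["a"])
        assert df["ratio"].iloc[0] == pytest.approx(1.2)

    def test_nonpositive_predictive_excluded(self):
        df = explanatory_predictive_ratio([0.6, 0.5], [0.0, -0.2],
                                          ["a", "b"])
        assert df["ratio"].isna().all()

    def test_ranking_matches_sort(self, rng):
        e = rng.random(10)
        p = rng.random(10) - 0.2
        df = explanatory_predictive_ratio(e, p, [f"a{i}" for i in range(10)])
        ok = (e > 0) & (p > 0)
        expected = np.sort((e / p)[ok])
        np.testing.assert_allclose(df["ratio"].dropna().values, expected)


def _toy_data(seed=42, n=40, slopes=None):
    """Poisson responses with known per-ASV Gaussian temperature niches."""
    rng = np.random.default_rng(seed)
    T = rng.uniform(6.2, 8.2, n)
    base = np.array([0.25, 0.22, 0.2, 0.18, 0.15])
    opts = np.array([7.5, 7.7, 6.0, 9.0, 7.0])
    widths = np.array([0.6, 0.6, 5.0, 5.0, 6.0])
    comp = base[None] * np.exp(-(T[:, None] - opts[None]) ** 2
                               / (2 * widths[None] ** 2))
    comp /= comp.sum(1, keepdims=True)
    y = np.vstack([rng.poisson(dummy_transform(c, 100)) for c in comp])
    data = JSDMInput(lat=44 + rng.uniform(0, 1, n),
                     lon=-62 + rng.uniform(0, 1, n),
                     temperature=T, counts=y,
                     asvs=tuple(f"ASV{i + 1}" for i in range(5)))
    return data, comp


class TestFit:
    def test_fixed_seed_identical_posteriors(self):
        data, _ = _toy_data()
        f1 = fit_jsdm(data, samples=80, warmup=80, seed=5,
                      compute_diagnostics=False)
        f2 = fit_jsdm(data, samples=80, warmup=80, seed=5,
                      compute_diagnostics=False)
        np.testing.assert_array_equal(f1.beta, f2.beta)

    def test_slope_signs_recovered_for_detectable_asvs(self):
        data, comp = _toy_data()
        fit = fit_jsdm(data, samples=400, warmup=400, seed=5,
                       compute_diagnostics=False)
        b1 = fit.beta[:, :, 1, :].reshape(-1, 5).mean(axis=0)
        # ground-truth standardized log-share slopes per ASV
        ts = (data.temperature - fit.t_mean) / fit.t_sd
        for j in range(5):
            true_slope = np.polyfit(ts, np.log(comp[:, j]), 1)[0]
            if abs(true_slope) > 0.15:      # detectability bound
                assert np.sign(b1[j]) == np.sign(true_slope)

    def test_null_slope_credible_interval_covers_zero(self):
        # flat-composition data: temperature slopes are zero
        rng = np.random.default_rng(1)
        n = 30
        y = rng.poisson(25.0, size=(n, 4))
        data = JSDMInput(lat=44 + rng.uniform(0, 1, n),
                         lon=-62 + rng.uniform(0, 1, n),
                         temperature=rng.uniform(6.2, 8.2, n), counts=y,
                         asvs=("a", "b", "c", "d"))
        fit = fit_jsdm(data, samples=400, warmup=400, seed=2,
                       compute_diagnostics=False)
        b1 = fit.beta[:, :, 1, :].reshape(-1, 4)
        lo, hi = np.percentile(b1, [2.5, 97.5], axis=0)
        assert ((lo <= 0) & (0 <= hi)).sum() >= 3  # >=3 of 4 cover zero

    def test_non_integer_responses_rejected(self):
        with pytest.raises(ValueError):
            JSDMInput(lat=[44.0, 44.1], lon=[-62.0, -62.1],
                      temperature=[7.0, 7.5],
                      counts=np.array([[0.5, 1.0], [1.0, 2.0]]),
                      asvs=("a", "b"))


@pytest.fixture(scope="module")
def quad_fit():
    data, _ = _toy_data(n=100)
    return fit_jsdm(data, samples=800, warmup=800, seed=3,
                    quadratic=True, compute_diagnostics=False)


class TestPredictions:

    def test_shares_sum_to_100_per_cell(self, quad_fit):
        temps = np.full((4, 5), 7.0)
        temps[0, 0] = 3.0  # outside window
        grid = _temp_grid(temps)
        out = spatial_predict(quad_fit, grid, "t", np.ones((4, 5)))
        stack = np.stack(list(out.values()))
        sums = stack.sum(axis=0)
        inside = np.isfinite(sums)
        assert np.allclose(sums[inside], 100.0)
        assert not inside[0, 0]

    def test_optimum_recovery_within_tolerance(self, quad_fit):
        # compare against the true share-curve optima of the generating
        # community (the renormalized composition peaks near the configured
        # 7.5 / 7.7 deg C numerator optima)
        t_opt1, interior1 = optimal_temperature(quad_fit, "ASV1")
        t_opt2, interior2 = optimal_temperature(quad_fit, "ASV2")
        assert interior1 and interior2
        assert t_opt1 == pytest.approx(7.42, abs=0.2)
        assert t_opt2 == pytest.approx(7.79, abs=0.2)
        assert t_opt2 > t_opt1

    def test_grid_refinement_stable(self, quad_fit):
        a, _ = optimal_temperature(quad_fit, "ASV1", step=0.01)
        b, _ = optimal_temperature(quad_fit, "ASV1", step=0.002)
        assert a == pytest.approx(b, abs=0.011)

    def test_monotone_linear_share_flags_boundary(self):
        rng = np.random.default_rng(3)
        n = 30
        T = rng.uniform(6.2, 8.2, n)
        lam = np.exp(np.column_stack([3 + 0.8 * (T - 7), 3 - 0.8 * (T - 7)]))
        y = rng.poisson(lam)
        data = JSDMInput(lat=44 + rng.uniform(0, 1, n),
                         lon=-62 + rng.uniform(0, 1, n), temperature=T,
                         counts=y, asvs=("up", "down"))
        fit = fit_jsdm(data, samples=300, warmup=300, seed=4,
                       compute_diagnostics=False)
        t_up, interior = optimal_temperature(fit, "up")
        assert not interior
        assert t_up == pytest.approx(8.2, abs=0.05)


def test_cross_validation_predictive_r2(rng):
    data, _ = _toy_data(n=60)
    r2 = cross_validate(data, folds=2, seed=8, samples=200, warmup=200,
                        quadratic=True)
    assert r2.shape == (5,)
    # the two sharply temperature-driven ASVs are predictable out of fold
    assert r2[0] > 0.2 and r2[1] > 0.2
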