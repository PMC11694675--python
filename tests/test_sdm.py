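"""Occurrence gridding, pseudo-absences, RF fitting, thresholds, metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holomap.grid import PRESENT
from holomap.sdm import (ConfusionMatrix, add_pseudo_absences, auc,
                         binary_map, confusion_metrics, cross_validate_sdm,
                         fit_rf, grid_records, mss_threshold, project,
                         response_curves, spatial_block_cv)


class TestGridRecords:
    def test_presence_wins_and_deduplicates(self, masked_grid):
        lat0 = masked_grid.lat[10]
        lon0 = masked_grid.lon[20]
        raw = pd.DataFrame({
            "species": ["a"] * 3,
            "lat": [lat0, lat0 + 0.01, lat0],
            "lon": [lon0, lon0 - 0.01, lon0],
            "presence": [1, 1, 0],
            "source": ["observed"] * 3,
        })
        out = grid_records(raw, masked_grid)
        assert len(out) == 1
        assert out.iloc[0]["presence"] == 1
        assert out.iloc[0]["lat"] == pytest.approx(lat0)

    def test_cell_counts_match_brute_force(self, records, masked_grid,
                                           gridded):
        flat = masked_grid.flat_index(records["lat"].values,
                                      records["lon"].values)
        ok = (flat >= 0) & masked_grid.mask.ravel()[np.maximum(flat, 0)]
        expected = (records.loc[ok].assign(cell=flat[ok])
                    .groupby("species")["cell"].nunique())
        got = gridded.groupby("species")["cell"].count()
        pd.testing.assert_series_equal(got, expected, check_names=False)


class TestPseudoAbsences:
    def test_union_of_cells_identical_across_species(self, gridded,
                                                     sdm_records):
        union = set(gridded["cell"])
        for sp, sub in sdm_records.groupby("species"):
            assert set(sub["cell"]) == union
            assert sub["cell"].is_unique

    def test_observed_records_never_overwritten(self, gridded, sdm_records):
        merged = sdm_records.merge(gridded, on=["species", "cell"],
                                   suffixes=("", "_obs"))
        assert (merged["presence"] == merged["presence_obs"]).all()
        assert (merged["source"] == merged["source_obs"]).all()

    def test_idempotent(self, sdm_records):
        again = add_pseudo_absences(sdm_records)
        a = sdm_records.sort_values(["species", "cell"]).reset_index(drop=True)
        b = again.sort_values(["species", "cell"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b[a.columns], check_dtype=False)

    def test_disjoint_species_end_with_union(self):
        rows = []
        for k, sp in enumerate("abc"):
            rows.append({"species": sp, "lat": 45.0, "lon": -60.0 - k,
                         "presence": 1, "source": "observed", "cell": k})
        out = add_pseudo_absences(pd.DataFrame(rows))
        assert (out.groupby("species")["cell"].count() == 3).all()
        assert (out["source"] == "pseudo-absence").sum() == 6


class TestSpatialBlockCV:
    def test_partition_properties(self, sdm_records, masked_grid):
        sub = (sdm_records[sdm_records["species"] == "W. bursa"]
               .reset_index(drop=True))
        folds = spatial_block_cv(sub, masked_grid, k=5, block_size_cells=5)
        assert len(folds) == len(sub)
        assert set(folds) == set(range(5))
        # records of one spatial block never straddle folds
        nlon = len(masked_grid.lon)
        bi = (sub["cell"] // nlon) // 5
        bj = (sub["cell"] % nlon) // 5
        df = pd.DataFrame({"b": bi * 1000 + bj, "fold": folds})
        assert (df.groupby("b")["fold"].nunique() == 1).all()

    def test_separated_clusters_one_per_fold(self, masked_grid):
        nlon = len(masked_grid.lon)
        rows = []
        for c, (i0, j0) in enumerate([(0, 0), (0, 20), (10, 0), (10, 20),
                                      (20, 10)]):
            for k in range(4):
                rows.append({"species": "a", "presence": k % 2,
                             "source": "observed",
                             "cell": (i0 + k % 2) * nlon + j0 + k // 2,
                             "lat": 0.0, "lon": 0.0})
        sub = pd.DataFrame(rows)
        folds = spatial_block_cv(sub, masked_grid, k=5, block_size_cells=5)
        df = pd.DataFrame({"cluster": np.repeat(np.arange(5), 4),
                           "fold": folds})
        assert (df.groupby("cluster")["fold"].nunique() == 1).all()
        assert len(set(folds)) == 5

    def test_too_few_blocks_rejected(self, masked_grid):
        sub = pd.DataFrame({"species": "a", "presence": [1, 0],
                            "source": "o", "cell": [0, 1],
                            "lat": 0.0, "lon": 0.0})
        with pytest.raises(ValueError, match="blocks"):
            spatial_block_cv(sub, masked_grid, k=5, block_size_cells=10)


class TestAUC:
    def test_separable(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        scores = np.round(rng.random(n), 2)  # ties likely
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        oracle = wins / (len(pos) * len(neg))
        assert auc(scores, labels) == pytest.approx(oracle)


class TestMSS:
    def test_clean_separation(self):
        thr = mss_threshold([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1])
        assert thr == pytest.approx(0.5)
        pred = np.array([0.1, 0.4, 0.6, 0.9]) >= thr
        cm = ConfusionMatrix.from_predictions(pred, [0, 0, 1, 1])
        m = confusion_metrics(cm)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_interleaved_degenerate_returns_smallest_candidate(self):
        thr = mss_threshold([0.1, 0.2, 0.3, 0.4], [1, 0, 1, 0])
        assert thr == 0.0  # sens+spec = 1 everywhere; smallest candidate

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_maximizes_against_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(30), 2)
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        thr = mss_threshold(scores, labels)

        def total(t):
            pred = scores >= t
            cm = ConfusionMatrix.from_predictions(pred, labels)
            m = confusion_metrics(cm)
            return m["sensitivity"] + m["specificity"]

        best = max(total(t) for t in np.linspace(0, 1, 2001))
        assert total(thr) == pytest.approx(best, abs=1e-9)


class TestConfusionMetrics:
    @pytest.mark.parametrize("cm,tss", [
        (ConfusionMatrix(10, 0, 10, 0), 1.0),
        (ConfusionMatrix(8, 3, 7, 2), 0.8 + 0.7 - 1.0),
    ])
    def test_tss_identity(self, cm, tss):
        m = confusion_metrics(cm)
        assert m["tss"] == pytest.approx(m["sensitivity"]
                                         + m["specificity"] - 1.0)
        assert m["tss"] == pytest.approx(tss)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionMatrix(0, 3, 4, 0))


class TestRandomForest:
    def test_separable_training_auc_is_one(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (40, 9)),
                       rng.normal(3, 0.3, (40, 9))])
        y = np.repeat([0, 1], 40)
        model = fit_rf(X, y, n_trees=100, seed=0)
        scores = model.predict_proba(X)[:, 1]
        assert auc(scores, y) == 1.0

    def test_single_class_fold_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            fit_rf(rng.normal(size=(10, 9)), np.ones(10, dtype=int))

    def test_fixed_seed_identical_predictions(self, rng):
        X = rng.normal(size=(60, 9))
        y = (X[:, 0] > 0).astype(int)
        Xnew = rng.normal(size=(20, 9))
        p1 = fit_rf(X, y, n_trees=50, seed=4).predict_proba(Xnew)
        p2 = fit_rf(X, y, n_trees=50, seed=4).predict_proba(Xnew)
        np.testing.assert_array_equal(p1, p2)


class TestProjection:
    def test_mean_equals_manual_average_and_sd_bounds(self, vaz_sdm,
                                                      masked_grid):
        mean, sd = project(vaz_sdm, masked_grid, PRESENT)
        cells = np.flatnonzero(masked_grid.mask.ravel())
        X = masked_grid.covariate_matrix(PRESENT, cells=cells)
        manual = np.mean([m.predict_proba(X)[:, 1] for m in vaz_sdm.models],
                         axis=0)
        np.testing.assert_allclose(mean.ravel()[cells], manual)
        valid = np.isfinite(sd)
        assert (sd[valid] >= 0).all() and (sd[valid] <= 0.5).all()
        assert np.isnan(mean[~masked_grid.mask]).all()

    def test_identical_models_zero_sd(self, vaz_sdm, masked_grid):
        from dataclasses import replace
        clone = replace(vaz_sdm, models=[vaz_sdm.models[0]] * 5)
        _, sd = project(clone, masked_grid, PRESENT)
        assert np.nanmax(sd) == pytest.approx(0.0, abs=1e-12)

    def test_binary_map_boundary_and_monotonicity(self, vaz_sdm, masked_grid):
        mean, _ = project(vaz_sdm, masked_grid, PRESENT)
        thr = 0.4
        b = binary_map(mean, thr)
        cell = np.unravel_index(np.nanargmax(mean == thr), mean.shape) \
            if np.any(mean == thr) else None
        if cell:
            assert b[cell] == 1  # boundary inclusive
        areas = [np.nansum(binary_map(mean, t))
                 for t in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(a >= b_ for a, b_ in zip(areas, areas[1:]))
        assert areas[0] == masked_grid.mask.sum()

    def test_threshold_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            binary_map(np.array([0.5]), 1.5)


class TestResponseCurves:
    def test_curve_in_unit_interval_and_niche_peak(self, vaz_sdm, sdm_records,
                                                   masked_grid):
        sub = (sdm_records[sdm_records["species"] == "V. pourtalesii"]
               .reset_index(drop=True))
        X = masked_grid.covariate_matrix(PRESENT, cells=sub["cell"].values)
        grid_vals, curve = response_curves(vaz_sdm, X, "bottom_temperature")
        assert ((curve >= 0) & (curve <= 1)).all()
        # the simulated thermal optimum sits at 7.4 deg C
        assert grid_vals[int(np.argmax(curve))] == pytest.approx(7.4, abs=1.2)


class TestCrossValidatedModel:
    def test_fold_auc_high_for_separated_niche(self, vaz_sdm):
        assert vaz_sdm.auc_mean > 0.8
        assert vaz_sdm.threshold > 0.0
        m = vaz_sdm.metrics
        assert m["tss"] == pytest.approx(m["sensitivity"]
                                         + m["specificity"] - 1.0)

    def test_importance_is_a_normalized_profile(self, vaz_sdm):
        imp = vaz_sdm.importance
        assert len(imp) == 9
        assert all(v >= 0 for v in imp.values())
        assert sum(imp.values()) == pytest.approx(1.0)

    def test_sharp_niche_recovers_top_covariate(self, masked_grid):
        # strongly separated single-covariate niche: the niche covariate
        # must dominate the Gini importance profile
        from holomap.config import SimConfig
        from holomap.simulate import TrueNiche, generate_host_occurrences
        cfg = SimConfig(seed=7, lat_min=43.0, lat_max=45.5, lon_min=-64.0,
                        lon_max=-61.0, records_per_species=400, n_species=1)
        sharp = TrueNiche(species="sharp",
                          optima={"bottom_temperature": 7.5},
                          tolerances={"bottom_temperature": 0.7},
                          baseline=3.0)
        recs = generate_host_occurrences(masked_grid, [sharp], cfg)
        sub = grid_records(recs, masked_grid).reset_index(drop=True)
        res = cross_validate_sdm(sub, masked_grid, PRESENT, k=5, n_trees=200,
                                 block_size_cells=5, seed=0)
        assert max(res.importance, key=res.importance.get) \
            == "bottom_temperature"
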