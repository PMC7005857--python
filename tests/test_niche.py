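"""Niche-model protocol: distances, thinning, background sampling, the
maximum-entropy fit and its KKT property, thresholding, and the composed
three-run protocol."""

import warnings

import numpy as np
import pytest
from scipy import stats
from shapely.geometry import Point

from ecogap.geo import haversine_km
from ecogap.niche import (HullRegion, NicheConfig, ThinningGrid, fit_maxent,
                          longest_interpoint_distance, predict,
                          resample_presences, run_protocol, sample_background,
                          threshold_max_ss)
from ecogap.synth import sample_presences


class TestLongestDistance:
    def test_one_meridian_degree_is_111_19_km(self):
        d = longest_interpoint_distance([0.0, 1.0], [0.0, 0.0])
        assert d == pytest.approx(111.19, abs=0.01)

    def test_duplicated_points_do_not_change_the_maximum(self):
        lats = [0.0, 1.0, 0.5]
        lons = [0.0, 0.5, 0.2]
        d1 = longest_interpoint_distance(lats, lons)
        d2 = longest_interpoint_distance(lats * 3, lons * 3)
        assert d1 == d2

    def test_matches_exhaustive_pairwise_maximum(self):
        rng = np.random.default_rng(4)
        lats = rng.uniform(-30, 30, 50)
        lons = rng.uniform(-40, 40, 50)
        best = max(haversine_km(lats[i], lons[i], lats[j], lons[j])
                   for i in range(50) for j in range(i + 1, 50))
        assert longest_interpoint_distance(lats, lons) == pytest.approx(best)

    def test_single_point_raises(self):
        with pytest.raises(ValueError, match="insufficient points"):
            longest_interpoint_distance([0.0], [0.0])


class TestThinning:
    def test_distinct_cells_full_keep_is_identity(self, world):
        grid = ThinningGrid(cell_deg=0.5, x0=0.0, y0=0.0)
        lats = np.array([0.1, 1.1, 2.1, 3.1])
        lons = np.array([0.1, 1.1, 2.1, 3.1])
        sel = resample_presences(lats, lons, grid, keep_frac=1.0, seed=0)
        assert list(sel) == [0, 1, 2, 3]

    def test_cohabiting_points_thin_to_one(self):
        grid = ThinningGrid(cell_deg=1.0, x0=0.0, y0=0.0)
        lats = np.full(10, 0.5)
        lons = np.linspace(0.05, 0.95, 10)
        sel = resample_presences(lats, lons, grid, keep_frac=1.0, seed=1)
        assert len(sel) == 1

    def test_per_cell_retention_uniform_over_repeats(self):
        # 5 points in one cell: each should survive stage 1 in ~1/5 of runs
        grid = ThinningGrid(cell_deg=1.0, x0=0.0, y0=0.0)
        lats = np.full(5, 0.5)
        lons = np.linspace(0.1, 0.9, 5)
        counts = np.zeros(5)
        n_runs = 1000
        for s in range(n_runs):
            sel = resample_presences(lats, lons, grid, keep_frac=1.0, seed=s)
            assert len(sel) == 1          # one survivor per occupied cell
            counts[sel[0]] += 1
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_keep_frac_subsamples_thinned_set(self):
        grid = ThinningGrid(cell_deg=0.5, x0=0.0, y0=0.0)
        lats = np.arange(10, dtype=float)
        lons = np.arange(10, dtype=float)
        sel = resample_presences(lats, lons, grid, keep_frac=0.8, seed=3)
        assert len(sel) == 8  # ceil(0.8 * 10)


@pytest.fixture(scope="module")
def hull(clean_world):
    recs = [r for r in clean_world["cleaned"] if r.taxon_id == "taxon02"]
    lats = np.array([r.lat for r in recs])
    lons = np.array([r.lon for r in recs])
    return HullRegion.from_points(lats, lons)


class TestBackground:
    def test_ten_to_one_ratio(self, hull, world):
        blon, blat = sample_background(hull, world["stack"], 20, ratio=10, seed=0)
        assert len(blon) == 200

    def test_all_points_inside_buffered_polygon(self, hull, world):
        blon, blat = sample_background(hull, world["stack"], 50, seed=1)
        for x, y in zip(blon, blat):
            assert hull.buffered.covers(Point(x, y))

    def test_density_uniform_across_eligible_cells(self, hull, world):
        # chi-square goodness of fit over 1e5 draws must not reject uniformity
        stack = world["stack"]
        blon, blat = sample_background(hull, stack, 10000, ratio=10, seed=2)
        rows, cols = stack.grid.cell_of(blon, blat)
        import shapely
        lon, lat = stack.grid.center_grids()
        eligible = (stack.data_mask.ravel()
                    & shapely.contains_xy(hull.buffered, lon.ravel(), lat.ravel()))
        n_cells = int(eligible.sum())
        counts = np.bincount(rows * stack.grid.ncols + cols,
                             minlength=stack.grid.nrows * stack.grid.ncols)
        observed = counts[eligible]
        assert observed.sum() == 100000
        p = stats.chisquare(observed).pvalue
        assert p > 0.01, f"uniformity rejected over {n_cells} cells"

    def test_hull_contains_all_presences(self, clean_world, hull):
        recs = [r for r in clean_world["cleaned"] if r.taxon_id == "taxon02"]
        for r in recs:
            assert hull.hull.covers(Point(r.lon, r.lat))
        assert hull.buffered.contains(hull.hull)


class TestMaxent:
    def test_zero_signal_gives_zero_weights_and_flat_map(self):
        # presence feature means exactly equal background feature means
        rng = np.random.default_rng(0)
        env = rng.normal(size=(400, 2))
        model = fit_maxent(env, env, beta=0.05)
        assert np.allclose(model.weights, 0.0, atol=1e-6)

    def test_presences_at_high_values_give_monotone_suitability(self):
        rng = np.random.default_rng(1)
        bg = rng.uniform(0, 10, size=(500, 1))
        pres = rng.uniform(8, 10, size=(60, 1))
        model = fit_maxent(pres, bg, beta=0.05)
        xs = np.linspace(1, 9, 20).reshape(-1, 1)
        scores = model.raw_score(xs)
        assert np.all(np.diff(scores) > 0)

    def test_kkt_feature_matching_within_beta(self, clean_world):
        stack = clean_world["stack"]
        for taxon in ("taxon01", "taxon05"):
            recs = [r for r in clean_world["cleaned"] if r.taxon_id == taxon]
            env = stack.values_at([r.lon for r in recs],
                                  [r.lat for r in recs], ("BIO1", "BIO12"))
            env = env[~np.isnan(env).any(axis=1)]
            lats = np.array([r.lat for r in recs])
            lons = np.array([r.lon for r in recs])
            hull = HullRegion.from_points(lats, lons)
            blon, blat = sample_background(hull, stack, len(env), seed=5)
            benv = stack.values_at(blon, blat, ("BIO1", "BIO12"))
            model = fit_maxent(env, benv, beta=0.05)
            # constraint oracle from the stated objective: expectations under
            # the fitted Gibbs distribution match presence means within beta
            Fs = np.vstack([model.features(benv), model.features(env)])
            s = Fs @ model.weights
            p = np.exp(s - s.max())
            p /= p.sum()
            gap = np.abs(Fs.T @ p - model.features(env).mean(axis=0))
            assert gap.max() <= 0.05 + 1e-6

    def test_too_few_presences_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            fit_maxent(rng.normal(size=(3, 2)), rng.normal(size=(30, 2)))


class TestPredict:
    def test_zero_weights_give_constant_raster(self, world):
        stack = world["stack"]
        rng = np.random.default_rng(0)
        env = rng.normal(size=(100, 2)) * [3, 300] + [20, 900]
        model = fit_maxent(env, env, beta=0.05)
        raster = predict(model, stack, ("BIO1", "BIO12"))
        vals = raster[raster != stack.grid.nodata]
        assert np.allclose(vals, vals[0])

    def test_equal_climate_cells_get_equal_suitability(self, world):
        stack = world["stack"]
        rng = np.random.default_rng(1)
        bg = np.column_stack([rng.uniform(10, 30, 300),
                              rng.uniform(200, 2000, 300)])
        model = fit_maxent(bg[:50] * 0.9 + 2, bg, beta=0.05)
        raster = predict(model, stack, ("BIO1", "BIO12"))
        b1 = stack.layers["BIO1"]
        b12 = stack.layers["BIO12"]
        mask = stack.data_mask
        rows, cols = np.nonzero(mask)
        key = {}
        for r, c in zip(rows[:2000], cols[:2000]):
            k = (b1[r, c], b12[r, c])
            if k in key:
                assert raster[r, c] == key[k]
            key[k] = raster[r, c]


class TestThreshold:
    def test_separable_case_with_tie_break(self):
        tau = threshold_max_ss([0.9, 0.8], [0.2, 0.1])
        assert tau == 0.8

    def test_identical_distributions_match_brute_force(self):
        scores = [0.1, 0.3, 0.5, 0.7]
        tau = threshold_max_ss(scores, scores)
        assert tau == _brute_force_tau(scores, scores)

    @pytest.mark.parametrize("ps,bs", [
        ([0.9, 0.4], [0.5, 0.1]),
        ([0.2, 0.6, 0.6, 0.9], [0.1, 0.6, 0.3]),
        ([0.5], [0.5]),
    ])
    def test_matches_exhaustive_scan(self, ps, bs):
        assert threshold_max_ss(ps, bs) == _brute_force_tau(ps, bs)

    def test_random_instances_match_exhaustive_scan(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            ps = rng.uniform(size=rng.integers(1, 20))
            bs = rng.uniform(size=rng.integers(1, 20))
            assert threshold_max_ss(ps, bs) == _brute_force_tau(ps, bs)


def _brute_force_tau(ps, bs):
    ps, bs = np.asarray(ps), np.asarray(bs)
    cands = sorted(set(ps) | set(bs))
    vals = [(ps >= t).mean() + (bs < t).mean() for t in cands]
    best = max(vals)
    return next(t for t, v in zip(cands, vals) if v >= best - 1e-12)


class TestProtocol:
    def test_averaged_raster_is_cellwise_mean_of_runs(self, clean_world):
        stack = clean_world["stack"]
        recs = [r for r in clean_world["cleaned"] if r.taxon_id == "taxon01"]
        cfg = NicheConfig(seed=21, variables=("BIO1", "BIO12"))
        smap = run_protocol(recs, stack, cfg)
        rasters = [predict(m, stack, ("BIO1", "BIO12"), clip=smap.hull.buffered)
                   for m in smap.models]
        nod = stack.grid.nodata
        valid = np.all([r != nod for r in rasters], axis=0)
        expect = np.mean([r[valid] for r in rasters], axis=0)
        np.testing.assert_allclose(smap.continuous[valid], expect)

    def test_binary_cells_confined_to_buffered_hull(self, clean_world):
        stack = clean_world["stack"]
        recs = [r for r in clean_world["cleaned"] if r.taxon_id == "taxon03"]
        smap = run_protocol(recs, stack, NicheConfig(seed=22,
                                                     variables=("BIO1", "BIO12")))
        rows, cols = np.nonzero(smap.binary)
        assert rows.size > 0
        lon, lat = stack.grid.cell_center(rows, cols)
        for x, y in zip(lon, lat):
            assert smap.hull.buffered.covers(Point(x, y))

    def test_binary_consistent_with_threshold(self, clean_world):
        stack = clean_world["stack"]
        recs = [r for r in clean_world["cleaned"] if r.taxon_id == "taxon06"]
        smap = run_protocol(recs, stack, NicheConfig(seed=23,
                                                     variables=("BIO1", "BIO12")))
        nod = stack.grid.nodata
        data = smap.continuous != nod
        np.testing.assert_array_equal(
            smap.binary[data], (smap.continuous[data] >= smap.tau).astype(int))
        assert not smap.binary[~data].any()

    def test_protocol_deterministic_given_seed(self, clean_world):
        stack = clean_world["stack"]
        recs = [r for r in clean_world["cleaned"] if r.taxon_id == "taxon02"]
        cfg = NicheConfig(seed=5, variables=("BIO1", "BIO12"))
        a = run_protocol(recs, stack, cfg)
        b = run_protocol(recs, stack, cfg)
        np.testing.assert_array_equal(a.continuous, b.continuous)
        assert a.tau == b.tau

    def test_too_few_records_raises(self, clean_world):
        recs = [r for r in clean_world["cleaned"] if r.taxon_id == "taxon02"][:4]
        with pytest.raises(ValueError, match="min_model_records"):
            run_protocol(recs, clean_world["stack"], NicheConfig())
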