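"""The five cleaning rules, their geometric/arithmetic oracles, and the
composed pipeline (ledger recall, idempotence, report conservation)."""

import warnings

import numpy as np
import pytest
from shapely.geometry import Point

from ecogap.cleaning import (CleaningConfig, clean_pipeline, dedupe,
                             drop_centroids, filter_climate_outliers,
                             filter_country_mismatch, iqr_fences,
                             relocate_coastal)
from ecogap.geo import angular_arcmin
from ecogap.types import PresenceRecord


def rec(rid, lat, lon, taxon="t1", cc="C01", **kw):
    kw.setdefault("source", "herbarium")
    return PresenceRecord(record_id=rid, taxon_id=taxon, lat=lat, lon=lon,
                          country_code=cc, **kw)


def densified_boundary_arcmin(lat, lon, poly, step=0.002):
    """Brute-force angular distance to a polygon via dense boundary sampling."""
    b = poly.boundary
    ds = np.arange(0.0, b.length, step)
    pts = [b.interpolate(d) for d in ds]
    return min(angular_arcmin(lat, lon, p.y, p.x) for p in pts)


class TestCountryMismatch:
    def test_interior_point_with_matching_code_kept(self, world):
        cmap = world["countries"]
        c = cmap.countries["C01"]
        kept, removed, _ = filter_country_mismatch(
            [rec("a", c.centroid_lat, c.centroid_lon, cc="C01")], cmap)
        assert len(kept) == 1 and removed == []

    def test_point_inside_10_arcmin_buffer_kept(self, world):
        # 5 arc-min outside the declared country's western border
        cmap = world["countries"]
        c = cmap.countries["C01"]
        minx, miny, maxx, maxy = c.polygon.bounds
        lat = (miny + maxy) / 2
        lon = minx - (5.0 / 60.0) / np.cos(np.radians(lat))
        assert not c.polygon.covers(Point(lon, lat))
        kept, removed, _ = filter_country_mismatch([rec("a", lat, lon)], cmap)
        assert len(kept) == 1

    def test_point_30_arcmin_outside_removed(self, world):
        cmap = world["countries"]
        c = cmap.countries["C01"]
        minx, miny, maxx, maxy = c.polygon.bounds
        lat = (miny + maxy) / 2
        lon = minx - (30.0 / 60.0) / np.cos(np.radians(lat))
        kept, removed, _ = filter_country_mismatch([rec("a", lat, lon)], cmap)
        assert kept == [] and removed[0][1].startswith("outside")
        # geometric oracle: brute-force boundary distance really exceeds 10'
        assert densified_boundary_arcmin(lat, lon, c.polygon) > 10.0

    def test_decisions_match_brute_force_distance(self, world):
        cmap = world["countries"]
        c = cmap.countries["C02"]
        minx, miny, maxx, maxy = c.polygon.bounds
        rng = np.random.default_rng(0)
        records = [rec(f"r{i}", float(rng.uniform(miny - 0.5, maxy + 0.5)),
                       float(rng.uniform(minx - 0.5, maxx + 0.5)), cc="C02")
                   for i in range(40)]
        kept, removed, _ = filter_country_mismatch(records, cmap)
        kept_ids = {r.record_id for r in kept}
        for r in records:
            if c.polygon.covers(Point(r.lon, r.lat)):
                expect_keep = True
            else:
                d = densified_boundary_arcmin(r.lat, r.lon, c.polygon)
                if abs(d - 10.0) < 0.2:   # skip knife-edge cases
                    continue
                expect_keep = d <= 10.0
            assert (r.record_id in kept_ids) == expect_keep

    def test_missing_code_kept_and_flagged(self, world):
        kept, removed, flagged = filter_country_mismatch(
            [rec("a", 0.0, 0.0, cc=None)], world["countries"])
        assert len(kept) == 1 and flagged == ["a"]

    def test_unknown_code_removed_with_reason(self, world):
        kept, removed, _ = filter_country_mismatch(
            [rec("a", 0.0, 10.0, cc="ZZZ")], world["countries"])
        assert removed[0][1] == "unknown country"


class TestCoastalRelocation:
    def test_land_point_unchanged(self, world):
        cmap = world["countries"]
        c = cmap.countries["C03"]
        r = rec("a", c.centroid_lat, c.centroid_lon)
        out, relocated = relocate_coastal([r], cmap)
        assert out == [r] and relocated == []

    def test_sea_point_within_buffer_moved_to_nearest_coast(self, world):
        cmap = world["countries"]
        minx, miny, maxx, maxy = cmap.land_union.bounds
        lat = (miny + maxy) / 2
        lon = minx - (5.0 / 60.0) / np.cos(np.radians(lat))  # 5' off the coast
        r = rec("a", lat, lon, cc=None)
        out, relocated = relocate_coastal([r], cmap)
        assert relocated == ["a"]
        moved = out[0]
        assert moved.georef_status == "relocated_coast"
        # nearest-point oracle: distance moved equals the brute-force minimum
        # over the densified coastline (within discretisation tolerance)
        d_moved = angular_arcmin(lat, lon, moved.lat, moved.lon)
        d_brute = densified_boundary_arcmin(lat, lon, cmap.land_union)
        assert d_moved == pytest.approx(d_brute, abs=0.05)
        assert cmap.land_union.covers(Point(moved.lon, moved.lat))

    def test_sea_point_far_beyond_buffer_untouched(self, world):
        cmap = world["countries"]
        minx, miny, maxx, maxy = cmap.land_union.bounds
        lat = (miny + maxy) / 2
        lon = minx - 1.0  # 60 arc-min offshore
        r = rec("a", lat, lon, cc=None)
        out, relocated = relocate_coastal([r], cmap)
        assert out == [r] and relocated == []


class TestCentroids:
    def test_record_exactly_at_centroid_removed(self, world):
        c = world["countries"].countries["C04"]
        kept, removed = drop_centroids(
            [rec("a", c.centroid_lat, c.centroid_lon)], world["countries"])
        assert kept == [] and len(removed) == 1

    def test_record_far_from_all_centroids_kept(self, world):
        cmap = world["countries"]
        c = cmap.countries["C04"]
        kept, removed = drop_centroids(
            [rec("a", c.centroid_lat + 0.5, c.centroid_lon)], cmap, tol_arcmin=1.0)
        assert len(kept) == 1

    def test_randomised_decisions_equal_brute_force(self, world):
        cmap = world["countries"]
        cents = [(c.centroid_lat, c.centroid_lon)
                 for c in cmap.countries.values()]
        rng = np.random.default_rng(3)
        records = []
        for i in range(60):
            cla, clo = cents[i % len(cents)]
            records.append(rec(f"r{i}", float(cla + rng.normal(0, 0.03)),
                               float(clo + rng.normal(0, 0.03))))
        kept, removed = drop_centroids(records, cmap, tol_arcmin=1.0)
        removed_ids = {r.record_id for r, _ in removed}
        for r in records:
            d = min(angular_arcmin(r.lat, r.lon, cla, clo) for cla, clo in cents)
            assert (r.record_id in removed_ids) == (d <= 1.0)


class TestDedupe:
    def test_same_taxon_same_coordinates_collapse(self):
        a, b = rec("a", 1.0, 2.0), rec("b", 1.0, 2.0)
        kept, removed = dedupe([a, b])
        assert kept == [a] and removed[0][0] == b

    def test_same_coordinates_different_taxa_both_kept(self):
        a = rec("a", 1.0, 2.0, taxon="t1")
        b = rec("b", 1.0, 2.0, taxon="t2")
        kept, _ = dedupe([a, b])
        assert kept == [a, b]

    def test_survivor_count_equals_distinct_rounded_pairs(self):
        rng = np.random.default_rng(5)
        records = [rec(f"r{i}", float(rng.integers(0, 4) + 0.12345),
                       float(rng.integers(0, 4)), taxon=f"t{i % 2}")
                   for i in range(50)]
        kept, removed = dedupe(records, precision_decimals=4)
        distinct = {(r.taxon_id, round(r.lat, 4), round(r.lon, 4))
                    for r in records}
        assert len(kept) == len(distinct)
        assert len(kept) + len(removed) == len(records)

    def test_rounding_precision_drives_collapse(self):
        a = rec("a", 1.00001, 2.0)
        b = rec("b", 1.00002, 2.0)
        kept4, _ = dedupe([a, b], precision_decimals=4)
        kept6, _ = dedupe([a, b], precision_decimals=6)
        assert len(kept4) == 1 and len(kept6) == 2


class TestClimateOutliers:
    def test_fence_arithmetic_on_known_sample(self):
        # {1,2,3,4,100}: Q1=2, Q3=4, IQR=2 -> upper fence 4 + 2.5*2 = 9
        lo, hi = iqr_fences(np.array([[1.0], [2.0], [3.0], [4.0], [100.0]]))
        assert lo[0] == pytest.approx(2 - 5.0)
        assert hi[0] == pytest.approx(9.0)

    def test_two_violating_variables_not_enough(self, world):
        # on the injected fixture, every removed record violates >= 3
        # variables, so the reason string never reports 1 or 2
        _, removed = filter_climate_outliers(world["records"], world["stack"])
        for _, why in removed:
            if why.startswith("climate outlier"):
                n = int(why.split()[3])
                assert n >= 3

    def test_ledgered_outliers_recovered_and_match_fence_oracle(self):
        from ecogap.synth import (DEFAULT_ERROR_RATES, SyntheticWorldSpec,
                                  make_world)

        rates = {k: 0.0 for k in DEFAULT_ERROR_RATES}
        rates["climate_outlier"] = 0.03
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = make_world(SyntheticWorldSpec(seed=9, error_rates=rates),
                           n_per_taxon=100)
        kept, removed = filter_climate_outliers(w["records"], w["stack"])
        removed_ids = {r.record_id for r, _ in removed}
        assert removed_ids == w["ledger"].ids("climate_outlier")
        # brute-force fence oracle over the full 19-variable matrix
        stack = w["stack"]
        vals = stack.values_at([r.lon for r in w["records"]],
                               [r.lat for r in w["records"]])
        taxa = np.array([r.taxon_id for r in w["records"]])
        for t in np.unique(taxa):
            tv = vals[taxa == t]
            lo, hi = iqr_fences(tv)
            nviol = ((tv < lo) | (tv > hi)).sum(axis=1)
            ids = np.array([r.record_id for r in w["records"]])[taxa == t]
            assert set(ids[nviol >= 3]) == removed_ids & set(ids)

    def test_record_on_nodata_cell_removed_with_reason(self, world):
        sea = rec("sea", world["spec"].lat_min + 0.01,
                  world["spec"].lon_min + 0.01, cc=None)
        _, removed = filter_climate_outliers([sea], world["stack"])
        assert removed[0][1] == "no climate data"

    def test_small_taxa_exempt_from_fences(self, world):
        recs = [rec(f"r{i}", 0.0, 20.0 + i, taxon="rare") for i in range(3)]
        kept, removed = filter_climate_outliers(recs, world["stack"])
        assert {r.record_id for r in kept} == {"r0", "r1", "r2"}


class TestPipeline:
    def test_error_free_input_passes_through(self, pristine_world):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cleaned, report = clean_pipeline(
                pristine_world["records"], pristine_world["countries"],
                pristine_world["stack"])
        # only chance coordinate duplicates may go; nothing else
        for step in report.steps:
            if step.name != "dedupe":
                assert step.n_removed == 0, step.name

    def test_all_error_types_attributed_to_their_step(self, clean_world):
        report = clean_world["report"]
        ledger = clean_world["ledger"]
        assert ledger.ids("country_mismatch") <= report.removed_ids("country_mismatch")
        assert ledger.ids("offshore", "far") <= report.removed_ids("country_mismatch")
        assert ledger.ids("offshore", "near") <= set(
            report.step("coastal_relocation").modified)
        assert ledger.ids("centroid") <= report.removed_ids("centroid_removal")
        assert ledger.ids("duplicate") <= report.removed_ids("dedupe")

    def test_ledger_recall_at_least_95_percent_on_1000_records(self, clean_world):
        ledger = clean_world["ledger"]
        removable = (ledger.ids("country_mismatch") | ledger.ids("offshore", "far")
                     | ledger.ids("centroid") | ledger.ids("duplicate")
                     | ledger.ids("climate_outlier"))
        removed = clean_world["report"].removed_ids()
        assert len(clean_world["records"]) >= 1000
        recall = len(removable & removed) / len(removable)
        assert recall >= 0.95

    def test_pipeline_idempotent_on_its_own_output(self, clean_world):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again, report2 = clean_pipeline(
                clean_world["cleaned"], clean_world["countries"],
                clean_world["stack"])
        assert again == clean_world["cleaned"]
        assert all(s.n_removed == 0 and s.n_modified == 0
                   for s in report2.steps)

    def test_coastal_genebank_record_within_buffer_survives(self, world):
        # a collection reported just offshore of its own country must be
        # relocated, not dropped: relocation precedes the final verdicts
        cmap = world["countries"]
        c = cmap.countries["C01"]
        minx, miny, maxx, maxy = c.polygon.bounds
        lat = (miny + maxy) / 2
        lon = minx - (4.0 / 60.0) / np.cos(np.radians(lat))
        r = rec("coastal", lat, lon, cc="C01", source="genebank")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cleaned, report = clean_pipeline([r], cmap, world["stack"],
                                             CleaningConfig(min_records_for_fences=99))
        assert [x.record_id for x in cleaned] == ["coastal"]
        assert cleaned[0].georef_status == "relocated_coast"

    def test_report_conservation_invariant(self, clean_world):
        steps = clean_world["report"].steps
        for prev, nxt in zip(steps, steps[1:]):
            assert nxt.n_in == prev.n_in - prev.n_removed + prev.n_added
        assert steps[-1].n_out == len(clean_world["cleaned"])
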