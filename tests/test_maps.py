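"""Floor-rule artifact detection, AR computation, quality strata, and
circle-scan geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnflt.errors import GeometryError, ShapeError, UndefinedRegionError
from rnflt.maps import (
    ArtifactMask,
    CircleGeometry,
    DiscMask,
    RNFLTMap,
    classify_quality,
    compute_artifact_mask,
    compute_artifact_ratio,
    extract_circle_scan,
    stratum,
)


def _map(values, pitch=0.03):
    return RNFLTMap(values=np.asarray(values, dtype=float), pixel_pitch=pitch)


class TestArtifactMask:
    def test_no_subfloor_pixels_gives_empty_mask(self):
        m = _map(np.full((10, 10), 100.0))
        am = compute_artifact_mask(m, DiscMask.empty((10, 10)))
        assert not am.mask.any()

    def test_subfloor_pixels_outside_disc_are_flagged(self):
        vals = np.full((10, 10), 100.0)
        vals[0, :5] = 30.0
        am = compute_artifact_mask(_map(vals), DiscMask.empty((10, 10)))
        assert am.n_pixels == 5
        assert am.mask[0, :5].all()

    def test_subfloor_pixel_inside_disc_is_not_an_artifact(self):
        vals = np.full((10, 10), 100.0)
        vals[4, 4] = 30.0
        disc = np.zeros((10, 10), dtype=bool)
        disc[4, 4] = True
        am = compute_artifact_mask(_map(vals), DiscMask(disc))
        assert not am.mask[4, 4]
        assert not am.mask.any()

    def test_original_values_untouched(self):
        vals = np.full((10, 10), 100.0)
        vals[2, 2] = 10.0
        m = _map(vals)
        compute_artifact_mask(m, DiscMask.empty((10, 10)))
        assert m.values[2, 2] == 10.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeError):
            compute_artifact_mask(_map(np.full((10, 10), 80.0)),
                                  DiscMask.empty((8, 8)))


class TestArtifactRatio:
    def test_no_disc(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask.ravel()[:5] = True
        ar = compute_artifact_ratio(ArtifactMask(mask), DiscMask.empty((10, 10)))
        assert ar == 5 / 100

    def test_disc_excluded_from_denominator(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask.ravel()[:4] = True
        disc = np.zeros((10, 10), dtype=bool)
        disc.ravel()[-20:] = True
        assert compute_artifact_ratio(ArtifactMask(mask), DiscMask(disc)) == 4 / 80

    def test_empty_numerator(self):
        ar = compute_artifact_ratio(
            ArtifactMask(np.zeros((5, 5), dtype=bool)), DiscMask.empty((5, 5))
        )
        assert ar == 0.0

    def test_full_disc_is_undefined(self):
        with pytest.raises(UndefinedRegionError):
            compute_artifact_ratio(
                ArtifactMask(np.zeros((5, 5), dtype=bool)),
                DiscMask(np.ones((5, 5), dtype=bool)),
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_count_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 150, size=(20, 20))
        disc = rng.uniform(size=(20, 20)) < 0.15
        m = _map(vals)
        am = compute_artifact_mask(m, DiscMask(disc))
        ar = compute_artifact_ratio(am, DiscMask(disc))
        # independent brute force: explicit pixel loop
        n_art = sum(
            1
            for i in range(20)
            for j in range(20)
            if vals[i, j] < 50.0 and not disc[i, j]
        )
        n_disc = sum(1 for i in range(20) for j in range(20) if disc[i, j])
        assert ar == n_art / (400 - n_disc)

    def test_monotone_in_artifact_pixels(self, rng):
        vals = rng.uniform(40, 150, size=(20, 20))
        disc = DiscMask.empty((20, 20))
        m = _map(vals)
        ar0 = compute_artifact_ratio(compute_artifact_mask(m, disc), disc)
        above = np.argwhere(vals >= 50)
        i, j = above[0]
        vals2 = vals.copy()
        vals2[i, j] = 10.0
        ar1 = compute_artifact_ratio(compute_artifact_mask(_map(vals2), disc), disc)
        assert ar1 > ar0


class TestQualityAndStrata:
    @pytest.mark.parametrize(
        "ar,expected",
        [(0.01, "high"), (0.0199, "high"), (0.02, "intermediate"),
         (0.03, "intermediate"), (0.05, "intermediate"), (0.0501, "low"),
         (0.06, "low")],
    )
    def test_quality_cutoffs(self, ar, expected):
        assert classify_quality(ar) == expected

    @pytest.mark.parametrize(
        "ar,le10,gt10,gt20",
        [(0.25, False, True, True), (0.10, True, False, False),
         (0.15, False, True, False), (0.20, False, True, False),
         (0.0, True, False, False)],
    )
    def test_stratum_flags(self, ar, le10, gt10, gt20):
        s = stratum(ar)
        assert (s["le10"], s["gt10"], s["gt20"]) == (le10, gt10, gt20)

    @given(st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_strata_are_nested_and_exclusive(self, ar):
        s = stratum(ar)
        assert s["le10"] != s["gt10"]          # partition
        if s["gt20"]:
            assert s["gt10"]                   # nesting


class TestCircleScan:
    def test_constant_map_is_exact(self, flat_map):
        geom = CircleGeometry.for_map(flat_map)
        scan = extract_circle_scan(flat_map, geom)
        assert scan.thickness.shape == (256,)
        np.testing.assert_allclose(scan.thickness, 100.0, rtol=0, atol=1e-10)

    def test_linear_field_mean_equals_center_value(self):
        rr, cc = np.mgrid[0:200, 0:200].astype(float)
        vals = 80.0 + 0.1 * rr + 0.05 * cc
        m = RNFLTMap(values=vals)
        geom = CircleGeometry.for_map(m)
        scan = extract_circle_scan(m, geom)
        center_value = 80.0 + 0.1 * 99.5 + 0.05 * 99.5
        assert np.isclose(scan.thickness.mean(), center_value, atol=1e-9)

    def test_radial_map_matches_analytic_profile(self):
        # peak 100 um on the scan-circle radius; samples must follow the
        # analytic value to interpolation accuracy
        rr, cc = np.mgrid[0:200, 0:200].astype(float)
        r_mm = 0.03 * np.hypot(rr - 99.5, cc - 99.5)
        m = RNFLTMap(values=60.0 + 40.0 * np.exp(-((r_mm - 1.73) ** 2)))
        scan = extract_circle_scan(m, CircleGeometry.for_map(m))
        assert np.abs(scan.thickness - 100.0).max() < 0.5

    def test_quarter_rotation_rotates_samples(self, rng):
        n = 128
        vals = rng.uniform(60, 140, size=(201, 201))
        m = RNFLTMap(values=vals)
        geom = CircleGeometry(center=(100.0, 100.0), n_samples=n)
        scan = extract_circle_scan(m, geom)
        m90 = RNFLTMap(values=np.rot90(vals))          # 90 deg CCW about center
        scan90 = extract_circle_scan(m90, geom)
        np.testing.assert_allclose(
            np.roll(scan.thickness, -n // 4), scan90.thickness, atol=1e-9
        )

    def test_circle_leaving_grid_raises(self):
        m = RNFLTMap(values=np.full((40, 40), 90.0), pixel_pitch=0.03)
        with pytest.raises(GeometryError):
            extract_circle_scan(m, CircleGeometry.for_map(m))

    def test_center_defaults_to_disc_centroid(self):
        vals = np.full((100, 100), 90.0)
        m = RNFLTMap(values=vals, pixel_pitch=0.06)
        disc = DiscMask.circular((100, 100), 0.06, radius_mm=0.8, center=(40.0, 60.0))
        geom = CircleGeometry.for_map(m, disc)
        assert np.allclose(geom.center, disc.centroid(), atol=0.5)


class TestMapInvariants:
    def test_rejects_non_finite(self):
        vals = np.full((5, 5), 80.0)
        vals[0, 0] = np.nan
        with pytest.raises(ValueError):
            RNFLTMap(values=vals)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            RNFLTMap(values=np.full((5, 5), 600.0))

    def test_default_disc_area_is_plausible(self):
        # ~2 mm^2 disc on the default geometry
        disc = DiscMask.circular((200, 200), 0.03)
        area_mm2 = disc.n_pixels * 0.03**2
        assert 1.7 < area_mm2 < 2.3
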