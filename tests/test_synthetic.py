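"""Synthetic map/artifact/VF/cohort generators: determinism, anatomy,
quality contracts, and the built-in structure-function link."""

import numpy as np
import pytest

from rnflt.maps import (
    CircleGeometry,
    classify_quality,
    compute_artifact_mask,
    compute_artifact_ratio,
    extract_circle_scan,
)
from rnflt.synthetic import (
    ArtifactModelParams,
    MapModelParams,
    StructureFunctionLink,
    VFSimParams,
    generate_cohort,
    generate_rnflt_map,
    generate_segmentation_failure,
    generate_vf_series,
)
from rnflt.vf import fit_series_slope, is_eligible


class TestMapGenerator:
    def test_same_seed_is_bit_identical(self, small_params):
        m1, _ = generate_rnflt_map(small_params)
        m2, _ = generate_rnflt_map(small_params)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_generated_map_is_high_quality(self, small_map):
        m, disc = small_map
        ar = compute_artifact_ratio(compute_artifact_mask(m, disc), disc)
        assert classify_quality(ar) == "high"

    def test_peak_equals_base_plus_amplitude_without_noise(self):
        p = MapModelParams(shape=(64, 64), pixel_pitch=6 / 64, severity=0.0,
                           noise_sd=0.0, seed=0)
        m, disc = generate_rnflt_map(p)
        peak = m.values[~disc.mask].max()
        assert np.isclose(peak, p.base_thickness + p.bundle_amplitude, atol=0.5)

    def test_severity_lowers_mean_thickness(self):
        base = dict(shape=(64, 64), pixel_pitch=6 / 64, noise_sd=0.0, seed=0)
        m0, d = generate_rnflt_map(MapModelParams(severity=0.0, **base))
        m1, _ = generate_rnflt_map(MapModelParams(severity=1.0, **base))
        assert m1.values[~d.mask].mean() < m0.values[~d.mask].mean()

    def test_severity_to_circle_mean_is_monotone(self):
        base = dict(shape=(64, 64), pixel_pitch=6 / 64, noise_sd=0.0, seed=0)
        means = []
        for sev in (0.0, 0.25, 0.5, 0.75, 1.0):
            m, d = generate_rnflt_map(MapModelParams(severity=sev, **base))
            scan = extract_circle_scan(m, CircleGeometry.for_map(m, d))
            means.append(scan.mean_um)
        assert all(a > b for a, b in zip(means, means[1:]))


class TestArtifactGenerator:
    @pytest.mark.parametrize("target", [0.05, 0.10, 0.25])
    def test_achieved_ar_within_tolerance(self, small_map, target):
        m, disc = small_map
        low = generate_segmentation_failure(
            m, disc, ArtifactModelParams(target_ar=target, seed=3)
        )
        ar = compute_artifact_ratio(compute_artifact_mask(low, disc), disc)
        assert 0.8 * target <= ar <= 1.2 * target

    def test_zero_target_is_a_noop(self, small_map):
        m, disc = small_map
        out = generate_segmentation_failure(
            m, disc, ArtifactModelParams(target_ar=0.0, seed=3)
        )
        np.testing.assert_array_equal(out.values, m.values)

    def test_overwritten_values_are_subfloor(self, small_map):
        m, disc = small_map
        low = generate_segmentation_failure(
            m, disc, ArtifactModelParams(target_ar=0.15, seed=3)
        )
        changed = low.values != m.values
        assert changed.any()
        assert (low.values[changed] < 50.0).all()
        assert not (changed & disc.mask).any()

    def test_deterministic_given_seed(self, small_map):
        m, disc = small_map
        p = ArtifactModelParams(target_ar=0.15, seed=9)
        a = generate_segmentation_failure(m, disc, p)
        b = generate_segmentation_failure(m, disc, p)
        np.testing.assert_array_equal(a.values, b.values)


class TestVFGenerator:
    def test_noiseless_slope_recovered_exactly(self):
        p = VFSimParams(n_exams=5, span_years=4.0, md_slope=-1.0,
                        md_intercept=-2.0, noise_sd=0.0, unreliable_prob=0.0)
        s = generate_vf_series(p)
        years = s.years_from_first()
        fit = fit_series_slope(np.array([e.md for e in s.exams]), years)
        # exam dates are whole calendar days, so the realized time axis is
        # day-quantized: the slope matches to that quantization, and the
        # fit is as close to perfect as the rounding allows
        assert np.isclose(fit.slope, -1.0, atol=5e-3)
        assert fit.p_value < 1e-6

    def test_five_exams_over_four_years_is_eligible(self):
        s = generate_vf_series(
            VFSimParams(n_exams=5, span_years=4.0, unreliable_prob=0.0, seed=2)
        )
        assert is_eligible(s)

    def test_same_seed_identical_series(self):
        p = VFSimParams(seed=5)
        a, b = generate_vf_series(p), generate_vf_series(p)
        assert [e.md for e in a.exams] == [e.md for e in b.exams]
        assert all(
            np.array_equal(x.td, y.td) for x, y in zip(a.exams, b.exams)
        )

    def test_reliability_fraction_near_target(self):
        # unreliable_prob 0.1 -> ~90% of exams pass the filter
        n_pass = n_tot = 0
        for seed in range(80):
            s = generate_vf_series(VFSimParams(n_exams=8, seed=seed))
            n_pass += len(s.reliable_exams())
            n_tot += 8
        assert 0.84 < n_pass / n_tot < 0.96

    def test_vfi_is_clipped_affine_in_md(self):
        s = generate_vf_series(VFSimParams(md_intercept=-1.0, noise_sd=0.0,
                                           unreliable_prob=0.0))
        for e in s.exams:
            assert np.isclose(e.vfi, np.clip(100 + 3.3 * e.md, 0, 100))


class TestCohort:
    def test_patient_ids_unique_and_counted(self):
        c = generate_cohort(10, map_params=MapModelParams(shape=(32, 32),
                                                          pixel_pitch=6 / 32),
                            seed=4)
        assert len(c.patient_ids) == 10
        assert len(set(e.eye_id for e in c.eyes)) == len(c.eyes)

    def test_noiseless_link_makes_md_affine_in_circle_mean(self):
        link = StructureFunctionLink(noise_sd=0.0)
        c = generate_cohort(
            8,
            map_params=MapModelParams(shape=(32, 32), pixel_pitch=6 / 32),
            vf_params=VFSimParams(noise_sd=0.0, unreliable_prob=0.0),
            sf_link=link,
            seed=4,
        )
        for e in c.eyes:
            expected = link.slope_db_per_um * (e.mean_circle_um - link.pivot_um)
            assert np.isclose(e.vf.exams[0].md, expected, atol=1e-9)

    def test_seeded_regeneration_is_identical(self):
        kw = dict(map_params=MapModelParams(shape=(32, 32), pixel_pitch=6 / 32),
                  seed=7)
        a = generate_cohort(5, **kw)
        b = generate_cohort(5, **kw)
        assert a.manifest().equals(b.manifest())
        for x, y in zip(a.eyes, b.eyes):
            np.testing.assert_array_equal(x.rnflt_map.values, y.rnflt_map.values)

    def test_donor_maps_classify_low(self):
        c = generate_cohort(
            12,
            map_params=MapModelParams(shape=(32, 32), pixel_pitch=6 / 32),
            donor_prob=1.0,
            seed=3,
        )
        assert any(e.donor_map is not None for e in c.eyes)
        for e in c.eyes:
            if e.donor_map is not None:
                ar = compute_artifact_ratio(
                    compute_artifact_mask(e.donor_map, e.disc), e.disc
                )
                assert classify_quality(ar) == "low"
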