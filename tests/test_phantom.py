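"""Phantom generator: determinism, jitter semantics, geometry, separability."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from radiomaps.phantom import (
    DEFAULT_ACQUISITIONS,
    AcquisitionSpec,
    ConfigurationError,
    PhantomSpec,
    SubjectJitter,
    generate_cohort,
    generate_subject_truth,
    render_fov,
)


@pytest.fixture(scope="module")
def spec():
    return PhantomSpec(seed=7)


class TestSubjectTruth:
    def test_same_seed_and_subject_is_bitwise_identical(self, spec):
        a = generate_subject_truth(spec, 0)
        b = generate_subject_truth(spec, 0)
        assert a.r_inner_mm == b.r_inner_mm
        assert a.myo_mean == b.myo_mean
        np.testing.assert_array_equal(a.texture, b.texture)

    def test_zero_jitter_gives_identical_geometry_distinct_texture(self):
        spec = PhantomSpec(seed=7, subject_jitter=SubjectJitter(0.0, 0.0))
        a = generate_subject_truth(spec, 0)
        b = generate_subject_truth(spec, 1)
        assert a.r_inner_mm == b.r_inner_mm == spec.r_inner_mm
        assert a.r_outer_mm == b.r_outer_mm == spec.r_outer_mm
        assert a.myo_mean == b.myo_mean == spec.myo_mean_intensity
        assert not np.array_equal(a.texture, b.texture)

    def test_jitter_stays_within_fractional_bounds(self, spec):
        jit = spec.subject_jitter
        for sid in range(12):
            t = generate_subject_truth(spec, sid)
            assert abs(t.myo_mean / spec.myo_mean_intensity - 1) <= jit.intensity_frac
            assert abs(t.r_inner_mm / spec.r_inner_mm - 1) <= jit.radius_frac
            assert abs(t.r_outer_mm / spec.r_outer_mm - 1) <= jit.radius_frac

    def test_invalid_spec_names_the_violated_invariant(self):
        with pytest.raises(ConfigurationError, match="r_inner_mm < r_outer_mm"):
            generate_subject_truth(PhantomSpec(r_inner_mm=30.0, r_outer_mm=20.0), 0)
        with pytest.raises(ConfigurationError, match="3\\*myo_texture_sd"):
            generate_subject_truth(PhantomSpec(myo_mean_intensity=160.0), 0)
        with pytest.raises(ConfigurationError, match="blood_intensity"):
            generate_subject_truth(PhantomSpec(blood_intensity=150.0), 0)


class TestRenderFov:
    def test_matrix_sets_grid_dimensions(self, spec):
        truth = generate_subject_truth(spec, 0)
        img = render_fov(truth, DEFAULT_ACQUISITIONS[0])
        assert img.shape == (224, 157)

    def test_spacing_is_fov_over_matrix(self, spec):
        truth = generate_subject_truth(spec, 0)
        img = render_fov(truth, DEFAULT_ACQUISITIONS[0])
        assert img.spacing_mm[0] == pytest.approx(329.0 / 224.0)
        assert img.spacing_mm[0] == pytest.approx(1.469, abs=1e-3)
        assert img.spacing_mm[1] == pytest.approx(256.0 / 157.0)

    def test_same_anatomy_center_across_fovs(self, spec):
        truth = generate_subject_truth(spec, 0)
        imgs = [render_fov(truth, acq) for acq in DEFAULT_ACQUISITIONS]
        spacings = {img.spacing_mm for img in imgs}
        assert len(spacings) == 3
        for img in imgs:
            # image center in mm equals the phantom center for every FOV
            h, w = img.shape
            center = (
                img.origin_mm[0] + h * img.spacing_mm[0] / 2,
                img.origin_mm[1] + w * img.spacing_mm[1] / 2,
            )
            assert center[0] == pytest.approx(truth.center_mm[0])
            assert center[1] == pytest.approx(truth.center_mm[1])

    def test_render_is_deterministic(self, spec):
        truth = generate_subject_truth(spec, 3)
        a = render_fov(truth, DEFAULT_ACQUISITIONS[1])
        b = render_fov(truth, DEFAULT_ACQUISITIONS[1])
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestCohort:
    @pytest.mark.parametrize(
        "n_subjects,n_acq,expected",
        [(12, 3, 36), (1, 1, 1)],
    )
    def test_image_count(self, spec, n_subjects, n_acq, expected):
        cohort = generate_cohort(spec, DEFAULT_ACQUISITIONS[:n_acq], n_subjects)
        assert len(cohort) == expected

    def test_clinical_surrogate_count(self, spec):
        # 61 subjects at one FOV each, the clinical cohort size
        cohort = generate_cohort(spec, DEFAULT_ACQUISITIONS[:1], 61)
        assert len(cohort) == 61
        assert len({r.subject_id for r in cohort}) == 61

    def test_cohort_is_deterministic(self, spec):
        a = generate_cohort(spec, DEFAULT_ACQUISITIONS[:2], 2)
        b = generate_cohort(spec, DEFAULT_ACQUISITIONS[:2], 2)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.image.pixels, rb.image.pixels)

    def test_nrrd_round_trip(self, spec, tmp_path):
        from radiomaps import io as rio

        cohort = generate_cohort(spec, DEFAULT_ACQUISITIONS[:1], 1, tmp_path)
        rec = cohort.records[0]
        assert rec.path is not None
        back = rio.read_image(rec.path)
        np.testing.assert_allclose(back.pixels, rec.image.pixels)
        assert back.spacing_mm == pytest.approx(rec.image.spacing_mm)
        assert back.slice_thickness_mm == rec.image.slice_thickness_mm
        assert (tmp_path / "manifest.csv").exists()


class TestSeparability:
    def test_threshold_separates_myocardium_from_blood(self):
        """Sampling the default cohort at every FOV: >=99% of annulus pixels
        sit in [0, 170] and >=99% of blood-pool pixels above 170 — the
        premise of the threshold segmentation.  Individual images may lose a
        few partial-volume boundary pixels, so the 99% bound is asserted on
        pixels pooled across subjects per FOV, with a per-image sanity floor."""
        spec = PhantomSpec(seed=0)
        for acq in DEFAULT_ACQUISITIONS:
            myo_ok = myo_n = blood_ok = blood_n = 0
            for sid in range(12):
                truth = generate_subject_truth(spec, sid)
                img = render_fov(truth, acq)
                rr, cc = img.pixel_centers_mm()
                d = np.hypot(rr - truth.center_mm[0], cc - truth.center_mm[1])
                myo = (d >= truth.r_inner_mm) & (d < truth.r_outer_mm)
                blood = d < truth.r_inner_mm
                okm = (img.pixels[myo] >= 0) & (img.pixels[myo] <= 170)
                okb = img.pixels[blood] > 170
                assert okm.mean() >= 0.97
                assert okb.mean() >= 0.97
                myo_ok += okm.sum()
                myo_n += okm.size
                blood_ok += okb.sum()
                blood_n += okb.size
            assert myo_ok / myo_n >= 0.99
            assert blood_ok / blood_n >= 0.99


def test_resolution_effect_exists():
    """Between the smallest and largest FOV, at least one conventional
    feature of the same subject changes by more than 10% — the premise of
    the reproducibility study."""
    from radiomaps.features import extract_all
    from radiomaps.segmentation import circle_region, threshold_segment

    spec = PhantomSpec(seed=0)
    truth = generate_subject_truth(spec, 0)
    vals = []
    for acq in (DEFAULT_ACQUISITIONS[0], DEFAULT_ACQUISITIONS[2]):
        img = render_fov(truth, acq)
        roi = circle_region(img, truth.center_mm, truth.r_outer_mm + 1.0)
        mask = threshold_segment(img, roi)
        vals.append(extract_all(img, mask))
    rel = [
        abs(vals[0][k] - vals[1][k]) / abs(vals[0][k])
        for k in vals[0].names()
        if vals[0].valid[k] and vals[1].valid[k] and vals[0][k] != 0
    ]
    assert max(rel) > 0.10
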