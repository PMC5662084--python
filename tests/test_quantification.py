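"""Per-object feature extraction, overlays, t-test and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ctc_markerquant as cm
from ctc_markerquant.errors import FormatError
from ctc_markerquant.segmentation import trace_contour

from conftest import (
    BACKGROUND_MU,
    BACKGROUND_SIGMA,
    disk_mask,
    make_frame,
    marker_blob_spec,
)


def make_object(mask, channel="MARKER1"):
    return cm.SegmentedObject(
        channel_name=channel, mask=mask, contour=trace_contour(mask),
        scale_index=0, area_px=int(mask.sum()))


class TestMeasureChannel:
    def test_absent_object_is_all_zero(self):
        meas = cm.measure_channel(None, make_frame(np.ones((10, 10))))
        assert meas == cm.ChannelMeasurements()
        assert meas.size == 0 and meas.mean_intensity == 0.0

    def test_single_pixel_object(self):
        px = np.zeros((9, 9))
        px[4, 4] = 42.0
        mask = px > 0
        meas = cm.measure_channel(make_object(mask), make_frame(px))
        assert meas.mean_intensity == meas.max_intensity == meas.mass == 42.0
        assert meas.size == 1 and meas.std_intensity == 0.0

    def test_digital_disk_radius_5(self):
        """Brute-force oracle: 81 pixel centers within distance 5, value 50."""
        mask = disk_mask((20, 20), (10, 10), 5.0)
        assert mask.sum() == 81  # enumeration oracle
        frame = make_frame(np.where(mask, 50.0, 0.0))
        meas = cm.measure_channel(make_object(mask), frame)
        assert meas.size == 81
        assert meas.mean_intensity == pytest.approx(50.0)
        assert meas.mass == pytest.approx(4050.0)
        assert meas.eccentricity < 0.1
        assert 1.0 <= meas.perimeter2area <= 1.3

    def test_ellipse_eccentricity_from_moments(self):
        """Digital ellipse with semi-axes (10, 5): ecc = sqrt(1-25/100)."""
        yy, xx = np.mgrid[0:41, 0:41].astype(float)
        mask = ((yy - 20) / 5.0) ** 2 + ((xx - 20) / 10.0) ** 2 <= 1.0
        meas = cm.measure_channel(make_object(mask),
                                  make_frame(np.ones((41, 41))))
        assert meas.eccentricity == pytest.approx(np.sqrt(1 - 25 / 100), abs=0.05)

    def test_shape_mismatch_is_error(self):
        mask = disk_mask((20, 20), (10, 10), 3.0)
        with pytest.raises(FormatError):
            cm.measure_channel(make_object(mask), make_frame(np.ones((30, 30))))

    def test_mass_identity_and_circularity_on_random_shapes(self, rng):
        """mass == mean*size exactly; p2a >= 1, minimized by disks."""
        disk_p2a = None
        for trial in range(50):
            shape = (60, 60)
            base = rng.uniform(20, 40, 2)
            mask = disk_mask(shape, tuple(base), rng.uniform(3.5, 8))
            for _ in range(int(rng.integers(0, 3))):
                # satellite blobs overlap the base disk, keeping the mask
                # 8-connected as segmentation guarantees
                c = base + rng.uniform(-3, 3, 2)
                mask |= disk_mask(shape, tuple(c), rng.uniform(3.5, 8))
            px = rng.uniform(1, 300, size=shape)
            meas = cm.measure_channel(make_object(mask), make_frame(px, header=(0, 4095)))
            assert meas.mass == pytest.approx(
                meas.mean_intensity * meas.size, rel=1e-9)
            assert meas.perimeter2area >= 1.0
            if disk_p2a is None:
                disk = disk_mask(shape, (30, 30), 6)
                disk_p2a = cm.measure_channel(
                    make_object(disk), make_frame(px, header=(0, 4095))
                ).perimeter2area
            if mask.sum() > 2 * disk_mask(shape, (30, 30), 6).sum():
                # clearly non-circular multi-blob shapes are less circular
                assert meas.perimeter2area >= disk_p2a - 0.25


class TestRelativeOverlay:
    def test_identical_masks(self):
        m = disk_mask((20, 20), (10, 10), 3.0)
        assert cm.relative_overlay(m, m) == 1.0

    def test_disjoint_masks(self):
        a = disk_mask((30, 30), (8, 8), 3.0)
        b = disk_mask((30, 30), (22, 22), 3.0)
        assert cm.relative_overlay(a, b) == 0.0

    def test_partial_overlap_fraction(self):
        a = np.zeros((10, 10), bool)
        a[:4, :10] = True          # 40 px
        b = np.zeros((10, 10), bool)
        b[3, :10] = True           # overlaps 10 px of a
        assert cm.relative_overlay(a, b) == pytest.approx(0.25)

    def test_empty_reference_gives_zero(self):
        empty = np.zeros((5, 5), bool)
        full = np.ones((5, 5), bool)
        assert cm.relative_overlay(empty, full) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(FormatError):
            cm.relative_overlay(np.ones((4, 4), bool), np.ones((5, 5), bool))


class TestMeasureEvent:
    def _event_spec(self, marker_plateau, seed=0):
        blobs = {
            "DAPI": (cm.BlobSpec(center=(40, 40), radius_px=6, plateau=800.0),),
            "CK": (cm.BlobSpec(center=(40, 40), radius_px=9, plateau=400.0),),
        }
        if marker_plateau > 0:
            blobs["MARKER1"] = (cm.BlobSpec(center=(40, 40), radius_px=8,
                                            plateau=marker_plateau),)
        return cm.EventSpec(blobs=blobs, seed=seed)

    def test_zero_marker_means_zero_intensity(self):
        thumb, _ = cm.thumbnail_from_spec(self._event_spec(0.0, seed=4))
        record = cm.measure_event(thumb)
        assert record.channels["MARKER1"].mean_intensity == 0.0
        assert record.channels["MARKER1"].size == 0

    def test_marker_plateau_recovered_within_noise(self):
        thumb, truth = cm.thumbnail_from_spec(self._event_spec(150.0, seed=8))
        record = cm.measure_event(thumb)
        meas = record.channels["MARKER1"]
        tol = 3 * BACKGROUND_SIGMA / np.sqrt(meas.size)
        assert meas.mean_intensity == pytest.approx(150.0, abs=tol)
        assert meas.median_intensity == pytest.approx(150.0, abs=2 * tol)

    def test_overlays_reflect_channel_geometry(self):
        """CK blob covering the nucleus, CD45 silent: high CK overlay, 0 CD45."""
        thumb, _ = cm.thumbnail_from_spec(self._event_spec(150.0, seed=15))
        record = cm.measure_event(thumb)
        assert record.dapi_ck_overlay >= 0.9
        assert record.dapi_cd45_overlay == 0.0

    def test_invariant_to_tiff_frame_order(self, tmp_path):
        spec = self._event_spec(150.0, seed=23)
        order_a = ("DAPI", "CK", "CD45", "MARKER1")
        order_b = ("MARKER1", "CD45", "CK", "DAPI")
        path_a, _ = cm.generate_thumbnail(spec, tmp_path, event_id="a",
                                          channel_order=order_a)
        path_b, _ = cm.generate_thumbnail(spec, tmp_path, event_id="b",
                                          channel_order=order_b)
        rec_a = cm.measure_event(cm.load_thumbnail(
            path_a, dict(enumerate(order_a))))
        rec_b = cm.measure_event(cm.load_thumbnail(
            path_b, dict(enumerate(order_b))))
        for ch in cm.CHANNELS:
            assert rec_a.channels[ch] == rec_b.channels[ch]


class TestIntensityDifferenceTest:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = cm.intensity_difference_test(a, a)
        assert t == 0.0 and p == 1.0

    def test_separated_populations_are_significant(self, rng):
        a = rng.normal(30, BACKGROUND_SIGMA, 500)
        b = rng.normal(60, BACKGROUND_SIGMA, 500)
        t, p = cm.intensity_difference_test(a, b)
        assert p < 0.001
        # closed-form Welch statistic as oracle
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        assert t == pytest.approx((a.mean() - b.mean()) / se, rel=1e-12)

    def test_reshuffled_sample_has_zero_statistic(self, rng):
        a = rng.normal(50, 5, 100)
        b = a[rng.permutation(a.size)]
        t, _ = cm.intensity_difference_test(a, b)
        assert t == pytest.approx(0.0, abs=1e-10)

    def test_small_sample_rejected(self):
        with pytest.raises(FormatError):
            cm.intensity_difference_test([1.0], [1.0, 2.0])


class TestAntigenCalibration:
    def test_exact_collinear_points(self):
        line = cm.fit_antigen_calibration([(0, 0), (1, 10), (2, 20)])
        assert line.slope == pytest.approx(10.0)
        assert line.intercept == pytest.approx(0.0, abs=1e-9)
        assert line.r_squared == pytest.approx(1.0)

    def test_perturbed_points_match_normal_equations(self, rng):
        x = np.array([10.0, 120.0, 400.0])
        y = 2000.0 * x + 5000.0 + rng.normal(0, 3000, 3)
        line = cm.fit_antigen_calibration(list(zip(x, y)))
        # brute-force normal equations oracle
        X = np.c_[x, np.ones_like(x)]
        slope, intercept = np.linalg.lstsq(X, y, rcond=None)[0]
        assert line.slope == pytest.approx(slope, rel=1e-9)
        assert line.intercept == pytest.approx(intercept, rel=1e-9)
        assert 0 < line.r_squared < 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FormatError):
            cm.fit_antigen_calibration([(1.0, 5.0)])
        with pytest.raises(FormatError):
            cm.fit_antigen_calibration([(1.0, 5.0), (1.0, 9.0)])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 4095), min_size=4, max_size=30))
def test_mass_identity_property(values):
    """mass == mean*size for arbitrary in-mask intensity samples."""
    n = len(values)
    side = int(np.ceil(np.sqrt(n)))
    px = np.zeros((side + 2, side + 2))
    mask = np.zeros_like(px, dtype=bool)
    for i, v in enumerate(values):
        r, c = divmod(i, side)
        px[r + 1, c + 1] = v
        mask[r + 1, c + 1] = True
    meas = cm.measure_channel(make_object(mask), make_frame(px))
    assert meas.mass == pytest.approx(meas.mean_intensity * meas.size, rel=1e-9,
                                      abs=1e-9)
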