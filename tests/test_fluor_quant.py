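"""Projections, ROI intensities, profiles, alignment and the rim-spread index."""

import numpy as np
import pytest

from sepexo.fluor_quant import (
    ImageStack,
    LineProfile,
    RectROI,
    align_profiles,
    axial_colocalization_profile,
    line_scan,
    project,
    read_stack,
    rim_spread_index,
    roi_background_subtracted_intensity,
    write_stack,
)
from sepexo.synthetic_data import division_pattern_mask, make_division_stack


def _stack(data, px=0.1, dz=0.5):
    data = np.asarray(data, float)
    return ImageStack(data=data, pixel_size_um=px, z_step_um=dz,
                      channels=[f"ch{i}" for i in range(data.shape[0])])


# ---------------------------------------------------------------- projections

def test_single_slice_projection_equals_slice():
    rng = np.random.default_rng(0)
    img = rng.uniform(0, 10, (1, 1, 8, 9))
    stack = _stack(img)
    np.testing.assert_array_equal(project(stack, 0, "sum"), img[0, 0])
    np.testing.assert_array_equal(project(stack, 0, "max"), img[0, 0])


def test_constant_stack_projections():
    stack = _stack(np.full((1, 5, 4, 4), 3.0))
    np.testing.assert_allclose(project(stack, 0, "sum"), 15.0)
    np.testing.assert_allclose(project(stack, 0, "max"), 3.0)


def test_sum_projection_matches_loop_oracle():
    rng = np.random.default_rng(1)
    data = rng.uniform(0, 100, (2, 6, 10, 12))
    stack = _stack(data)
    oracle = np.zeros((10, 12))
    for z in range(2, 5):
        oracle += data[1, z]
    np.testing.assert_allclose(project(stack, 1, "sum", z_range=(2, 5)), oracle)
    with pytest.raises(ValueError, match="empty z range"):
        project(stack, 0, "sum", z_range=(3, 3))


# ------------------------------------------------------------- ROI intensity

def test_uniform_image_background_subtracts_to_zero():
    img = np.full((40, 40), 7.5)
    roi1 = RectROI(10, 10, 10, 10)
    roi2 = RectROI(5, 5, 20, 20)
    assert roi_background_subtracted_intensity(img, roi1, roi2) == pytest.approx(0.0)


def test_planted_signal_recovered_exactly_over_background():
    rng = np.random.default_rng(3)
    b = 12.5
    img = np.full((50, 60), b)
    signal = rng.uniform(0, 50, (6, 8))
    img[20:26, 30:38] += signal
    roi1 = RectROI(28, 18, 12, 10)  # contains the signal entirely
    roi2 = RectROI(22, 12, 24, 22)
    corrected = roi_background_subtracted_intensity(img, roi1, roi2)
    assert corrected == pytest.approx(signal.sum(), rel=1e-12)


def test_double_area_roi_reduces_to_annulus_subtraction():
    """With A2 = 2*A1 the correction is I(ROI1) - I(annulus)."""
    rng = np.random.default_rng(4)
    img = rng.uniform(0, 20, (30, 30))
    roi1 = RectROI(10, 10, 10, 10)
    roi2 = RectROI(10, 5, 10, 20)  # 200 px = twice the area, containing roi1
    i1 = img[roi1.slice()].sum()
    annulus = img[roi2.slice()].sum() - i1
    got = roi_background_subtracted_intensity(img, roi1, roi2)
    assert got == pytest.approx(i1 - annulus, rel=1e-12)


def test_roi_validation_errors():
    img = np.zeros((20, 20))
    with pytest.raises(ValueError, match="within ROI2"):
        roi_background_subtracted_intensity(img, RectROI(0, 0, 10, 10), RectROI(5, 5, 10, 10))
    with pytest.raises(ValueError, match="strictly larger"):
        roi_background_subtracted_intensity(img, RectROI(5, 5, 10, 10), RectROI(5, 5, 10, 10))


def test_intensity_outputs_scale_linearly_with_image():
    rng = np.random.default_rng(5)
    img = rng.uniform(0, 30, (40, 40))
    roi1, roi2 = RectROI(10, 10, 8, 8), RectROI(6, 6, 16, 16)
    base = roi_background_subtracted_intensity(img, roi1, roi2)
    scaled = roi_background_subtracted_intensity(3.5 * img, roi1, roi2)
    assert scaled == pytest.approx(3.5 * base, rel=1e-12)
    prof = line_scan(img, (2, 20), (37, 20), 3)
    prof_scaled = line_scan(3.5 * img, (2, 20), (37, 20), 3)
    np.testing.assert_allclose(prof_scaled.values, 3.5 * prof.values, rtol=1e-12)


def test_translation_equivariance_of_roi_intensity():
    rng = np.random.default_rng(6)
    patch = rng.uniform(0, 30, (30, 30))
    img = np.zeros((50, 50))
    img[5:35, 5:35] = patch
    shifted = np.zeros((50, 50))
    shifted[12:42, 9:39] = patch
    a = roi_background_subtracted_intensity(img, RectROI(10, 10, 8, 8), RectROI(7, 7, 16, 16))
    b = roi_background_subtracted_intensity(
        shifted, RectROI(14, 17, 8, 8), RectROI(11, 14, 16, 16)
    )
    assert b == pytest.approx(a, rel=1e-12)


# ------------------------------------------------------------------- profiles

def test_axial_profile_flat_on_uniform_image():
    img = np.full((30, 40), 4.0)
    prof = axial_colocalization_profile(img, RectROI(5, 10, 30, 10), 0.1)
    np.testing.assert_allclose(prof.values, 4.0)
    assert np.all(np.diff(prof.positions) > 0)


def test_axial_profile_matches_column_mean_oracle():
    rng = np.random.default_rng(7)
    img = rng.uniform(0, 9, (25, 35))
    roi = RectROI(4, 6, 20, 12)
    prof = axial_colocalization_profile(img, roi, 0.2)
    oracle = img[6:18, 4:24].mean(axis=0)
    np.testing.assert_allclose(prof.values, oracle)
    assert prof.positions[0] == pytest.approx((4 + 0.5) * 0.2)


def test_two_channel_offset_recovered_from_axial_profiles():
    stack, truth = make_division_stack(
        pattern="disk", second_channel_offset_um=0.4, seed=9
    )
    n = stack.data.shape[-1]
    roi = RectROI(0, n // 2 - 7, n, 15)
    profs = [
        axial_colocalization_profile(project(stack, ch, "max"), roi, stack.pixel_size_um)
        for ch in stack.channels
    ]
    aligned = align_profiles(profs, "brightest_pixel")
    sep = aligned[1].alignment["origin_um"] - aligned[0].alignment["origin_um"]
    assert sep == pytest.approx(0.4, abs=stack.pixel_size_um)


# ------------------------------------------------------------------ line scan

def test_line_scan_uniform_and_width_one_row():
    img = np.full((20, 30), 2.0)
    prof = line_scan(img, (3, 10), (25, 10), width_pixels=3)
    np.testing.assert_allclose(prof.values, 2.0)
    rng = np.random.default_rng(8)
    img = rng.uniform(0, 5, (20, 30))
    prof1 = line_scan(img, (3, 10), (25, 10), width_pixels=1)
    np.testing.assert_allclose(prof1.values, img[10, 3:26])


def test_width3_scan_is_mean_of_three_parallel_width1_scans():
    rng = np.random.default_rng(9)
    img = rng.uniform(0, 5, (20, 30))
    prof3 = line_scan(img, (3, 10), (25, 10), width_pixels=3)
    rows = [line_scan(img, (3, y), (25, y), width_pixels=1).values for y in (9, 10, 11)]
    np.testing.assert_allclose(prof3.values, np.mean(rows, axis=0))


def test_oblique_line_scan_runs_and_zero_length_errors():
    rng = np.random.default_rng(10)
    img = rng.uniform(0, 5, (30, 30))
    prof = line_scan(img, (5.0, 5.0), (20.0, 24.0), width_pixels=3)
    assert prof.values.size == prof.positions.size > 10
    with pytest.raises(ValueError, match="zero-length"):
        line_scan(img, (5, 5), (5, 5))


# ------------------------------------------------------------------ alignment

def _gauss_profile(center, positions, label=""):
    vals = np.exp(-((positions - center) ** 2) / 0.08)
    return LineProfile(positions=positions, values=vals, label=label)


def test_reference_peak_alignment_shifts_by_planted_peak():
    pos = np.linspace(-2, 3, 101)
    ref = _gauss_profile(1.2, pos, "ref")
    profs = [_gauss_profile(0.0, pos), _gauss_profile(0.5, pos)]
    aligned = align_profiles(profs, "reference_peak", reference=ref)
    for orig, moved in zip(profs, aligned):
        np.testing.assert_allclose(moved.positions, orig.positions - 1.2, atol=1e-9)
        np.testing.assert_array_equal(moved.values, orig.values)


def test_brightest_pixel_alignment_is_idempotent_when_centered():
    pos = np.linspace(-2, 2, 81)
    prof = _gauss_profile(0.0, pos)
    aligned = align_profiles([prof], "brightest_pixel")[0]
    np.testing.assert_allclose(aligned.positions, prof.positions, atol=1e-9)


def test_two_peak_midpoint_alignment_exact_on_symmetric_profile():
    pos = np.linspace(0, 4, 161)
    vals = np.exp(-((pos - 1.3) ** 2) / 0.02) + np.exp(-((pos - 2.7) ** 2) / 0.02)
    prof = LineProfile(positions=pos, values=vals)
    aligned = align_profiles([prof], "two_peak_midpoint")[0]
    assert aligned.alignment["origin_um"] == pytest.approx(2.0, abs=1e-9)
    single = _gauss_profile(1.0, pos, label="mono")
    with pytest.raises(ValueError, match="mono"):
        align_profiles([single], "two_peak_midpoint")


def test_external_center_alignment():
    pos = np.linspace(0, 2, 21)
    prof = LineProfile(positions=pos, values=np.ones(21))
    aligned = align_profiles([prof], "external_center", centers=[0.7])[0]
    assert aligned.positions[0] == pytest.approx(-0.7)
    with pytest.raises(ValueError, match="one center per profile"):
        align_profiles([prof], "external_center")


# ------------------------------------------------------------ rim spread index

def _diameter_profile(stack, truth):
    mid = stack.data.shape[1] // 2
    img = stack.data[0, mid]
    c = int(truth.center_px)
    r = int(round(truth.cell_radius_um / stack.pixel_size_um))
    return line_scan(img, (c - r, c), (c + r, c), 3, stack.pixel_size_um)


def test_ring_and_disk_rim_spread_indices():
    ring_stack, ring_truth = make_division_stack("ring", psf_sigma_um=0.1,
                                                 poisson_noise=True, seed=12)
    disk_stack, disk_truth = make_division_stack("disk", psf_sigma_um=0.1,
                                                 poisson_noise=True, seed=13)
    assert rim_spread_index(_diameter_profile(ring_stack, ring_truth)) < 0.2
    assert rim_spread_index(_diameter_profile(disk_stack, disk_truth)) > 0.6


def test_rim_spread_index_undefined_on_zero_profile():
    prof = LineProfile(positions=np.arange(9.0), values=np.zeros(9))
    with pytest.raises(ValueError, match="all-zero"):
        rim_spread_index(prof)


# ----------------------------------------------------------------- stack I/O

def test_stack_roundtrip_with_calibration(tmp_path):
    stack, _ = make_division_stack("ring", seed=1)
    path = tmp_path / "stack.tif"
    write_stack(stack, path)
    back = read_stack(path)
    assert back.pixel_size_um == stack.pixel_size_um
    assert back.z_step_um == stack.z_step_um
    assert back.channels == stack.channels
    np.testing.assert_allclose(back.data, stack.data, rtol=1e-6)


def test_analytic_mask_exact_without_noise_or_psf():
    stack, truth = make_division_stack("ring", psf_sigma_um=0.0,
                                       poisson_noise=False, seed=0)
    n = stack.data.shape[-1]
    mask = division_pattern_mask("ring", n, 0.1, truth.cell_radius_um)
    zc = (stack.data.shape[1] - 1) / 2
    for zi in range(stack.data.shape[1]):
        expected = truth.peak_intensity * mask * np.exp(-((zi - zc) ** 2) / 2)
        np.testing.assert_allclose(stack.data[0, zi], expected, rtol=1e-12)
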