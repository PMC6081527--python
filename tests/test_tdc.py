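"""ROI placement, TDC extraction, arrival trigger, smoothing, decimation."""

import numpy as np
import pytest

from stenoflow import (
    ImageSeries,
    PhantomGeometry,
    ROISpec,
    TimeDensityCurve,
    decimate_frames,
    detect_bolus_arrival,
    extract_tdc,
    place_default_rois,
    smooth_tdc,
)

# --- ROI placement ---------------------------------------------------------


def test_default_roi_centres_match_protocol():
    rois = {r.label: r for r in place_default_rois(PhantomGeometry.for_grade(80))}
    assert rois["IV"].center_axial - rois["I"].center_axial == pytest.approx(100.0)
    # inner edges of ROI II and III abut the shoulders of the 4 mm stenosis
    gap = (rois["III"].center_axial - rois["III"].size / 2) - (
        rois["II"].center_axial + rois["II"].size / 2
    )
    assert gap == pytest.approx(4.0)


def test_wider_stenosis_shifts_abutting_rois_outward():
    geometry = PhantomGeometry(stenosis_inner_diameter=6.0, stenosis_length=30.0)
    rois = {r.label: r for r in place_default_rois(geometry)}
    assert rois["II"].center_axial == pytest.approx(-20.0)  # -15 shoulder - 5 half size
    assert rois["III"].center_axial == pytest.approx(20.0)
    assert rois["I"].center_axial == pytest.approx(-50.0)


def test_roi_beyond_imaged_field_rejected():
    geometry = PhantomGeometry(tube_length=80.0)
    with pytest.raises(ValueError, match="beyond"):
        place_default_rois(geometry)


# --- extraction ------------------------------------------------------------


def make_series(frames, frame_rate=30.0, pixel_size=0.5, injection_start=0.3):
    geometry = PhantomGeometry()
    ny, nx = frames.shape[1:]
    return ImageSeries(
        timestamps=np.arange(frames.shape[0]) / frame_rate,
        frames=frames.astype(np.uint16),
        pixel_size=pixel_size,
        origin=(-nx * pixel_size / 2.0, -ny * pixel_size / 2.0),
        geometry=geometry,
        meta={"frame_rate": frame_rate, "injection_start": injection_start},
    )


def test_constant_frames_yield_zero_tdc():
    series = make_series(np.full((60, 28, 400), 7))
    tdc = extract_tdc(series, ROISpec("I", -50.0))
    assert np.all(tdc.values == 0.0)


def test_step_in_roi_appears_at_step_frame():
    frames = np.zeros((300, 28, 400))
    rows, cols = slice(4, 24), slice(90, 110)  # the ROI footprint at x=-50, 0.5 mm px
    frames[30:, rows, cols] = 10
    series = make_series(frames)
    tdc = extract_tdc(series, ROISpec("I", -50.0))
    assert tdc.values[29] == 0.0
    assert tdc.values[30] == pytest.approx(10.0)
    assert tdc.times[30] == pytest.approx(1.0)


def test_extraction_ignores_pixels_outside_roi():
    frames = np.zeros((30, 28, 400))
    frames[:, 4:24, 90:110] = 50
    series = make_series(frames)
    base = extract_tdc(series, ROISpec("I", -50.0))
    frames2 = frames.copy()
    frames2[:, :, 200:] = 9999  # clutter far away from the ROI
    series2 = make_series(frames2)
    assert np.array_equal(base.values, extract_tdc(series2, ROISpec("I", -50.0)).values)


def test_roi_outside_imaged_field_rejected():
    series = make_series(np.zeros((10, 28, 400)))
    with pytest.raises(ValueError, match="ROI 'offfield'"):
        extract_tdc(series, ROISpec("offfield", 300.0))


def test_extraction_matches_field_level_oracle(small_series):
    """Noise-free TDC equals the mean projected signal computed straight
    from the concentration field over the ROI span (flat profile)."""
    from stenoflow import AcquisitionSettings, project_to_images

    field, base_series = small_series
    geometry = PhantomGeometry.for_grade(0)
    acq = AcquisitionSettings(duration=6.0, pixel_size=0.5, noise_sd=0.0)
    series = project_to_images(
        field, geometry, acq, lateral_profile="flat",
        meta={"injection_start": base_series.meta["injection_start"]},
    )
    roi = place_default_rois(geometry)[0]
    tdc = extract_tdc(series, roi)

    # oracle: flat profile spreads atten*phi*pi*r/2 uniformly across the lumen
    atten, r = 500.0, geometry.inner_diameter / 2.0
    span = (field.axial_grid >= roi.center_axial - roi.size / 2) & (
        field.axial_grid < roi.center_axial + roi.size / 2
    )
    phi = field.sample(series.timestamps)[:, span] / geometry.lumen_area
    expected = atten * phi.mean(axis=1) * np.pi * r / 2.0
    expected = np.clip(expected - expected[series.timestamps < 0.5].mean(), 0.0, None)
    assert np.allclose(tdc.values, expected, atol=1.5, rtol=0.02)


# --- arrival trigger -------------------------------------------------------


def tri_tdc(peak_time=2.0, height=100.0, frame_rate=30.0, n=300, start=2.0, width=1.0):
    t = np.arange(n) / frame_rate
    values = np.clip(height * (1 - np.abs(t - (start + width)) / width), 0.0, None)
    values[t < start] = 0.0
    return TimeDensityCurve(t, values, ROISpec("I", -50.0), frame_rate)


def test_arrival_on_triangular_bolus_within_one_frame():
    tdc = tri_tdc()
    arrival = detect_bolus_arrival(tdc)
    first_above = tdc.times[np.argmax(tdc.values > 5.0)]
    assert abs(arrival - first_above) <= 1.0 / tdc.frame_rate


def test_arrival_on_step_is_exact():
    t = np.arange(100) / 30.0
    values = np.where(np.arange(100) >= 40, 100.0, 0.0)
    tdc = TimeDensityCurve(t, values, ROISpec("I", -50.0), 30.0)
    assert detect_bolus_arrival(tdc) == pytest.approx(t[40])


def test_degenerate_thresholds_rejected():
    tdc = tri_tdc()
    for frac in (0.0, 1.0, -0.1):
        with pytest.raises(ValueError, match="threshold_fraction"):
            detect_bolus_arrival(tdc, frac)


def test_no_bolus_raises():
    t = np.arange(50) / 30.0
    tdc = TimeDensityCurve(t, np.zeros(50), ROISpec("I", -50.0), 30.0)
    with pytest.raises(ValueError, match="no bolus detected"):
        detect_bolus_arrival(tdc)


# --- smoothing -------------------------------------------------------------


def test_zero_kernel_is_identity():
    tdc = tri_tdc()
    assert smooth_tdc(tdc, 0.0) is tdc


@pytest.mark.parametrize("sigma", [0.2, 0.4])
def test_gaussian_gain_on_valve_frequency_sinusoid(sigma):
    """Amplitude attenuation matches the analytic transfer exp(-2 pi^2 f^2 s^2)."""
    f0, rate = 1.25, 30.0
    t = np.arange(1200) / rate
    tdc = TimeDensityCurve(
        t, 100.0 + 10.0 * np.sin(2 * np.pi * f0 * t), ROISpec("I", -50.0), rate
    )
    sm = smooth_tdc(tdc, sigma)
    interior = slice(300, 900)
    gain = (sm.values[interior].max() - sm.values[interior].min()) / 20.0
    expected = np.exp(-2.0 * np.pi**2 * f0**2 * sigma**2)
    assert gain == pytest.approx(expected, rel=0.05)
    assert sm.smoothed and not tdc.smoothed


def test_smoothing_preserves_time_integral():
    tdc = tri_tdc(start=4.0)
    sm = smooth_tdc(tdc, 0.3)
    raw = np.trapezoid(tdc.values, tdc.times)
    smoothed = np.trapezoid(sm.values, sm.times)
    assert smoothed == pytest.approx(raw, rel=1e-3)


def test_smoothing_shifts_arrival_by_less_than_kernel_sd():
    tdc = tri_tdc(start=4.0)
    sigma = 0.3
    raw = detect_bolus_arrival(tdc)
    smoothed = detect_bolus_arrival(smooth_tdc(tdc, sigma))
    assert abs(smoothed - raw) <= sigma


def test_negative_kernel_rejected():
    with pytest.raises(ValueError):
        smooth_tdc(tri_tdc(), -0.1)


# --- frame decimation ------------------------------------------------------


def test_decimation_identity_and_subsampling():
    frames = np.arange(300 * 4 * 6, dtype=np.uint16).reshape(300, 4, 6) % 1000
    series = make_series(frames, pixel_size=2.0)
    assert decimate_frames(series, 30.0) is series
    dec = decimate_frames(series, 10.0)
    assert dec.frames.shape[0] == 100
    assert dec.frame_rate == pytest.approx(10.0)
    assert np.array_equal(dec.frames, series.frames[::3])


def test_decimation_validates_rate():
    series = make_series(np.zeros((30, 4, 6)), pixel_size=2.0)
    with pytest.raises(ValueError, match="positive"):
        decimate_frames(series, 0.0)
    with pytest.raises(ValueError, match="exceed"):
        decimate_frames(series, 60.0)
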