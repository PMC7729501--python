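"""Unit and property tests for the detection pipeline stages."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qdstem import (
    DetectionConfig,
    ImageGrid,
    SizeGate,
    derive_small_gate,
    diameter_to_area_px,
    fourier_background_filter,
    gaussian_smooth,
    gate_particles,
    kapur_threshold,
    label_components,
    run_pipeline,
    simulate_field,
    SimulationConfig,
)
from qdstem.detect import (
    Component,
    DegenerateHistogramError,
    area_px_to_diameter,
)

PIXEL = 0.83


# ---------------------------------------------------------------------------
# maximum-entropy threshold
# ---------------------------------------------------------------------------

def kapur_bruteforce(hist):
    """Independent exhaustive-search oracle: literal entropy sums per split."""
    h = np.asarray(hist, dtype=float)
    p = h / h.sum()
    best_t, best_val = None, -np.inf
    for t in range(len(h) - 1):
        back = p[: t + 1]
        fore = p[t + 1 :]
        val = 0.0
        for cls in (back, fore):
            mass = cls.sum()
            if mass > 0:
                q = cls[cls > 0] / mass
                val += -(q * np.log(q)).sum()
        if val > best_val + 1e-12:  # strict improvement => smallest-t tie break
            best_val, best_t = val, t
    return best_t


def test_kapur_two_delta_histogram_ties_to_smallest_split():
    # mass only at the extremes: every split separates them with zero
    # entropy on both sides, so the smallest candidate wins
    hist = np.zeros(256, dtype=int)
    hist[0] = hist[255] = 100
    assert kapur_threshold(hist) == 0


def test_kapur_degenerate_single_bin_raises():
    hist = np.zeros(256, dtype=int)
    hist[17] = 1000
    with pytest.raises(DegenerateHistogramError):
        kapur_threshold(hist)


def test_kapur_matches_bruteforce_on_random_histograms(rng):
    for _ in range(300):
        hist = rng.integers(0, 1000, size=256)
        # occasionally sparse histograms
        if rng.random() < 0.3:
            mask = rng.random(256) < 0.9
            hist = np.where(mask, 0, hist)
        if np.count_nonzero(hist) < 2:
            continue
        assert kapur_threshold(hist) == kapur_bruteforce(hist)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(min_value=0, max_value=10_000), min_size=2, max_size=64)
)
def test_kapur_property_equals_oracle(hist):
    hist = np.asarray(hist)
    if np.count_nonzero(hist) < 2:
        with pytest.raises(DegenerateHistogramError):
            kapur_threshold(hist)
    else:
        assert kapur_threshold(hist) == kapur_bruteforce(hist)


# ---------------------------------------------------------------------------
# linear filters
# ---------------------------------------------------------------------------

def test_gaussian_smooth_preserves_constant():
    image = ImageGrid(np.full((64, 64), 7.5), PIXEL)
    out = gaussian_smooth(image, 1.5)
    assert np.allclose(out.values, 7.5)


def test_gaussian_smooth_kernel_is_normalized():
    impulse = np.zeros((129, 129))
    impulse[64, 64] = 1.0
    out = gaussian_smooth(ImageGrid(impulse, PIXEL), 1.5)
    assert out.values.sum() == pytest.approx(1.0, rel=1e-9)


def test_gaussian_smooth_white_noise_variance(rng):
    # var of Gaussian-filtered unit white noise -> 1/(4 pi sigma^2)
    noise = rng.standard_normal((512, 512))
    out = gaussian_smooth(ImageGrid(noise, PIXEL), 1.5)
    expected = 1.0 / (4.0 * math.pi * 1.5**2)
    assert out.values.var() == pytest.approx(expected, rel=0.05)


def test_gaussian_smooth_rejects_bad_sigma():
    with pytest.raises(ValueError):
        gaussian_smooth(ImageGrid(np.ones((64, 64)), PIXEL), 0.0)


def test_bandpass_removes_constant_image():
    image = ImageGrid(np.full((128, 128), 123.0), PIXEL)
    out = fourier_background_filter(image, 40.0, 2.0, offset_to_non_negative=False)
    assert np.allclose(out.values, 0.0, atol=1e-8)


def test_bandpass_retains_qd_scale_sinusoid():
    # period-10 px sinusoid sits inside the (40, 2) passband: >= 90% kept
    n = 256
    x = np.arange(n)
    image = np.sin(2 * math.pi * x / 10.0)[None, :] * np.ones((n, 1))
    out = fourier_background_filter(
        ImageGrid(image, PIXEL), 40.0, 2.0, offset_to_non_negative=False
    )
    amplitude = out.values.max()
    assert amplitude >= 0.90


def test_bandpass_suppresses_linear_ramp():
    n = 256
    ramp = np.tile(np.linspace(0.0, 1000.0, n), (n, 1))
    out = fourier_background_filter(
        ImageGrid(ramp, PIXEL), 40.0, 2.0, offset_to_non_negative=False
    )
    interior = out.values[:, 16:-16]  # boundary wrap-around excluded
    assert np.ptp(interior) <= 0.05 * 1000.0


def test_bandpass_rejects_cutoff_beyond_frame():
    with pytest.raises(ValueError):
        fourier_background_filter(ImageGrid(np.ones((64, 64)), PIXEL), 100.0, 2.0)


def test_bandpass_offset_makes_output_non_negative(rng):
    image = ImageGrid(rng.random((128, 128)) * 100, PIXEL)
    out = fourier_background_filter(image, 40.0, 2.0)
    assert out.values.min() == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# size conversion and gates
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "d_nm, expected",
    [(11.0, 137.95), (9.0, 92.35), (13.0, 192.68)],
)
def test_diameter_to_area_px_worked_values(d_nm, expected):
    assert diameter_to_area_px(d_nm, PIXEL) == pytest.approx(expected, abs=0.05)


def test_diameter_area_unit_identity():
    # pixel size d*sqrt(pi)/2 gives exactly one pixel of area
    d = 7.0
    assert diameter_to_area_px(d, d * math.sqrt(math.pi) / 2) == pytest.approx(1.0)


def test_diameter_area_roundtrip_is_exact(rng):
    for d in rng.uniform(1.0, 30.0, size=50):
        area = diameter_to_area_px(d, PIXEL)
        assert area_px_to_diameter(area, PIXEL) == pytest.approx(d, rel=1e-12)


def test_derive_small_gate_scales_diameters():
    large = SizeGate("large", 9.0, 13.0)
    small = derive_small_gate(large, 7.0 / 11.0)
    assert small.d_min_nm == pytest.approx(9.0 * 7 / 11)
    assert small.d_max_nm == pytest.approx(13.0 * 7 / 11)


def test_derive_small_gate_clips_overlap_with_warning():
    large = SizeGate("large", 9.0, 13.0)
    with pytest.warns(UserWarning):
        small = derive_small_gate(large, 0.95)
    assert small.d_max_nm < large.d_min_nm


def test_derive_small_gate_rejects_ratio_one():
    with pytest.raises(ValueError):
        derive_small_gate(SizeGate("large", 9.0, 13.0), 1.0)


def _component(area, x=50.0, y=50.0):
    return Component(area_px=area, x_px=x, y_px=y, on_edge=False)


def test_gate_particles_assigns_each_component_once():
    large = SizeGate("large", 9.0, 13.0)       # 92.3 - 192.7 px^2
    small = derive_small_gate(large)           # 37.4 - 78.0 px^2
    comps = [_component(a) for a in (138, 55, 5, 300, 80)]
    records = gate_particles(comps, large, small, PIXEL)
    labels = [r.class_label for r in records]
    assert labels == ["large", "small", "rejected", "rejected", "rejected"]
    assert len(records) == len(comps)


def test_gate_boundaries_are_inclusive():
    # build a gate whose area bounds are exactly 100 and 200 px^2
    large = SizeGate(
        "large",
        area_px_to_diameter(100, PIXEL),
        area_px_to_diameter(200, PIXEL),
    )
    small = SizeGate(
        "small", area_px_to_diameter(20, PIXEL), area_px_to_diameter(50, PIXEL)
    )
    records = gate_particles(
        [_component(100), _component(200), _component(50)], large, small, PIXEL
    )
    assert [r.class_label for r in records] == ["large", "large", "small"]


def test_gate_overlap_rejected():
    large = SizeGate("large", 9.0, 13.0)
    bad_small = SizeGate("small", 5.0, 10.0)   # overlaps the large gate
    with pytest.raises(ValueError):
        gate_particles([_component(100)], large, bad_small, PIXEL)
    with pytest.raises(ValueError):
        DetectionConfig(small_gate=bad_small)


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------

def test_label_components_empty_image():
    assert label_components(np.zeros((32, 32), dtype=bool)) == []


def test_label_components_square_centroid():
    binary = np.zeros((32, 32), dtype=bool)
    binary[10:13, 10:13] = True
    comps = label_components(binary, 8)
    assert len(comps) == 1
    assert comps[0].area_px == 9
    assert (comps[0].x_px, comps[0].y_px) == (11.0, 11.0)
    assert not comps[0].on_edge


def test_label_components_connectivity_semantics():
    binary = np.zeros((16, 16), dtype=bool)
    binary[5, 5] = binary[6, 6] = True          # diagonal touch
    assert len(label_components(binary, 8)) == 1
    assert len(label_components(binary, 4)) == 2


def test_label_components_flags_edge_touchers():
    binary = np.zeros((16, 16), dtype=bool)
    binary[0, 3:6] = True
    (comp,) = label_components(binary, 8)
    assert comp.on_edge


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _flat_blank_config():
    return SimulationConfig(
        density_large_per_um2=0.0,
        density_small_per_um2=0.0,
        texture_amplitude=0.0,
        noise_gain=0.0,
        seed=0,
    )


def test_pipeline_blank_frame_yields_no_particles(det_config):
    image, truth = simulate_field(_flat_blank_config())
    assert truth.particles.empty
    result = run_pipeline(image, det_config)
    assert result.large == [] and result.small == []


def test_pipeline_is_deterministic(det_config):
    config = SimulationConfig(seed=7, min_separation_nm=20.0)
    image, _ = simulate_field(config)
    r1 = run_pipeline(image, det_config)
    r2 = run_pipeline(image, det_config)
    assert r1.large == r2.large
    assert r1.small == r2.small
    assert r1.rejected == r2.rejected
    assert r1.threshold_bin == r2.threshold_bin


def test_pipeline_count_conservation(det_config):
    image, _ = simulate_field(SimulationConfig(seed=3, min_separation_nm=20.0))
    result = run_pipeline(image, det_config)
    from qdstem.detect import gaussian_smooth as gs  # noqa: F401 (sanity import)

    n_large, n_small, n_rej = map(len, (result.large, result.small, result.rejected))
    assert n_large + n_small + n_rej == result.n_components


def test_pipeline_monotonic_in_large_gate_lower_bound():
    image, _ = simulate_field(SimulationConfig(seed=5, min_separation_nm=20.0))
    counts = []
    for d_min in (8.0, 9.0, 10.0, 11.0, 12.0):
        cfg = DetectionConfig(
            large_gate=SizeGate("large", d_min, 13.0),
            small_gate=SizeGate("small", 4.0, 7.0),
        )
        counts.append(len(run_pipeline(image, cfg).large))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_pipeline_recovers_isolated_particles_at_high_snr(det_config):
    from qdstem import evaluate_recovery

    config = SimulationConfig(seed=11, min_separation_nm=20.0)
    image, truth = simulate_field(config)
    result = run_pipeline(image, det_config)
    metrics = evaluate_recovery(
        result.large + result.small,
        truth.particles,
        match_radius_px=5.0,
        exclude_border_px=10.0,
        frame_shape=image.shape,
    )
    assert metrics.precision >= 0.95
    assert metrics.recall >= 0.95
    assert metrics.rmse_px <= 1.0
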