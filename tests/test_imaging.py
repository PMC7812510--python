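"""AIF selection, perfusion/permeability maps, PI counting and profiles."""

import numpy as np
import pytest

from ptstroke.config import ScenarioConfig
from ptstroke.imaging import (
    FrameStack,
    LesionCircle,
    PerfusionMap,
    distance_profile,
    ios_difference,
    lesion_circle,
    permeability_index,
    perfusion_mask,
    pi_at_electrode,
    pi_quantify,
    select_aif,
)
from ptstroke.synth.imaging import generate_imaging


def _make_stack(pixel_traces: np.ndarray, fs=5.0, inj=30, pixel_um=10.0):
    """Stack from per-pixel traces of shape (t, ny, nx)."""
    return FrameStack(
        frames=pixel_traces, frame_rate_hz=fs, injection_frame_index=inj,
        pixel_size_um=pixel_um,
    )


def _bolus(t, t0=2.0, tp=8.0, alpha=3.0):
    x = np.maximum(t - t0, 0.0) / tp
    return x**alpha * np.exp(alpha * (1.0 - x))


@pytest.fixture(scope="module")
def imaging_bundle():
    return generate_imaging(ScenarioConfig(group="urethane", seed=7))


@pytest.fixture(scope="module")
def small_synthetic_stack():
    """32x32 stack: one arterial pixel, a hypoperfused block, a leaky block."""
    n, ny, nx = 900, 32, 32
    t = (np.arange(n) - 30) / 5.0
    frames = np.zeros((n, ny, nx))
    frames += 0.5 * 100.0 * _bolus(t, 3.5)[:, None, None]   # perfused tissue
    frames[:, :8, :8] = 0.1 * 100.0 * _bolus(t, 3.5)[:, None, None]  # core
    aif_trace = 100.0 * _bolus(t)
    frames[:, 16, 16] = aif_trace                            # arterial pixel
    leak = np.cumsum(np.where(t > 0, aif_trace, 0.0)) / 5.0
    frames[:, 24:28, 24:28] += 1.5e-3 * leak[:, None, None]
    return _make_stack(frames), t


class TestSelectAif:
    def test_flat_stack_errors(self):
        with pytest.raises(ValueError):
            select_aif(_make_stack(np.zeros((400, 8, 8))))

    def test_single_aif_pixel_selected(self, small_synthetic_stack):
        stack, t = small_synthetic_stack
        aif = select_aif(stack)
        assert [tuple(p) for p in aif.source_pixels] == [(16, 16)]
        lo, hi = aif.first_pass_window_s
        assert lo < aif.peak_time_s < hi

    def test_peak_equals_max_over_arterial_pixels(self, small_synthetic_stack):
        stack, t = small_synthetic_stack
        aif = select_aif(stack)
        assert aif.peak_value == pytest.approx(stack.frames[:, 16, 16].max(), rel=1e-6)

    def test_generator_pixels_are_arterial(self, imaging_bundle):
        bundle, truth = imaging_bundle
        aif = select_aif(bundle.fluorescein["1h"])
        art = set(zip(*np.nonzero(truth.arterial_mask)))
        assert {tuple(p) for p in aif.source_pixels} <= art

    def test_arterial_hint_restricts_selection(self, imaging_bundle):
        bundle, truth = imaging_bundle
        aif = select_aif(bundle.fluorescein["1h"], arterial_hint=truth.arterial_mask)
        assert {tuple(p) for p in aif.source_pixels} <= set(
            zip(*np.nonzero(truth.arterial_mask))
        )


class TestPerfusion:
    def test_threshold_rule(self, small_synthetic_stack):
        stack, _ = small_synthetic_stack
        aif = select_aif(stack)
        pm = perfusion_mask(stack, aif)
        assert pm.hypoperfused_mask[0, 0]          # 10% of AIF: hypoperfused
        assert not pm.hypoperfused_mask[12, 12]    # 50% of AIF: perfused
        assert pm.hypoperfused_area_um2 == pm.hypoperfused_mask.sum() * 100.0

    def test_core_disc_area(self, imaging_bundle):
        bundle, truth = imaging_bundle
        stack = bundle.fluorescein["4h"]
        pm = perfusion_mask(stack, select_aif(stack))
        r_px = truth.core_radius_um["4h"] / stack.pixel_size_um
        assert pm.hypoperfused_mask.sum() == pytest.approx(np.pi * r_px**2, rel=0.10)

    def test_pre_pt_stack_has_no_hypoperfusion(self, imaging_bundle):
        bundle, _ = imaging_bundle
        stack = bundle.fluorescein["pre"]
        pm = perfusion_mask(stack, select_aif(stack))
        assert pm.hypoperfused_mask.sum() == 0

    def test_area_grows_with_time(self, imaging_bundle):
        bundle, _ = imaging_bundle
        areas = []
        for label in ("1h", "2h", "3h", "4h"):
            stack = bundle.fluorescein[label]
            areas.append(perfusion_mask(stack, select_aif(stack)).hypoperfused_area_um2)
        assert all(a2 >= a1 for a1, a2 in zip(areas, areas[1:]))

    def test_agrees_with_brute_force(self, small_synthetic_stack):
        stack, t = small_synthetic_stack
        aif = select_aif(stack)
        pm = perfusion_mask(stack, aif)
        lo, hi = aif.first_pass_window_s
        base = stack.frames[:30].mean(axis=0)
        expected = np.zeros_like(pm.hypoperfused_mask)
        for y in range(32):
            for x in range(32):
                trace = stack.frames[:, y, x] - base[y, x]
                peak = trace[(t >= lo) & (t <= hi)].max()
                expected[y, x] = peak < 0.30 * aif.peak_value
        assert np.array_equal(pm.hypoperfused_mask, expected)


class TestPermeability:
    def test_aif_identical_pixel_has_index_one(self, small_synthetic_stack):
        stack, _ = small_synthetic_stack
        aif = select_aif(stack)
        perm = permeability_index(stack, aif)
        assert perm.index[16, 16] == pytest.approx(1.0, abs=1e-9)

    def test_silent_pixel_has_index_zero(self):
        n = 900
        t = (np.arange(n) - 30) / 5.0
        frames = np.zeros((n, 4, 4))
        frames[:, 0, 0] = 100.0 * _bolus(t)
        frames[:, 1:, :] = 0.0
        stack = _make_stack(frames)
        aif = select_aif(stack)
        perm = permeability_index(stack, aif)
        assert perm.index[2, 2] == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_brute_force_integration(self, small_synthetic_stack):
        stack, t = small_synthetic_stack
        aif = select_aif(stack)
        perm = permeability_index(stack, aif)
        tail = t > aif.first_pass_window_s[1]
        base = stack.frames[:30].mean(axis=0)
        denom = np.trapezoid(aif.intensity[tail], t[tail])
        for y, x in [(0, 0), (25, 25), (16, 16), (12, 3)]:
            num = np.trapezoid(stack.frames[tail, y, x] - base[y, x], t[tail])
            assert perm.index[y, x] == pytest.approx(max(num / denom, 0.0), rel=1e-9, abs=1e-12)

    def test_monotone_in_leakage_constant(self, imaging_bundle):
        bundle, truth = imaging_bundle
        stack = bundle.fluorescein["4h"]
        aif = select_aif(stack)
        perm = permeability_index(stack, aif)
        k = truth.permeability_k
        sel = ~truth.arterial_mask & (truth.core_radius_um["4h"] / 10.0 < 100)
        order = np.argsort(k.ravel())
        binned = perm.index.ravel()[order].reshape(8, -1).mean(axis=1)
        kb = k.ravel()[order].reshape(8, -1).mean(axis=1)
        grow = np.diff(binned[np.argsort(kb)])
        assert (grow[-4:] > 0).all()  # index rises across the upper k range

    def test_invariant_to_global_intensity_scaling(self, small_synthetic_stack):
        stack, _ = small_synthetic_stack
        scaled = _make_stack(stack.frames * 3.7)
        p1 = permeability_index(stack, select_aif(stack)).index
        p2 = permeability_index(scaled, select_aif(scaled)).index
        assert np.allclose(p1, p2, atol=1e-9)


class TestPi:
    def test_flat_image_has_no_positives(self):
        img = np.full((64, 64), 10.0)
        count, _ = pi_quantify(img, img.copy())
        assert count == 0

    def test_smooth_background_removed(self):
        yy, xx = np.mgrid[0:256, 0:256]
        img = 20.0 + 5.0 * np.sin(2 * np.pi * xx / 256.0)
        count, _ = pi_quantify(img, img.copy())
        assert count == 0

    def test_generated_spots_recovered(self, imaging_bundle):
        bundle, truth = imaging_bundle
        count, _ = pi_quantify(bundle.pi["4h"], bundle.pi["pre"])
        assert count == pytest.approx(truth.pi_true_mask["4h"].sum(), rel=0.10)

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError):
            pi_quantify(np.zeros((8, 8)), None)

    def test_electrode_disc_fractions(self):
        mask = np.zeros((64, 64), dtype=bool)
        assert pi_at_electrode(mask, (32, 32), pixel_size_um=10.0) == 0.0
        mask[:] = True
        assert pi_at_electrode(mask, (32, 32), pixel_size_um=10.0) == 1.0
        mask[:, :32] = False
        frac = pi_at_electrode(mask, (32, 31.5), pixel_size_um=10.0)
        assert frac == pytest.approx(0.5, abs=0.15)

    def test_disc_outside_frame_errors(self):
        with pytest.raises(ValueError):
            pi_at_electrode(np.zeros((64, 64), dtype=bool), (2, 2), pixel_size_um=10.0)


class TestLesionCircleAndProfile:
    def _disc_map(self, r_px=20, shape=(96, 96)):
        yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
        c = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
        return (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= r_px**2, c

    def test_disc_self_consistency(self):
        mask, c = self._disc_map(50, shape=(128, 128))
        pm = PerfusionMap(hypoperfused_mask=mask, threshold_fraction=0.3, pixel_size_um=1.0)
        circ = lesion_circle(pm)
        assert circ.radius_um == pytest.approx(50.0, abs=1.0)
        assert circ.center_px[0] == pytest.approx(c[0], abs=0.5)

    def test_two_discs_merge_to_equivalent_area(self):
        mask1, _ = self._disc_map(10)
        mask2 = np.roll(mask1, 40, axis=1)
        both = mask1 | mask2
        pm = PerfusionMap(hypoperfused_mask=both, threshold_fraction=0.3, pixel_size_um=1.0)
        circ = lesion_circle(pm)
        assert np.pi * circ.radius_um**2 == pytest.approx(both.sum(), rel=1e-6)

    def test_empty_mask_errors(self):
        pm = PerfusionMap(
            hypoperfused_mask=np.zeros((8, 8), dtype=bool),
            threshold_fraction=0.3, pixel_size_um=1.0,
        )
        with pytest.raises(ValueError):
            lesion_circle(pm)

    def test_generator_core_radius_recovered(self, imaging_bundle):
        bundle, truth = imaging_bundle
        stack = bundle.fluorescein["1h"]
        circ = lesion_circle(perfusion_mask(stack, select_aif(stack)))
        assert circ.radius_um == pytest.approx(truth.core_radius_um["1h"], rel=0.10)

    def test_signed_distances(self):
        circ = LesionCircle(center_px=(32.0, 32.0), radius_um=100.0, pixel_size_um=10.0)
        vals = np.zeros((65, 65))
        prof = distance_profile(vals, circ, pixel_size_um=10.0, bin_width_um=100.0)
        # the bin holding the center must start at -radius
        assert prof.bin_edges_um[0] <= -100.0 < prof.bin_edges_um[-1]
        assert prof.counts.sum() == vals.size

    def test_radial_field_profile(self):
        circ = LesionCircle(center_px=(64.0, 64.0), radius_um=200.0, pixel_size_um=10.0)
        yy, xx = np.mgrid[0:129, 0:129]
        r_um = np.hypot(yy - 64.0, xx - 64.0) * 10.0
        field = np.exp(-r_um / 300.0)
        prof = distance_profile(field, circ, pixel_size_um=10.0, bin_width_um=50.0)
        centers = 0.5 * (prof.bin_edges_um[:-1] + prof.bin_edges_um[1:])
        sel = (prof.counts > 30) & (centers > -180) & (centers + 200.0 < 600)
        expected = np.exp(-(centers[sel] + 200.0) / 300.0)
        assert np.allclose(prof.mean_value[sel], expected, rtol=0.05)

    def test_counts_conserved(self):
        circ = LesionCircle(center_px=(10.0, 50.0), radius_um=150.0, pixel_size_um=10.0)
        vals = np.random.default_rng(0).normal(size=(77, 91))
        prof = distance_profile(vals, circ, pixel_size_um=10.0)
        assert prof.counts.sum() == vals.size


class TestIos:
    def test_identical_images_zero(self):
        img = np.random.default_rng(0).normal(size=(32, 32))
        assert np.allclose(ios_difference(img, img), 0.0)

    def test_constant_offset(self):
        img = np.zeros((16, 16))
        assert np.allclose(ios_difference(img, img + 2.5), 2.5)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            ios_difference(np.zeros((8, 8)), np.zeros((9, 8)))

    def test_generator_front_ring(self, imaging_bundle):
        bundle, truth = imaging_bundle
        diff = ios_difference(bundle.brightfield_pre, bundle.brightfield_during_sd)
        ny, nx = diff.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        r_um = np.hypot(yy - (ny - 1) / 2, xx - (nx - 1) / 2) * 10.0
        front = truth.core_radius_um["ios_front"]
        ring = np.abs(r_um - front) < 20.0
        away = np.abs(r_um - front) > 80.0
        assert diff[ring].mean() > 5 * max(diff[away].mean(), 1e-6)
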