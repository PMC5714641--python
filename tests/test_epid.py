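import numpy as np
import pytest

from modcalc.config import ModelConfig
from modcalc.epid import (CalibrationError, EPIDKernel, calibrate_leak_weight,
                          calibrate_templates, calibrate_tng,
                          calibrate_transmission_weight, central_profile,
                          closed_field_ratio, convolve, deconvolve,
                          extract_leak_profile, interleaf_peak_metric,
                          predict_sbasic, simulate_field, tng_dip_metric)
from modcalc.fixtures import FixtureSpec, make_commissioning_images
from modcalc.fluence import accumulate_ideal_fluence, jaw_mask
from modcalc.grids import centered_grid
from modcalc.headscatter import flood_fluence
from modcalc.mlc_sequence import (closed_field_sequence,
                                  generate_sweeping_window,
                                  open_counterpart, open_field_sequence)

from conftest import COMMISSIONING_FIELDS

NARROW = EPIDKernel(((1.0, 0.3),))  # near-delta single Gaussian


class TestKernel:
    def test_rasterized_kernel_is_normalized_and_symmetric(self):
        k = EPIDKernel.default().to_array()
        assert k.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(k >= 0)
        assert np.allclose(k, k.T) and np.allclose(k, k[::-1, ::-1])

    def test_delta_kernel_convolution_is_identity(self):
        rng = np.random.default_rng(0)
        grid = centered_grid(20.0, 20.0, 784.0)
        grid.values = rng.random(grid.shape)
        out = convolve(grid, EPIDKernel.delta())
        assert np.allclose(out.values, grid.values, atol=1e-12)

    def test_convolution_preserves_total_sum(self):
        # grid large enough that the kernel tails stay inside it
        grid = centered_grid(170.0, 170.0, 784.0)
        xx, yy = np.meshgrid(grid.x_mm, grid.y_mm)
        grid.values = np.exp(-(xx ** 2 + yy ** 2) / 50.0)
        out = convolve(grid, EPIDKernel.default())
        assert out.values.sum() == pytest.approx(grid.values.sum(), rel=1e-6)

    @pytest.mark.parametrize("kernel", [NARROW, EPIDKernel.default()],
                             ids=["near-delta", "nine-gaussian"])
    def test_deconvolve_inverts_convolve_for_band_limited_maps(self, kernel):
        grid = centered_grid(60.0, 60.0, 784.0)
        xx, yy = np.meshgrid(grid.x_mm, grid.y_mm)
        grid.values = np.exp(-(xx ** 2 + yy ** 2) / (2 * 8.0 ** 2))
        rec = deconvolve(convolve(grid, kernel), kernel)
        rms = np.sqrt(np.mean((rec.values - grid.values) ** 2))
        assert rms < 1e-3

    def test_all_zero_kernel_rejected(self):
        grid = centered_grid(10.0, 10.0, 784.0)
        with pytest.raises(ValueError, match="zero kernel"):
            convolve(grid, np.zeros((3, 3)))


class TestBasicResponse:
    def test_open_field_uniform_inside_magnified_jaws(self):
        seq = open_field_sequence(10.0, 1.0)
        phi = accumulate_ideal_fluence(seq, 500.0, 10)
        flat = phi.copy(values=np.ones(phi.shape), units="relative")
        flood = flood_fluence("synthetic", horn_height=0.0, spacing_um=500.0,
                              half_x_mm=phi.x_mm[-1], half_y_mm=phi.y_mm[-1])
        s = predict_sbasic(phi, flat, flood, EPIDKernel.delta())
        inner = (np.abs(s.x_mm) < 49)[None, :] & (np.abs(s.y_mm) < 49)[:, None]
        outer = (np.abs(s.x_mm) > 56)[None, :] | (np.abs(s.y_mm) > 56)[:, None]
        assert np.allclose(s.values[inner], 1.0, atol=1e-6)
        assert np.allclose(s.values[outer], 0.0, atol=1e-9)

    def test_aperture_magnified_by_sid_ratio(self):
        # a 100 mm aperture at isocenter spans 105 mm on the imager
        seq = open_field_sequence(10.0, 1.0)
        phi = accumulate_ideal_fluence(seq, 500.0, 10)
        flat = phi.copy(values=np.ones(phi.shape), units="relative")
        flood = flood_fluence("synthetic", horn_height=0.0, spacing_um=500.0,
                              half_x_mm=phi.x_mm[-1], half_y_mm=phi.y_mm[-1])
        s = predict_sbasic(phi, flat, flood, EPIDKernel.delta())
        row = s.values[np.argmin(np.abs(s.y_mm))]
        width = s.spacing_mm * np.count_nonzero(row > 0.5)
        assert width == pytest.approx(105.0, abs=2 * s.spacing_mm)


class TestFullResponse:
    def test_open_field_reduces_to_basic_response(self, model_flat):
        seq = open_field_sequence(10.0, 1.0)
        comp = simulate_field(seq, model_flat, 1000.0, 10)
        assert np.allclose(comp.response().values, comp.s_basic.values,
                           atol=1e-12)

    def test_covered_field_closed_form_values(self, delta_model,
                                              aligned_geometry):
        """With a delta kernel and flat headscatter, an MLC-covered field
        reads B mid-leaf and A + B at an interleaf center."""
        model = delta_model.replace(geometry=aligned_geometry,
                                    magnification=1.0)
        seq = closed_field_sequence(4.0, 100.0, aligned_geometry)
        comp = simulate_field(seq, model, 784.0, 10)
        resp = comp.response()
        A, B = model.templates.weight_A, model.templates.weight_B
        iy_mid = np.argmin(np.abs(resp.y_mm - 3.92))   # leaf midline
        iy_bound = np.argmin(np.abs(resp.y_mm - 7.84))  # interleaf center
        ix = np.argmin(np.abs(resp.x_mm))
        assert resp.values[iy_mid, ix] == pytest.approx(B, abs=1e-9)
        assert resp.values[iy_bound, ix] == pytest.approx(A + B, abs=1e-9)
        assert A + B == pytest.approx(1.620e-2, abs=5e-5)

    def test_window_shows_periodic_interleaf_peaks(self, model_flat):
        seq = generate_sweeping_window(1.0, 10.0, 400.0)
        comp = simulate_field(seq, model_flat, 500.0, 600)
        prof = central_profile(comp.response())
        y = comp.p_img.y_mm
        sel = np.abs(y) < 42.0
        interior = prof[sel]
        peaks = (interior[1:-1] > interior[:-2]) & (interior[1:-1] > interior[2:])
        y_peaks = y[sel][1:-1][peaks]
        # one peak per interior boundary, spaced one magnified leaf pitch
        assert len(y_peaks) == 15
        assert np.allclose(np.diff(y_peaks), 5.0 * 1.05, atol=0.8)

    def test_responses_non_negative(self, model_flat):
        seq = generate_sweeping_window(2.0, 10.0, 400.0)
        resp = simulate_field(seq, model_flat, 1000.0, 150).response()
        assert resp.values.min() > -1e-9


class TestFullFluence:
    def test_open_field_delta_kernel_recovers_input(self, delta_model):
        seq = open_field_sequence(10.0, 1.0)
        comp = simulate_field(seq, delta_model, 1000.0, 10)
        phi = comp.full_fluence()
        mask = jaw_mask(phi, seq.jaws, scale=delta_model.magnification)
        assert np.allclose(phi.values[mask], comp.p_img.values[mask],
                           atol=1e-9)

    def test_clipping_contract(self, model_flat):
        seq = generate_sweeping_window(1.0, 10.0, 400.0)
        comp = simulate_field(seq, model_flat, 1000.0, 150)
        phi = comp.full_fluence()
        assert phi.values.min() >= 0.0
        outside = ~jaw_mask(phi, seq.jaws, scale=model_flat.magnification,
                            guard_px=1)
        assert np.all(phi.values[outside] == 0.0)

    def test_forward_backward_consistency(self, model_flat):
        """Re-convolving the recovered fluence reproduces the predicted
        response inside the jaws (regularization tolerance)."""
        seq = generate_sweeping_window(1.0, 10.0, 400.0)
        comp = simulate_field(seq, model_flat, 500.0, 600)
        from modcalc._fft import convolve2d_same

        resp = comp.response()
        back = convolve2d_same(comp.full_fluence().values, comp.kernel2d)
        inner = (np.abs(comp.p_img.x_mm) < 45)[None, :] \
            & (np.abs(comp.p_img.y_mm) < 45)[:, None]
        err = np.abs(back - resp.values)[inner]
        assert err.max() < 1e-3 * resp.values.max()

    def test_checker_boundary_dips_survive_deconvolution(self, model_flat,
                                                         commissioning_set):
        seq = commissioning_set.sequences["checker_4cm"]
        comp = simulate_field(seq, model_flat, 1000.0, 200)
        phi = comp.full_fluence(tng_profile=(0.76, 0.84, 0.92, 0.96))
        prof = central_profile(phi)
        y = comp.p_img.y_mm
        at_boundary = float(np.interp(5.0 * 1.05, y, prof))
        at_midleaf = float(np.interp(2.5 * 1.05, y, prof))
        assert at_boundary < 0.9 * at_midleaf


class TestLeakProfileExtraction:
    def test_round_trip_through_forward_model(self, commissioning_set):
        c = commissioning_set
        got = extract_leak_profile(c.images["window_1cm"], c.model.geometry,
                                   c.sequences["window_1cm"].jaws)
        want = np.asarray(c.ground_truth.leak_profile)
        assert np.abs(np.asarray(got) - want).max() < 0.02

    def test_normalization_contract(self, commissioning_set):
        c = commissioning_set
        got = extract_leak_profile(c.images["window_1cm"], c.model.geometry,
                                   c.sequences["window_1cm"].jaws)
        assert got[3] == 1.0 and got[0] == 0.0 and got[-1] == 0.0
        assert got == tuple(reversed(got))

    def test_flat_image_raises(self, commissioning_set):
        c = commissioning_set
        flat = c.images["window_1cm"].copy(
            values=np.ones_like(c.images["window_1cm"].values))
        with pytest.raises(CalibrationError, match="peaks"):
            extract_leak_profile(flat, c.model.geometry,
                                 c.sequences["window_1cm"].jaws)


class TestCalibration:
    def test_parameter_recovery_noise_free(self, commissioning_set,
                                           calibrated_templates):
        """Calibrating against noise-free synthetic commissioning images
        recovers the embedded ground truth within 2% relative."""
        truth = commissioning_set.ground_truth
        ts = calibrated_templates
        assert ts.weight_A == pytest.approx(truth.weight_A, rel=0.02)
        assert ts.weight_B == pytest.approx(truth.weight_B, rel=0.02)
        for got, want in zip(ts.tng_profile, truth.tng_profile):
            assert got == pytest.approx(want, rel=0.02)
        for got, want in zip(ts.leak_profile, truth.leak_profile):
            assert abs(got - want) < 0.02

    def test_noisy_images_residual_at_noise_level(self):
        """At 0.5% image noise the calibrated model's prediction residual
        against the noisy image stays at the noise level."""
        noise = 0.005
        cset = make_commissioning_images(FixtureSpec(noise_rel=noise, seed=7),
                                         fields=COMMISSIONING_FIELDS)
        ts = calibrate_templates(
            cset.images["window_1cm"], cset.images["checker_4cm"],
            cset.sequences["window_1cm"], cset.sequences["checker_4cm"],
            cset.sequences["closed_10x10"], cset.model, cset.spec.closed_total)
        model = cset.model.replace_templates(ts)
        sim = simulate_field(cset.sequences["window_1cm"], model).response()
        meas = cset.images["window_1cm"]
        inner = (np.abs(sim.x_mm) < 42)[None, :] & (np.abs(sim.y_mm) < 42)[:, None]
        rel = (sim.values[inner] - meas.values[inner]) / meas.values[inner]
        assert np.sqrt(np.mean(rel ** 2)) <= 1.2 * noise

    def test_transmission_weight_closed_form_limit(self, delta_model):
        """With no interleaf contribution and a flat model the closed-field
        constraint gives B = 0.014 exactly."""
        closed = closed_field_sequence(10.0, 100.0)
        comp_closed = simulate_field(closed, delta_model, 1000.0, 10)
        comp_open = simulate_field(open_counterpart(closed), delta_model,
                                   1000.0, 10)
        B = calibrate_transmission_weight(comp_closed,
                                          comp_open.response(A=0.0),
                                          target_total=0.014, A=0.0)
        assert B == pytest.approx(0.014, abs=1e-12)

    def test_leak_weight_zero_for_peakless_image(self, model_flat):
        seq = generate_sweeping_window(1.0, 10.0, 400.0)
        comp = simulate_field(seq, model_flat, 1000.0, 150)
        measured = comp.response(A=0.0)
        assert calibrate_leak_weight(measured, comp) == 0.0

    def test_calibration_closure(self, commissioning_set,
                                 calibrated_templates):
        """Re-simulating the commissioning fields with the calibrated
        templates reproduces the images' peak and dip amplitudes."""
        c = commissioning_set
        model = c.model.replace_templates(calibrated_templates)
        g, jaws = c.model.geometry, c.sequences["window_1cm"].jaws
        sim_w = simulate_field(c.sequences["window_1cm"], model).response()
        sim_c = simulate_field(c.sequences["checker_4cm"], model).response()
        assert interleaf_peak_metric(sim_w, g, jaws) == pytest.approx(
            interleaf_peak_metric(c.images["window_1cm"], g, jaws), rel=0.02)
        assert tng_dip_metric(sim_c, g, jaws) == pytest.approx(
            tng_dip_metric(c.images["checker_4cm"], g, jaws), rel=0.02)
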