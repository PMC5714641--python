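"""EPID response modeling, fluence recovery, and template calibration.

The portal imager's point response is a radially symmetric sum of Gaussians
covering radiation and optical glare. The forward model composes the basic
response (ideal fluence x headscatter x flood, magnified to the imager and
convolved with the kernel) with the dynamically weighted interleaf-leakage
and transmission terms and a multiplicative tongue-and-groove factor:

    S = S_basic * TG|D + conv(HSF * [A * deconv(leak|D) + B * T|D])

Inverting the kernel from the same composition yields the full fluence used
for dose calculation. Calibration extracts the leakage profile shape from a
sweeping-window image, then fixes the leakage weight A against that image's
interleaf peak amplitude, the transmission weight B against the closed-field
commissioning total, and the tongue-and-groove penumbra against a
sweeping-checkerboard image, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import brentq, least_squares

from ._fft import convolve2d_same, deconvolve2d_same
from .fluence import (accumulate_exposure, expand_to_grid, fluence_grid_for,
                      jaw_mask, sample_and_widen, transmission_map)
from .grids import EPID_PITCH_UM, PlaneGrid, magnify_to_imager
from .headscatter import compute_hsf_map, flood_fluence
from .mlc_effects import TemplateSet, tile_leak_map, tng_map_from_stagger
from .mlc_sequence import DynamicSequence, open_counterpart

if TYPE_CHECKING:  # pragma: no cover
    from .config import ModelConfig

MAGNIFICATION = 1.05
CLOSED_FIELD_TARGET = 0.014  # TPS commissioning: leakage + transmission total


@dataclass(frozen=True)
class EPIDKernel:
    """Radially symmetric EPID response kernel, a sum of Gaussians.

    ``gaussians`` is a sequence of (amplitude, sigma_mm) pairs (up to nine);
    a sigma of 0 denotes a delta (single-pixel) contribution. The rasterized
    kernel is normalized to unit integral.
    """

    gaussians: tuple[tuple[float, float], ...]
    pixel_um: float = EPID_PITCH_UM

    def __post_init__(self):
        if not self.gaussians:
            raise ValueError("kernel needs at least one Gaussian")
        if any(a < 0 or s < 0 for a, s in self.gaussians):
            raise ValueError("kernel amplitudes and sigmas must be non-negative")

    def to_array(self, pitch_um: float | None = None) -> np.ndarray:
        pitch = (pitch_um or self.pixel_um) / 1000.0
        sig_max = max(s for _, s in self.gaussians)
        half_px = max(int(np.ceil(4.0 * sig_max / pitch)), 1)
        r = pitch * np.arange(-half_px, half_px + 1)
        xx, yy = np.meshgrid(r, r)
        r2 = xx * xx + yy * yy
        k = np.zeros_like(r2)
        for a, s in self.gaussians:
            if s == 0.0:
                k[half_px, half_px] += a
            else:
                k += a * np.exp(-r2 / (2.0 * s * s))
        return k / k.sum()

    @classmethod
    def delta(cls) -> "EPIDKernel":
        return cls(((1.0, 0.0),))

    @classmethod
    def default(cls) -> "EPIDKernel":
        """Nine Gaussians: a dominant sub-mm core plus low-amplitude glare
        tails out to sigma = 30 mm (about 60% of the integral in the core)."""
        sigmas = (0.6, 1.2, 2.4, 4.0, 7.0, 11.0, 16.0, 22.0, 30.0)
        amps = (1.0, 5e-2, 1e-2, 2e-3, 5e-4, 1.5e-4, 5e-5, 2e-5, 8e-6)
        return cls(tuple(zip(amps, sigmas)))


# --------------------------------------------------------------------------- #
def convolve(grid: PlaneGrid, kernel: EPIDKernel | np.ndarray) -> PlaneGrid:
    k = kernel.to_array(grid.spacing_um) if isinstance(kernel, EPIDKernel) else kernel
    return grid.copy(values=convolve2d_same(grid.values, k))


def deconvolve(grid: PlaneGrid, kernel: EPIDKernel | np.ndarray,
               eps_rel: float = 1e-3) -> PlaneGrid:
    k = kernel.to_array(grid.spacing_um) if isinstance(kernel, EPIDKernel) else kernel
    return grid.copy(values=deconvolve2d_same(grid.values, k, eps_rel))


def predict_sbasic(phi_ideal: PlaneGrid, hsf: PlaneGrid, psi_flood: PlaneGrid,
                   kernel: EPIDKernel, magnification: float = MAGNIFICATION,
                   total_mu: float = 1.0) -> PlaneGrid:
    """The basic EPID response: fluence x headscatter x flood, magnified to
    the imager plane, resampled to the EPID pitch, convolved with the
    kernel."""
    if phi_ideal.shape != hsf.shape:
        raise ValueError("grid mismatch between fluence and HSF maps")
    product = phi_ideal.copy(
        values=(phi_ideal.values / total_mu) * hsf.values
        * psi_flood.resample_onto(phi_ideal).values,
        units="relative")
    img = magnify_to_imager(product, magnification)
    return convolve(img, kernel)


# --------------------------------------------------------------------------- #
class FieldComputation:
    """All per-field maps needed by the response/fluence composition.

    Building one is the expensive step (fluence sweep, headscatter map and
    kernel FFTs); recombining with different template weights afterwards is
    cheap, which is what the calibration loops exploit. The response is
    linear in the leakage weight A and transmission weight B:

        S(A, B, tng) = S_basic * TG(tng) + A * U + B * V
    """

    def __init__(self, seq: DynamicSequence, model: "ModelConfig",
                 spacing_um: float | None = None,
                 n_intervals: int | None = None):
        self.seq = seq
        self.model = model
        self.spacing_um = spacing_um or model.commissioning_spacing_um
        self.n_intervals = n_intervals or model.commissioning_intervals
        m = model.magnification
        self.magnification = m

        grid_iso = fluence_grid_for(seq, self.spacing_um, model.margin_mm)
        sampled = sample_and_widen(seq, self.n_intervals, model.dlg_mm,
                                   exempt_closed=model.closed_exempt,
                                   closed_threshold_mm=model.closed_threshold_mm)
        self.acc = accumulate_exposure(sampled, grid_iso.x_mm, with_stagger=True)
        exposure2d = expand_to_grid(self.acc, seq.geometry, grid_iso)
        mask_iso = jaw_mask(grid_iso, seq.jaws)
        self.phi_ideal = grid_iso.copy(values=exposure2d * mask_iso
                                       * seq.total_mu, units="MU")

        if model.flat_hsf:
            hsf = grid_iso.copy(values=np.ones(grid_iso.shape), units="relative")
        else:
            hsf = compute_hsf_map(model.source, seq.jaws, self.spacing_um,
                                  half_x_mm=grid_iso.x_mm[-1],
                                  half_y_mm=grid_iso.y_mm[-1])
        self.hsf_iso = hsf
        self.flood_iso = flood_fluence(
            model.flood_mode, spacing_um=self.spacing_um,
            half_x_mm=grid_iso.x_mm[-1], half_y_mm=grid_iso.y_mm[-1],
            horn_height=model.horn_height,
            horn_radius_cm=model.horn_radius_cm)

        product = grid_iso.copy(
            values=(exposure2d * mask_iso) * hsf.values
            * self.flood_iso.resample_onto(grid_iso).values,
            units="relative")
        self.p_img = magnify_to_imager(product, m)
        self.kernel2d = model.epid_kernel.to_array(self.p_img.spacing_um)
        self.s_basic = convolve(self.p_img, self.kernel2d)

        self.hsf_img = magnify_to_imager(hsf, m)
        t_iso = transmission_map(self.phi_ideal, seq.total_mu, seq.jaws)
        t_img = t_iso.resample_onto(self.p_img, coord_scale=1.0 / m)
        t_img.values *= jaw_mask(self.p_img, seq.jaws, scale=m)
        self.t_img = t_img

        self.leak_tiled = tile_leak_map(model.templates, seq.geometry,
                                        self.p_img, magnification=m)
        self.leak_d = self.leak_tiled.copy(
            values=self.leak_tiled.values * t_img.values)

        eps = model.deconv_eps_rel
        leak_deconv = deconvolve2d_same(self.leak_d.values, self.kernel2d, eps)
        self.u = convolve2d_same(self.hsf_img.values * leak_deconv,
                                 self.kernel2d)
        self.v = convolve2d_same(self.hsf_img.values * t_img.values,
                                 self.kernel2d)
        self._leak_deconv = leak_deconv

    # ------------------------------------------------------------------ #
    def _defaults(self, A, B, tng_profile):
        ts = self.model.templates
        return (ts.weight_A if A is None else A,
                ts.weight_B if B is None else B,
                ts.tng_profile if tng_profile is None else tng_profile)

    def tng_grid(self, tng_profile=None) -> PlaneGrid:
        _, _, profile = self._defaults(None, None, tng_profile)
        ts = self.model.templates.with_(tng_profile=tuple(profile))
        return tng_map_from_stagger(ts, self.seq.geometry, self.acc,
                                    self.p_img, self.magnification)

    def response(self, A: float | None = None, B: float | None = None,
                 tng_profile=None) -> PlaneGrid:
        """Predicted relative EPID image (per MU) for the delivery."""
        A, B, profile = self._defaults(A, B, tng_profile)
        tg = self.tng_grid(profile)
        vals = self.s_basic.values * tg.values + A * self.u + B * self.v
        return self.p_img.copy(values=vals, units="relative")

    def full_fluence(self, A: float | None = None, B: float | None = None,
                     tng_profile=None) -> PlaneGrid:
        """Recovered full fluence (imager plane, per MU).

        Negative values are clamped to zero and everything outside the
        magnified jaw rectangle (one-pixel guard) is rejected as unphysical.
        """
        A, B, profile = self._defaults(A, B, tng_profile)
        tg = self.tng_grid(profile)
        eps = self.model.deconv_eps_rel
        basic = deconvolve2d_same(self.s_basic.values * tg.values,
                                  self.kernel2d, eps)
        vals = basic + self.hsf_img.values * (
            A * self._leak_deconv + B * self.t_img.values)
        vals = np.clip(vals, 0.0, None)
        vals *= jaw_mask(self.p_img, self.seq.jaws, scale=self.magnification,
                         guard_px=1)
        return self.p_img.copy(values=vals, units="relative")


def simulate_field(seq: DynamicSequence, model: "ModelConfig",
                   spacing_um: float | None = None,
                   n_intervals: int | None = None) -> FieldComputation:
    return FieldComputation(seq, model, spacing_um, n_intervals)


def predict_full_response(seq: DynamicSequence, model: "ModelConfig",
                          spacing_um: float | None = None,
                          n_intervals: int | None = None,
                          **weights) -> PlaneGrid:
    return simulate_field(seq, model, spacing_um, n_intervals).response(**weights)


def recover_full_fluence(seq: DynamicSequence, model: "ModelConfig",
                         spacing_um: float | None = None,
                         n_intervals: int | None = None,
                         **weights) -> PlaneGrid:
    return simulate_field(seq, model, spacing_um, n_intervals).full_fluence(**weights)


# --------------------------------------------------------------------------- #
# profile metrics shared by calibration, fixtures and validation

CENTRAL_STRIP_HALF_MM = 10.0
BOUNDARY_EDGE_MARGIN_MM = 7.0


def central_profile(grid: PlaneGrid, half_x_mm: float = CENTRAL_STRIP_HALF_MM,
                    ) -> np.ndarray:
    """Mean profile perpendicular to leaf travel over a central x strip."""
    cols = np.abs(grid.x_mm) <= half_x_mm
    return grid.values[:, cols].mean(axis=1)


def _interior_boundaries(geometry, jaws_mm) -> np.ndarray:
    yb = np.asarray(geometry.boundaries[1:-1], float)
    y1, y2 = jaws_mm[2], jaws_mm[3]
    keep = (yb >= y1 + BOUNDARY_EDGE_MARGIN_MM) & (yb <= y2 - BOUNDARY_EDGE_MARGIN_MM)
    return yb[keep]


def _interior_midleaves(geometry, jaws_mm) -> np.ndarray:
    yc = geometry.centers
    y1, y2 = jaws_mm[2], jaws_mm[3]
    keep = (yc >= y1 + BOUNDARY_EDGE_MARGIN_MM) & (yc <= y2 - BOUNDARY_EDGE_MARGIN_MM)
    return yc[keep]


def _base_interp(profile: np.ndarray, y_mm: np.ndarray, geometry, jaws_mm,
                 magnification: float):
    mids = _interior_midleaves(geometry, jaws_mm) * magnification
    base_vals = np.interp(mids, y_mm, profile)
    return lambda y: np.interp(y, mids, base_vals)


def interleaf_peak_metric(grid: PlaneGrid, geometry, jaws_mm,
                          magnification: float = MAGNIFICATION) -> float:
    """Mean relative height of the interleaf peaks above the local base,
    on the central profile perpendicular to leaf travel."""
    prof = central_profile(grid)
    y = grid.y_mm
    base = _base_interp(prof, y, geometry, jaws_mm, magnification)
    rel = []
    for yb in _interior_boundaries(geometry, jaws_mm) * magnification:
        peak = float(np.interp(yb, y, prof))
        b = float(base(yb))
        rel.append((peak - b) / b)
    return float(np.mean(rel))


def tng_dip_metric(grid: PlaneGrid, geometry, jaws_mm,
                   magnification: float = MAGNIFICATION) -> float:
    """Maximum relative signal decrease at leaf boundaries on the central
    profile perpendicular to leaf travel."""
    prof = central_profile(grid)
    y = grid.y_mm
    base = _base_interp(prof, y, geometry, jaws_mm, magnification)
    dips = []
    for yb in _interior_boundaries(geometry, jaws_mm) * magnification:
        low = float(np.interp(yb, y, prof))
        b = float(base(yb))
        dips.append((b - low) / b)
    return float(np.max(dips))


def closed_field_ratio(closed_response: PlaneGrid, open_response: PlaneGrid,
                       half_mm: float = 40.0,
                       magnification: float = MAGNIFICATION) -> float:
    """Mean closed-field response relative to the open field over the
    central interior square (half-width in isocenter-plane mm)."""
    h = half_mm * magnification
    sel_x = np.abs(closed_response.x_mm) <= h
    sel_y = np.abs(closed_response.y_mm) <= h
    region = np.ix_(sel_y, sel_x)
    return float(np.mean(closed_response.values[region]
                         / open_response.values[region]))


# --------------------------------------------------------------------------- #
# calibration

class CalibrationError(RuntimeError):
    pass


def extract_leak_profile(measured: PlaneGrid, geometry, jaws_mm,
                         magnification: float = MAGNIFICATION,
                         pixel_um: float = EPID_PITCH_UM) -> tuple[float, ...]:
    """Extract the 7-point interleaf profile from a sweeping-window image.

    The profile over the field interior is modeled as the superposition of
    the 7-node template tiled over every leaf boundary plus a smooth
    (cubic) base, and the node amplitudes are recovered by one linear
    least-squares solve. Inverting the tiling this way avoids the smear a
    naive per-boundary resampling suffers when image pixels do not coincide
    with the node offsets, and keeps neighboring boundaries' tails out of
    the base estimate. The result is normalized 0..1 and symmetrized.
    """
    prof = central_profile(measured)
    y = measured.y_mm
    px = pixel_um / 1000.0
    nodes = (np.arange(7) - 3) * px
    margin = 10.0  # stay clear of the jaw penumbra, which the base
    y1 = (jaws_mm[2] + margin) * magnification  # polynomial cannot follow
    y2 = (jaws_mm[3] - margin) * magnification
    sel = (y >= y1) & (y <= y2)
    ys = y[sel]
    # hat-function weights of every node, summed over all boundaries
    all_bounds = np.asarray(geometry.boundaries[1:-1], float) * magnification
    W = np.zeros((ys.size, 7))
    for yb in all_bounds:
        d = ys - yb
        W += np.clip(1.0 - np.abs(d[:, None] - nodes[None, :]) / px, 0.0, None)
    u = (ys - ys.mean()) / (0.5 * (ys[-1] - ys[0]))
    P = np.vander(u, 7, increasing=True)  # smooth degree-6 base
    sol, *_ = np.linalg.lstsq(np.hstack([W, P]), prof[sel], rcond=None)
    p = sol[:7]
    base_level = float(np.median(prof[sel]))
    if p.max() <= 0.02 * base_level:
        raise CalibrationError("no detectable interleaf peaks in image")
    p = np.clip(p, 0.0, None)
    p = 0.5 * (p + p[::-1])
    p = p / p[3]
    p[0] = p[-1] = 0.0
    return tuple(p)


def calibrate_leak_weight(measured: PlaneGrid, comp: FieldComputation,
                          max_weight: float = 0.1) -> float:
    """Weight A such that the relative interleaf-peak magnitude of the
    predicted response matches the measured image."""
    geometry = comp.seq.geometry
    jaws = comp.seq.jaws
    m = comp.magnification
    target = interleaf_peak_metric(measured, geometry, jaws, m)

    def g(A):
        return interleaf_peak_metric(comp.response(A=A), geometry, jaws, m) - target

    if g(0.0) >= 0.0:
        return 0.0
    if g(max_weight) < 0.0:
        raise CalibrationError("interleaf peaks too large to match within "
                               f"A <= {max_weight}")
    return float(brentq(g, 0.0, max_weight, xtol=1e-9))


def calibrate_transmission_weight(comp_closed: FieldComputation,
                                  open_response: PlaneGrid,
                                  target_total: float = CLOSED_FIELD_TARGET,
                                  A: float | None = None) -> float:
    """Weight B such that leakage plus transmission of an MLC-covered field
    totals ``target_total`` of the open-field response (the commissioning
    constraint). The constraint is linear in B and solved exactly."""
    m0 = closed_field_ratio(comp_closed.response(A=A, B=0.0), open_response,
                            magnification=comp_closed.magnification)
    m1 = closed_field_ratio(comp_closed.response(A=A, B=1.0), open_response,
                            magnification=comp_closed.magnification)
    slope = m1 - m0
    if slope <= 0:
        raise CalibrationError("transmission term has no effect on the "
                               "closed-field response")
    B = (target_total - m0) / slope
    if B < 0:
        raise CalibrationError(
            f"closed-field target {target_total} already exceeded by "
            f"leakage alone ({m0:.4f})")
    return float(B)


def calibrate_tng(measured: PlaneGrid, comp: FieldComputation,
                  A: float | None = None, B: float | None = None,
                  ) -> tuple[tuple[float, ...], np.ndarray]:
    """Fit the 4-point tongue-and-groove penumbra to a sweeping-checker
    image; returns (profile, residuals)."""
    geometry = comp.seq.geometry
    jaws = comp.seq.jaws
    m = comp.magnification
    y = comp.p_img.y_mm
    sel = ((y >= (jaws[2] + BOUNDARY_EDGE_MARGIN_MM) * m)
           & (y <= (jaws[3] - BOUNDARY_EDGE_MARGIN_MM) * m))
    meas_prof = central_profile(measured)
    if measured.shape != comp.p_img.shape:
        meas_prof = np.interp(y, measured.y_mm, meas_prof)
    meas_sel = meas_prof[sel]
    meas_norm = meas_sel / meas_sel.mean()

    def resid(p):
        profile = tuple(np.sort(np.clip(p, 1e-3, 1.0)))
        sim = central_profile(comp.response(A=A, B=B, tng_profile=profile))[sel]
        return sim / sim.mean() - meas_norm

    x0 = np.asarray(comp.model.templates.tng_profile, float)
    sol = least_squares(resid, x0, bounds=(0.2, 1.0), xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise CalibrationError(f"tongue-and-groove fit failed: {sol.message}")
    profile = tuple(np.sort(np.clip(sol.x, 1e-3, 1.0)))
    return profile, sol.fun


def calibrate_templates(window_img: PlaneGrid, checker_img: PlaneGrid,
                        window_seq: DynamicSequence,
                        checker_seq: DynamicSequence,
                        closed_seq: DynamicSequence,
                        model: "ModelConfig",
                        closed_target: float = CLOSED_FIELD_TARGET,
                        spacing_um: float | None = None,
                        n_intervals: int | None = None) -> TemplateSet:
    """Full commissioning chain: leak profile -> A -> B -> tongue-and-groove.

    Returns a calibrated :class:`TemplateSet`.
    """
    leak_profile = extract_leak_profile(window_img, window_seq.geometry,
                                        window_seq.jaws, model.magnification)
    working = model.replace_templates(
        model.templates.with_(leak_profile=leak_profile))

    comp_window = simulate_field(window_seq, working, spacing_um, n_intervals)
    A = calibrate_leak_weight(window_img, comp_window)

    comp_closed = simulate_field(closed_seq, working, spacing_um, n_intervals)
    comp_open = simulate_field(open_counterpart(closed_seq), working,
                               spacing_um, n_intervals)
    B = calibrate_transmission_weight(comp_closed, comp_open.response(A=A),
                                      closed_target, A=A)

    comp_checker = simulate_field(checker_seq, working, spacing_um, n_intervals)
    tng_profile, _ = calibrate_tng(checker_img, comp_checker, A=A, B=B)

    return working.templates.with_(leak_profile=leak_profile,
                                   tng_profile=tng_profile,
                                   weight_A=A, weight_B=B)
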