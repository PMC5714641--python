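"""Extrafocal headscatter, monitor backscatter, and the flood-field fluence.

The extrafocal (flattening-filter) source is modeled as a sum of three 2D
Gaussians on a plane at the bottom of the flattening filter. The scatter
reaching an isocenter-plane point is the integral of that source over the
region visible through both jaw pairs; because the jaws open rectangular
windows, the integral separates into exact error-function products per
Gaussian. Adding the focal (primary) component and a field-size-dependent
monitor-backscatter correction, and normalizing on the central axis of the
10x10 cm^2 reference field, yields the 2D headscatter factor map (HSF).

Source amplitudes and widths are fit to measured central-axis collimator
scatter factors Sc for square fields.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import ndtr  # standard normal CDF

from ._fft import deconvolve2d_same
from .grids import PlaneGrid, centered_grid, ISOCENTER

SAD_CM = 100.0
REFERENCE_SIDE_CM = 10.0
SC_FIELD_SIDES_CM = (4.0, 7.0, 10.0, 18.0, 29.0, 34.0, 38.0)

# Generic 2100-class head geometry (cm from target); configurable.
Z_FILTER_CM = 12.5
Z_JAW_Y_CM = 28.0
Z_JAW_X_CM = 36.7


@dataclass(frozen=True)
class ExtrafocalSource:
    """Three-Gaussian extrafocal source plus collimator geometry.

    ``amplitudes`` are dimensionless weights; ``sigmas`` are Gaussian widths
    in cm on the extrafocal plane. ``backscatter_coeff`` is the per-cm
    monitor-backscatter slope on the jaw-opening perimeter.
    """

    amplitudes: tuple[float, float, float] = (0.0805, 0.0553, 0.0523)
    sigmas: tuple[float, float, float] = (0.7552, 1.9982, 7.4928)
    z_target: float = 0.0
    z_filter: float = Z_FILTER_CM
    z_jaw_x: float = Z_JAW_X_CM
    z_jaw_y: float = Z_JAW_Y_CM
    backscatter_coeff: float = 1.0e-4

    def __post_init__(self):
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("Gaussian sigmas must be positive")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("Gaussian amplitudes must be non-negative")
        if not (self.z_target < self.z_filter < min(self.z_jaw_x, self.z_jaw_y)
                < SAD_CM):
            raise ValueError("require z_target < z_filter < jaw planes < SAD")


def extrafocal_intensity(src: ExtrafocalSource, x_cm, y_cm) -> np.ndarray:
    """Relative extrafocal intensity density on the source plane."""
    x = np.asarray(x_cm, float)
    y = np.asarray(y_cm, float)
    r2 = x * x + y * y
    out = np.zeros(np.broadcast_shapes(x.shape, y.shape))
    for a, s in zip(src.amplitudes, src.sigmas):
        out = out + a / (2.0 * np.pi * s * s) * np.exp(-r2 / (2.0 * s * s))
    return out


def _visible_window(u_cm: np.ndarray, e1_iso_cm: float, e2_iso_cm: float,
                    z_jaw: float, z_filter: float) -> tuple[np.ndarray, np.ndarray]:
    """Back-project one jaw pair from isocenter points onto the source plane.

    ``u_cm`` are point coordinates (isocenter plane) along the jaw axis;
    ``e1/e2`` the jaw edges in cm at isocenter scale. Returns the visible
    interval on the extrafocal plane, in physical cm.
    """
    ratio = (z_filter - SAD_CM) / (z_jaw - SAD_CM)
    e1 = e1_iso_cm * z_jaw / SAD_CM
    e2 = e2_iso_cm * z_jaw / SAD_CM
    w1 = u_cm + (e1 - u_cm) * ratio
    w2 = u_cm + (e2 - u_cm) * ratio
    return np.minimum(w1, w2), np.maximum(w1, w2)


def _scatter_sum(src: ExtrafocalSource, x_cm: np.ndarray, y_cm: np.ndarray,
                 jaws_cm: tuple[float, float, float, float]) -> np.ndarray:
    """Visible-source integral for all (y, x) grid combinations (outer)."""
    x1, x2, y1, y2 = jaws_cm
    wx1, wx2 = _visible_window(x_cm, x1, x2, src.z_jaw_x, src.z_filter)
    wy1, wy2 = _visible_window(y_cm, y1, y2, src.z_jaw_y, src.z_filter)
    total = np.zeros((y_cm.size, x_cm.size))
    for a, s in zip(src.amplitudes, src.sigmas):
        fx = ndtr(wx2 / s) - ndtr(wx1 / s)
        fy = ndtr(wy2 / s) - ndtr(wy1 / s)
        total += a * np.outer(fy, fx)
    return total


def backscatter_factor(src: ExtrafocalSource,
                       jaws_cm: tuple[float, float, float, float]) -> float:
    """Monitor-chamber backscatter correction, normalized at 10x10.

    Modeled as ``1 / (1 + b * (P_ref - P))`` on the jaw-opening perimeter
    ``P`` (cm): smaller openings return more radiation into the monitor
    chamber, depressing the output.
    """
    x1, x2, y1, y2 = jaws_cm
    perim = 2.0 * ((x2 - x1) + (y2 - y1))
    ref = 4.0 * REFERENCE_SIDE_CM * 2.0
    return 1.0 / (1.0 + src.backscatter_coeff * (ref - perim))


def _square_jaws_cm(side_cm: float) -> tuple[float, float, float, float]:
    h = side_cm / 2.0
    return (-h, h, -h, h)


def hsf_cax(src: ExtrafocalSource, side_cm: float) -> float:
    """Central-axis headscatter factor of a square field (Sc model)."""
    zero = np.zeros(1)
    s = _scatter_sum(src, zero, zero, _square_jaws_cm(side_cm))[0, 0]
    raw = (1.0 + s) * backscatter_factor(src, _square_jaws_cm(side_cm))
    s_ref = _scatter_sum(src, zero, zero, _square_jaws_cm(REFERENCE_SIDE_CM))[0, 0]
    ref = (1.0 + s_ref) * backscatter_factor(src, _square_jaws_cm(REFERENCE_SIDE_CM))
    return raw / ref


def compute_hsf_map(src: ExtrafocalSource,
                    jaws_mm: tuple[float, float, float, float],
                    spacing_um: float, half_x_mm: float | None = None,
                    half_y_mm: float | None = None,
                    margin_mm: float = 30.0) -> PlaneGrid:
    """The 2D headscatter factor map for a field's jaw settings.

    Normalized so HSF = 1 on the central axis of the 10x10 cm^2 reference
    field (the Sc convention).
    """
    x1, x2, y1, y2 = jaws_mm
    if not (x2 > x1 and y2 > y1):
        raise ValueError("degenerate jaws")
    if half_x_mm is None:
        half_x_mm = max(abs(x1), abs(x2)) + margin_mm
    if half_y_mm is None:
        half_y_mm = max(abs(y1), abs(y2)) + margin_mm
    grid = centered_grid(half_x_mm, half_y_mm, spacing_um, ISOCENTER, "relative")
    jaws_cm = tuple(v / 10.0 for v in jaws_mm)
    s = _scatter_sum(src, grid.x_mm / 10.0, grid.y_mm / 10.0, jaws_cm)
    raw = (1.0 + s) * backscatter_factor(src, jaws_cm)
    zero = np.zeros(1)
    s_ref = _scatter_sum(src, zero, zero, _square_jaws_cm(REFERENCE_SIDE_CM))[0, 0]
    ref = (1.0 + s_ref) * backscatter_factor(src, _square_jaws_cm(REFERENCE_SIDE_CM))
    grid.values = raw / ref
    return grid


# --------------------------------------------------------------------------- #
@dataclass
class SourceFit:
    source: ExtrafocalSource
    residuals: np.ndarray
    converged: bool


def fit_source_params(sc_table, geometry: ExtrafocalSource | None = None,
                      fit_backscatter: bool = False) -> SourceFit:
    """Fit the three-Gaussian source to a central-axis Sc table.

    ``sc_table`` is a sequence of ``(side_cm, Sc)`` pairs spanning small to
    large square fields; the fitted model reproduces the table's
    central-axis headscatter factors in a least-squares sense. Geometry
    (z planes) is taken from ``geometry`` or defaults.
    """
    table = np.asarray(sc_table, float)
    if table.ndim != 2 or table.shape[0] < 6:
        raise ValueError("need at least 6 (side_cm, Sc) pairs")
    base = geometry or ExtrafocalSource()

    def make(params) -> ExtrafocalSource:
        amps = tuple(np.maximum(params[0:3], 0.0))
        sigmas = tuple(np.exp(params[3:6]))
        b = params[6] if fit_backscatter else base.backscatter_coeff
        return replace(base, amplitudes=amps, sigmas=sigmas,
                       backscatter_coeff=float(b))

    def resid(params):
        src = make(params)
        return np.array([hsf_cax(src, side) - sc for side, sc in table])

    x0 = [0.06, 0.06, 0.06, np.log(0.5), np.log(2.5), np.log(10.0)]
    lo = [0.0, 0.0, 0.0, np.log(0.05), np.log(0.05), np.log(0.05)]
    hi = [5.0, 5.0, 5.0, np.log(50.0), np.log(50.0), np.log(50.0)]
    if fit_backscatter:
        x0 += [1e-4]
        lo += [0.0]
        hi += [1e-2]
    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
    fit = SourceFit(make(sol.x), sol.fun, sol.success)
    if not sol.success:
        raise RuntimeError(
            f"source fit did not converge; residuals {sol.fun}")
    return fit


# --------------------------------------------------------------------------- #
# flood-field relative fluence

DEFAULT_HORN_HEIGHT = 0.04
DEFAULT_HORN_RADIUS_CM = 20.0


def _horn_profile(r_mm: np.ndarray, horn_height: float,
                  horn_radius_cm: float) -> np.ndarray:
    u = r_mm / (horn_radius_cm * 10.0)
    return 1.0 + horn_height * u * u * np.exp(-u ** 6)


def flood_fluence(mode: str = "synthetic", *, spacing_um: float = 500.0,
                  half_x_mm: float = 220.0, half_y_mm: float = 220.0,
                  horn_height: float = DEFAULT_HORN_HEIGHT,
                  horn_radius_cm: float = DEFAULT_HORN_RADIUS_CM,
                  path=None, dose: PlaneGrid | None = None,
                  kernel2d: np.ndarray | None = None,
                  eps_rel: float = 1e-3) -> PlaneGrid:
    """The relative open 40x40 flood-field fluence, 1 on the central axis.

    Modes: ``synthetic`` evaluates a radial polynomial-times-Gaussian horn
    profile (``horn_height = 0`` gives a flat field); ``load`` reads a saved
    map; ``deconvolve`` recovers fluence from a dose (or EPID) map by
    frequency-space deconvolution of the supplied 2D kernel. Inverse-square
    falloff is considered part of the profile; no separate correction is
    applied.
    """
    if mode == "synthetic":
        grid = centered_grid(half_x_mm, half_y_mm, spacing_um, ISOCENTER,
                             "relative")
        xx, yy = np.meshgrid(grid.x_mm, grid.y_mm)
        grid.values = _horn_profile(np.hypot(xx, yy), horn_height,
                                    horn_radius_cm)
        return grid
    if mode == "load":
        from .grids import load_grid

        grid = load_grid(path)
    elif mode == "deconvolve":
        if dose is None or kernel2d is None:
            raise ValueError("deconvolve mode needs a dose map and a kernel")
        vals = deconvolve2d_same(dose.values, kernel2d, eps_rel)
        grid = dose.copy(values=vals, units="relative")
    else:
        raise ValueError(f"unknown flood mode {mode!r}")
    cax = grid.sample(0.0, 0.0)
    if not np.isfinite(cax) or cax <= 0:
        raise ValueError("flood field has a non-positive central-axis value")
    grid.values = grid.values / float(cax)
    return grid
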