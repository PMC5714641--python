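"""EPID-derived interleaf-leakage and tongue-and-groove templates.

Interleaf leakage is described by a symmetric 7-point profile across each
interior leaf boundary (peak 1 at the boundary, 0 at the ends), tiled
uniformly along the travel axis; its dynamic map weights the template by the
fraction of the delivery during which the point is blocked. Tongue-and-
groove is described by a 4-point penumbra from the leaf edge toward the
open leaf's midwidth; its dynamic map combines the tiled template T with
the cumulative staggered-edge exposure fraction C as ``1 - C * (1 - T)``,
so never-staggered regions stay at 1 and fully staggered regions fall to T.
Both profiles are sampled at the EPID pixel pitch and were extracted from
commissioning images, so no leaf cross-section geometry enters the model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fluence import ExposureAccumulator
from .grids import PlaneGrid, EPID_PITCH_UM
from .mlc_sequence import DynamicSequence, LeafGeometry

DEFAULT_LEAK_PROFILE = (0.0, 0.31, 0.81, 1.0, 0.81, 0.31, 0.0)
DEFAULT_TNG_PROFILE = (0.76, 0.84, 0.92, 0.96)
DEFAULT_WEIGHT_A = 6.054e-3   # interleaf-leakage weight
DEFAULT_WEIGHT_B = 1.014e-2   # mean MLC transmission weight


@dataclass(frozen=True)
class TemplateSet:
    """The EPID-derived MLC characterization.

    ``leak_profile``: 7 amplitudes at ``pixel_um`` spacing, symmetric, 1 at
    the interleaf center and 0 at the ends. ``tng_profile``: 4 amplitudes in
    (0, 1], increasing from the staggered leaf edge toward the open leaf's
    midwidth. ``weight_A``/``weight_B`` scale interleaf leakage and mean
    transmission in the EPID-response composition.
    """

    leak_profile: tuple[float, ...] = DEFAULT_LEAK_PROFILE
    tng_profile: tuple[float, ...] = DEFAULT_TNG_PROFILE
    weight_A: float = DEFAULT_WEIGHT_A
    weight_B: float = DEFAULT_WEIGHT_B
    pixel_um: float = EPID_PITCH_UM

    def __post_init__(self):
        p = np.asarray(self.leak_profile, float)
        if p.size != 7 or not np.allclose(p, p[::-1]):
            raise ValueError("leak profile must be 7 points, symmetric")
        if abs(p[3] - 1.0) > 1e-9 or abs(p[0]) > 1e-9 or abs(p[-1]) > 1e-9:
            raise ValueError("leak profile must peak at 1 with zero ends")
        t = np.asarray(self.tng_profile, float)
        if t.size != 4 or np.any(np.diff(t) <= 0):
            raise ValueError("tongue-and-groove profile must be 4 strictly "
                             "increasing points")
        if np.any(t <= 0) or np.any(t > 1):
            raise ValueError("tongue-and-groove amplitudes must lie in (0, 1]")
        if self.weight_A < 0 or self.weight_B < 0:
            raise ValueError("weights must be non-negative")

    def with_(self, **changes) -> "TemplateSet":
        return replace(self, **changes)


# --------------------------------------------------------------------------- #
def _interior_boundaries(geometry: LeafGeometry) -> np.ndarray:
    return np.asarray(geometry.boundaries[1:-1], float)


def tile_leak_map(ts: TemplateSet, geometry: LeafGeometry, grid: PlaneGrid,
                  magnification: float = 1.0) -> PlaneGrid:
    """Tile the 1D interleaf profile over every interior leaf boundary.

    The profile is centered on each boundary (positions magnified into the
    grid's plane), linearly interpolated between its 7 nodes at
    ``ts.pixel_um`` spacing, uniform along the travel axis, and honors both
    leaf widths because boundaries come from the geometry. Values are 1 on
    boundary lines and 0 at leaf midlines.
    """
    px = ts.pixel_um / 1000.0
    nodes = (np.arange(7) - 3) * px
    profile_1d = np.zeros_like(grid.y_mm)
    for yb in _interior_boundaries(geometry) * magnification:
        profile_1d += np.interp(grid.y_mm - yb, nodes, ts.leak_profile,
                                left=0.0, right=0.0)
    values = np.repeat(profile_1d[:, None], grid.x_mm.size, axis=1)
    return grid.copy(values=np.clip(values, 0.0, 1.0), units="relative")


def dynamic_leak_map(leak_map: PlaneGrid, transmission: PlaneGrid,
                     ) -> PlaneGrid:
    """Weight the tiled leakage template by the blocked fraction.

    ``transmission`` is the dynamic blocked-fraction map (1 - phi/MU inside
    the jaws). The result is 0 where never blocked or at leaf midlines, and
    1 where always blocked at an interleaf center.
    """
    if leak_map.shape != transmission.shape:
        raise ValueError("grid mismatch between leakage template and "
                         "transmission map")
    vals = leak_map.values * transmission.values
    return leak_map.copy(values=vals, units="relative")


# --------------------------------------------------------------------------- #
def _tng_lookup(ts: TemplateSet, dist_mm: np.ndarray) -> np.ndarray:
    """Template amplitude vs distance from the boundary into the open leaf.

    The 4 nodes sit at 0..3 EPID pixels from the edge; the profile relaxes
    linearly to 1 at 4 pixels and is 1 beyond (the blocked side is handled
    by transmission, not by this template).
    """
    px = ts.pixel_um / 1000.0
    nodes = np.concatenate([np.arange(4) * px, [4 * px]])
    amps = np.concatenate([np.asarray(ts.tng_profile, float), [1.0]])
    return np.interp(np.abs(dist_mm), nodes, amps, right=1.0)


def tng_map_from_stagger(ts: TemplateSet, geometry: LeafGeometry,
                         acc: ExposureAccumulator, grid: PlaneGrid,
                         magnification: float = 1.0) -> PlaneGrid:
    """Combine cumulative stagger fractions with the tiled template.

    For each interior boundary, the side belonging to the open leaf receives
    the factor ``1 - C * (1 - T(d))`` where ``C`` is the fraction of that
    side's exposure delivered while the neighbor across the boundary was
    blocked, and ``d`` the distance from the boundary in the grid's plane.
    Factors from the two adjacent boundaries of a leaf multiply.
    """
    c_low = acc.stagger_fraction_low()    # (n_pairs-1, nx_acc)
    c_high = acc.stagger_fraction_high()
    x_src = acc.x_mm
    bounds = np.asarray(geometry.boundaries, float)
    pair = geometry.pair_of(grid.y_mm / magnification)

    values = np.ones(grid.shape)
    x_grid = grid.x_mm / magnification
    for row, p in enumerate(pair):
        if p < 0:
            continue
        y = grid.y_mm[row]
        # boundary below this row's pair (stagger with pair p-1)
        if p - 1 >= 0:
            d = y - bounds[p] * magnification
            t = _tng_lookup(ts, d)
            if t < 1.0:
                c = np.interp(x_grid, x_src, c_high[p - 1])
                values[row] *= 1.0 - c * (1.0 - t)
        # boundary above (stagger with pair p+1)
        if p + 1 <= geometry.n_pairs - 1:
            d = bounds[p + 1] * magnification - y
            t = _tng_lookup(ts, d)
            if t < 1.0:
                c = np.interp(x_grid, x_src, c_low[p])
                values[row] *= 1.0 - c * (1.0 - t)
    return grid.copy(values=values, units="relative")


def dynamic_tng_map(ts: TemplateSet, seq: DynamicSequence, spacing_um: float,
                    n_intervals: int, grid: PlaneGrid,
                    magnification: float = 1.0,
                    dlg_mm: float | None = None) -> PlaneGrid:
    """The dynamic tongue-and-groove map for a delivery, on ``grid``.

    Stagger detection uses the same gap-widened tip positions as the ideal
    fluence. The map is multiplicative and bounded by
    ``[min(tng_profile), 1]``.
    """
    from .fluence import accumulate_exposure, sample_and_widen
    from .mlc_sequence import DEFAULT_DLG_MM

    dlg = DEFAULT_DLG_MM if dlg_mm is None else dlg_mm
    sampled = sample_and_widen(seq, n_intervals, dlg)
    dx = spacing_um / 1000.0
    half = max(abs(seq.jaws[0]), abs(seq.jaws[1])) + 30.0
    nx = 2 * int(np.ceil(half / dx)) + 1
    x_mm = (np.arange(nx) - nx // 2) * dx
    acc = accumulate_exposure(sampled, x_mm, with_stagger=True)
    return tng_map_from_stagger(ts, seq.geometry, acc, grid, magnification)
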