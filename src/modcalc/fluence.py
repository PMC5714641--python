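"""Ideal dynamic 2D fluence and MLC transmission on the isocenter plane.

The ideal fluence of a dynamic delivery, in MU, is the meterset-weighted
fraction of the delivery during which each point is exposed (inside the jaw
rectangle and between the gap-widened tips of its leaf pair), multiplied by
the total MU. Because leaf pairs are rigid across the field, the exposure is
accumulated in a compact ``(pair, x)`` representation and expanded to 2D
once; the moving leaf tips are anti-aliased by fractional pixel coverage
along the travel axis, while leaf sides and jaw edges are treated as sharp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import PlaneGrid, centered_grid, ISOCENTER
from .mlc_sequence import (DynamicSequence, SampledDelivery, apply_dosimetric_gap,
                           resample_time, DEFAULT_DLG_MM)

DEFAULT_MARGIN_MM = 30.0
COMMISSIONING_SPACING_UM = 500.0
COMMISSIONING_INTERVALS = 600
CLINICAL_SPACING_UM = 1486.0
CLINICAL_INTERVALS = 200


@dataclass
class ExposureAccumulator:
    """Meterset-fraction exposure of every leaf pair along the travel axis.

    ``exposure[p, i]`` is the fraction of the delivery (by meterset) during
    which the pixel column ``x_mm[i]`` of pair ``p`` lies in the open gap.
    ``stag_low[k]``/``stag_high[k]`` accumulate, for interior boundary ``k``
    (between pairs ``k-1`` and ``k``), the meterset during which the pair on
    that side of the boundary is open while its neighbor across the boundary
    is blocked — the staggered-edge condition driving tongue-and-groove.
    """

    x_mm: np.ndarray
    exposure: np.ndarray    # (n_pairs, nx)
    stag_low: np.ndarray    # (n_pairs + 1, nx): open pair k-1, blocked pair k
    stag_high: np.ndarray   # (n_pairs + 1, nx): open pair k, blocked pair k-1

    def stagger_fraction_low(self) -> np.ndarray:
        """C for the lower-y side of each interior boundary: the staggered
        share of that side's own exposure (0 where never exposed)."""
        e = self.exposure[:-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(e > 1e-12, self.stag_low[1:-1] / np.maximum(e, 1e-12), 0.0)
        return np.clip(c, 0.0, 1.0)

    def stagger_fraction_high(self) -> np.ndarray:
        e = self.exposure[1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(e > 1e-12, self.stag_high[1:-1] / np.maximum(e, 1e-12), 0.0)
        return np.clip(c, 0.0, 1.0)


def accumulate_exposure(sampled: SampledDelivery, x_mm: np.ndarray,
                        with_stagger: bool = True) -> ExposureAccumulator:
    """Run the per-interval sweep over an already gap-widened sampling."""
    n_pairs = sampled.tips_a.shape[1]
    nx = x_mm.size
    dx = x_mm[1] - x_mm[0] if nx > 1 else 1.0
    h = dx / 2.0
    lo = x_mm - h
    hi = x_mm + h

    exposure = np.zeros((n_pairs, nx))
    stag_low = np.zeros((n_pairs + 1, nx))
    stag_high = np.zeros((n_pairs + 1, nx))

    for k in range(sampled.n_intervals):
        a = sampled.tips_a[k][:, None]
        b = sampled.tips_b[k][:, None]
        cov = np.clip((np.minimum(b, hi) - np.maximum(a, lo)) / dx, 0.0, 1.0)
        w = sampled.weights[k]
        exposure += w * cov
        if with_stagger and n_pairs > 1:
            # exact per-pixel symmetric difference of adjacent apertures:
            # open on one side of the boundary, blocked on the other
            a_int = np.maximum(a[:-1], a[1:])
            b_int = np.minimum(b[:-1], b[1:])
            cov_int = np.clip((np.minimum(b_int, hi) - np.maximum(a_int, lo))
                              / dx, 0.0, 1.0)
            stag_low[1:-1] += w * np.clip(cov[:-1] - cov_int, 0.0, None)
            stag_high[1:-1] += w * np.clip(cov[1:] - cov_int, 0.0, None)
    return ExposureAccumulator(x_mm, exposure, stag_low, stag_high)


def jaw_mask(grid: PlaneGrid, jaws: tuple[float, float, float, float],
             scale: float = 1.0, guard_px: int = 0) -> np.ndarray:
    """Binary pixel-center mask of the jaw rectangle (edges treated as
    ideal). ``scale`` magnifies the rectangle (imager plane); ``guard_px``
    dilates it by whole pixels."""
    x1, x2, y1, y2 = (v * scale for v in jaws)
    g = guard_px * grid.spacing_mm
    in_x = (grid.x_mm >= x1 - g) & (grid.x_mm <= x2 + g)
    in_y = (grid.y_mm >= y1 - g) & (grid.y_mm <= y2 + g)
    return np.outer(in_y, in_x)


def expand_to_grid(acc: ExposureAccumulator, geometry, grid: PlaneGrid,
                   ) -> np.ndarray:
    """Expand a (pair, x) exposure onto a 2D grid with sharp leaf sides."""
    pair = geometry.pair_of(grid.y_mm)
    out = np.zeros(grid.shape)
    inside = pair >= 0
    out[inside, :] = acc.exposure[pair[inside], :]
    return out


def sample_and_widen(seq: DynamicSequence, n_intervals: int,
                     dlg_mm: float = DEFAULT_DLG_MM, **dlg_kwargs,
                     ) -> SampledDelivery:
    return apply_dosimetric_gap(resample_time(seq, n_intervals), dlg_mm,
                                **dlg_kwargs)


def fluence_grid_for(seq: DynamicSequence, spacing_um: float,
                     margin_mm: float = DEFAULT_MARGIN_MM) -> PlaneGrid:
    x1, x2, y1, y2 = seq.jaws
    half_x = max(abs(x1), abs(x2)) + margin_mm
    half_y = max(abs(y1), abs(y2)) + margin_mm
    return centered_grid(half_x, half_y, spacing_um, ISOCENTER, "MU")


def accumulate_ideal_fluence(seq: DynamicSequence, spacing_um: float,
                             n_intervals: int,
                             dlg_mm: float = DEFAULT_DLG_MM,
                             margin_mm: float = DEFAULT_MARGIN_MM,
                             acc: ExposureAccumulator | None = None,
                             ) -> PlaneGrid:
    """The ideal dynamic fluence map, in MU, on the isocenter plane.

    For an open 1 MU field this is 1 MU inside the jaws and 0 under the
    leaves or outside the jaws.
    """
    grid = fluence_grid_for(seq, spacing_um, margin_mm)
    if acc is None:
        sampled = sample_and_widen(seq, n_intervals, dlg_mm)
        acc = accumulate_exposure(sampled, grid.x_mm, with_stagger=False)
    values = expand_to_grid(acc, seq.geometry, grid)
    values *= jaw_mask(grid, seq.jaws)
    grid.values = values * seq.total_mu
    return grid


def transmission_map(phi_ideal: PlaneGrid, total_mu: float,
                     jaws: tuple[float, float, float, float]) -> PlaneGrid:
    """The dynamic MLC transmission weight: blocked fraction of the delivery.

    Since transmission plus ideal fluence make up the whole delivery, the
    map is ``1 - phi_ideal/total_mu`` inside the jaws and 0 outside.
    """
    mask = jaw_mask(phi_ideal, jaws)
    values = np.where(mask, 1.0 - phi_ideal.values / total_mu, 0.0)
    return phi_ideal.copy(values=np.clip(values, 0.0, 1.0), units="relative")
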