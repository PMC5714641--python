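"""Regular 2D scalar maps in a named beam plane.

All fluence, headscatter, EPID-response and modulation maps are carried by
:class:`PlaneGrid`: a regular grid of pixel-center samples in either the
isocenter plane (100 cm from the source) or the imager plane (105 cm).
Coordinates are millimetres in the plane itself; ``values[iy, ix]`` is the
sample at ``(x_mm[ix], y_mm[iy])``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

ISOCENTER = "isocenter"
IMAGER = "imager"

#: EPID pixel pitch in the imager plane (aS500 panel), micrometres.
EPID_PITCH_UM = 784.0


@dataclass
class PlaneGrid:
    """A 2D scalar map on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (ny, nx)
        Pixel-center samples.
    spacing_um : float
        Grid pitch in micrometres, equal in x and y, measured in ``plane``.
    plane : {"isocenter", "imager"}
    origin : (float, float)
        Physical (x, y) position in mm of the center of pixel ``[0, 0]``.
    units : str
        One of "MU", "relative", "ratio".
    """

    values: np.ndarray
    spacing_um: float
    plane: str = ISOCENTER
    origin: tuple[float, float] = (0.0, 0.0)
    units: str = "relative"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("PlaneGrid values must be 2D")
        if not self.spacing_um > 0:
            raise ValueError("grid spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PlaneGrid values must be finite")

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um / 1000.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def x_mm(self) -> np.ndarray:
        return self.origin[0] + self.spacing_mm * np.arange(self.values.shape[1])

    @property
    def y_mm(self) -> np.ndarray:
        return self.origin[1] + self.spacing_mm * np.arange(self.values.shape[0])

    def copy(self, values: np.ndarray | None = None, **changes) -> "PlaneGrid":
        g = replace(self, **changes)
        g.values = self.values.copy() if values is None else np.asarray(values, float)
        return g

    # ------------------------------------------------------------------ #
    def interpolator(self, fill_value: float = 0.0) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.y_mm, self.x_mm),
            self.values,
            method="linear",
            bounds_error=False,
            fill_value=fill_value,
        )

    def sample(self, x_mm, y_mm):
        """Bilinear sample at (x, y); zero outside the grid. Scalar inputs
        return a float."""
        x_mm = np.asarray(x_mm, float)
        y_mm = np.asarray(y_mm, float)
        shape = np.broadcast_shapes(x_mm.shape, y_mm.shape)
        pts = np.stack([np.broadcast_to(y_mm, shape).ravel(),
                        np.broadcast_to(x_mm, shape).ravel()], axis=-1)
        out = self.interpolator()(pts).reshape(shape)
        return float(out) if out.ndim == 0 else out

    def resample_onto(self, template: "PlaneGrid", coord_scale: float = 1.0) -> "PlaneGrid":
        """Sample this map at the pixel positions of ``template``.

        ``coord_scale`` maps template coordinates into this grid's frame
        (e.g. ``1/1.05`` when projecting an isocenter map onto the imager).
        """
        xx, yy = np.meshgrid(template.x_mm * coord_scale, template.y_mm * coord_scale)
        vals = self.sample(xx, yy)
        return PlaneGrid(vals, template.spacing_um, template.plane,
                         template.origin, self.units)


def centered_grid(half_x_mm: float, half_y_mm: float, spacing_um: float,
                  plane: str = ISOCENTER, units: str = "relative") -> PlaneGrid:
    """An all-zero grid symmetric about the beam axis with a pixel at (0, 0)."""
    dx = spacing_um / 1000.0
    nx = 2 * int(np.ceil(half_x_mm / dx)) + 1
    ny = 2 * int(np.ceil(half_y_mm / dx)) + 1
    origin = (-dx * (nx // 2), -dx * (ny // 2))
    return PlaneGrid(np.zeros((ny, nx)), spacing_um, plane, origin, units)


def magnify_to_imager(grid: PlaneGrid, magnification: float = 1.05,
                      spacing_um: float = EPID_PITCH_UM) -> PlaneGrid:
    """Project an isocenter-plane map onto the imager plane.

    The map is geometrically magnified (coordinates scaled by
    ``magnification``) and resampled to the imager pixel pitch.
    """
    if grid.plane != ISOCENTER:
        raise ValueError("expected an isocenter-plane map")
    half_x = grid.x_mm[-1] * magnification
    half_y = grid.y_mm[-1] * magnification
    out = centered_grid(half_x, half_y, spacing_um, plane=IMAGER, units=grid.units)
    return grid.resample_onto(out, coord_scale=1.0 / magnification)


# ---------------------------------------------------------------------- #
# persistence: plain-text matrix + JSON sidecar, or single-precision TIFF

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_grid(grid: PlaneGrid, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "spacing_um": grid.spacing_um,
        "plane": grid.plane,
        "origin_mm": list(grid.origin),
        "units": grid.units,
    }
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, grid.values.astype(np.float32))
    else:
        np.savetxt(path, grid.values)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_grid(path: str | Path) -> PlaneGrid:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        values = np.asarray(tifffile.imread(path), dtype=float)
    else:
        values = np.loadtxt(path)
    return PlaneGrid(values, meta["spacing_um"], meta["plane"],
                     tuple(meta["origin_mm"]), meta["units"])
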