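"""Pencil-beam dose convolution and modulation factors.

The full fluence of a modulated field and of its open-field counterpart
(same jaws and MU, leaves retracted) are each convolved with a radially
symmetric pencil-beam dose kernel for the depth of interest in water; the
pixelwise ratio of the two dose maps is the 2D modulation map, and its ROI
average at the plan's reference point — after a small placement search that
absorbs setup/lookup uncertainty — is the modulation factor reported by the
second check.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

from ._fft import convolve2d_same
from .fluence import jaw_mask
from .grids import EPID_PITCH_UM, ISOCENTER, PlaneGrid, centered_grid
from .epid import simulate_field
from .mlc_sequence import DynamicSequence, open_counterpart, parse_mlc_file

if TYPE_CHECKING:  # pragma: no cover
    from .config import ModelConfig

#: ROI geometries, mm in the isocenter plane: (extent along leaf travel,
#: extent perpendicular). The chamber ROI emulates averaging over the ion
#: chamber's cylindrical volume with its long axis along leaf travel.
ROI_SHAPES_MM = {"chamber": (10.5, 3.5), "tps": (2.5, 2.5)}
DEFAULT_SEARCH_MM = {"chamber": 1.0, "tps": 1.25}
RESAMPLE_UM = 187.0
PASS_THRESHOLD_PCT = 5.0
TIGHT_THRESHOLD_PCT = 2.0


@dataclass(frozen=True)
class DoseKernel:
    """Radially symmetric pencil-beam dose kernel at one water depth.

    ``radii_mm``/``values`` tabulate the radial profile (monotone
    non-increasing beyond the core); the rasterized 2D kernel is normalized
    to unit integral.
    """

    depth_cm: float
    radii_mm: tuple[float, ...]
    values: tuple[float, ...]
    pitch_um: float = EPID_PITCH_UM

    def __post_init__(self):
        r = np.asarray(self.radii_mm, float)
        v = np.asarray(self.values, float)
        if r.size != v.size or r.size < 1:
            raise ValueError("radial table must pair radii with values")
        if np.any(np.diff(r) <= 0) or np.any(v < 0):
            raise ValueError("radii must increase and values be non-negative")

    def to_array(self, pitch_um: float | None = None) -> np.ndarray:
        pitch = (pitch_um or self.pitch_um) / 1000.0
        r = np.asarray(self.radii_mm, float)
        v = np.asarray(self.values, float)
        if r.size == 1:  # delta kernel
            return np.ones((1, 1))
        half_px = max(int(np.ceil(r[-1] / pitch)), 1)
        ax = pitch * np.arange(-half_px, half_px + 1)
        xx, yy = np.meshgrid(ax, ax)
        k = np.interp(np.hypot(xx, yy), r, v, right=0.0)
        s = k.sum()
        if s <= 0:
            raise ValueError("kernel rasterized to zero")
        return k / s

    # -------------------------------------------------------------- #
    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["radius_mm", "value"])
            for r, v in zip(self.radii_mm, self.values):
                w.writerow([f"{r:.6g}", f"{v:.8g}"])
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(
            {"depth_cm": self.depth_cm, "pitch_um": self.pitch_um}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DoseKernel":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        radii, values = [], []
        with open(path) as fh:
            for row in csv.DictReader(fh):
                radii.append(float(row["radius_mm"]))
                values.append(float(row["value"]))
        return cls(meta["depth_cm"], tuple(radii), tuple(values),
                   meta.get("pitch_um", EPID_PITCH_UM))


def nearest_kernel(kernels, depth_cm: float,
                   tol_cm: float = 10.0) -> DoseKernel:
    """The shipped kernel closest in depth (within ``tol_cm``)."""
    best = min(kernels, key=lambda k: abs(k.depth_cm - depth_cm))
    if abs(best.depth_cm - depth_cm) > tol_cm:
        raise ValueError(f"no dose kernel within {tol_cm} cm of depth "
                         f"{depth_cm} cm")
    return best


# --------------------------------------------------------------------------- #
@dataclass
class ModResult:
    mod_calc: float
    mod_ref: float
    pct_diff: float
    offset_mm: tuple[float, float]
    depth_cm: float
    field_id: str = ""

    def __post_init__(self):
        if not (0.0 < self.mod_calc <= 1.5):
            raise ValueError(f"modulation factor {self.mod_calc} outside (0, 1.5]")

    @property
    def pass_5pct(self) -> bool:
        return abs(self.pct_diff) <= PASS_THRESHOLD_PCT

    @property
    def pass_2pct(self) -> bool:
        return abs(self.pct_diff) <= TIGHT_THRESHOLD_PCT


def percent_difference(mod_calc: float, mod_ref: float) -> float:
    return (mod_calc - mod_ref) / mod_ref * 100.0


# --------------------------------------------------------------------------- #
def dose_map(phi_full: PlaneGrid, kernel: DoseKernel) -> PlaneGrid:
    """Dose in water at the kernel's depth: fluence convolved with the
    pencil-beam kernel at a common pitch."""
    k = kernel.to_array(phi_full.spacing_um)
    vals = np.clip(convolve2d_same(phi_full.values, k), 0.0, None)
    return phi_full.copy(values=vals, units="relative")


def _demagnify(phi_img: PlaneGrid, magnification: float,
               pitch_um: float) -> PlaneGrid:
    """Project an imager-plane fluence back to the isocenter plane at the
    dose kernel's native pitch."""
    half_x = phi_img.x_mm[-1] / magnification
    half_y = phi_img.y_mm[-1] / magnification
    out = centered_grid(half_x, half_y, pitch_um, ISOCENTER, phi_img.units)
    return phi_img.resample_onto(out, coord_scale=magnification)


def modulation_map(seq: DynamicSequence, kernel: DoseKernel,
                   model: "ModelConfig", spacing_um: float | None = None,
                   n_intervals: int | None = None) -> PlaneGrid:
    """The 2D modulation map at the kernel's depth.

    Ratio of the dose maps of the modulated field and its open counterpart,
    defined inside the jaw rectangle and zero outside.
    """
    spacing = spacing_um or model.clinical_spacing_um
    intervals = n_intervals or model.clinical_intervals
    comp_mod = simulate_field(seq, model, spacing, intervals)
    comp_open = simulate_field(open_counterpart(seq), model, spacing, intervals)
    phi_mod = _demagnify(comp_mod.full_fluence(), model.magnification,
                         EPID_PITCH_UM)
    phi_open = _demagnify(comp_open.full_fluence(), model.magnification,
                          EPID_PITCH_UM)
    d_mod = dose_map(phi_mod, kernel)
    d_open = dose_map(phi_open, kernel)
    mask = jaw_mask(d_mod, seq.jaws)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mask & (d_open.values > 0),
                         d_mod.values / np.maximum(d_open.values, 1e-300), 0.0)
    out = d_mod.copy(values=ratio, units="ratio")
    return out


# --------------------------------------------------------------------------- #
def sample_modulation(mod: PlaneGrid, point_mm: tuple[float, float],
                      mod_ref: float, roi: str = "tps",
                      search_mm: float | None = None,
                      collimator_deg: float = 0.0,
                      resample_um: float = RESAMPLE_UM,
                      depth_cm: float = 10.0,
                      field_id: str = "") -> ModResult:
    """ROI-averaged modulation factor with a placement search.

    The reference point (BEV mm) is rotated by the collimator angle into the
    field frame — the point moves, not the map. The map is linearly
    resampled to ``resample_um``; the ROI mean is evaluated at every
    displacement on that grid with ``|dx|, |dy| <= search_mm`` and the
    displacement minimizing the percent discrepancy against ``mod_ref`` is
    reported. Ties prefer the smallest displacement, then lexicographic
    (dy, dx) order.
    """
    if roi not in ROI_SHAPES_MM:
        raise ValueError(f"unknown ROI kind {roi!r}")
    if search_mm is None:
        search_mm = DEFAULT_SEARCH_MM[roi]
    theta = np.deg2rad(collimator_deg)
    px, py = point_mm
    qx = np.cos(theta) * px - np.sin(theta) * py
    qy = np.sin(theta) * px + np.cos(theta) * py
    inside = mod.sample(qx, qy)
    if inside <= 0.0:
        raise ValueError(f"reference point ({qx:.1f}, {qy:.1f}) mm is outside "
                         "the field's jaws")

    step = resample_um / 1000.0
    rx, ry = ROI_SHAPES_MM[roi]
    nx = max(int(round(rx / step)), 1)
    ny = max(int(round(ry / step)), 1)
    roi_x = (np.arange(nx) - (nx - 1) / 2.0) * step
    roi_y = (np.arange(ny) - (ny - 1) / 2.0) * step
    n_off = int(np.floor(search_mm / step + 1e-9))
    offsets = step * np.arange(-n_off, n_off + 1)

    interp = mod.interpolator()
    best = None
    for dy in offsets:
        yy = qy + dy + roi_y
        for dx in offsets:
            xx = qx + dx + roi_x
            gy, gx = np.meshgrid(yy, xx, indexing="ij")
            mean = float(interp(np.stack([gy, gx], axis=-1)).mean())
            pct = percent_difference(mean, mod_ref)
            key = (abs(pct), dx * dx + dy * dy, dy, dx)
            if best is None or key < best[0]:
                best = (key, mean, pct, (float(dx), float(dy)))
    _, mod_calc, pct, offset = best
    return ModResult(mod_calc, mod_ref, pct, offset, depth_cm, field_id)


# --------------------------------------------------------------------------- #
RECORD_COLUMNS = ["timestamp", "plan", "field", "depth_cm", "mod_ref",
                  "mod_calc", "pct_diff", "offset_x_mm", "offset_y_mm",
                  "pass_5pct", "pass_2pct"]


def append_record(result: ModResult, records_path: str | Path,
                  plan: str = "") -> None:
    path = Path(records_path)
    new = not path.exists()
    with open(path, "a", newline="") as fh:
        w = csv.writer(fh)
        if new:
            w.writerow(RECORD_COLUMNS)
        w.writerow([datetime.now(timezone.utc).isoformat(timespec="seconds"),
                    plan, result.field_id, result.depth_cm,
                    f"{result.mod_ref:.5f}", f"{result.mod_calc:.5f}",
                    f"{result.pct_diff:.3f}",
                    f"{result.offset_mm[0]:.3f}", f"{result.offset_mm[1]:.3f}",
                    result.pass_5pct, result.pass_2pct])


def run_field(seq: DynamicSequence | str | Path,
              ref_point_mm: tuple[float, float], depth_cm: float,
              mod_ref: float, model: "ModelConfig", kernels,
              collimator_deg: float | None = None, roi: str = "tps",
              records_path: str | Path | None = None, plan: str = "",
              field_id: str = "", spacing_um: float | None = None,
              n_intervals: int | None = None) -> ModResult:
    """End-to-end second check of one field at clinical sampling.

    Computes the modulation map at the nearest kernel depth, samples it at
    the reference point with the TPS-matched ROI and placement search, and
    appends a row to the records file when one is given.
    """
    if not isinstance(seq, DynamicSequence):
        seq = parse_mlc_file(seq, model.geometry)
    if collimator_deg is None:
        collimator_deg = seq.collimator_deg
    kernel = nearest_kernel(kernels, depth_cm)
    mod = modulation_map(seq, kernel, model, spacing_um, n_intervals)
    result = sample_modulation(mod, ref_point_mm, mod_ref, roi=roi,
                               collimator_deg=collimator_deg,
                               depth_cm=depth_cm, field_id=field_id)
    if records_path is not None:
        append_record(result, records_path, plan)
    return result
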