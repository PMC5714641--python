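"""Dynamic multileaf-collimator delivery sequences.

A dynamic delivery is a list of control points, each giving the position of
every leaf tip together with the cumulative meterset fraction at which those
positions are reached. This module represents such sequences, reads and
writes a plain-text Varian-style control-point dialect (and a CSV table for
arc deliveries), resamples them into uniform meterset intervals, applies the
rounded-leaf dosimetric gap correction, and generates the sweeping-window
and sweeping-checkerboard commissioning deliveries.

Sign convention: leaf travel is along the beam's-eye-view x axis. Bank A
forms the low-x side of each aperture and bank B the high-x side, so the
open interval of pair ``i`` is ``[bank_a[i], bank_b[i]]`` in mm at the
isocenter plane. In the text dialect bank-A tips are written negated (in
cm), following the convention of Varian MLC files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

DEFAULT_DLG_MM = 1.9  # rounded-leaf dosimetric gap, from TPS commissioning
CLOSED_GAP_THRESHOLD_MM = 0.5

DYNAMIC = "dynamic"
STEP_AND_SHOOT = "step_and_shoot"
ARC = "arc"


class MLCParseError(ValueError):
    """Raised for malformed control-point files."""


# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class LeafGeometry:
    """Leaf-pair layout across the field (perpendicular to leaf travel).

    ``boundaries`` are the ``n_pairs + 1`` leaf-edge positions in mm at the
    isocenter plane, strictly increasing; pair ``i`` spans
    ``[boundaries[i], boundaries[i+1]]``. At most two distinct leaf widths
    are permitted (the Millennium-120 has 5 mm and 10 mm leaves).
    """

    boundaries: tuple[float, ...]

    def __post_init__(self):
        b = np.asarray(self.boundaries, float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("need at least two leaf boundaries")
        if not np.all(np.diff(b) > 0):
            raise ValueError("leaf boundaries must be strictly increasing")
        widths = np.round(np.diff(b), 6)
        if np.unique(widths).size > 2:
            raise ValueError("at most two distinct leaf widths are permitted")

    @property
    def n_pairs(self) -> int:
        return len(self.boundaries) - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(np.asarray(self.boundaries, float))

    @property
    def centers(self) -> np.ndarray:
        b = np.asarray(self.boundaries, float)
        return 0.5 * (b[:-1] + b[1:])

    def pair_of(self, y_mm: np.ndarray) -> np.ndarray:
        """Index of the pair containing each y (-1 outside the leaf bank)."""
        b = np.asarray(self.boundaries, float)
        idx = np.searchsorted(b, np.asarray(y_mm, float), side="right") - 1
        idx = np.where((idx < 0) | (idx >= self.n_pairs), -1, idx)
        return idx

    @classmethod
    def millennium120(cls) -> "LeafGeometry":
        """Standard Millennium-120 layout: 10 outer 10 mm pairs per side,
        40 central 5 mm pairs, spanning +-200 mm."""
        edges = np.concatenate([
            np.arange(-200.0, -100.0, 10.0),
            np.arange(-100.0, 100.0, 5.0),
            np.arange(100.0, 200.0 + 1e-9, 10.0),
        ])
        return cls(tuple(edges))


@dataclass(frozen=True)
class ControlPoint:
    """Leaf tip positions at one cumulative meterset fraction."""

    index: float                       # cumulative meterset fraction in [0, 1]
    bank_a: tuple[float, ...]          # mm at isocenter, low-x tips
    bank_b: tuple[float, ...]          # mm at isocenter, high-x tips
    gantry_deg: float | None = None    # arcs only

    def __post_init__(self):
        if not (0.0 <= self.index <= 1.0 + 1e-9):
            raise ValueError(f"control point index {self.index} outside [0, 1]")
        a = np.asarray(self.bank_a, float)
        b = np.asarray(self.bank_b, float)
        if a.shape != b.shape:
            raise ValueError("bank A and bank B must have the same leaf count")
        if np.any(b - a < -1e-6):
            raise ValueError("negative aperture: a bank-A tip exceeds its bank-B tip")


@dataclass(frozen=True)
class DynamicSequence:
    """A complete dynamic MLC delivery for one field."""

    geometry: LeafGeometry
    points: tuple[ControlPoint, ...]
    jaws: tuple[float, float, float, float]  # x1, x2, y1, y2 in mm at isocenter
    collimator_deg: float = 0.0
    total_mu: float = 100.0
    delivery_kind: str = DYNAMIC

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValueError("a dynamic sequence needs at least two control points")
        idx = np.array([p.index for p in self.points])
        if abs(idx[0]) > 1e-9 or abs(idx[-1] - 1.0) > 1e-9:
            raise ValueError("control point indices must run from 0 to 1")
        bad = np.nonzero(np.diff(idx) < -1e-12)[0]
        if bad.size:
            raise ValueError(
                f"non-monotonic meterset index at control point {bad[0] + 2}")
        x1, x2, y1, y2 = self.jaws
        if not (x2 > x1 and y2 > y1):
            raise ValueError("jaws must define a non-empty rectangle")
        for p in self.points:
            if len(p.bank_a) != self.geometry.n_pairs:
                raise ValueError("control point leaf count does not match geometry")
        if self.delivery_kind not in (DYNAMIC, STEP_AND_SHOOT, ARC):
            raise ValueError(f"unknown delivery kind {self.delivery_kind!r}")

    @property
    def n_pairs(self) -> int:
        return self.geometry.n_pairs

    def bank_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(indices, bank_a, bank_b) stacked over control points."""
        idx = np.array([p.index for p in self.points])
        a = np.array([p.bank_a for p in self.points])
        b = np.array([p.bank_b for p in self.points])
        return idx, a, b

    def approx_equal(self, other: "DynamicSequence", tol_mm: float = 1e-6) -> bool:
        if (self.geometry.n_pairs != other.geometry.n_pairs
                or len(self.points) != len(other.points)
                or self.delivery_kind != other.delivery_kind):
            return False
        ia, aa, ba = self.bank_arrays()
        ib, ab, bb = other.bank_arrays()
        return (np.allclose(ia, ib, atol=1e-9)
                and np.allclose(aa, ab, atol=tol_mm)
                and np.allclose(ba, bb, atol=tol_mm)
                and np.allclose(self.jaws, other.jaws, atol=tol_mm)
                and abs(self.total_mu - other.total_mu) < 1e-6
                and abs(self.collimator_deg - other.collimator_deg) < 1e-9)


@dataclass
class SampledDelivery:
    """Per-interval leaf positions and meterset increments.

    ``tips_a``/``tips_b`` have shape ``(n_intervals, n_pairs)`` in mm at
    isocenter; ``weights`` are meterset fractions summing exactly to 1.
    """

    tips_a: np.ndarray
    tips_b: np.ndarray
    weights: np.ndarray
    gantry_deg: np.ndarray | None = None

    @property
    def n_intervals(self) -> int:
        return self.weights.size


# --------------------------------------------------------------------------- #
# time resampling and the dosimetric-gap correction

def resample_time(seq: DynamicSequence, n_intervals: int) -> SampledDelivery:
    """Resolve the delivery into ``n_intervals`` meterset intervals.

    Dynamic deliveries interpolate leaf positions linearly in cumulative
    meterset and are sampled at interval midpoints; step-and-shoot
    deliveries hold the positions of the governing control point constant
    within each segment; arc deliveries are sampled uniformly across the
    control-point table, each interval carrying its meterset increment from
    the table (which encodes the gantry-dependent dose rate).
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    idx, a, b = seq.bank_arrays()
    n = n_intervals
    gantry = None

    if seq.delivery_kind == ARC:
        s_edges = np.linspace(0.0, len(seq.points) - 1.0, n + 1)
        s_mid = 0.5 * (s_edges[:-1] + s_edges[1:])
        cp = np.arange(len(seq.points), dtype=float)
        weights = np.diff(np.interp(s_edges, cp, idx))
        tips_a = np.vstack([np.interp(s_mid, cp, a[:, j]) for j in range(a.shape[1])]).T
        tips_b = np.vstack([np.interp(s_mid, cp, b[:, j]) for j in range(b.shape[1])]).T
        g = np.array([p.gantry_deg if p.gantry_deg is not None else 0.0
                      for p in seq.points])
        gantry = np.interp(s_mid, cp, g)
    else:
        m = (np.arange(n) + 0.5) / n
        weights = np.full(n, 1.0 / n)
        if seq.delivery_kind == STEP_AND_SHOOT:
            seg = np.clip(np.searchsorted(idx, m, side="right") - 1, 0, len(idx) - 1)
            tips_a = a[seg]
            tips_b = b[seg]
        else:
            tips_a = np.vstack([np.interp(m, idx, a[:, j]) for j in range(a.shape[1])]).T
            tips_b = np.vstack([np.interp(m, idx, b[:, j]) for j in range(b.shape[1])]).T

    weights = np.asarray(weights, float)
    weights[-1] += 1.0 - weights.sum()  # partition of unity, exactly
    return SampledDelivery(tips_a, tips_b, weights, gantry)


def apply_dosimetric_gap(sampled: SampledDelivery,
                         dlg_mm: float = DEFAULT_DLG_MM,
                         exempt_closed: bool = True,
                         closed_threshold_mm: float = CLOSED_GAP_THRESHOLD_MM,
                         ) -> SampledDelivery:
    """Widen every open leaf gap by ``dlg_mm`` (each tip retreats half).

    This models transmission through the rounded leaf ends; no further
    leaf-position offset is applied. Pairs whose nominal gap does not exceed
    ``closed_threshold_mm`` are treated as fully closed and left unchanged
    when ``exempt_closed`` is set, so parked pairs do not acquire a spurious
    leakage slit.
    """
    if dlg_mm < 0:
        raise ValueError("dosimetric gap must be non-negative")
    gap = sampled.tips_b - sampled.tips_a
    widen = np.ones_like(gap, dtype=bool)
    if exempt_closed:
        widen = gap > closed_threshold_mm
    half = 0.5 * dlg_mm * widen
    return SampledDelivery(sampled.tips_a - half, sampled.tips_b + half,
                           sampled.weights.copy(),
                           None if sampled.gantry_deg is None
                           else sampled.gantry_deg.copy())


# --------------------------------------------------------------------------- #
# text dialect

_HEADER_REV = "File Rev = G"


def write_mlc_file(seq: DynamicSequence, path: str | Path) -> None:
    """Write the control-point text dialect (positions in cm, two decimals).

    Bank-A tips are negated on output, mirroring Varian's sign convention.
    Jaw positions and total MU are carried in extra header lines so that the
    file round-trips through :func:`parse_mlc_file`.
    """
    lines = [_HEADER_REV,
             "Treatment = Dynamic Dose",
             f"Number of Fields = {len(seq.points)}",
             f"Total MU = {seq.total_mu:.4f}",
             f"Delivery = {seq.delivery_kind}"]
    for name, v in zip(("X1", "X2", "Y1", "Y2"), seq.jaws):
        lines.append(f"Jaw {name} = {v / 10.0:.2f}")
    for k, p in enumerate(seq.points, start=1):
        lines.append("")
        lines.append(f"Field = {k}/{len(seq.points)}")
        lines.append(f"Index = {p.index:.4f}")
        lines.append("Carriage Group = 1")
        lines.append("Operator = ")
        lines.append(f"Collimator = {seq.collimator_deg:.2f}")
        if p.gantry_deg is not None:
            lines.append(f"Gantry = {p.gantry_deg:.2f}")
        for j, v in enumerate(p.bank_a, start=1):
            lines.append(f"Leaf {j:>3}A = {-v / 10.0:7.2f}")
        for j, v in enumerate(p.bank_b, start=1):
            lines.append(f"Leaf {j:>3}B = {v / 10.0:7.2f}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_mlc_file(path: str | Path, geometry: LeafGeometry | None = None,
                   ) -> DynamicSequence:
    """Parse the control-point text dialect into a validated sequence.

    Leaf positions are converted to mm at isocenter and meterset indices
    normalized to [0, 1]. Raises :class:`MLCParseError` naming the offending
    record for malformed headers, wrong leaf counts, or a non-monotonic
    meterset index.
    """
    geometry = geometry or LeafGeometry.millennium120()
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != _HEADER_REV:
        raise MLCParseError("malformed header: expected 'File Rev = G'")

    kv = {}
    records: list[dict] = []
    current: dict | None = None
    for ln in lines[1:]:
        if "=" not in ln:
            raise MLCParseError(f"malformed line: {ln!r}")
        key, _, val = ln.partition("=")
        key = key.strip()
        val = val.strip()
        if key == "Field":
            current = {"a": {}, "b": {}}
            records.append(current)
        elif current is None:
            kv[key] = val
        elif key.startswith("Leaf"):
            name = key.split()[1]
            bank = name[-1].upper()
            try:
                num = int(name[:-1])
                pos = float(val)
            except ValueError as exc:
                raise MLCParseError(f"bad leaf record {ln!r}") from exc
            current["a" if bank == "A" else "b"][num] = pos
        else:
            current[key] = val

    if not records:
        raise MLCParseError("no control points found")
    n_pairs = geometry.n_pairs
    jaws = tuple(float(kv.get(f"Jaw {n}", d)) * 10.0
                 for n, d in zip(("X1", "X2", "Y1", "Y2"),
                                 ("-5", "5", "-5", "5")))
    total_mu = float(kv.get("Total MU", 100.0))
    kind = kv.get("Delivery", DYNAMIC)

    points = []
    collimator = 0.0
    prev_index = -np.inf
    for k, rec in enumerate(records, start=1):
        if "Index" not in rec:
            raise MLCParseError(f"control point {k} missing Index")
        index = float(rec["Index"])
        if index < prev_index - 1e-12:
            raise MLCParseError(f"non-monotonic meterset index at control point {k}")
        prev_index = index
        for bank_key, bank_name in (("a", "A"), ("b", "B")):
            if len(rec[bank_key]) != n_pairs:
                raise MLCParseError(
                    f"control point {k}: bank {bank_name} has "
                    f"{len(rec[bank_key])} leaves, expected {n_pairs}")
        a = [-10.0 * rec["a"][j + 1] for j in range(n_pairs)]
        b = [10.0 * rec["b"][j + 1] for j in range(n_pairs)]
        gantry = float(rec["Gantry"]) if "Gantry" in rec else None
        collimator = float(rec.get("Collimator", collimator))
        points.append(ControlPoint(index, tuple(a), tuple(b), gantry))

    lo, hi = points[0].index, points[-1].index
    if hi > lo:  # normalize cumulative meterset to [0, 1]
        points = [replace(p, index=(p.index - lo) / (hi - lo)) for p in points]
    return DynamicSequence(geometry, tuple(points), jaws, collimator,
                           total_mu, kind)


# --------------------------------------------------------------------------- #
# arc control-point table (CSV)

def write_arc_table(seq: DynamicSequence, path: str | Path) -> None:
    """Write an arc delivery as a CSV control-point table.

    Columns: control_point, cumulative_meterset_weight, gantry_deg, then the
    120 leaf positions in cm (A1..An negated, B1..Bn). Jaw settings, total
    MU and collimator angle travel in ``#``-comment header lines.
    """
    n = seq.geometry.n_pairs
    with open(path, "w", newline="") as fh:
        fh.write(f"# total_mu = {seq.total_mu:.4f}\n")
        fh.write("# jaws_mm = " + ",".join(f"{v:.2f}" for v in seq.jaws) + "\n")
        fh.write(f"# collimator_deg = {seq.collimator_deg:.2f}\n")
        writer = csv.writer(fh)
        writer.writerow(["control_point", "cumulative_meterset_weight", "gantry_deg"]
                        + [f"A{j+1}" for j in range(n)] + [f"B{j+1}" for j in range(n)])
        for k, p in enumerate(seq.points):
            row = [k, f"{p.index:.6f}",
                   f"{(p.gantry_deg if p.gantry_deg is not None else 0.0):.2f}"]
            row += [f"{-v/10.0:.2f}" for v in p.bank_a]
            row += [f"{v/10.0:.2f}" for v in p.bank_b]
            writer.writerow(row)


def parse_arc_table(path: str | Path, geometry: LeafGeometry | None = None,
                    ) -> DynamicSequence:
    """Parse the CSV arc table written by :func:`write_arc_table`."""
    geometry = geometry or LeafGeometry.millennium120()
    n = geometry.n_pairs
    total_mu, jaws, collimator = 100.0, (-50.0, 50.0, -50.0, 50.0), 0.0
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                key, _, val = ln[1:].partition("=")
                key = key.strip()
                if key == "total_mu":
                    total_mu = float(val)
                elif key == "jaws_mm":
                    jaws = tuple(float(v) for v in val.split(","))
                elif key == "collimator_deg":
                    collimator = float(val)
                continue
            rows.append(ln.split(","))
    header, data = rows[0], rows[1:]
    if len(header) != 3 + 2 * n:
        raise MLCParseError(
            f"arc table has {len(header) - 3} leaf columns, expected {2 * n}")
    points = []
    for rec in data:
        index = float(rec[1])
        gantry = float(rec[2])
        a = [-10.0 * float(v) for v in rec[3:3 + n]]
        b = [10.0 * float(v) for v in rec[3 + n:3 + 2 * n]]
        points.append(ControlPoint(index, tuple(a), tuple(b), gantry))
    return DynamicSequence(geometry, tuple(points), jaws, collimator,
                           total_mu, ARC)


# --------------------------------------------------------------------------- #
# generators

def _sweep(window_mm: float, offsets_mm: np.ndarray, field_mm: float,
           mu: float, geometry: LeafGeometry, kind: str = DYNAMIC,
           ) -> DynamicSequence:
    half = field_mm / 2.0
    o = np.asarray(offsets_mm, float)
    a0 = -half - window_mm - (o.max() - o.min())
    a1 = half
    cp = []
    for pos, index in ((a0, 0.0), (a1, 1.0)):
        tips_a = pos + o
        tips_b = tips_a + window_mm
        cp.append(ControlPoint(index, tuple(tips_a), tuple(tips_b)))
    jaws = (-half, half, -half, half)
    return DynamicSequence(geometry, tuple(cp), jaws, 0.0, mu, kind)


def generate_sweeping_window(gap_cm: float, field_cm: float, mu: float,
                             geometry: LeafGeometry | None = None,
                             ) -> DynamicSequence:
    """A constant-gap window swept across a square field at constant rate.

    All leaf pairs move in unison; the window overtravels the jaw edges so
    that every point of the field receives the same exposure. A gap equal to
    the field size degenerates to a static open field.
    """
    geometry = geometry or LeafGeometry.millennium120()
    if gap_cm <= 0 or field_cm <= 0 or gap_cm > field_cm:
        raise ValueError("require 0 < gap <= field size")
    if gap_cm >= field_cm:  # no room to sweep: open-field delivery
        return open_field_sequence(field_cm, mu, geometry)
    return _sweep(gap_cm * 10.0, np.zeros(geometry.n_pairs), field_cm * 10.0,
                  mu, geometry)


def generate_sweeping_checker(stagger_cm: float, field_cm: float, mu: float,
                              geometry: LeafGeometry | None = None,
                              ) -> DynamicSequence:
    """A sweeping checkerboard: adjacent pairs offset by the stagger.

    Both banks sweep with a window equal to the stagger, alternating pairs
    displaced by the stagger along leaf travel for the entire delivery, so
    every interior leaf boundary is staggered throughout.
    """
    geometry = geometry or LeafGeometry.millennium120()
    if stagger_cm <= 0 or field_cm <= 0 or stagger_cm > field_cm:
        raise ValueError("require 0 < stagger <= field size")
    offsets = (np.arange(geometry.n_pairs) % 2) * stagger_cm * 10.0
    return _sweep(stagger_cm * 10.0, offsets, field_cm * 10.0, mu, geometry)


def open_field_sequence(field_cm: float, mu: float,
                        geometry: LeafGeometry | None = None,
                        park_margin_mm: float = 100.0) -> DynamicSequence:
    """A static field with all leaves retracted well beyond the jaws."""
    geometry = geometry or LeafGeometry.millennium120()
    half = field_cm * 10.0 / 2.0
    park = half + park_margin_mm
    n = geometry.n_pairs
    cp0 = ControlPoint(0.0, tuple([-park] * n), tuple([park] * n))
    cp1 = ControlPoint(1.0, tuple([-park] * n), tuple([park] * n))
    return DynamicSequence(geometry, (cp0, cp1), (-half, half, -half, half),
                           0.0, mu, DYNAMIC)


def closed_field_sequence(field_cm: float, mu: float,
                          geometry: LeafGeometry | None = None,
                          park_mm: float | None = None) -> DynamicSequence:
    """A static field fully covered by the MLC (all pairs closed, parked
    beyond the positive-x jaw edge)."""
    geometry = geometry or LeafGeometry.millennium120()
    half = field_cm * 10.0 / 2.0
    park = park_mm if park_mm is not None else half + 20.0
    n = geometry.n_pairs
    cp0 = ControlPoint(0.0, tuple([park] * n), tuple([park] * n))
    cp1 = ControlPoint(1.0, tuple([park] * n), tuple([park] * n))
    return DynamicSequence(geometry, (cp0, cp1), (-half, half, -half, half),
                           0.0, mu, DYNAMIC)


def open_counterpart(seq: DynamicSequence) -> DynamicSequence:
    """The same field with the MLC removed: identical jaws, MU, collimator,
    leaves parked outside the largest jaw extent."""
    x1, x2, y1, y2 = seq.jaws
    park = max(abs(x1), abs(x2)) + 100.0
    n = seq.geometry.n_pairs
    cp0 = ControlPoint(0.0, tuple([-park] * n), tuple([park] * n))
    cp1 = ControlPoint(1.0, tuple([-park] * n), tuple([park] * n))
    return DynamicSequence(seq.geometry, (cp0, cp1), seq.jaws,
                           seq.collimator_deg, seq.total_mu, DYNAMIC)
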