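"""Synthetic commissioning inputs: EPID images, Sc tables, dose kernels.

Everything the pipeline consumes during commissioning can be generated here
without measured data. "Measured" EPID images are produced by the forward
response model itself, but with ground-truth template weights chosen so the
images exhibit the stated commissioning magnitudes — interleaf peaks of a
given relative height on the 1 cm sweeping window, a given maximum
tongue-and-groove dip on the 4 cm sweeping checker, and a given closed-field
leakage-plus-transmission total. Calibrating against these images is then a
genuine inverse problem whose solution is known, which is what the recovery
tests exercise. Dose kernels are analytic two-exponential radial stand-ins
with depth-dependent broadening; the kernel file interface accepts
externally generated Monte Carlo tables unchanged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .config import ModelConfig
from .dose import DoseKernel
from .epid import (FieldComputation, closed_field_ratio, interleaf_peak_metric,
                   simulate_field, tng_dip_metric)
from .headscatter import ExtrafocalSource, SC_FIELD_SIDES_CM, hsf_cax
from .mlc_effects import TemplateSet
from .mlc_sequence import (DynamicSequence, closed_field_sequence,
                           generate_sweeping_checker, generate_sweeping_window,
                           open_counterpart)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters embedded in the synthetic commissioning set.

    The embedded magnitudes are the commissioning constants the templates
    are later calibrated against: the relative interleaf-peak height on the
    1 cm sweeping window, the maximum tongue-and-groove dip on the 4 cm
    sweeping checker, and the closed-field leakage + transmission total
    relative to the open field.
    """

    seed: int = 0
    noise_rel: float = 0.0
    interleaf_peak: float = 0.057
    checker_dip: float = 0.23
    closed_total: float = 0.014
    field_cm: float = 10.0
    mu: float = 400.0
    spacing_um: float | None = None     # defaults to the model's sampling
    n_intervals: int | None = None

    def __post_init__(self):
        if self.noise_rel < 0:
            raise ValueError("noise must be non-negative")
        if min(self.interleaf_peak, self.checker_dip, self.closed_total) <= 0:
            raise ValueError("embedded amplitudes must be positive")


COMMISSIONING_FIELDS = ("window_1cm", "window_2cm", "window_4cm",
                        "checker_1cm", "checker_2cm", "checker_4cm",
                        "closed_10x10")


def commissioning_sequences(spec: FixtureSpec,
                            model: ModelConfig) -> dict[str, DynamicSequence]:
    g = model.geometry
    f, mu = spec.field_cm, spec.mu
    return {
        "window_1cm": generate_sweeping_window(1.0, f, mu, g),
        "window_2cm": generate_sweeping_window(2.0, f, mu, g),
        "window_4cm": generate_sweeping_window(4.0, f, mu, g),
        "checker_1cm": generate_sweeping_checker(1.0, f, mu, g),
        "checker_2cm": generate_sweeping_checker(2.0, f, mu, g),
        "checker_4cm": generate_sweeping_checker(4.0, f, mu, g),
        "closed_10x10": closed_field_sequence(f, mu, g),
    }


@dataclass
class CommissioningSet:
    """Synthetic commissioning images plus the embedded ground truth."""

    images: dict[str, "object"]
    ground_truth: TemplateSet
    sequences: dict[str, DynamicSequence]
    model: ModelConfig
    spec: FixtureSpec


def _scaled_tng(base: tuple[float, ...], scale: float) -> tuple[float, ...]:
    t = np.asarray(base, float)
    return tuple(np.clip(1.0 - scale * (1.0 - t), 1e-3, 1.0))


def make_commissioning_images(spec: FixtureSpec,
                              model: ModelConfig | None = None,
                              fields=COMMISSIONING_FIELDS) -> CommissioningSet:
    """Generate the commissioning EPID image set.

    Ground-truth A, B and tongue-and-groove scale are solved so the key
    images carry the spec's embedded magnitudes; the remaining fields are
    rendered with the same ground truth. Optional multiplicative Gaussian
    noise is seeded from ``spec.seed`` (bit-identical images per seed).
    """
    model = model or ModelConfig(flat_hsf=False, horn_height=0.0)
    seqs = commissioning_sequences(spec, model)
    spacing = spec.spacing_um or model.commissioning_spacing_um
    intervals = spec.n_intervals or model.commissioning_intervals
    geometry, jaws = model.geometry, seqs["window_1cm"].jaws
    m = model.magnification

    comp_window = simulate_field(seqs["window_1cm"], model, spacing, intervals)
    comp_closed = simulate_field(seqs["closed_10x10"], model, spacing, intervals)
    comp_open = simulate_field(open_counterpart(seqs["closed_10x10"]), model,
                               spacing, intervals)
    comp_checker = simulate_field(seqs["checker_4cm"], model, spacing, intervals)
    open_resp = comp_open.response()

    # ground-truth A and B: the interleaf-peak and closed-field constraints
    # are coupled (A contributes to both), so alternate the two solves.
    A, B = model.templates.weight_A, model.templates.weight_B
    for _ in range(4):
        def g_peak(a, b=B):
            resp = comp_window.response(A=a, B=b)
            return interleaf_peak_metric(resp, geometry, jaws, m) - spec.interleaf_peak
        A = float(brentq(g_peak, 0.0, 0.2, xtol=1e-10))
        m0 = closed_field_ratio(comp_closed.response(A=A, B=0.0), open_resp, magnification=m)
        m1 = closed_field_ratio(comp_closed.response(A=A, B=1.0), open_resp, magnification=m)
        B = float((spec.closed_total - m0) / (m1 - m0))

    def g_dip(s):
        resp = comp_checker.response(A=A, B=B,
                                     tng_profile=_scaled_tng(model.templates.tng_profile, s))
        return tng_dip_metric(resp, geometry, jaws, m) - spec.checker_dip

    scale = float(brentq(g_dip, 0.05, 3.5, xtol=1e-8))
    tng = _scaled_tng(model.templates.tng_profile, scale)
    truth = model.templates.with_(weight_A=A, weight_B=B, tng_profile=tng)

    comps: dict[str, FieldComputation] = {
        "window_1cm": comp_window,
        "checker_4cm": comp_checker,
        "closed_10x10": comp_closed,
    }
    rng = np.random.default_rng(spec.seed)
    images = {}
    for name in fields:
        comp = comps.get(name)
        if comp is None:
            comp = simulate_field(seqs[name], model, spacing, intervals)
        img = comp.response(A=A, B=B, tng_profile=tng)
        if spec.noise_rel > 0:
            img.values = img.values * (
                1.0 + spec.noise_rel * rng.standard_normal(img.shape))
            img.values = np.clip(img.values, 0.0, None)
        images[name] = img
    return CommissioningSet(images, truth, seqs, model, spec)


# --------------------------------------------------------------------------- #
def make_sc_table(src: ExtrafocalSource | None = None,
                  sides_cm=SC_FIELD_SIDES_CM,
                  path: str | Path | None = None) -> np.ndarray:
    """Central-axis collimator-scatter factors for the commissioning square
    fields, Sc(10) = 1 by construction."""
    src = src or ExtrafocalSource()
    table = np.array([[side, hsf_cax(src, side)] for side in sides_cm])
    if path is not None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["side_cm", "Sc"])
            for side, sc in table:
                w.writerow([f"{side:g}", f"{sc:.6f}"])
    return table


def read_sc_table(path: str | Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            rows.append([float(row["side_cm"]), float(row["Sc"])])
    return np.asarray(rows)


# --------------------------------------------------------------------------- #
DEFAULT_KERNEL_DEPTHS_CM = (5.0, 10.0, 15.0, 20.0)


def make_dose_kernels(depths_cm=DEFAULT_KERNEL_DEPTHS_CM,
                      out_dir: str | Path | None = None,
                      delta: bool = False) -> list[DoseKernel]:
    """Analytic radial pencil-beam kernels with depth-dependent broadening.

    Each kernel is a sharp primary core plus a scatter tail that widens and
    gains weight with depth: k(r) = exp(-r/rho1) + w2 * exp(-r/rho2), with
    rho1 = 2.0 + 0.08 d mm, rho2 = 15 + 1.5 d mm, w2 = 0.02 + 0.002 d for
    depth d in cm. ``delta=True`` yields single-pixel kernels for exact
    tests.
    """
    kernels = []
    for d in depths_cm:
        if delta:
            kernels.append(DoseKernel(d, (0.0,), (1.0,)))
            continue
        rho1 = 2.0 + 0.08 * d
        rho2 = 15.0 + 1.5 * d
        w2 = 0.02 + 0.002 * d
        r = np.arange(0.0, 120.0001, 0.4)
        v = np.exp(-r / rho1) + w2 * np.exp(-r / rho2)
        kernels.append(DoseKernel(d, tuple(r), tuple(v)))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for k in kernels:
            k.save(out_dir / f"kernel_d{k.depth_cm:g}cm.csv")
    return kernels
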