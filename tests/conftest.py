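import numpy as np
import pytest

from modcalc import (EPIDKernel, FixtureSpec, ModelConfig,
                     make_commissioning_images, make_dose_kernels)
from modcalc.epid import calibrate_templates
from modcalc.mlc_sequence import LeafGeometry

COMMISSIONING_FIELDS = ("window_1cm", "checker_4cm", "closed_10x10")


@pytest.fixture(scope="session")
def model_flat():
    """Default machine model with a flat flood field (horns off)."""
    return ModelConfig(horn_height=0.0)


@pytest.fixture(scope="session")
def delta_model():
    """Exact-algebra model: flat HSF and flood, single-pixel EPID kernel."""
    return ModelConfig(flat_hsf=True, horn_height=0.0,
                       epid_kernel=EPIDKernel.delta())


@pytest.fixture(scope="session")
def aligned_geometry():
    """Leaf boundaries commensurate with the EPID pixel pitch, so template
    nodes land exactly on grid pixels (for closed-form response checks)."""
    return LeafGeometry(tuple(7.84 * np.arange(-3, 4)))


@pytest.fixture(scope="session")
def commissioning_set():
    return make_commissioning_images(FixtureSpec(), fields=COMMISSIONING_FIELDS)


@pytest.fixture(scope="session")
def calibrated_templates(commissioning_set):
    c = commissioning_set
    return calibrate_templates(
        c.images["window_1cm"], c.images["checker_4cm"],
        c.sequences["window_1cm"], c.sequences["checker_4cm"],
        c.sequences["closed_10x10"], c.model, c.spec.closed_total)


@pytest.fixture(scope="session")
def dose_kernels():
    return make_dose_kernels()


# --------------------------------------------------------------------------- #
def brute_force_fluence(seq, spacing_um, n_steps, dlg_mm=1.9, oversample=4,
                        margin_mm=30.0):
    """Independent time-stepping oracle for the ideal dynamic fluence.

    Interpolates leaf tips directly from the control points at every time
    midpoint, tests point-in-gap on a spatially oversampled grid and block-
    averages down — no shared code with the accumulation under test.
    """
    idx = np.array([p.index for p in seq.points])
    banks_a = np.array([p.bank_a for p in seq.points])
    banks_b = np.array([p.bank_b for p in seq.points])
    n_pairs = banks_a.shape[1]

    dx = spacing_um / 1000.0
    x1, x2, y1, y2 = seq.jaws
    half_x = max(abs(x1), abs(x2)) + margin_mm
    half_y = max(abs(y1), abs(y2)) + margin_mm
    nx = 2 * int(np.ceil(half_x / dx)) + 1
    ny = 2 * int(np.ceil(half_y / dx)) + 1
    x_centers = dx * (np.arange(nx) - nx // 2)
    y_centers = dx * (np.arange(ny) - ny // 2)
    sub = (np.arange(oversample) + 0.5) / oversample - 0.5
    x_fine = (x_centers[:, None] + sub[None, :] * dx).ravel()

    exposure = np.zeros((n_pairs, x_fine.size))
    for j in range(n_steps):
        t = (j + 0.5) / n_steps
        a = np.array([np.interp(t, idx, banks_a[:, p]) for p in range(n_pairs)])
        b = np.array([np.interp(t, idx, banks_b[:, p]) for p in range(n_pairs)])
        gap_open = (b - a) > 0.5
        a = a - 0.5 * dlg_mm * gap_open
        b = b + 0.5 * dlg_mm * gap_open
        exposure += ((x_fine[None, :] >= a[:, None])
                     & (x_fine[None, :] <= b[:, None])) / n_steps
    exposure = exposure.reshape(n_pairs, nx, oversample).mean(axis=2)

    bounds = np.asarray(seq.geometry.boundaries)
    pair_of_row = np.searchsorted(bounds, y_centers, side="right") - 1
    values = np.zeros((ny, nx))
    for row, p in enumerate(pair_of_row):
        if 0 <= p < n_pairs:
            values[row] = exposure[p]
    in_jaws = (np.outer((y_centers >= y1) & (y_centers <= y2),
                        (x_centers >= x1) & (x_centers <= x2)))
    return values * in_jaws * seq.total_mu, x_centers, y_centers
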