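# Methods

`modcalc` computes point modulation factors for dynamic MLC deliveries by
building a 2D fluence model of each field, convolving it with a pencil-beam
dose kernel in water, and taking the ratio against the same field with the
MLC removed. This note records the model, its assumptions, the parameters
that matter, and the choices made where the design was genuinely open.

## Delivery representation and time sampling

A delivery is a list of control points: per-leaf tip positions (mm at the
isocenter plane) with cumulative meterset fractions. Three delivery kinds
are supported. *Dynamic* (sliding-window) deliveries interpolate tip
positions linearly in cumulative meterset; *step-and-shoot* deliveries hold
the governing control point's positions constant within each segment; *arc*
deliveries are sampled uniformly across the control-point table so each
interval carries the meterset increment the table assigns it — variable
(gantry-dependent) dose rate is therefore encoded in the table, not
modeled separately. Deliveries are resolved into `n_intervals` intervals
(600 for commissioning work, 200 for routine clinical sampling), positions
taken at interval midpoints in the interpolation parameter. Interval
weights always sum to 1 to within 1e-12 (the last interval absorbs the
float residual).

Rounded leaf ends are modeled by the dosimetric leaf gap: every open gap is
widened by 1.9 mm (0.95 mm per tip), a value taken from TPS commissioning
of this machine class; no additional leaf-position offset table is needed
under a rounded-leaf model. Pairs whose nominal gap is ≤ 0.5 mm are treated
as fully closed and exempt from the widening, so parked pairs do not acquire
a spurious leakage slit; the threshold and the exemption are configurable.

## Ideal fluence

The ideal fluence Φ_ideal(x, y), in MU, is the meterset-weighted fraction of
the delivery during which the point lies inside the jaw rectangle and
between its leaf pair's (gap-widened) tips, times the total MU. Because leaf
pairs are rigid bars, exposure is accumulated in a compact `(pair, x)`
array and expanded to 2D once. Moving leaf tips are anti-aliased by
fractional pixel coverage along the travel axis; leaf sides and jaw edges
are treated as sharp (jaw transmission and penumbra are not modeled — jaws
enter only through headscatter visibility and the final fluence clipping).
Default grids are 500 µm at isocenter for commissioning and 1486 µm for
clinical use (about half the detector sampling projected to isocenter).

The sweeping-window generator overtravels the jaw edges so every point of
the field receives the same exposure, `(gap + DLG) / (field + gap)` of the
delivery; a window as wide as the field cannot sweep and degenerates to a
static open field. The checkerboard generator sweeps both banks with a
window equal to the stagger, alternate pairs displaced by the stagger for
the entire delivery, so every interior boundary is staggered throughout.

## Headscatter and flood field

Extrafocal radiation is modeled as a source at the bottom of the flattening
filter whose relative intensity is a sum of three concentric 2D Gaussians,

f(x, y) = Σᵢ Aᵢ/(2πσᵢ²) exp(−(x² + y²)/2σᵢ²),

with defaults A = (0.0805, 0.0553, 0.0523), σ = (0.7552, 1.9982, 7.4928) cm.
For a calculation point, each jaw pair is back-projected through its
physical plane onto the source plane; the visible region is a rectangle, so
the source integral separates into exact error-function products per
Gaussian — no sub-grid quadrature is needed, which is both faster and free
of integration error (the 90° jaw-exchange symmetry then holds to machine
precision when the two jaw planes coincide; with distinct X/Y jaw planes the
small asymmetry is physical). Head geometry defaults (filter bottom at
12.5 cm, Y jaws at 28 cm, X jaws at 36.7 cm from the target) describe a
generic 2100-class head and are config entries.

Monitor backscatter is a documented stand-in: output is multiplied by
1/(1 + b·(P_ref − P)) on the jaw-opening perimeter P (cm), normalized at
10×10 cm², with b = 1e-4 per cm by default, fittable or zero. HSF maps are
normalized to 1 on the central axis of the 10×10 cm² reference field,
matching the S_c convention. Source parameters are fit to a table of
central-axis collimator-scatter factors for square fields of 4–38 cm side
by bounded least squares from a generic starting point; the fit reproduces
its generating table to well under 0.3%.

The flood fluence Ψ_flood (relative, 1 on axis, horns included) comes in
three modes: a synthetic radial horn profile 1 + h·u²·exp(−u⁶) with
u = r/r₀ (default h = 0.04, r₀ = 20 cm, peaking near 17 cm off-axis — flat
when h = 0), a file loader, and frequency-space deconvolution of a supplied
dose map by a supplied kernel. Inverse-square falloff is considered part of
the profile; no separate correction is applied.

## MLC effects and the EPID model

The detector's point response is radially symmetric, a sum of up to nine
Gaussians normalized to unit integral. The published machine data do not
include the kernel parameters (they are a planning-system commissioning
output), so the default is a plausible stand-in: a dominant σ = 0.6 mm core
with low-amplitude glare tails out to σ = 30 mm, about 60% of the integral
in the core. All algebra runs at the detector pitch (784 µm); isocenter
maps are magnified once by 1.05 (the source-to-imager over source-to-axis
ratio). Deconvolution divides in frequency space and zeroes spectral
components where the kernel transfer function falls below 1e-3 of its peak
(configurable); maps entering a deconvolution must decay inside their grid,
which the jaw margins guarantee.

Interleaf leakage is a 7-point symmetric template across each interior leaf
boundary (0, 0.31, 0.81, 1, 0.81, 0.31, 0 at 784 µm spacing by default),
tiled uniformly along travel over both leaf widths; its dynamic map weights
the template by the blocked fraction 1 − Φ_ideal/MU. Transmission is the
blocked fraction itself, weighted by B. The full response composition is

S = S_basic·TG|D + conv(HSF·[A·deconv(leak|D) + B·T|D], K_EPID),

the leakage term deconvolved before the headscatter weighting because the
template is itself already a detector response. Inverting K_EPID from the
same composition gives the full fluence; negative values are clamped and
everything outside the jaw rectangle (one-pixel guard) is rejected.

Tongue-and-groove is a 4-point penumbra (0.76, 0.84, 0.92, 0.96 by default)
from the staggered leaf edge toward the open leaf's midwidth, applied on
the open-leaf side only, 4 detector pixels deep, relaxing linearly to 1 at
the next pixel (under the extended leaf the signal is transmission-
dominated, so no further reduction is applied there). The template depth is
kept fixed in mm for the 10 mm leaves. Dynamically, each interval
contributes to a boundary's staggered-exposure tally where exactly one of
the two adjacent leaves covers the point — computed as the exact per-pixel
symmetric difference of the two apertures, which correctly vanishes when
tips coincide. The cumulative tally is normalized by the point's own
exposure to give C ∈ [0, 1], and the map is 1 − C·(1 − T). This combination
rule reproduces both limits: unison deliveries (C = 0) leave the map at 1,
and a fully staggered checkerboard (C ≈ 1) drops the edge to the template
amplitude. (A literal multiplication of the cumulative image by the
template would zero never-staggered regions, so the complement form is
used.) C is meterset-weighted, which extends unchanged to variable-dose-
rate arcs. Note the 1.9 mm gap widening makes adjacent checker windows
overlap briefly, so C tops out near 0.95 rather than 1 — the calibration
absorbs this into the fitted template.

## Calibration

Commissioning needs three synthetic or measured EPID images: a 1 cm
sweeping window (10×10 cm², 400 MU), the same field MLC-covered (as a
scalar constraint), and a 4 cm sweeping checkerboard. The chain is:

1. **Leak profile** — the central profile perpendicular to travel is
   modeled as the tiled 7-node template plus a smooth degree-6 polynomial
   base and solved by one linear least squares. Solving the tiling
   directly avoids two biases of naive peak resampling: interpolation
   smear when pixels miss the node offsets, and contamination of mid-leaf
   base samples by the neighboring boundary's tail. The result is clipped,
   symmetrized and normalized to 1 at the center with zero ends.
2. **Weight A** — chosen (by bracketing root find) so the predicted
   relative interleaf-peak height matches the measured image. Peak height
   is read at the boundary position by interpolation, not as a local
   maximum, so the estimator is unbiased under image noise.
3. **Weight B** — the closed-field constraint (leakage + transmission
   total, 1.4% of the open field by default, averaged over the central
   8×8 cm²) is linear in B and solved exactly.
4. **Tongue-and-groove penumbra** — bounded least squares of the four
   amplitudes against the checkerboard's central profile (both profiles
   mean-normalized, so an overall detector scale factor drops out).

On noise-free synthetic images the chain recovers embedded ground truth to
≲0.1% in A, B and the penumbra and ≲3e-4 per leak node; at 0.5% image
noise the prediction residual stays at the noise level.

## Dose and modulation factors

Pencil-beam kernels are radial tables (CSV + JSON sidecar) at their native
784 µm pitch; externally generated Monte Carlo tables load unchanged. The
shipped analytic stand-ins are two-exponential profiles
exp(−r/ρ₁) + w₂·exp(−r/ρ₂) with ρ₁ = 2.0 + 0.08·d mm, ρ₂ = 15 + 1.5·d mm,
w₂ = 0.02 + 0.002·d at depths 5, 10, 15 and 20 cm — a sharp primary core
plus a scatter tail that broadens and gains weight with depth. Kernel
selection takes the nearest shipped depth.

The recovered fluence is projected back to the isocenter plane at the
kernel pitch, convolved, and the modulation map is the pixelwise dose ratio
of the modulated field and its open counterpart (identical jaws, MU,
headscatter and flood), masked to the jaw rectangle. For an unmodulated
field the ratio is exactly 1. Because both doses share the kernel, point
factors are nearly depth-independent (< 0.03 between the 5 and 20 cm
kernels for the sliding-window field), and calculation is normal-incidence
water-phantom only — patient geometry enters solely through the choice of
depth.

Point sampling emulates the clinical comparison: the map is linearly
resampled to 187 µm, the ROI mean (2.5×2.5 mm² matching a TPS calculation
voxel, or 3.5×10.5 mm emulating the ion chamber with its long axis along
leaf travel — orientation is a flag, since either convention is defensible)
is evaluated at every displacement on that grid within the search radius
(±1.25 mm or ±1 mm, a square search matching the half-pixel uncertainty it
models), and the displacement minimizing |%diff| against the reference
factor is reported; ties prefer the smallest displacement. Collimator
rotation is applied to the query point, never to the map. Each evaluation
appends a row (timestamp, plan, field, factors, %diff, 5%/2% pass flags) to
an append-only CSV record file; 5% is the action threshold.

## Synthetic commissioning data

The fixture generator produces every input the pipeline consumes. The
"measured" EPID images are rendered by the same forward model but with
ground-truth weights *solved* so the images carry the stated commissioning
magnitudes — interleaf peaks 5.7% above base on the 1 cm window, a 23%
maximum tongue-and-groove dip on the 4 cm checker, a 1.4% closed-field
total — with optional seeded multiplicative Gaussian noise. Calibration
tests are therefore genuine inverse problems with known answers, not
tautologies. What the fixtures do not emulate: detector arm backscatter,
beam-hardening of the transmitted component (a transmission-specific
kernel is deliberately out of scope), pixel defects, image lag, and the
absolute dose calibration of the detector (all comparisons are relative).
Passing tests therefore demonstrate the internal consistency and
invertibility of the model chain at commissioning magnitudes, not agreement
with any particular machine's measured images.

## Numerical choices and limitations

* Sampling: 500 µm / 600 intervals (commissioning), 1486 µm / 200 intervals
  (clinical); doubling the interval count changes commissioning fluences by
  < 0.2% of the total MU. Grids carry a 30 mm margin beyond the jaws so
  kernel tails are not truncated where it matters.
* Deconvolution threshold 1e-3 of the peak transfer amplitude; forward—
  backward consistency holds to ~1e-3 of the response maximum.
* Degenerate inputs: all-zero kernels, degenerate jaws, non-monotonic
  meterset indices and malformed control-point files are rejected with
  named errors; a reference point outside the jaws is an error, never a
  silent zero.
* The kernel is spatially invariant and tilt-free; off-axis spectral
  softening is not modeled. This matters little for modulation factors
  because numerator and denominator share the kernel.
* Jaw transmission, couch/jaw tracking, leaf-velocity limits, electron
  contamination and 3D patient dose are out of scope.
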