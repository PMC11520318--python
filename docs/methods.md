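# Methods

`deformacyte` models a combined electro-optical deformability cytometer: a
microfluidic channel (40 × 30 µm cross-section) in which cells suspended in a
viscoelastic carrier are deformed by shear, sensed electrically by two
differential electrode configurations, and photographed in a downstream
optical window by an LED flash fired from the impedance signal. The package
contains both the measurement chain (event detection → velocity → trigger →
segmentation → ellipse fit → correlation → gating → dose–response) and a
synthetic-data generator that produces traces and frames with the statistical
structure the chain assumes, carrying ground truth for recovery testing.

## Electrical model

A particle crossing one differential electrode configuration produces an
anti-symmetric double Gaussian: a positive lobe centred on the first
electrode pair and a negative lobe on the second, `D1 = 40 µm` apart. The
generator writes, per particle and configuration,

    s(t) = A · [ g(t − t0; σ) − g(t − t0 − Δt1; σ) ],      Δt1 = D1 / v,

with `σ = (electrode half-width 10 µm)/v`, so the extrema track the electrode
centres at every flow rate. Amplitudes follow the Coulter volume law
`A1 = (d/10 µm)³` (unity for a 10 µm bead) and the second, coplanar
configuration — sensitive to the flow-axis dimension — carries
`A2 = A1 / deform_true`. The identity link `A1/A2 = deform_true` is a
modelling convenience, not device physics: it makes the ground truth
trivially invertible and anchors rigid spheres at exactly 1. The device's
true shape-to-signal mapping is unpublished; because electrical
deformability is bead-normalised downstream, any strictly increasing link
with value 1 at a sphere would behave identically at first order.

Detection mirrors the instrument's peak–valley algorithm: extrema exceeding
a prominence *and* height threshold (default 5× the MAD-estimated noise SD —
both conditions are required so that a million-sample noise-only record
yields no events) are paired greedily in time under a magnitude-ratio guard
(0.5–2.0) and a maximum transit time corresponding to 0.01 m/s. Extremum
times and values are refined with a least-squares parabola over ±3 samples;
at 87 ksps an event spans only ~24 samples, and the 7-sample fit brings the
median velocity error at SNR 20 to ~0.7% where 3-point interpolation leaves
~2%. The configuration-2 amplitude is taken from a matched window downstream
at the delay predicted from the measured velocity. Amplitude is half the
peak-to-valley excursion, robust to baseline offset in the differential
signal.

Electrical diameter follows the cube-root law referenced to beads,
`d = 10 µm · (ΔI1 / median_bead ΔI1)^(1/3)`; electrical deformability is the
bead-normalised ratio `ED = (ΔI1/ΔI2) / median_bead(ΔI1/ΔI2)`. Medians, not
means, are used for calibration (outlier robustness); block-wise drift
correction is not implemented (single-session assumption).

## Trigger and imaging

Velocity `v = D1/Δt1` predicts the arrival at the optical window centre,
`t_trigger = t_midpoint + D2/v`, where `D2` (sensing-to-imaging distance,
default 350 µm) is a configurable parameter — the physical value is
unpublished, and all analyses read it from configuration. The simulated
flash adds a Gaussian microcontroller latency (SD 30 µs by default, a free
knob chosen so that ≥95% of flashes land inside the 34 µm ROI, matching the
qualitative spread the instrument shows). Flashes landing in the same 100 fps
camera frame accumulate into one image — which is exactly how optical
coincidences arise — and coincidence is quantified per frame and compared
with the Poisson expectation P(≥2 | ≥1).

Frames show dark cell outlines on a light background at 0.63 µm/px. The cell
boundary in polar form is an area-preserving ellipse stretched along the flow
axis by the optical elongation, multiplied by a tear-drop term
`1 + tail_skew · ((1 + cos θ)/2)³` that grows a smooth downstream tail. (A
plain `1 + d·cos θ` limaçon was rejected: it *reduces* the flow-axis second
moment and therefore cannot reproduce the wall artefact it is meant to
model.) Motion blur is a 1-D box convolution along the flow of length
`v × 2 µs`; sub-pixel lengths degenerate to the identity kernel.

## Wall artefact

Cells near the channel walls appear tear-drop-shaped and optically more
elongated, but the electrical shape signal is insensitive to this asymmetry.
The generator therefore keeps `deform_true` (what the electrodes sense)
independent of lateral position and applies the wall effects only to the
rendered image: optical elongation is multiplied by
`1 + κ·(2|y|/W)²` (κ = `wall_deform_gain`, default 0.25) and the tail grows
as `wall_skew_gain·(2|y|/W)²` (default 0.5). Recovery tests verify the
consequence: regressed on y², measured OD shows a strong positive slope while
ED is flat, and the ±6.3 µm (±10 px) midline gate lowers the OD mean while
moving the ED mean by <1%.

## Optics

Measurement is: grayscale conversion and 1st–99th percentile contrast
rescaling; Canny edge detection with hysteresis thresholds set from the
image-noise estimate; morphological closing and hole filling; a cut back to
the 50%-coverage isophote (the edge line straddles the outline, and without
the cut the filled mask is ~1 px inflated); connected components filtered by
minimum area, with components touching the left/right frame edge excluded
and multi-component frames routed to coincidence handling rather than
silently measured. The ellipse fit uses normalised second-order central
moments with the 1/12 per-pixel variance correction; axis lengths are
`4·√eigenvalue` — stated explicitly because conventions differ by factors of
two; this one returns a disk's diameter for a disk. OD is the major/minor
ratio (axes sorted, so OD ≥ 1). Optical diameter is the geometric mean of
the axes (area-equivalent circle) rescaled so the bead median reads 10 µm;
bead referencing makes the result insensitive to the convention chosen.
Pixel scale is calibrated as 10 µm over the median bead mean-axis in pixels.

## Flow profile

Axial velocity uses the Newtonian rectangular-duct series solution scaled so
the cross-sectional mean equals Q/A, with no-slip walls and the maximum at
the channel centre. The carrier is actually viscoelastic (0.5% w/v
methylcellulose); the Newtonian profile is a deliberate simplification that
nonetheless reproduces the printed magnitude — the computed centre velocity
at 5 µl/min is 0.1443 m/s against the instrument's 0.144 m/s. The series is
validated against an independent finite-difference Poisson solve to 1%.

## Dose–response

Treatment with glutaraldehyde stiffens cells toward the rigid-bead floor.
The group deformability follows a three-parameter Hill curve with unit
slope, `y(c) = y_max + (y_min − y_max)·c/(EC50 + c)`: `y_max` the zero-dose
plateau, `y_min` the saturating floor (≈1), `EC50` the half-maximal
concentration in % v/v. Zero concentration is fitted as the exact zero-dose
anchor, not log-transformed. Fitting is multi-start nonlinear least squares
over a log grid of EC50 initials spanning the positive concentrations ±1
decade, with concentrations internally rescaled by a power-of-two anchor so
that scaling all concentrations by a constant scales the fitted EC50 by
exactly that constant to solver precision. Constant responses, solver
failure, or an EC50 driven >10³× outside the sampled range are reported as
`converged=False`, never silently. Bootstrap CIs resample replicates within
each concentration level.

Identifiability matters here: with five dose levels, three replicates,
response noise SD 0.02 and a response range of only 0.16 (untreated plateau
1.16 to floor 1.0), the Cramér–Rao bound on log10(EC50) is ≈0.16, so even an
efficient estimator lands within ±25% of the truth only about half the
time. The fitter attains this bound in simulation; tight EC50 recovery under
those conditions requires either lower noise (SD ≲ 0.005), more replicates,
or a larger dynamic range (≳0.4, as at higher flow rates). The recovery-bias
invariant (bias → 0 as noise → 0) holds throughout.

No multiple-testing correction is applied to group comparisons (Welch
t-tests), matching how such panels are conventionally starred; a Holm
correction can be applied by the caller.

## Study conditions (generator defaults)

| parameter | default | rationale |
|---|---|---|
| channel | 40 × 30 µm | device cross-section |
| D1 / D2 | 40 / 350 µm | electrode spacing printed; D2 unpublished, configurable |
| sample rate | 87 ksps | instrument ADC |
| frame rate / pulse | 100 fps / 2 µs | camera and LED settings |
| pixel scale | 0.63 µm/px | ±10 px ≡ ±6.3 µm gate |
| cell diameter | N(12, 1) µm | typical HL60 size |
| beads | 10 ± 0.1 µm | calibration particles |
| deformability | N(1.16, 0.06) | untreated population level and spread |
| focusing SD (y) | 7 µm | partial viscoelastic focusing; some cells near walls |
| event rate | 10 s⁻¹ | dilute suspension; low trace coincidence |
| trace SNR | 20 | bead amplitude / noise SD |
| image noise | 5% of contrast | visually comparable to brightfield frames |
| gate half-width | 6.3 µm | ±10 px about the midline |

## Problem sizes

Recovery tests run at a few hundred particles per cohort (e.g. 500 cells +
100 beads for the end-to-end demonstration, 500 events for velocity
recovery, 200 random blobs for the moment-fit property, 200 Monte-Carlo
dose–response fits), sizes at which every check completes in seconds to a
couple of minutes on a single core while keeping the Monte-Carlo standard
errors well inside the asserted tolerances.

## What the generator does not emulate

Electrode field inhomogeneity (no Schwarz–Christoffel or FEM field maps) and
z-dependent impedance sensitivity; viscoelastic constitutive behaviour of the
methylcellulose (Newtonian profile only); lock-in demodulation and
multi-frequency dielectric spectra; phase-contrast optics, deconvolution, or
camera readout artefacts; real-time firmware constraints. Passing recovery
tests therefore demonstrate that the analysis chain is correct and unbiased
*under the stated noise and shape models*, not that it is robust to every
artefact of real acquisitions; bead normalisation on both modalities is the
main defence against the unmodelled systematics on real data.
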