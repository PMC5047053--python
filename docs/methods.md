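# Methods

## Physical model

The model is a 2D plane-strain cross-section of a fractured rat tibia
under its soft-tissue envelope.  Nine horizontal layers (skin 0.55, fat
0.58, muscle 1.73, cortical bone 0.04, marrow 0.10, cortical bone 0.04,
muscle 1.73, fat 0.58, skin 0.55 mm; 5.90 mm total) are rasterized onto
a uniform grid.  The two cortical plates are interrupted over a central
lateral span (the fracture gap, 4 mm by default); the interrupted band
is filled with bone-marrow material, reflecting a marrow channel exposed
by the break (configurable — a hematoma would be water-like, and no
published value constrains it).  A 10-mm line source on the upper skin
surface emits a 1-MHz, 3-µs Hann-windowed toneburst; fifteen receivers
sit on the vertical axis through the gap center: R1 on the surface, even
labels at layer mid-depths, odd labels one grid cell above each
interface, with R11 assigned to the lower muscle–fat interface (the only
assignment consistent with 15 receivers and all interfaces covered) and
R15 one cell above the bottom surface.

Each tissue is isotropic with Young's modulus E, Poisson's ratio σ and
density ρ; the solver consumes the plane-strain stiffnesses
c11 = λ+2µ, c12 = λ, c33 = µ.  The published fat row is internally
inconsistent: ρ = 1940 kg/m³ yields c_l ≈ 1001 m/s, while the printed
velocity (1462.84) and impedance (13.75×10⁵) both imply ρ ≈ 940.  The
verbatim table is kept, flagged; a "reconciled" variant (the simulation
default) sets ρ = 940 **and** rescales E (3.50→3.62×10⁻⁵ GPa) so that
both printed c_l and Z are reproduced exactly — the impedance column
drives interface reflections, so it is the one worth honoring.
Intrinsic absorption, viscoelasticity and 3D effects are out of scope.

## Solver

Virieux-type staggered-grid velocity–stress FDTD, second order in time
and space.  Density is arithmetically averaged onto velocity points and
the shear modulus harmonically averaged onto the corner points, keeping
the discrete operator self-adjoint across interfaces.  The time step is
dt = CFL·dx/(c_max·√2) with CFL = 0.95 and c_max the cortical-bone
velocity; the near-incompressible soft tissues (σ → 0.5) keep their
tiny printed shear moduli rather than being zeroed.

Boundaries are convolutional PML (40 cells, cubic grading,
σ_max = −4·c_max·ln(10⁻⁶)/(2L), α linear from π·f₀), applied on all four
sides with the material map edge-replicated into the collar; internal
interfaces are welded.  A `rigid` mode replaces the PML with fixed-edge
walls for energy-accounting runs; the discrete energy (product-form
kinetic term ρ·v^{n−1/2}·v^{n+1/2} plus strain term ½σ:C⁻¹σ) is then
conserved to machine precision after source cutoff.

The source injects normal stress on the aperture cells, scaled by the
local plane-strain volumetric modulus (c11+c12)/2 — a volume-injection
source.  This makes the pressure-source/pressure-receiver pairing
exactly reciprocal in heterogeneous media (raw stress injection leaves
the records differing by the local modulus ratio).  Receivers record
p = −(σxx+σyy)/2 every step.  A guard aborts with an instability error
if the field exceeds 10³ × the injected peak or becomes non-finite.

## Receiver metrics

* **TOF_FAS** — first sample whose |amplitude| exceeds a threshold
  (default 5 % of the record's own peak; the original threshold is
  unpublished, so reported magnitudes are qualitative), refined by a
  least-squares parabola through the five surrounding |amplitude|
  points; the refined onset is clamped to within one sample of the
  crossing.  On a ramped toneburst this detector carries a systematic
  onset lag (~0.2 µs for the 3-cycle burst) that cancels in
  receiver-to-receiver differences; grid-convergence is therefore
  measured on differential TOF between two depths.  R1 sits inside the
  source aperture, so its TOF is reported but flagged non-comparable.
* **SPL** — 20·log₁₀(peak_k/peak_R1) dB; 0 dB at R1 by construction.
* **RMS** — √(Σa²/N) over the N samples in [FAS, FAS+10.9 µs]; N is the
  window's own sample count (tying it to anything else would couple
  receivers).  Windows extending past the record truncate with a
  warning.
* **Travel-time oracle** — Σ thicknessᵢ/cᵢ along the vertical ray, used
  as an independent bound: simulated TOF agrees within one source
  period at every receiver.
* **Dose arithmetic** — duty = PRF×pulse width (100 Hz × 2 ms = 20 %);
  on-pulse intensity = SATA/duty = 40/0.2 = 200 mW/cm².

## Statistics

Pooled two-sample t from (mean, SD, n) summaries with df = n₁+n₂−2 and
a 95 % CI on the mean difference.  Mann–Whitney U with mid-rank ties,
reported as min(U₁, U₂); p by exact enumeration of all C(n, n₁) group
assignments when min(n) ≤ 8 (capped at 2×10⁵ combinations), otherwise a
tie-corrected normal approximation with continuity correction.  Cohen's
κ = (p_o−p_e)/(1−p_e) with marginal-product expectation, undefined when
both raters are constant and identical.  Normality screening is a
one-sample KS statistic against N(x̄, s) with the p value simulated
(Lilliefors), since plugging in sample moments invalidates the
classical null distribution.  Sample sizing iterates the noncentral-t
power function to the smallest per-group n reaching the target
(d = 1.2, α = 0.05, power 0.8 → n = 12).  The worked example's 8/7
group split is the only split of the 15 retained samples that
reproduces the published t(13) = 0.440.  No multiplicity correction is
applied, matching the study design.

## Synthetic data

Waveform fixtures are Hann-windowed sinusoids with prescribed onset,
cycle count, amplitude and white Gaussian noise — they emulate the
delayed-toneburst structure of receiver records, not multipath or
dispersion, so detector tests validate onset logic rather than
field realism.  Study fixtures draw biochemistry from per-group
Gaussians (defaults: the published means/SDs with n = 8/7) and ordinal
scores from per-category multinomials; rater 2 copies rater 1 with a
set agreement probability, else redraws.  Scores are categorical, not
latent-continuous — the simplest model honoring the discrete 0–3/0–3/0–2
scale.  All generators are pure functions of (spec, seed).

## Problem sizes and numerical choices

The default ("reduced") pipeline profile uses dx = 0.02 mm, 8-mm width
and 16 µs of recording, completing in about a minute while keeping ≥3
grid cells between the closely spaced gap receivers and complete
10.9-µs RMS windows for all receivers; the "paper" profile (0.01 mm,
16 mm, 20 µs) matches the published geometry.  Layer boundaries snap to
the nearest grid row (round-half-up, every layer ≥1 cell) with a
warning when they move.  Solver property measurements use small
single-purpose grids: plane-wave runs span the full padded width so
lateral boundaries cannot diffract; reflection is measured between
time-gated incident and reflected peaks 2.5 mm above a muscle/cortical
interface; energy runs use CFL 0.6 to keep the staggered-time energy
estimate clean.  Monte-Carlo calibrations use 1000 null and 2000
powered replicates (SE ≈ 0.007 and 0.009 on the reported rates).

## Known limitations

The original study's detection threshold, envelope handling and PML
settings are unpublished, so absolute SPL/RMS magnitudes and exact
TOF values are not bit-reproducible; the package asserts the described
qualitative patterns instead.  With the marrow gap fill, the TOF slope
*per unit depth* inside the gap slightly exceeds the muscle slope
(marrow is the slower medium) — the "smallest change" across the gap is
a statement about the closely spaced receivers R7–R9, and that is what
the model reproduces.  The published U = 118 cannot be reconstructed
from unpublished raw scores and is not asserted.  2D plane strain
overestimates geometric spreading relative to 3D, and rigid-edge energy
runs are a verification device, not a physical boundary condition.
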