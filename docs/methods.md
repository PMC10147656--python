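# Methods

This note records the models, conventions and numerical choices behind
`microrheo`, in the order data flows through the package.

## Physical model and assumptions

A rigid sphere of radius *a* is embedded in (or optically trapped within)
a medium at absolute temperature *T*. Its thermal motion is overdamped
everywhere: for micron beads in aqueous media at frame rates ≤ 5 kHz the
momentum relaxation time (~µs) is far below the sampling interval, so
inertia is neglected and every simulator integrates a first-order
(Ornstein–Uhlenbeck type) Langevin equation. Hydrodynamic memory (Basset
forces), bead–bead interactions and sedimentation are not modelled.

* **Free diffusion** — increments are i.i.d. Gaussian with variance
  2·D·dt per axis, D = k_BT/(6πη_s a).
* **Optical trap** — per axis with stiffness κ the exact discretisation
  x ← x·e^(−dt/τ_c) + N(0, (k_BT/κ)(1−e^(−2dt/τ_c))), τ_c = γ/κ, is used
  rather than Euler–Maruyama, so the stationary variance k_BT/κ and the
  autocorrelation e^(−τ/τ_c) are exact at any step size and oracle tests
  carry no step-size bias. The default stiffnesses (3.2×10⁻⁷ N/m
  laterally, 6.7×10⁻⁸ N/m axially, ≈ 5× weaker in z) describe a weak
  single-beam trap used only to hold the probe in the field of view.
* **Gel** — the default constitutive stand-in is a single Kelvin–Voigt
  element: spring 6πa·G₀ and dashpot 6πa·η per axis, i.e. an OU process
  whose per-axis stationary variance is k_BT/(6πa·G₀) and whose long-lag
  MSD plateaus at twice that. The measured response of real gels (rubbery
  plateau at low frequency, glassy rise at high frequency) motivates the
  optional Prony extension: Maxwell arms (modulus, relaxation time) in
  parallel with the plateau spring, integrated by exact-conditional
  operator splitting (each half-step is the exact conditional propagator,
  so the scheme is unconditionally stable; splitting error vanishes once
  dt is below the shortest mode time). Real gels are not Kelvin–Voigt
  solids; a green gel test establishes estimator correctness for a
  plateau-forming medium, not constitutive fidelity to any particular gel
  chemistry.
* **Near-wall** — the wall normal is the z axis; the x/y drag is
  multiplied by the Faxén wall correction and the z drag by a truncated
  Brenner series (below). Stationary variances are unchanged; only the
  relaxation slows.

## Rendering and tracking

The renderer draws a dark disk of the bead's physical diameter on a
bright background (transmission contrast), with an erfc edge profile
whose width grows linearly with defocus, plus optional Poisson shot noise
and Gaussian read noise. It is a phenomenological defocus model, not a
physical point-spread function; tracking results validated on it
establish the estimators' geometry and noise behaviour, not performance
under real optical aberrations.

2D localization thresholds each frame with two-level multi-Otsu
thresholding (three intensity classes; the bead is the darkest class, with
an inversion flag for fluorescent beads), keeps the largest connected
component, dilates it by two pixels to capture the blurred edge, and takes
the darkness-weighted centre of mass. Pixel convention: 0-based indices
with pixel centres at integers; centroids are continuous pixel coordinates
scaled by the pixel size. Frames that fail (empty mask, multiple
comparable components) are dropped and flagged — never interpolated, since
interpolation biases the MSD; statistics downstream are NaN-pair-aware.

The focus score is normalised squared-gradient energy (Tenengrad): mean
squared Sobel gradient divided by the squared mean intensity. It is zero
for structureless images, insensitive to translation and gain, and
strictly decreasing with Gaussian blur — the only properties the z
machinery relies on. Nine-plane frames (3×3 tiles, row-major plane labels
−4..+4, label = 3·(row−1)+(col−1)−4, tile p imaging defocus z − p·Δz with
Δz = 0.79 µm by default) yield a 9-vector of sharpness values; z is the
least-squares match of the L2-normalised vector against cubic-spline
interpolated calibration profiles recorded at known stage offsets, with
parabolic sub-grid refinement. The calibration's valid range is the sweep
minus half a plane spacing at each end; matches pinning to the range edge
are dropped.

## Trajectory cleaning

Drift is removed by subtracting a fitted linear trend by default
(polynomial or moving-mean alternatives are selectable); linear is the
simplest model that removes stage drift without distorting the plateau
variance. Narrow-band instrument noise is removed in the Fourier domain:
a bin is a noise line when its single-sided amplitude 2|X_k|/N is at
least 2×10⁻¹⁰ m *and* exceeds 5× the median magnitude of its 50-bin
neighbourhood, and the contiguous flagged group spans ≤ 3 bins ("single
frequency width" — wider structures are broadband signal and are left
alone). Flagged bins are scaled down to the local median background
rather than zeroed, because zeroing deletes legitimate Brownian power;
phases are kept. All parameters are exposed; the filter is idempotent and
reports every removal. Note the threshold is meaningful for quiet,
nm-scale gel records: in a weak trap in water the Brownian background
itself reaches ~3×10⁻¹⁰ m per bin at tens of Hz, and a comparable line is
then (correctly) not classified as sharp.

## MSD, NPAF and the smoothing fit

The MSD is the time average over all overlapping pairs at each lag, on a
log-spaced grid of 16 points/decade from one frame to 10% of the record
(broadband coverage at O(N·n_lags) cost). Directional MSDs project the 3D
trajectory on u(θ, φ) first; projections snap exactly onto coordinate
axes so the directional and scalar pipelines agree bit-for-bit there.

The stretched bi-exponential smoother is fitted by bounded nonlinear
least squares on the log-spaced lags, weighted by pair counts, with a
data-driven start (plateau from the last lags, rise time from the
half-rise lag) plus randomised restarts. Amplitude signs are deliberately
unconstrained — as written the form decays unless an amplitude is
negative, and a rising, saturating MSD is exactly the A₁ < 0 case. The
long time constant τ₂ of a plateau term is not identifiable from a finite
record (any value ≫ the record length fits equally well); tests therefore
check the identifiable parameters and the smoothed curve, not τ₂ itself.

The NPAF is ⟨x(t)x(t+τ)⟩/⟨x²⟩ with the per-lag ("unbiased") pair-count
normalisation, exactly 1 at τ = 0. The direct time-domain estimator is
the default for transparency; a Wiener–Khinchin FFT path produces all
lags cheaply and is tested equivalent.

## Compliance, moduli and conventions

J(t) is converted to G*(ω) through the Fourier transform of its
piecewise-linear interpolant with declared extrapolations: below the
first lag, a straight line from (0, J(0)) with J(0) taken as the
(clipped, non-negative) linear extrapolation of the first two samples;
beyond the last lag, a linear tail of gradient `terminal_slope` — 0 for
gels (elastic plateau), 1/η estimated from the last decade of J(t) for
fluids. The closed-form transform of that interpolant gives
G* = iω/A(ω) with

    A(ω) = iω·J₀ + (1−e^(−iωt₁))(J₁−J₀)/t₁ + J̇_∞·e^(−iωt_N)
           + Σ_k ΔJ_k/Δt_k · (e^(−iωt_{k−1}) − e^(−iωt_k)).

The default frequency grid is log-spaced, 10 points/decade, over
ω ∈ [2π/t_max, π/t_min]. The piecewise-linear transform develops phase
artifacts once ω approaches the reciprocal local sample spacing, which
corrupts whichever of G′/G″ is the smaller near the band top; inputs are
therefore PCHIP-resampled onto a 1000 points/decade log grid first
(disable with `oversample_per_decade=None`). On closed-form Kelvin–Voigt
and Newtonian oracles the recovered moduli agree with G₀ + iωη and iωη to
within 5% over the central 80% of the band (the residual ~1.5% comes from
the t→0 segment treatment).

**Dimension conventions.** The prefactor k_BT/(πa) in the MSD–compliance
relation corresponds to a 3D MSD, while gel tracking is typically 2D.
Both conventions are implemented and recorded in every output:
`"paper"` applies the literal prefactor to whatever MSD/variance it is
given (faithful to common practice and the default for reproduction);
`"dimension_corrected"` rescales by the true dimensionality d —
J = 3πa/(d·k_BT)·MSD_d (identical to the literal form at d = 3) and
G₀ = d·k_BT/(6πa·⟨r²⟩_d) for a position variance summed over d axes,
which inverts the per-axis confinement ⟨x²⟩ = k_BT/(6πaG₀) exactly. The
literal plateau formula is exact when fed the long-lag 3D MSD plateau,
which equals twice the 3-axis position variance; fed a bare d-axis
variance it overestimates G₀ by 6/d, which is why the corrected
convention is used in all round-trip tests. Whether published plateau
values used per-axis, 2D-summed or 3D-equivalent variances is generally
not stated in the literature; both routes are provided so either reading
can be reproduced.

## Viscometry

The NPAF e⁻¹ intercept on τ* = κτ/(6πaη_s) reads η/η_s directly (for an
OU process the crossing sits at τ = τ_c exactly). The first *downward*
crossing is used, refined by log-linear interpolation between the
bracketing samples, because estimator noise can cause re-crossings at
long lag. κ is taken from equipartition on the same record, so the
readout is a pure function of the trajectory plus probe metadata.

Directional viscosity uses the early-time window where a trapped bead
diffuses as if free: lags up to `window_fraction` (default 0.1) of the
trap relaxation time along the probed direction, itself estimated from
the directional NPAF's e⁻¹ decay. At the default window the trap-induced
downward bias of the fitted slope is ≤ ~5%; fewer than 5 usable lags is
an error (raise the frame rate rather than widen the window — widening
trades bias for noise).

Near-wall drag factors, η_app/η as functions of s = a/h:

* parallel (Faxén):  [1 − (9/16)s + (1/8)s³ − (45/256)s⁴ − (1/16)s⁵]⁻¹
* perpendicular (truncated Brenner series, Padé form):
  [1 − (9/8)s + (1/2)s³ − (57/100)s⁴ + (1/5)s⁵ + (7/200)s¹¹ − (1/25)s¹²]⁻¹

Both tend to 1 as h → ∞, increase monotonically toward the wall, and the
perpendicular factor dominates at every h. The truncation order is fixed
as written; at s = 0.5 the parallel factor is ≈ 1.386.

## Geometry mapping

Probe-to-cluster distances are exact point-to-triangle minima (face
interiors, edges and vertices all considered; Ericson's closest-point
construction, vectorised over faces), unsigned, with an interior flag
from ray-casting parity — spatial analyses bin by distance "from the
edge" and do not use a sign. Mesh files (ASCII OBJ/STL/PLY) must declare
their units; nothing is guessed. Distance-stratified summaries report
per-bin counts, medians and the spread in decades (log₁₀ max/min; zero
for a single record, absent for an empty bin).

## What the synthetic generators do and do not establish

The simulators reproduce the statistical structure the estimators rely
on — Gaussian increments, exponential position correlations, plateau
confinement, anisotropic near-wall relaxation, drift and narrow spectral
lines — under explicit seeds with bit-reproducible output. They do not
reproduce optical aberrations, depth-dependent point-spread functions,
non-Gaussian gel heterogeneity, hydrodynamic memory, or live-sample
dynamics; green tests therefore certify the analysis chain, not any
biological claim. Generator defaults (a = 3 µm, T = 298.15 K,
η_s = 0.89 mPa·s, 3×10⁵ frames at 300 Hz for trapped beads, 5 kHz for
gel records, κ_z ≈ κ_x/5) mirror a realistic trap-plus-camera
configuration and are fixed; tests and the acceptance script state
explicitly where they scale record lengths down (gel records 10×) to fit
their time budget.

## Known limitations

* The i-Rheo-style transform loses the minor modulus component within
  roughly half a decade of the Nyquist edge; report mid-band values.
* Multi-Otsu localization assumes a single bead per field of view.
* The z sharpness match assumes the calibration and measurement share
  illumination statistics; intensity is normalised away, but a change in
  noise character between calibration and measurement is not modelled.
* The spectral filter's absolute threshold is tuned to nm-scale confined
  records; for weakly trapped beads in water the Brownian background can
  exceed it, and lines of comparable amplitude are intentionally left.
* Interior probes get unsigned distances; analyses that need signed
  penetration depth must combine the distance with the interior flag.
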