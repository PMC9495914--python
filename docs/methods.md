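# Methods

## Exchange model

The simulator integrates the Bloch–McConnell equations for a water pool and
up to a few dilute solute pools, each described by a chemical shift relative
to water (thiol −2.7 ppm, amide +3.6 ppm), T1, T2, a proton fraction
relative to water, and a solute→water exchange rate k_ex (s⁻¹). Exchange is
star-topology (each solute exchanges with water only) and respects detailed
balance: the water→solute rate is fraction × k_ex. The state vector stacks
(Mx, My, Mz) per pool; the system `dM/dt = A M + b` is linear for constant
saturation amplitude, which the solvers exploit:

* **CW steady state** — the fixed point `M = −A⁻¹ b`, used as the analytic
  oracle.
* **Pulse train** — the acquisition applies one 30 ms Gaussian saturation
  pulse per radial spoke (302 per image) with the TR remainder (10.41 ms) of
  free relaxation. The envelope is discretized into equal sub-steps; each
  sub-step and gap is advanced by the exact affine propagator
  (`expm(A·dt)`), so the only error is the envelope staircase. One
  pulse+gap map is composed once and applied n times via a matrix power and
  geometric sum.

ppm→Hz conversion uses γ/2π = 42.577 MHz/T throughout (298.04 Hz/ppm at
7 T). B1 = 1.2 µT is interpreted as the Gaussian peak amplitude; an
equivalent-average-power CW mode (`SaturationPulse.as_equivalent_cw`) is
provided because vendor nominal amplitudes are ambiguous between peak and
RMS conventions. The Gaussian is truncated at ±2.5 σ with σ = duration/5
(configurable). The 10° readout excitation is available as an optional
longitudinal scaling after each pulse and is off by default.

### Numerical choices

* Integration sub-step default **0.1 ms**: halving it changes Z by ≲7×10⁻⁷,
  satisfying a ≤10⁻⁶ convergence requirement; at 0.5 ms the staircase error
  is ~1.5×10⁻⁵, which is why the finer default was chosen.
* With CW-shaped pulses, zero gaps and a train long against T1, the
  integrator matches the analytic steady state to ~10⁻¹⁵ (tested at ≤10⁻⁶).
* One physically notable subtlety: "adding a solute pool can only remove
  water signal" holds everywhere except inside the direct-saturation core,
  where the fully saturated water can receive ~10⁻⁵ of magnetization back
  from the less-saturated solute. The monotonicity property is therefore
  asserted off-resonance (|ω| ≥ 1 ppm) only.

## Acquisition schedules

Protocol timing: TR 40.41 ms × 302 spokes = 12.2 s per image; saturation
time per offset 30 ms × 302 = 9.06 s; every measurement offset acquired
twice in a row with the first instance discarded (saturation steady-state
violation after a frequency switch), giving a 24.4 s retained-point
resolution. FL1 = 12 dummy S0 images then cycles of
`[S0, −2.7, −2.7, S0, +3.6, +3.6]` (98 cycles ≈ 122 min); FL2/FL3 = 9
dummies then sweeps of `[S0, ω₁, ω₁, …, ω₅, ω₅]` over −4.3…−1.1 or
4.2…3.0 ppm (35 sweeps ≈ 80 min). The exact interleaving of S0 images
within an FL1 cycle is not fully constrained by the protocol description;
one S0 before each tracked-offset pair is the default and the cycle
structure is configurable. Timestamps are assigned at image midpoints
(symmetric attribution of the 12.2 s acquisition window). Total scan
durations are emergent from the cycle count, not hard-coded.

## Synthetic studies and what they emulate

`generate_series` renders, per schedule entry and pixel:
`S = baseline × Z(ω + drift(t); pools with the thiol fraction raised by the
uptake response) × signal-drift(t)`, minus a motion pseudo-CEST term on
measurement images (not S0), then magnitude noise. Components:

* **Uptake** — gamma-variate spike `A (t/tp)^α e^{α(1−t/tp)}` (shape α = 2,
  the standard bolus-response form; a width override maps FWHM→α) peaking
  `tp` = 7 min after the 23-min injection, default amplitude 0.64 % MTR
  (the cohort-level in vivo estimate; the representative-animal value is
  ~1.3 %), plus a linear accumulation (default 5×10⁻⁵ MTR/min, chosen so
  the late rise reaches a few tenths of a percent by two hours) and an
  optional late decline. The model is parameterized in MTR units because
  that is the observable; it enters the physics as an added thiol pool
  fraction via a one-time Brent root-solve of the Bloch–McConnell model at
  the spike peak (exact at the peak, linearized elsewhere — the error of the
  linearization is far below noise at these dilutions).
* **Artifacts** — monotone B0 drift (default 0.05 Hz/min ≈ 6 Hz over two
  hours, the "few Hz" scale of gradient/RF heating), multiplicative signal
  drift (default −0.05 %/min, cancelled by design by the S0 normalization),
  and a motion pseudo-CEST ramp (default 0→0.2 % MTR between 60 and
  120 min) applied to measurement images only — the simplest mechanism that
  reproduces a late control-group rise. Test and control cohorts share
  artifact settings.
* **Noise** — Rician magnitude noise, σ = 0.5 % of the mean liver baseline
  (a calibration choice, not a measured value; background pixels then show
  the Rayleigh floor σ√(π/2), which is tested).
* **Phantom** — a crescent-shaped liver ROI covering ~30 % of the 96×96
  grid with ±10 % smooth intensity texture; deterministic per seed.

Per-entry Z values are evaluated from an interpolating spline over a small
tensor grid of exact Bloch–McConnell solutions in (B0 drift, added thiol
fraction) per scheduled offset. The knots include drift 0 and fraction 0, so
artifact-free renderings coincide with direct simulation; within the tiny
drift (≲0.03 ppm) and dilute-fraction ranges the spline error is ≲10⁻⁹.
The recorded ground truth (the injected, artifact-free MTR at every
retained entry, referenced to the same S0 convention the protocol uses)
is produced by the same evaluator, which is what makes the noiseless
generate→analyze round trip an exact identity (≲10⁻¹²; required ≤10⁻⁸).

**What the generator does not emulate**: radial k-space sampling and its
reconstruction artifacts, respiratory image deformation (motion enters only
as an intensity term), chemical-shift artifacts from adipose tissue,
saturation-state carry-over between consecutive images (each image is
simulated from thermal equilibrium, so the early approach-to-steady-state
transient of real dynamic scans is absent — the pre-injection window option
exists for real data that needs it), spatial B0 inhomogeneity within a
dynamic series (uniform drift only; the full-Z-spectrum generator does
support per-pixel shift maps), and between-subject biological variability
(cohort subjects differ only by noise and phantom seed). Passing tests
therefore validate the quantification chain and its statistical calibration,
not the biological realism of any particular uptake curve.

## Quantification chain

* The S0 baseline uses the non-dummy S0 entries' ROI means, Savitzky–Golay
  filtered (window 3, order 2 — note this is mathematically the identity,
  since a quadratic through three points interpolates them; it is
  implemented faithfully and larger windows are accepted for genuine
  smoothing), then linearly interpolated to all entry times with boundary
  values held. Beyond the last S0 image the held baseline no longer tracks
  drift, so drift cancellation is only guaranteed inside the S0-bracketed
  range.
* MTR sign convention: positive for saturation-induced signal loss. The
  pre-injection average may be restricted to a window (e.g. to skip early
  pre-steady-state points in real data); default uses all pre-injection
  retained points.
* AUC maps run the identical chain per pixel (per-pixel S0 baselines) and
  integrate trapezoidally over closed windows in minutes, with the window
  endpoints interpolated onto the retained-point grid. AUC is additive over
  adjacent windows and linear in the MTR.
* Group curves: pointwise mean, sample SD (the per-point uncertainty), and
  a display-smoothed variant (Savitzky–Golay window 7, order 2).

## B0 mapping

The inverted-Lorentzian fit is bounded to |δ| ≤ 1 ppm and 0.2 ≤ Γ ≤ 4 ppm
and initialized at the discrete grid argmin: the DWS dip dominates ±1 ppm
and unbounded fits can chase the thiol dip. These bounds are this package's
choices — the in vivo protocol did not state its fit window. Unfittable
pixels are flagged (NaN) rather than raised, with a logged warning above
20 % flagged. No WASSR-style correction is applied to dynamic data (the
sweep cannot be interleaved into a dynamic scan); the map is diagnostic.
The map is equivariant: shifting the input spectra's origin shifts every
fitted centre by the same constant.

## Statistics

Welch's unequal-variance t (Welch–Satterthwaite df) between groups, the
paired t within subjects, both two-sided (sidedness was an open choice;
two-sided is the conservative default). The offsets × time significance map
applies Welch's test per cell with **no multiplicity correction** — matching
the exploratory use of such maps, and meaning ~5 % of null cells are
expected to light up at α = 0.05 (verified by the null-calibration harness:
3–7 % over ≥1000 cells from two control cohorts). A Benjamini–Hochberg
option exists but is off by default. This is a known limitation, not an
oversight.

## Validation harnesses and problem sizes

`dyncest.validation` packages the five end-to-end checks with the study
conditions as defaults: CW-limit comparison on 2- and 3-pool systems at
three offsets; noiseless round trip on the full 98-cycle FL1 study at
96×96; group recovery with 5 noisy subjects (the group mean is read at the
retained time point where the injected curve peaks — an unbiased estimator,
unlike the max over noisy points — and its standard error pools the
across-subject SD over all retained time points, since the noise is
homoscedastic and subjects share the injected curve, giving the 2-SE
acceptance band near-normal calibration instead of a heavy-tailed t₄
ratio); B0 recovery of ±0.1 ppm shifts over 100 noisy repeats per shift
(mean absolute centre error reported); and a null calibration accumulating
1000 cells as 10 independently seeded batches of two 5-subject control
cohorts with 20-sweep partial schedules on a 48×48 grid (batching keeps
each simulated scan a realistic ~46 min rather than one implausible
7-hour scan).

## Default physical parameters (placeholders)

The solute kinetics and liver relaxation defaults are field-typical values,
not fitted to any dataset, and should be overridden when calibrating
against measurements: liver water T1/T2 = 1.8 s / 30 ms at 7 T; thiol pool
k_ex = 1000 s⁻¹, T1/T2 = 1 s / 20 ms; amide pool k_ex = 30 s⁻¹, fraction
2×10⁻⁴. A second generic upfield pool can be added through the pool list to
mix the thiol signal with other upfield magnetization-transfer mechanisms,
whose in vivo decomposition is unresolved.

## Known limitations

* No semi-solid magnetization-transfer pool with a super-Lorentzian
  lineshape (a Lorentzian MT pool can be added as an ordinary pool).
* No MTR-asymmetry or multi-Lorentzian decomposition of in vivo spectra;
  the only spectral fit is the DWS Lorentzian.
* The significance map is uncorrected for multiplicity (above).
* Eq-chain drift compensation removes multiplicative signal drift but not
  the spectral consequences of B0 drift (the shifting/broadening of the
  water line), which is exactly the residual artifact the B0 maps are
  there to diagnose.
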