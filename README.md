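# dyncest

Dynamic thiol/amide CEST-MRI analysis of hepatic contrast-agent uptake, with
a Bloch–McConnell synthetic-study generator for ground-truth validation.

## The problem

Chemical exchange saturation transfer (CEST) MRI detects dilute solutes
through their exchangeable protons: a long, frequency-selective saturation
pulse applied at a solute resonance is carried to the water pool by chemical
exchange and attenuates the water signal. At 7 T, the thiol proton of
N-acetylcysteine (NAC) resonates 2.7 ppm upfield of water (−2.7 ppm) and the
glutathione amide 3.6 ppm downfield, so hepatic uptake of an injected NAC
bolus can be followed as a time-resolved signal loss while saturating those
offsets. This package is for imaging scientists who run or re-analyze such
dynamic CEST experiments: it implements the full quantification chain and a
physics-based simulator of the experiment, so every stage can be validated
against known ground truth without animal data.

## The model and the quantification

The physics core integrates the Bloch–McConnell equations of a water pool
coupled to one or more solute pools (star topology, detailed balance:
water→solute rate = fraction × k_ex). Saturation is the protocol's train of
302 × 30 ms Gaussian pulses at B1 = 1.2 µT — one pulse per radial readout
spoke, 9.06 s of saturation per image — integrated by exact matrix
propagators over a piecewise-constant envelope, with the analytic
continuous-wave steady state as an independent oracle.

The measured quantities follow the dynamic protocol:

* **Normalization** — liver-ROI intensities of interleaved far-off-resonance
  (333 ppm) *S₀* images are Savitzky–Golay filtered and interpolated in time
  to form the baseline *S₀,SG*; each retained image gives
  `Z = S / S₀,SG`, cancelling the slow multiplicative signal drift.
* **Dynamic MTR** — `MTR = Z_pre,avg − Z`, the pre-injection-referenced
  signal loss (positive = saturation-induced attenuation); by construction
  the pre-injection MTR mean is zero.
* **AUC maps** — the same chain per pixel, integrated over chosen time
  windows (e.g. 24–39 min post-injection vs the 8–23 min baseline).
* **Partial Z-spectral maps** — five-offset sweeps (−4.3…−1.1 ppm or
  4.2…3.0 ppm) arranged as offset × time matrices, with cellwise Welch
  significance against a control group.
* **B0 maps** — per-pixel inverted-Lorentzian fits
  `Z(ω) = b − d·(Γ/2)² / ((Γ/2)² + (ω − δ)²)` of the direct-water-saturation
  dip; the centre δ is the pixel's apparent water resonance, i.e. its B0
  shift.

The synthetic generator renders complete 96×96 dynamic studies from an
acquisition schedule: a gamma-variate uptake spike (default 0.64 % MTR
peaking 7 min post-injection) plus slow accumulation entering the physics as
an added thiol pool fraction, B0 and signal drift, a late motion
pseudo-CEST ramp, and Rician magnitude noise — with the injected MTR curve
recorded as ground truth.

## Worked example

```sh
python examples/03_synthetic_roundtrip.py
```

```
noiseless round-trip error: 6.50e-13
injected peak MTR: 0.673% at 29.8 min
recovered (noisy, with B0/signal drift): 0.691%
```

The first line verifies the analysis chain is the exact inverse of the
noise-free generator; the next two compare the injected uptake peak (0.64 %
spike plus the accumulation term, ~30 min into the scan = ~7 min
post-injection) with what the full pipeline recovers from a noisy, drifting
single subject. The other example scripts cover Z-spectrum simulation and
MTR profiles (`01`), the three acquisition frequency lists and their timing
arithmetic (`02`), B0-gradient mapping (`04`) and a test-vs-control group
study with the significance map (`05`). A YAML-configured end-to-end run
(simulation → curves → AUC maps → statistics → figures) is available as
`dyncest report --config my_study.yaml` or `dyncest.run_pipeline(...)`.

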