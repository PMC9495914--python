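"""Generate a synthetic test subject and recover its injected MTR curve.

A noiseless, artifact-free study must be reproduced exactly by the
S0-normalization + pre-injection-correction chain; with default noise the
recovered curve scatters around the injected one.
"""

import numpy as np

from dyncest import dynamics, schedule as sched, synth

fl1 = sched.build_fl1()                      # ~122 min dynamic scan
uptake = synth.UptakeModel()                 # 0.64% spike peaking 7 min post-injection

clean = synth.generate_series(fl1, uptake, synth.ArtifactModel.none(),
                              synth.NoiseModel.none(), seed=1)
curve = dynamics.roi_mtr_curves(clean)[-2.7]
t_true, mtr_true = clean.truth.for_offset(-2.7)
print(f"noiseless round-trip error: {np.abs(curve.mtr_values - mtr_true).max():.2e}")

noisy = synth.generate_series(fl1, uptake, synth.ArtifactModel(),
                              synth.NoiseModel(), seed=1)
c = dynamics.roi_mtr_curves(noisy)[-2.7]
k = int(np.argmax(mtr_true))
j = int(np.argmin(np.abs(c.times_min - t_true[k])))
print(f"injected peak MTR: {100 * mtr_true[k]:.3f}% at {t_true[k]:.1f} min")
print(f"recovered (noisy, with B0/signal drift): {100 * c.mtr_values[j]:.3f}%")
print("positive MTR = saturation-induced signal loss relative to the")
print("pre-injection baseline; the spike marks the hepatic uptake bolus.")
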