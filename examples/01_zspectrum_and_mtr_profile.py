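"""Simulate Z-spectra with and without an exchanging thiol pool.

Builds the 7 T two-pool system (liver water + NAC thiol at -2.7 ppm), sweeps
the saturation offset over +-5 ppm with the protocol's Gaussian pulse train,
and prints where the exchange-induced MTR profile peaks.
"""

import numpy as np

from dyncest import bmc
from dyncest.schedule import build_full_zspec_list

field = bmc.FieldParams()
train = bmc.SaturationTrain(bmc.SaturationPulse("gaussian", 1.2, 0.030),
                            n_pulses=302, interpulse_delay_s=0.01041)
offsets = build_full_zspec_list()          # 51 offsets, +-5 ppm at 0.2 ppm

water_only = [bmc.water_pool()]
with_thiol = water_only + [bmc.thiol_pool(fraction=1e-3)]

z0 = bmc.zspectrum(water_only, offsets, train, field)
z1 = bmc.zspectrum(with_thiol, offsets, train, field)
profile = bmc.mtr_profile(z0, z1)

k = int(np.argmax(profile))
print(f"Z at water resonance (direct saturation): {z0.z_values[offsets == 0][0]:.4f}")
print(f"MTR profile peak: {100 * profile[k]:.3f}% at {offsets[k]:+.1f} ppm")
print("The peak sits at the grid offset nearest the thiol resonance (-2.7 ppm):")
print("saturation there is transferred to water by exchange and removes signal.")
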