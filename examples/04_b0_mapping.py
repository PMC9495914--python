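"""Map a spatial B0-shift gradient from per-pixel Z-spectrum fits.

Generates a full +-5 ppm Z-spectrum scan of the liver phantom whose water
resonance is shifted by a left-right linear gradient, fits the inverted
Lorentzian to each pixel's direct-water-saturation dip, and compares the
fitted map with the injected one.
"""

import numpy as np

from dyncest import synth, zspec
from dyncest.schedule import build_full_zspec_list

offsets = build_full_zspec_list()
phantom = synth.make_liver_phantom(48, seed=0)
h, w = phantom.shape
gradient = np.linspace(-0.1, 0.1, w)[None, :] * np.ones((h, 1))   # ppm

scan = synth.generate_zspectrum_scan(offsets, phantom=phantom,
                                     b0_shift_ppm=gradient,
                                     noise=synth.NoiseModel(0.01), seed=0)
shift_map = zspec.b0_map(scan)

liver = scan.masks["liver"]
err = np.abs(shift_map - gradient)[liver]
print(f"fitted {np.sum(~np.isnan(shift_map[liver]))} of {liver.sum()} liver pixels")
print(f"mean |fitted - injected| shift: {np.nanmean(err) * 1e3:.2f} milli-ppm")
print(f"map range: {np.nanmin(shift_map[liver]):+.3f} ... "
      f"{np.nanmax(shift_map[liver]):+.3f} ppm (injected +-0.100 ppm)")
print("each pixel's fitted dip centre is its apparent water resonance, i.e.")
print("the local B0 shift; the gradient sign and magnitude are recovered.")
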