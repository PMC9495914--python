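"""Build the three dynamic frequency lists and print their arithmetic.

FL1 alternates the thiol (-2.7 ppm) and amide (+3.6 ppm) offsets with
interleaved S0 reference images; FL2/FL3 sweep five-offset partial
Z-spectra.  Every measurement offset is acquired twice with the first
instance discarded.
"""

from dyncest import schedule as sched

timing = sched.TimingParams()
print(f"image duration: {timing.image_duration_s:.2f} s "
      f"(TR {1e3 * timing.tr_s:.2f} ms x {timing.n_spokes} spokes)")
print(f"saturation time per offset: {sched.saturation_time_per_offset(timing):.2f} s")
print(f"retained-point time resolution: {sched.retained_time_resolution(timing):.1f} s")

fl1 = sched.build_fl1(timing)
fl2 = sched.build_fl2(timing)
print(f"\nFL1: {len(fl1)} images, {fl1.duration_s / 60:.1f} min, "
      f"offsets {[float(w) for w in sorted(fl1.measure_offsets)]}")
print(f"FL2: {len(fl2)} images, {fl2.duration_s / 60:.1f} min, "
      f"offsets {[float(w) for w in sorted(fl2.measure_offsets)]}")
print("\nfirst FL1 cycle after the 12 dummy S0 images:")
print(fl1.to_frame().iloc[12:18].to_string(index=False))
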