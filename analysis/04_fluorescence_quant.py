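#!/usr/bin/env python
"""Division-site fluorescence quantification on simulated image stacks.

Simulates ring-like (rim-localised) and disk-like (centre-spread) division
plane signals with PSF blur and Poisson noise, then measures rim-spread
indices from 3-pixel line scans, recovers a planted two-channel axial
offset from aligned colocalization profiles, and computes a
background-subtracted ROI intensity on the sum projection.
"""

from sepexo.pipeline import RunConfig, run

config = RunConfig(seed=1, out_dir="results/runs/quant", stages=["quant"])
report = run(config)["stages"]["quant"]

print(f"rim-spread index: ring cells max {report['rim_index_ring_max']:.3f}, "
      f"disk cells min {report['rim_index_disk_min']:.3f} "
      f"(classes separate: {report['rim_index_ring_max'] < report['rim_index_disk_min']})")
print(f"planted channel offset {report['channel_offset_planted_um']} um, "
      f"measured {report['channel_offset_measured_um']} um")
print(f"background-corrected ROI intensity (sum projection): "
      f"{report['roi_corrected_intensity']:.1f}")
print("tables: results/runs/quant/reports/quant_rim.tsv, quant_profiles.tsv")
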