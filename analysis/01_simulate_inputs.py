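#!/usr/bin/env python
"""Generate one example of every synthetic input class, with ground truth.

Writes text fixtures (PDB models, FRAP CSV, ground-truth JSON) under
results/fixtures/ and the image stack (binary TIFF) under scratch/.
"""

from pathlib import Path

from sepexo.fluor_quant import write_stack
from sepexo.model_io import write_structure
from sepexo.synthetic_data import (
    make_complex_model,
    make_division_stack,
    make_frap_trace,
    make_pair_model,
)

SEED = 1
out = Path("results/fixtures")
out.mkdir(parents=True, exist_ok=True)
scratch = Path("scratch")
scratch.mkdir(exist_ok=True)

pair, pair_truth = make_pair_model(20, 20, 6, seed=SEED)
write_structure(pair, out / "pair_model.pdb")
pair_truth.to_json(out / "pair_model.truth.json")
print(f"pair model: {pair.n_residues} residues, "
      f"{len(pair_truth.planted_contacts)} planted contacts")

complex_model, complex_truth = make_complex_model(seed=SEED)
write_structure(complex_model, out / "complex_model.pdb")
complex_truth.to_json(out / "complex_model.truth.json")
print(f"complex model: {len(complex_model.chains)} chains, "
      f"{complex_truth.expected_percent_accessible():.1f}% residues exposed by design")

stack, stack_truth = make_division_stack("ring", psf_sigma_um=0.1,
                                         poisson_noise=True, seed=SEED)
write_stack(stack, scratch / "division_stack.tif")
stack_truth.to_json(out / "division_stack.truth.json")
print(f"division stack: pattern={stack_truth.pattern}, shape={stack.data.shape}")

trace, frap_truth = make_frap_trace(acquisition_bleach_rate=0.002, noise_sd=2.0,
                                    seed=SEED)
trace.to_csv(out / "frap_trace.csv")
frap_truth.to_json(out / "frap_trace.truth.json")
print(f"FRAP trace: {trace.times.size} frames, planted off-rate "
      f"m3={frap_truth.m3}/s (t_half={0.6931/frap_truth.m3:.2f} s)")
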