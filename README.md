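# sepexo

Computational toolkit for screening predicted septin–exocyst interactions and
quantifying division-site fluorescence in fission yeast.

Septins (Spn1–Spn4 in *Schizosaccharomyces pombe*) form rings at the rim of
the cytokinetic division plane; the octameric exocyst complex (Sec3, Sec5,
Sec6, Sec8, Sec10, Sec15, Exo70, Exo84) tethers secretory vesicles there.
Testing whether the two machineries interact physically leads to two
computational problems that this package implements as a reusable, fully
tested pipeline:

1. **Structure-prediction screening.** Given pairwise predicted complex
   models of every septin–exocyst subunit combination (PDB/mmCIF with
   per-residue pLDDT in the B-factor field, optional PAE matrices), extract
   interface residues as residue pairs with minimum heavy-atom distance
   ≤ 4 Å, discard contacts whose residues have pLDDT < 50, rank the candidate
   models of each input by mean pLDDT, and call a subunit pair an interaction
   only when the rank-1 model of *each* input order (A:B **and** B:A) shows
   filtered contacts — the bidirectional-order consensus. Interface residues
   are then mapped (by explicit per-subunit offsets) onto an assembled
   whole-complex model, and their solvent accessibility in the complex
   context (Shrake–Rupley relative SASA ≥ 0.25) quantifies whether the
   predicted binding sites remain sterically available.
2. **Fluorescence quantification.** Sum/max z-projections; ROI intensities
   with local background subtracted from a surrounding ROI of about twice the
   area; width-averaged axial colocalization profiles; 3-pixel line scans
   across the division plane with peak-based alignment strategies; a
   rim-spread index separating rim-localised (ring) from centre-spread (disk)
   signal; and FRAP kinetics — correction against reference/background,
   normalization (pre-bleach = 100 %, first post-bleach = 0 %), 3-point
   rolling average, and the single-exponential fit
   `y = m1 + m2·exp(−m3·x)` with half-time `t½ = ln 2 / m3`. The two
   β-galactosidase activity formulas used for yeast two-hybrid quantification
   are included as exact arithmetic helpers.

Because no real predicted models or microscopy data ship with the package, a
first-class synthetic-data module generates every input class with known
ground truth (planted contacts and confidence labels, constructed
exposed/buried residues, ring/disk image geometry, forward-simulated FRAP
traces), so every stage is verified end to end against what was planted.

## Worked example

The numbered scripts under `analysis/` run each stage on synthetic data.
For example:

```sh
$ python analysis/02_interface_screen.py
screened 32 unordered subunit pairs (both orders each)
consensus interactions found: 6 (planted: 6, correctly recovered: 6)
all consensus pairs ranked above non-consensus pairs: True
per-pair table: results/runs/screen/reports/screen.tsv
```

Thirty-two septin–exocyst combinations were simulated in both input orders;
six carried planted bidirectional interfaces, five carried one-sided decoy
interfaces. The screen recovers exactly the six planted pairs, ranked above
everything else by the conservative consensus score (minimum over the two
orders of the interface mean pLDDT).

```sh
$ python analysis/05_frap_kinetics.py
max noiseless m3 relative error: 0.00e+00
max noisy (sd=2) m3 relative error: 0.018
all fits converged: True
```

Forward-simulated recovery traces (both acquisition designs: 150 frames at
0.33 s and 70 frames at 10 s, with acquisition photobleaching) are inverted
by the correction/normalization/smoothing/fit pipeline: noiseless traces
recover the planted off-rate exactly, and Gaussian noise of 2 % of the
recovery amplitude perturbs the fitted `m3` by under 2 % here.

The same stages are available from the command line (`sepexo run`,
`sepexo screen`, `sepexo feasibility`, `sepexo quant`, `sepexo frap`,
`sepexo simulate`) and as a library (`sepexo.interface_screen`,
`sepexo.accessibility`, `sepexo.fluor_quant`, `sepexo.frap`,
`sepexo.assays`, `sepexo.synthetic_data`, `sepexo.pipeline`).

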