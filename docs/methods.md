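# Methods

This note documents the models and conventions implemented in `sepexo`, the
parameters that matter with their defaults and rationale, what the synthetic
generators do and do not emulate, and the numerical choices made where the
design was genuinely open. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Structural data model and I/O

Predicted models are read and written through gemmi (PDB and mmCIF).
Per-residue confidence (pLDDT, 0–100) is taken from the B-factor field: the
CA atom's value when present, otherwise the mean over the residue's atoms.
Prediction pipelines write identical per-residue values on all atoms, so the
two conventions agree on real inputs while staying defined for synthetic
single-atom residues. A model whose B-factor column is entirely zero (the
parsed value of a blank column) is rejected with an explicit
"no confidence data" error rather than silently treated as pLDDT 0; a
genuinely all-zero-confidence model is indistinguishable from a blank
column, a corner we accept because it does not occur in practice.

Author residue numbering is preserved verbatim (1-based, no renumbering);
numbering discrepancies between pairwise and complex models are handled
explicitly in the accessibility stage. Hydrogens are parsed but flagged and
excluded from contacts and SASA (predicted models lack them). The first
altloc is kept; insertion codes are rejected (predicted models never contain
them). PAE matrices are read from JSON in two dialects — a
`predicted_aligned_error` list-of-lists payload and a bare `pae` object —
with square-shape and non-negativity validation, and chain boundaries
attached from a companion model.

## Interface screen

**Contact definition.** Two residues of different chains are in contact when
their minimum non-hydrogen inter-atomic distance is ≤ 4.0 Å, *inclusive*.
The heavy-atom minimum (rather than CA–CA or centroid distance) is the
standard interface convention at this length scale. A k-d tree prunes
candidate atom pairs, but the inclusion decision is the plain squared
distance comparison, so output is bit-identical to a brute-force scan (and
is tested against one).

**Confidence filter.** A contact is kept only when *both* partner residues
have pLDDT ≥ 50 (inclusive: exactly 50 passes, 49.99 fails). A contact with
one unreliable side is unreliable; a config switch (`both`/`either`)
relaxes this.

**Ranking and consensus.** Candidate models of one input are ranked by mean
pLDDT, descending, with ties broken by model id for determinism. A subunit
pair counts as an interaction when the rank-1 model of each input order
shows ≥ `min_contacts` filtered contacts (default 1 — no stronger criterion
is standard, and the threshold is exposed). Pairs are ranked by the minimum
over the two orders of the interface mean pLDDT, a conservative consensus
score; an empty interface scores 0. Pairs missing one input order are
reported non-evaluable with a warning and the run continues.

## Steric feasibility

Solvent-accessible surface area is computed with a deterministic
Shrake–Rupley scheme: each heavy atom's extended sphere (van der Waals
radius + 1.4 Å probe) is sampled at 960 golden-spiral points, a point being
accessible when outside every neighbouring extended sphere. Bondi-type
element radii are used (C 1.70, N 1.55, O 1.52, S 1.80 Å); unknown elements
fall back to a configurable default with a warning. Exactly coincident
equal-radius atoms are counted once — sample points of duplicated spheres
sit exactly on the occluding boundary, where an inequality test is
ill-defined. Isolated-sphere output is verified against the closed form
4π(r+probe)², and the whole computation is cross-checked against an
independent implementation (biotite) in the test suite.

Relative SASA divides by the residue-type theoretical maximum (Tien et
al. 2013 table; the table name is recorded in every report). A mapped
interface residue is classified *accessible* when its relative SASA in the
assembled-complex context is ≥ 0.25 — the widely used exposure threshold —
so a residue buried by its own complex partners counts as unavailable. This
quantitative criterion replaces visual inspection of rendered surfaces; it
is the only reproducible surrogate, and the threshold is configurable and
reported alongside every percentage. Octamer and hexamer complexes run
through the identical pipeline, distinguished only by the input file.

Mapping from pairwise-model numbering to (possibly truncated) complex
numbering is explicit per-subunit configuration — offsets plus kept ranges —
never sequence alignment, to avoid hidden alignment errors. Residues inside
trimmed ranges are reported unmappable (never silently dropped); a
residue-name mismatch or target collision is a hard error, guarding against
off-by-one offsets. The percent-accessible summary is over mapped residues
only, with the unmappable count carried separately.

## Fluorescence quantification

Pixel coordinates are 0-based, origin top-left, x rightwards, y downwards;
ROI bounds are half-open; physical positions are micrometres via the stack
calibration (stored in the TIFF metadata; default synthetic geometry 0.1
μm/pixel, 0.5 μm z-step).

**ROI intensity.** Total intensity of ROI1 on a sum projection, minus local
cytoplasmic background estimated from a surrounding ROI2 (containing ROI1,
about twice its area — the ratio is configurable, default 2.0):
`corrected = I1 − A1·(I2 − I1)/(A2 − A1)`, i.e. the mean per-pixel intensity
of the ROI2∖ROI1 annulus scaled to ROI1's area. This is the implemented
convention for the common "background ROI around the signal ROI" recipe.

**Profiles.** Axial colocalization profiles average all pixels across the
ROI width per position along the long axis (the standard use is a
1.5 × 3.5 μm ROI across the division plane). Line scans average a 3-pixel
band perpendicular to the line; axis-aligned integer lines reduce to exact
pixel means, oblique lines sample bilinearly at unit-pixel steps.

**Alignment.** Four strategies shift positions (never values) so the chosen
origin sits at 0: the peak of a common reference profile, each profile's own
brightest position, the midpoint of the two highest local maxima (≥ 3
positions apart), or externally supplied centres. Peaks are global maxima
after 3-point smoothing.

**Rim-spread index.** For a profile spanning the full cell diameter, the
index is `center/(center + rim)` of the mean intensities of the centre third
versus the outer thirds: ~0 for a rim-confined ring, ~1 for centre-spread
signal. It is an explicit quantitative surrogate for visual
"intact vs mislocalized" scoring, not a published measure.

## FRAP kinetics

The pipeline is correct → normalize → smooth → fit. Correction:
`(bleach − background) · R̄ / (reference − background)` with R̄ the mean
pre-bleach background-subtracted reference, dividing out acquisition
photobleaching while preserving the pre-bleach scale; a reference at or
below background is an error naming the timepoint. Normalization is the
affine map sending mean pre-bleach → 100 % and first post-bleach → 0 %.
Smoothing is a centred 3-point rolling average over post-bleach points only,
with shrink-to-available windows at the ends. Fitting minimises least
squares for `y = m1 + m2·exp(−m3·t)` (t = 0 at the first post-bleach frame,
m3 > 0 bounded), from a deterministic start (m1 from the last 10 % of
points, m2 from the first point, m3 from a log-linear regression of m1 − y).
`t½ = ln 2/m3` exactly, by construction.

A 3-point rolling average multiplies the amplitude of a sampled exponential
by a cosh-type factor (≈ 1 + (m3·Δt)²/6) and distorts the segment ends, so a
naive fit of the raw model to smoothed data is biased at the ~10⁻⁴ level.
The fit therefore applies the identical rolling-average operator to the
model prediction inside the least squares whenever it consumes a smoothed
series, making the estimator exact on noiseless data and unbiased in
expectation. Fitting the smoothed series is the default; a switch fits the
raw normalized series instead.

## Assays

The two β-galactosidase activity conventions are evaluated exactly as
printed in the underlying protocols: `OD420 × 1.7 / (0.0045 · protein(mg/ml)
· volume(ml) · time(min))` (nmol/min/mg) and `1000 × OD420 / (T · V ·
OD595)` (units). The constants 1.7 and 0.0045 are used verbatim; their unit
derivations are not re-derived here.

## Synthetic data: what it emulates, and what it does not

**Pair models.** Chains are rigid 5-atom alanine-like clusters (four atoms
within 1 Å of the centre in a plane, a CB protruding 0.9 Å) spaced 8 Å apart
on straight scaffolds 10 Å apart. Planted contacts lower a chain-B residue
over its chain-A partner so the CB–CB distance — provably the minimum
heavy-atom distance of the pair — equals the requested contact distance
(drawn from (2.5, 4.0]); every non-planted inter-chain residue pair stays
beyond a 6 Å guard margin by construction. This controls contact geometry
and confidence labels exactly, but does not emulate real folds, flexible
side chains, or the confidence behaviour of an actual structure predictor.

**Complexes.** Exposed residues are clusters spaced ≥ 12 Å apart on a convex
ring (relative SASA well above 0.5); buried residues are single CA atoms
inside a 16-atom carbon cage of radius 3.0 Å that occludes the entire
extended sphere (relative SASA ≈ 0). `validate=True` self-checks every
construction by an actual SASA computation (buried < 0.05, exposed > 0.5).
These planted labels make the feasibility percentage exactly predictable;
they do not model partial burial, conformational variability, or realistic
packing densities.

**Image stacks.** End-on division-plane geometry on a calibrated grid (cell
radius 1.8 μm, 0.1 μm pixels, seven 0.5 μm z-sections, Gaussian z-envelope):
a Gaussian annulus at the cell radius (ring), a Gaussian disk over the
centre (disk), or their mean; optional Gaussian PSF, Poisson noise (default
peak 200 counts, peak SNR ≈ 14) and a planted second-channel x-offset.
Real cell outlines, autofluorescence, camera noise beyond Poisson and
chromatic shifts are not modelled, so passing tests demonstrate correctness
of the measurement conventions, not robustness to every imaging artefact.

**FRAP traces.** Five pre-bleach frames at 100 plus post-bleach
`m1 + m2·exp(−m3·t)` in both acquisition designs (150 frames at 0.33 s, 70
at 10 s), multiplied by a shared per-frame acquisition-bleaching decay, plus
constant background and optional Gaussian noise. Ground truth records the
planted parameters on the normalized scale, so recovery is checked exactly
for any planted values. Diffusion-limited recovery shapes and double
exponentials are out of scope.

## Pipeline and reproducibility

A single YAML-serialisable `RunConfig` carries every threshold and
simulation size; validation rejects out-of-domain values before any
computation. Stages run in dependency order; reports are TSV/JSON with
fixed float formatting and sorted keys, so a rerun with the same config and
seed is byte-identical. Every run directory carries the resolved config, a
config hash over the scientific parameters (output location excluded), the
package version and a log. All randomness flows from the single config seed
through numpy Generators.

Default problem sizes (a 4×8 subunit grid with 5 models per order and 16
residues per chain; 4-chain complexes of 10 residues per chain; 20 cells
per pattern; four FRAP traces) keep the full demo to a few seconds while
exercising every code path; the acceptance script scales the oracle
comparison to hundreds of models and the Monte-Carlo recovery study to 200
traces.

## Known limitations

- The exposure threshold (relative SASA ≥ 0.25) is a surrogate for visual
  assessment; percentages shift with the threshold, which is therefore
  recorded in every report.
- The consensus criterion's `min_contacts = 1` default is a choice; no
  community standard exists for "shows an interaction" at the contact-count
  level.
- SASA uses a fixed-resolution point sampling (960 points, ~1–2 % error on
  closed forms); it is not an analytic surface.
- The synthetic generators guarantee exact planted properties at the price
  of unrealistic geometry; conclusions about real predicted models rest on
  the conventions being standard, not on these fixtures resembling real
  proteins.
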