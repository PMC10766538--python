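# Methods

This note documents the models, conventions and design choices behind
`petmrbids`: what each stage computes, which parameters matter, what the
synthetic generator emulates, and where the numerical edges are.

## DICOM ingest

**Series grouping.** Files are grouped by (subject, session,
SeriesInstanceUID). The subject/session labels come from the directory
tree through a layout descriptor — an ordered tuple of roles, one per
directory level under the root (`("subject", "session", "series")` by
default, `("subject", "series")` for single-session studies). A
declarative descriptor was chosen over hard-coded paths because raw
export layouts genuinely differ between sites; anything the descriptor
cannot express should be renamed on disk rather than special-cased in
code. Series whose files disagree on image dimensions are flagged
invalid and refuse assembly — silently merging mismatched files is the
kind of error no downstream check would catch.

**Volume assembly.** Slices are ordered by their position along the
slice normal (the cross product of the row/column direction cosines),
with InstanceNumber as the fallback when positions are absent. Duplicate
positions or duplicate instance numbers raise instead of guessing. The
echo axis is keyed on distinct EchoTime values and the frame axis on
distinct temporal position identifiers, so a series carrying both yields
a 5-D stack. Classic one-file-per-slice series and multi-frame files
(one file per time frame holding the whole slice stack, the common PET
export shape) assemble to identical arrays; the test suite asserts this
equivalence explicitly. The affine is built in DICOM LPS coordinates
from the orientation/position/spacing tags and converted to RAS by
negating the first two rows.

**Reorientation.** Axis-code changes (`RSA` → `RPI` and the like) are
signed permutations computed with nibabel's orientation machinery,
applied only to the three spatial axes. Because the transform is exact,
round trips reproduce the voxel array bit for bit and composing two
reorientations equals the direct one — both are property-tested. Oblique
affines are snapped to the nearest axis-aligned code; if the maximal
axis deviation exceeds a configurable tolerance (default 20°) a warning
flags the series for manual review rather than failing, since mildly
oblique acquisitions are the norm when no stereotaxic frame is used.

**Diffusion tables.** b-values and gradient vectors are read from the
per-volume standard tags (`DiffusionBValue`,
`DiffusionGradientOrientation`), ordered as the frame axis of the 4-D
stack. b = 0 volumes get zero vectors; nonzero vectors are normalised to
unit length. Vectors are re-expressed under the same signed permutation
as the voxel reorientation, which preserves norms exactly. Written
tables follow the FSL convention (one `.bval` row; `.bvec` as three
rows).

## BIDS building

**Configuration.** Three CSV files (UTF-8, header row) drive the
conversion: the *sequence overview* (regex match pattern per sequence,
BIDS suffix/entities/datatype, required sidecar keys, fallback values),
the *tag map* (BIDS key → DICOM tag keyword or `(group,element)` pair),
and the *PET doses* table (per subject/session/tracer:
InjectedRadioactivity in MBq, InjectedMass in nmol, SpecificRadioactivity
in GBq/µmol). The doses file is only required when PET series are
selected. List- and mapping-valued cells use `;`-separated
`key=value` items.

**Resolution precedence.** Each required sidecar key is filled from the
first available source in the order **dose config > DICOM header (via
the tag map) > overview fallback**, and the winning source is recorded
per key. Dose values outrank scanner tags because they are measured
study inputs, not header echoes. An unresolvable required key is an
error; a series matching no overview row is skipped with a warning; a
series matching two rows is an error — ambiguity is never auto-resolved.
Timing keys (EchoTime, RepetitionTime, InversionTime) are converted from
the millisecond DICOM convention to BIDS seconds at resolution time.

**Frame schedules.** Dynamic-PET timing is declared as ordered
`repeat × duration` blocks and expanded cumulatively into
`FrameTimesStart`/`FrameDuration`. The water-tracer schedule
(8×4 s, 4×6 s, 6×10 s, 8×20 s) expands to 26 frames spanning 276 s.
When a protocol document states a frame count that disagrees with the
block arithmetic, the expansion trusts the blocks and emits a warning —
the arithmetic is checkable, a transcribed count is not.

**Writing.** Images go out as gzipped NIfTI-1 with the stack's affine
and zooms; sidecars are JSON with keys serialised in sorted order so
identical inputs produce byte-identical files. `dataset_description.json`
and `participants.tsv` templates are emitted at the dataset level; the
participants columns (participant_id, species, age in years, sex, weight
in kg) cover the variables a preclinical cohort description reports.
Round-tripping a written image restores the converted voxels exactly
(integer arrays keep their dtype end to end).

## Quality metrics

**Segmentation.** The VOI is defined by Otsu thresholding the 3-D
volume with the highest *mean* intensity in the stack (the reference
volume — for a dynamic PET scan this is the bolus-peak frame). "Highest
intensity" is interpreted as highest mean rather than highest single
voxel because the mean is robust to isolated hot voxels; the chosen
reference index is stored on every record. Voxels at or above the
threshold are tissue, voxels below are background. The masks from the
reference volume are applied to every volume of the stack; background
statistics are then computed per volume (masks fixed, statistics local),
so frame-wise noise changes remain visible.

**Otsu convention.** Raw samples are histogrammed into 256 equal-width
bins between the observed min and max; candidate thresholds are interior
bin edges; the between-class variance `w0·w1·(μ0−μ1)²` is maximised with
bins represented by their centres. Two determinism rules make the result
canonical: ties select the lowest threshold, and splits whose lower
class ends in an empty bin are skipped (they partition the data
identically to an earlier split, so plateaus across empty histogram gaps
resolve to their lowest edge instead of depending on floating-point
associativity). The implementation is verified against an exhaustive
search on random histograms and cross-checked against
scikit-image's reference implementation.

**Metrics.** σ_noise is the sample standard deviation (n−1) of
background voxels. SNR = μ_VOI/σ_noise; CNR = (max_VOI −
min_VOI)/σ_noise with literal max/min, no percentile clipping — the
definition is deliberately simple and its sensitivity to single extreme
voxels is accepted; median intensity uses the mean-of-middle convention
for even counts. A zero σ_noise raises rather than returning infinity.
Aggregation per acquisition: dynamic sequences average each metric over
frames; multi-echo sequences average the median over echoes and compute
SNR/CNR on the first echo only, where SNR is maximal; a 1-frame, 1-echo
stack reduces exactly to the static path (property-tested).

**PNECR.** For each frame with total prompts P and total randoms D,
`PNECR = (P − D)²/P` (0 for an empty frame; D > P is rejected). The
curve is reported as a rate — the per-frame value divided by the frame
duration — so scans with different schedules are comparable; the
undivided totals are kept alongside since the defining formula uses
totals. The scan-level summary is the maximum of the rate curve.
Log-scale exports drop nonpositive values and report how many frames
were dropped. Whether prompts should be decay-corrected is left to the
data producer: counts are taken exactly as given in the input table.

**Outlier flagging.** Within each sequence group, records with
`|value − group median| > 3 × scaled MAD` (MAD × 1.4826, consistent
with a normal σ) are flagged; groups smaller than 4 get no flags, with
a warning. This rule is an automation convenience for review queues, not
a hypothesis test: with ~20 well-behaved records per group, a spurious
flag occurs in roughly 5 % of cohorts, so flags mean "look at this",
never "discard this".

## Synthetic cohorts

The generator produces the raw material the converter and QC battery
expect, with every quantity of interest planted and recorded in a
manifest:

* **Structural phantoms** — an ellipsoid of tissue mean μ over zero-mean
  Gaussian noise of SD σ on a 64×64×32 grid at 2 mm isotropic (a
  desk-scale stand-in for a 256×256×127 clinical matrix, keeping the
  full loop around a minute for 20 subjects). Multi-echo variants scale
  tissue by `exp(−TE/T2*)`. Values are stored as signed 16-bit integers
  and the returned ground truth is the stored array, so round-trip
  comparisons can demand bit-exact equality.
* **Dynamic PET** — per-frame tissue intensity follows a gamma-variate
  bolus curve (amplitude, delay t0, shape α, scale β; mode at
  t0 + αβ) averaged over each frame. Prompts are Poisson with mean
  proportional to the frame's curve integral plus an independent Poisson
  randoms floor; prompts = trues + randoms by construction, so D ≤ P
  always holds. The default schedules are the two printed tracer
  schedules (26 frames each).
* **Cohorts** — n subjects (default 20) with configurable test–retest
  subjects, planted missing acquisitions, planted noise-inflated outlier
  sessions, and per-sequence DICOM tag dropout; plus the three CSV
  configs, a participants table (ages 5/6/7 years at 20/60/20 %,
  weights ~ N(7.37, 1.11²) kg, matching the study conditions) and
  per-tracer dose draws (water 255 ± 15 MBq; the carbon-11 tracer
  140.1 ± 21.4 MBq with molar activity 48.0 ± 24.5 GBq/µmol and mass
  3.50 ± 1.7 nmol). Tissue means carry a ±3 % between-session jitter so
  group statistics have realistic spread. Identical seeds produce
  byte-identical trees.

**What the phantoms do not emulate.** No anatomy (an ellipsoid, not a
brain), no Rician magnitude-MR noise (pure additive Gaussian, acceptable
at the SNR levels generated but wrong near zero signal), no scanner
physics (no attenuation, scatter, dead time or reconstruction point
spread), no motion. Passing tests therefore certify the *pipeline* —
grouping, assembly, orientation, metadata resolution, metric arithmetic,
planted-truth recovery — not the behaviour of the metrics on real
tissue contrast or real noise fields. Geometry-critical tag dropout
(orientation/position/spacing) breaks assembly by design and is only
permitted with an explicit force flag, for negative tests.

## Numerical and edge-case conventions

* Constant images are rejected as degenerate before thresholding; empty
  VOI or empty background after thresholding is an error.
* Slice-ordering ties, inconsistent pixel spacing and mixed image
  dimensions are errors, never guesses.
* Echo times are stored strictly increasing; frame start times strictly
  increasing with matching duration counts.
* Dose values must be positive; a PET series selected without a doses
  file is an error naming the subject.
* The PNECR identity `(P−0)²/P = P` holds to one ulp in floating point,
  and homogeneity `PNECR(kP, kD) = k·PNECR(P, D)` to ~1e−13 relative.

## Known limitations

* Enhanced multi-frame DICOM is supported read-only and only in the
  stacked-slices shape the generator produces; exotic functional-group
  layouts are out of scope.
* Oblique handling is snap-with-warning; data more oblique than the
  tolerance still converts but needs manual review, mirroring standard
  practice for frameless animal positioning.
* The CNR definition (literal range over noise) is intentionally
  non-robust; a single hot voxel moves it.
* Outlier flags are stochastic screening aids (see above), not
  exclusion criteria.
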