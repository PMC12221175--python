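# Methods

## Overview

`ppigru` predicts whether two proteins interact from their sequences alone.
The pipeline has three stages:

1. **Feature coding.** Each protein is converted into six descriptor
   vectors. Three read a 20 x 13 physicochemical property matrix
   (pseudo amino-acid composition, autocorrelation descriptors,
   autocovariance); three read a seven-class alphabet in which the 20
   residues are grouped by dipole and side-chain volume (conjoint triad,
   local descriptor, multivariate mutual information). A pair is encoded by
   concatenating the two proteins' vectors per technique.
2. **GRU reduction.** Each technique's pair vector (width d) is fed to a
   bidirectional gated recurrent layer as a univariate sequence of d
   timesteps. The per-direction hidden width is `2^(floor(log2 d) - 3)`,
   so the bidirectional output is twice that. The layer is trained for a
   few epochs with a single sigmoid unit under binary cross-entropy, then
   the sigmoid head is discarded and the concatenated final hidden states
   become the reduced representation.
3. **Classification.** The six reduced representations are concatenated
   (584 features at the default lags) and classified by LightGBM.

Evaluation is stratified five-fold cross-validation with accuracy,
precision, sensitivity, specificity, F1, Matthews correlation, AUC and
AUPR.

## Encoders

All property-profile encoders operate on the z-scored (per column over the
20 residues, ddof = 1) property table, which makes them invariant to affine
rescaling of any raw property column. Per-protein dimensions at the default
lags (8, 7, 9): 28, 273, 117; the class-alphabet encoders are lag-free with
343, 630 and 119 features.

* **PseAAC** (type 1, weight w = 0.05): 20 composition terms plus lag
  sequence-order factors; the correlation kernel is the mean squared
  difference of the 13 standardized property components; all entries share
  one denominator so the vector sums to 1. w is exposed as configuration;
  0.05 is the conventional default for this descriptor family.
* **Autocorrelation descriptors**: normalized Moreau-Broto, Moran and
  Geary statistics per property and distance d = 1..lag, ordered
  descriptor-major, then property, then distance. For a property that is
  constant along the sequence, Moran and Geary are defined as 0 (the
  continuous limit of the vanishing variance ratio); constancy is tested
  exactly (column max == min) so floating-point residue in the mean cannot
  produce spurious ratios.
* **Autocovariance**: sequence-mean-centered covariance at each distance,
  property-major ordering.
* **Conjoint triad**: counts of the 343 ordered class 3-mers over sliding
  windows, normalized per protein as (f - min f) / max f with max taken
  over the raw counts. For real sequences with fewer than 343 distinct
  triads the minimum is 0 and at least one entry equals 1.
* **Local descriptor**: ten regions — four quarters, two halves, the
  middle half, the first and last three quarters, and the central 75%
  (12.5%..87.5%). Region bounds use round(fraction x L) with a minimum
  width of one residue. Per region: 7 class frequencies, 21 unordered
  adjacent-transition frequencies (divided by region length - 1; 0 for
  single-residue regions), and per class the relative positions of its
  first, ceil(0.25 m)-th, ceil(0.5 m)-th, ceil(0.75 m)-th and last
  occurrence (zeros for an absent class).
* **Multivariate mutual information**: natural-log entropy chain over
  unordered class 2- and 3-grams (pooled over orderings, denominators
  L-1 and L-2) plus the 7 class frequencies, enumerated in lexicographic
  multiset order; every term applies the 0 * ln 0 := 0 convention, and any
  ratio with a zero denominator is 0.

Non-canonical residues (B, J, O, U, X, Z) are rejected by default
("strict"); an optional "drop" policy removes them with a logged warning.
Composition vectors are ordered alphabetically by one-letter code.

## Property table

The loader accepts any 20 x 13 tab-delimited table. The packaged default
(`data/svhehs_synthetic.tsv`) is a **synthetic stand-in**: a frozen, seeded
draw with heterogeneous per-column scales, shaped like a PCA-derived
amino-acid descriptor matrix. It exercises every code path identically to a
real descriptor table; users with a measured 20 x 13 descriptor should
point `--property-table` at it. Because the encoders standardize per
column, only the relative ordering of residues within each column carries
information.

## GRU reduction

The GRU engine is written in NumPy (float32), with the per-timestep gate
algebra fused into Numba kernels when Numba is available (a pure-NumPy
fallback computes identical quantities). Training uses Adam (learning rate
1e-3), global-norm gradient clipping at 1, binary cross-entropy through a
discardable sigmoid head, 5 epochs, batch size 64, and per-epoch shuffling
driven by the reducer seed. Parameters initialize uniformly in
[-1/sqrt(h), 1/sqrt(h)] from the seed, so a (seed, data) pair reproduces
training bit-for-bit on one platform. Backpropagation through time was
verified against central finite differences (worst relative error ~1e-5 at
float32 cache precision).

Design choices where the architecture was genuinely open:

* **Input shaping**: a flat pair vector enters the recurrent layer as d
  univariate timesteps. This is the only shaping for which the hidden
  width is independent of d, and it treats the feature vector's column
  order as the "sequence" the recurrence reads.
* **Readout**: final hidden state per direction (the backward direction
  reads the reversed sequence, so its final state corresponds to the first
  column), concatenated. Mean pooling over timesteps is a noted
  alternative that was not adopted.
* **Unidirectional variants** double the hidden width so forward-only,
  backward-only and bidirectional models emit equally wide features,
  keeping direction comparisons controlled.
* **Ensembling**: `multiens` trains six per-technique reducers
  (rule-derived widths 4/64/16/64/128/16); `multisep` trains one reducer
  per encoder family with fixed widths 84 (property-profile) and 208
  (class-alphabet); `multicon` trains a single reducer of width 292 on all
  blocks concatenated. The grouped widths are constants chosen so every
  strategy emits 584 features; applying the width rule to the concatenated
  inputs would give narrower layers and an uncontrolled comparison.
* **Leakage policy**: by default reducers are retrained inside every
  cross-validation fold and applied to the held-out fold ("per-fold"), so
  the reduced representation never sees test labels. The "train-once"
  policy trains reducers on the full set before cross-validation; it is
  cheap but measurably optimistic on small data —
  on a 64-pair null dataset the width-292 monolithic reducer pushed
  held-out accuracy to 0.64 by partially encoding the labels it was
  trained on. The "split" policy removes that bias at train-once cost:
  reducers train on a disjoint stratified subset (`reduction_fraction`,
  default 40%) and the classifier is cross-validated on the remaining rows
  only; a null-data check under this policy sits at chance. Strategy
  comparisons use "split" so each arm trains its reducers once, on the
  same rows, with matched seeds.

## Classifier

LightGBM with 500 boosting iterations, seed 1, library defaults otherwise;
the exact parameter set in effect is retrievable from the fitted wrapper
for audit. Hard labels threshold probabilities at 0.5. Any object with
`fit`/`predict_proba` can replace the default through the same interface.

## Lag optimization

The lag of the three property-profile encoders is searched over 1..11
(bounded by the shortest sequence length minus one) by five-fold
cross-validation of the **raw** pair features through the classifier —
the reducers are deliberately excluded from the search so the measured
effect is the lag's, and the search stays cheap. Ties break toward the
smaller lag. The pipeline defaults (8, 7, 9) are configuration inputs, not
re-derived per dataset.

## Synthetic data

The generator plants signal at the class-composition level: a background
profile (each class weighted by its residue count over an equiprobable
alphabet) and an "interactor" profile shifted from it by a chosen total
variation distance (`effect`), mass moving from the two largest classes to
the three smallest. Positive pairs draw both proteins from the interactor
profile; negative pairs mismatch one interactor protein with one
background protein. Residues are uniform within their class, lengths
uniform in the configured range, and one seed drives everything, so a
configuration regenerates byte-identical data. With `effect = 0` the
profiles coincide and labels carry no sequence information (the null
regime).

What the generator does *not* emulate: real proteins' domain structure,
positional motifs, phylogenetic correlation between sequences, shared
proteins across pairs, or sequence-identity filtering. Passing tests
therefore demonstrate that the pipeline recovers compositional interaction
signal and is calibrated under a compositional null — not that it attains
any particular accuracy on real interactome data.

## Evaluation problem sizes

The package's evaluation suite exercises the full pipeline at sizes chosen
for a single-CPU laptop-scale run: null calibration (effect 0) and signal
recovery (effect 0.3) at 160 pairs each with per-fold reducer training,
and the MultiEns-versus-MultiCon strategy comparison at 160 pairs under
the "split" leakage policy (64 reduction rows, 96 evaluation rows) with
matched seeds, since the width-292 monolithic reducer dominates runtime
if retrained per fold. Sequence lengths are 50-300 throughout, matching
the generator defaults.

## Degenerate inputs and numerical conventions

* Metric ratios with zero denominators (e.g. specificity on a
  positive-only test set) are reported as 0 and flagged; on single-class
  truth vectors AUC/AUPR are flagged as undefined.
* Sequences shorter than lag + 1 raise a lag error when encoded directly;
  the cross-dataset protocol instead skips such pairs and reports the
  skip count.
* Reducer inputs are float32; everything outside the GRU is float64.
* The stratified fold assignment, all reducer parameters, batch shuffling,
  and LightGBM are seeded; two runs with the same configuration and data
  produce identical reports.

## Known limitations

* The bit-reproducibility contract is per-platform; BLAS and fastmath
  differences across machines can change float32 results in the last few
  ulps (loss trajectories agree to ~1e-4 across the Numba and NumPy gate
  paths).
* Five epochs of univariate-sequence GRU training on a few hundred pairs
  leaves the reducers close to their initialization; they act mostly as
  seeded nonlinear projections with a supervised nudge. This matches the
  intended design at small scale but means reducer quality, not classifier
  quality, limits small-data performance.
* The packaged property table is synthetic (see above); published
  descriptor values should be substituted for scientific use.
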