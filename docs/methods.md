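# Methods

`oriseq` classifies fixed-length DNA windows (default 300 bp) as
replication-origin (ORI) windows versus flank windows. The method fuses
four feature views of each window, prunes the fused vector by
Shapley-value attribution, and classifies with a gradient-boosted tree
ensemble. This note records the model, its assumptions, the defaults and
why, and what the synthetic benchmarks do and do not demonstrate.

## Sequence model and benchmark geometry

Training data follow the standard ORI benchmark construction: positive
windows are fixed-length (300 bp) segments centred on mapped origins;
negative windows are cut from 300–600 bp up- or downstream flanks of the
same loci. The synthetic generator reproduces that geometry on simulated
loci. Per locus it draws one i.i.d. background segment (default uniform
base composition), re-draws the positive window under a skewed
composition, optionally plants a consensus motif at a uniform position,
and cuts the paired negative from a flank at a uniform offset in the
configured range, side chosen uniformly (the benchmark literature does
not state whether upstream/downstream flanks were balanced per positive;
a uniform coin is the least-informative choice and is documented here).
Coordinates are 0-based half-open; only relative offsets matter.

Two plantable signals are exposed because both are biologically
motivated for origins:

* `gc_skew_shift` *s*: positive windows use p(G) = 0.25 + s/2 and
  p(C) = 0.25 − s/2. GC *content* stays 0.5; only the strand asymmetry
  (GC skew), a classic origin-proximal signature, changes. Default 0.05;
  the benchmark used in tests and in the acceptance script uses 0.10.
* `motif` / `motif_rate`: an exact consensus (default `ACGTACGT`)
  planted in a fraction of positives (default 0.8), emulating a shared
  sequence element with incomplete penetrance.

With both signals at zero the two classes are exchangeable and every
downstream pipeline must score at chance; this null is tested.

What the generator does **not** emulate: chromatin context, replication
timing, repeat structure, nucleotide autocorrelation of real genomes,
species-specific composition, or label noise from imperfect origin
mapping. Passing the synthetic benchmarks therefore shows that the
pipeline recovers compositional and motif signals of realistic effect
size from 300-bp windows — not that it attains any particular accuracy
on real data.

## Feature views

**CKSNAP** — for each gap k ∈ {0..5}, the 16 pair frequencies
count(X·gapᵏ·Y)/(L−k−1), ordered AA..TT, sub-blocks concatenated in
ascending k. Each sub-block sums to exactly 1.

**PseDNC / PCPseDNC** — the 16 normalized dinucleotide frequencies f_m
augmented by λ sequence-order terms θ_j, where θ_j is the average over
positions of the mean squared difference, across μ physicochemical
indices, between the index profiles of dinucleotides j apart. The
(16+λ)-vector is normalized by 1 + wΣθ_j so it sums to 1. Defaults λ=2,
w=0.1 (the conventional values in the pseudo-composition family); μ=6
for PseDNC, μ=38 for PCPseDNC.

**DCC** — cross covariance of two *different* standardized indices at
dinucleotides lag apart, for all ordered distinct index pairs and lag ∈
1..LAG (default LAG=2, two-index default set). Output width is
n_idx·(n_idx−1)·LAG — the index-pair semantics standard in the
covariance-descriptor literature (the vector size is sometimes misprinted
with N read as "number of distinct nucleotides"; this package follows the
formula, not that reading). DCC is exactly zero on homopolymers and
invariant to adding a constant to a raw index.

**Index tables.** Indices are z-standardized across the 16 dinucleotides
(population SD; constant indices are rejected) before entering the θ and
DCC formulas, so both are scale-free. The packaged 6-index table holds
real nearest-neighbour thermodynamics (ΔH, ΔS, ΔG37 from the Breslauer
1986 and unified SantaLucia 1998 sets, as shipped with Biopython); the
packaged 38-index table is an explicitly *synthetic*, deterministic
stand-in that exercises the 38-index encoder at full width — substitute
your own TSV (`IndexTable.from_tsv`) to use a specific published
compilation. Because every table is standardized before use, the encoder
mathematics is identical either way.

**Deep features (DL)** — a compact neural classifier trained on the
training windows and then frozen as a feature extractor: six parallel
1-D convolution branches over one-hot input (kernel sizes 2–12, ReLU,
dropout 0.3), max-pooling along the sequence, two bidirectional GRU
stacks of different depth (one layer and two layers) run in parallel and
concatenated, a learned-query dot-product attention pool (weights are a
probability vector per sample), and a dense head with a single sigmoid
unit trained by cross-entropy with Adam (lr 1e-3), early stopping on a
seeded validation split. The exported "DL" block is the attention-pooled
vector (`penultimate_dense` is available). Ablation switches
(`use_attention=False`, `use_gru=False`) construct and train the reduced
architectures.

Implementation note: the network is a single-threaded numpy
implementation over a small reverse-mode autodiff tape inside the
package; the GRU and convolution run as fused ops with hand-written
backward passes, all verified against central finite differences in the
test suite. Max-pooling is applied to pre-activation maps (ReLU is
monotone, so `relu∘maxpool = maxpool∘relu`) purely for speed. Pooling
itself (default width 10) is this package's own design choice — it
shortens the sequence seen by the recurrent stacks roughly tenfold;
`pool=1` disables it.

## Fusion, attribution, selection

Blocks are concatenated in the fixed order DL, CKSNAP, PCPseDNC, DCC,
with a registry mapping each block to its column range (ablated subsets
keep the relative order). For a fitted XGBoost ensemble, per-sample
attributions are exact TreeSHAP values on the raw margin (log-odds), so
base value + Σ attributions reproduces the margin to numerical precision
— attribution on the margin rather than the probability is what makes
additivity exact for tree ensembles. For non-tree models a seeded
permutation-sampling estimator over a background sample (default 100
training rows) is used. Features are ranked by mean |attribution|
(descending, ties by ascending column), and the top_k form the selection
mask; default top_k = min(500, D), and top_k = D reproduces the
no-selection baseline exactly. The selector is always fitted on training
rows only and frozen before any validation or test row is touched. A
constant feature receives zero attribution (missingness). Block-level
sums of mean |attribution| provide the plot-ready importance summaries.

How many features the final classifier should keep is genuinely open
(display conventions show a top-20 ranking only); it is a configuration
knob, applied per-fold in cross-validation to avoid selection leakage.

## Classifier and hyperparameter search

The final classifier is a gradient-boosted decision-tree ensemble. The
method family was designed around an ordered-boosting engine (residuals
evaluated on examples unseen by earlier trees, avoiding prediction
shift); this build uses XGBoost as the engine, records the engine name
in the model bundle metadata, and treats ordered boosting as a property
of the engine, not something re-derived here. Defaults: 300 trees, depth
6, learning rate 0.1, L2 1.0, seeded and single-threaded for
determinism.

`tune_hyperparameters` implements the Bayesian-optimization loop:
declare a space (int / float / log-float / categorical dimensions;
default spans trees 100–1000, depth 4–10, lr 1e-3–0.3 log-uniform, L2
1–10), define a cross-validated objective (MCC by default — the headline
comparison metric in this literature), fit a Gaussian-process surrogate
to the unit-cube encodings of finished trials, acquire the next
candidate by expected improvement over 256 seeded candidates, and return
the best trial with the full log. The first 8 trials are random.

## Evaluation

Metrics: MCC, accuracy, sensitivity, specificity, AUC, F1, precision —
reported in that order. Conventions: any zero confusion marginal yields
0 (not NaN); AUC uses midranks for ties and refuses single-class labels;
threshold 0.5. Cross-validation is stratified 10-fold with a seeded
shuffle (fold construction is not standardized in this literature; a
fixed-seed stratified split is the reproducible choice), and everything
that learns is re-fitted per fold. Independent testing uses a stratified
20% held-out split, refitting on the full training split. The cross-cell
matrix trains one model per tagged dataset and reports accuracy on every
tag's independent split (training tag on rows).

## Problem sizes and numerical choices

The benchmarks the tests and `scripts/acceptance.py` run use 500 windows
per class, a six-branch extractor with 8 filters per branch, GRU widths
(6, 8), 5 training epochs for pipeline runs (12 when the extractor is
evaluated alone), and 200-tree classifiers; medians over 3 seeds are
reported for stochastic quantities. These sizes were chosen so a full
10-fold run of the complete pipeline is a minutes-scale, single-CPU
computation while leaving wide margins to the tested thresholds.
Encoder oracle comparisons use tolerance 1e-9, attribution additivity
1e-4 (float32 tree margins), index standardization 1e-9. Degenerate
inputs are rejected loudly rather than silently repaired: ambiguous
bases under the strict policy (the default; `drop` and seeded
`randomize` are available), single-class label vectors, λ or LAG too
large for the window, constant indices, NaN features.

## Known limitations

* The numpy extractor is CPU-bound and desk-scale; it is not a route to
  training on genome-scale corpora.
* XGBoost, not an ordered-boosting engine, backs the classifier; on
  small, noisy datasets conventional boosting can be more prone to
  prediction shift.
* The packaged 38-index table is a synthetic stand-in; results with it
  exercise the machinery, not any specific published property set.
* Synthetic benchmarks bound what the tests can claim about real ORI
  data (see above); the real-data headline numbers of this method family
  require external datasets and full-scale training, both outside this
  package's scope.
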