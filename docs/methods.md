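# Methods

## The problem this package models

An adaptive immune receptor repertoire (AIRR) is the collection of T-/B-cell
receptor sequences carried by one individual; here each repertoire is a set
of CDR3 amino-acid sequences (`junction_aa`). Repertoire classification asks
whether an individual's immune state (e.g. past exposure to an antigen) can
be predicted from their repertoire. The structure of the problem is multiple
instance learning: a positive-class repertoire contains a small fraction of
"witness" sequences that carry an immune-state–associated pattern; the
remaining sequences are background. The *witness rate* — the percent of
sequences per positive repertoire carrying the pattern — is the central
difficulty knob: realistic values run from 0.2% down to 0.001% (one witness
among 100,000 sequences).

Because ground-truth immune signals are unknown in experimental data, the
package builds fully synthetic benchmarks: background repertoires are
simulated, a known signal (a small set of k-mer motifs) is implanted at a
controlled witness rate, and classifiers are evaluated against that known
truth.

## Simulation model

**Background sequences.** The default generator draws sequence lengths from
a discretized Gaussian (mean 15, sd 2, clipped to [8, 23] amino acids — the
range of typical TCRβ CDR3 length profiles) and residues independently from
a configurable frequency vector (default uniform over the 20 standard amino
acids). Optional per-position overrides support terminal biases; the
"meta pool" source uses them (cysteine-biased starts, phenylalanine-biased
ends) so pooled repertoires are distributionally distinct from the fully
random source. V(D)J-recombination realism is explicitly *not* modeled;
sequences from an external recombination simulator can be imported verbatim
(plain text or AIRR TSV) and used as background repertoires. Consequences:
the synthetic background has no positional dependency structure or
amino-acid usage bias beyond what is configured, so results quantify signal
recoverability against an exchangeable background, not against the full
complexity of experimental repertoires.

**Signal.** A signal is 1–64 motifs of a common length k ∈ {2..5}, each
optionally containing one wildcard gap `*` at an interior position (drawn
once when the signal is constructed; a terminal gap would degenerate to a
shorter contiguous motif). At implantation time a gap is instantiated with
a uniformly drawn amino acid.

**Implantation.** The witness count per positive repertoire is
`round(rate/100 × size)` with half-away-from-zero rounding, applied
*exactly* (deterministically, not binomially): e.g. rate 0.005% × 100,000
sequences → exactly 5 witnesses. Witness sequences are drawn uniformly
without replacement, one implant each; the motif per witness is drawn
uniformly with replacement from the signal. The implant start position is
drawn uniformly among the IMGT junction positions 108–111 that admit the
motif; IMGT positions 105–111 map left-anchored (index = position − 105),
112–117 right-anchored, which preserves the germline-proximal flanks of
the loop. A motif may extend beyond position 111 (a 5-mer cannot fit inside
a 4-position window) but never beyond the sequence; if no window position
admits the motif for a drawn sequence, a replacement sequence is drawn.
Implantation overwrites residues in place, so repertoire size and all
sequence lengths are conserved. Every implant is recorded in a ground-truth
log; accidental creation of extra motif occurrences elsewhere is not
prevented and not logged.

**Labels.** `round(positive_fraction × n)` repertoires are labeled positive
and implanted at the witness rate; the rest are labeled negative and
implanted at the (default zero) noise rate. Noise implants never change a
label. Seeding is hierarchical (master seed → per-repertoire generation and
implantation seeds, all recorded in the dataset metadata), making every
dataset a pure function of its configuration and seed.

## Encoding

Repertoires are decomposed into overlapping contiguous k-mers summed over
sequences (default k = 4; 20⁴ = 160,000 possible 4-mers). Rows are
L2-normalized; since L2 normalization is scale-invariant, counts and
relative frequencies yield identical rows. The feature space defaults to
the k-mers observed in the encoded data (full 20^k optional); when encoding
against a fixed feature index (e.g. a test set against a training index),
unseen k-mers are dropped.

Standardization is a separate, fold-aware step fit on training rows only
(population sd, ddof = 0; zero-variance columns map to 0). Two variants are
provided: full mean-0/sd-1 standardization (the `Standardizer` default,
used for exported matrices and anywhere the interpretable centered scale
matters) and sparse-preserving variance scaling (`with_mean=False`). The
model pipelines use the sparse-preserving variant: for a linear model with
a free intercept, centering the columns is exactly an intercept
reparametrization, and keeping the ~160k-column matrix sparse makes the
L1 solver several-fold faster; it is also the standard treatment of sparse
design matrices (cf. `StandardScaler(with_mean=False)`). The liblinear
solver technically penalizes its intercept through an augmented feature; a
large `intercept_scaling` (100) keeps that penalty negligible so the two
formulations agree in practice (they were checked to produce the same
selected coefficients and CV accuracy at the grid's chosen C).

## Models and evaluation

The baseline is L1-penalized logistic regression: minimize the negative
log-likelihood L plus λ·Σ|β_j| with C = λ⁻¹ (scikit-learn's liblinear
implementation; iteration cap 500, non-convergence logged, not fatal).
Default C grid {0.05, 0.1, 1, 5}. Comparators: linear SVC with L1 or L2
penalty (same C grid and cap), random forest (tree grid {5, 10, 50, 100}),
and a feature-selection-aided classifier — per-feature two-sided
pooled-variance t-test on the training fold, retain features with
p < threshold, then an unpenalized logistic regression; if nothing
survives, an intercept-only majority predictor is used. The threshold is a
tuned hyperparameter; its default grid {1e-7, 1e-6, 1e-5, 1e-4} spans the
Bonferroni scale of the 10^4–10^6-feature k-mer spaces encoded here — a
lenient threshold such as 0.05 on 160,000 tests would retain thousands of
chance features and swamp the unpenalized model.

Performance estimation is 5×5 nested cross-validation, stratified by label
(required for the strongly imbalanced class-balance cells): the outer
5-fold (80% train / 20% test) wraps an inner 5-fold exhaustive grid search
that optimizes plain accuracy (a config switch optimizes balanced accuracy
instead, for sensitivity analysis); the reported metric is balanced
accuracy, ½(TP/(TP+FN) + TN/(TN+FP)), on the outer test folds. Grid ties
resolve to the smallest C (strongest regularization) or, for the
feature-selection model, the smallest threshold (fewest retained features).
Each benchmark cell is replicated on independently simulated datasets
(default 3, fresh signal and repertoires per replication) and reported as
mean ± sample sd.

Distributional-shift evaluation trains with the inner grid search on a full
training dataset, refits on all of it, and scores test datasets that share
the training signal but differ in witness rate; test sets are encoded with
the training feature index and standardizer.

## Diagnostics

*Disturbance testing* asks which k-mers' background frequency distributions
the implantation moved: per k-mer, a two-sided pooled-variance Student's
t-test compares per-repertoire relative frequencies (count / total k-mers —
the interpretable scale, before L2 or standardization) between classes,
followed by Benjamini–Hochberg correction across all tested k-mers
(significance at q < 0.05; a k-mer with zero variance in both groups gets
p = 1, and p = 0 in the degenerate zero-variance/different-means case).
Significant k-mers are stratified by their overlap with the implanted
motifs: overlap is k for identity, otherwise the longest m < k for which a
length-m prefix of one equals a length-m suffix of the other (the overlap
two adjacent windows of one sequence can share); for unequal lengths, full
containment of the shorter counts as its length; wildcard gaps match any
residue. The same overlap annotation is applied to the nonzero coefficients
of a fitted linear model, letting the univariate statistics and the model
weights be compared motif by motif.

The sparse-theory ratio s·log(p)/n (s expected nonzero coefficients,
p predictors, n minority-class training examples) uses the natural
logarithm (configurable via the `log_p` argument).

## Benchmark plan and scaling

`default_plan()` encodes the full published benchmark design: 17 rows
varying one property each (sample size, repertoire size, signal size and
shape, model feature size, class balance, negative-class noise, dataset
source, model family, and the sparse-theory grids), crossed with the
witness-rate list (0.001, 0.002, 0.005, 0.01, 0.05, 0.1, 0.2)% where
applicable, at 3 replications — 1,008 datasets and 248,550 repertoires in
total. `enumerate_plan` reproduces this bookkeeping exactly without
generating data. Rows that reuse data generated by other rows (the
distributional-shift row, the per-C regularization sweeps, the model
comparison) enumerate with zero or shared dataset counts and are executed
through the dedicated functions rather than the grid runner; the grid
runner simulates fresh datasets for every (value, rate) cell it runs.

The noise row implants the positive class at a fixed witness rate of
0.01% (the rate quoted with the corresponding results figure; an
alternative reading of the protocol gives 0.1% — configurable).

`run_benchmark` takes a scale factor in (0, 1] multiplying example counts
and repertoire sizes, with two modes: *proportional* (witness rates fixed;
faithful, but absolute implant counts shrink) and *witness-count-preserving*
(rates rescaled to keep the per-repertoire implant count of the unscaled
design; the mode used for desk-scale property checks, which are easier than
the full-scale design and labeled as such in outputs). Cells below 20
examples or 100 sequences per repertoire are rejected before any
simulation. `discretize_boundary` marks a cell adequate iff mean balanced
accuracy ≥ 0.7 and sd ≤ 0.1.

## Desk-scale study conditions used by the test suite

The full-scale design (200 repertoires × 100,000 sequences per dataset,
tens of millions of sequences per cell) is supported in principle but the
shipped tests run a desk-scale version: the *recovery cell* uses 100
repertoires × 2,000 sequences with three ungapped 4-mers at witness count
10 per positive repertoire (rate 0.5%), three replications; the null cell
is identical with witness count 0. The witness-count sweep {0, 1, 2, 5, 10}
uses two replications per count and the transfer grid tests counts
{2, 4, 10} against a model trained at count 2. At these sizes the L1
baseline recovers the implanted motifs as its top coefficients and reaches
balanced accuracy ≥ 0.9 on the recovery cell, while the null cell stays at
chance — the desk-scale analogue of the published behavior. Passing these
tests demonstrates correct mechanics and signal recovery against the
simplified background; it does not certify performance on experimental
repertoires with real positional and usage biases.

## Numerical choices and limitations

- Half-away-from-zero rounding for witness counts (an exact stated count,
  not a sampled one).
- Population (ddof = 0) sd in the standardizer; sample (ddof = 1) sd when
  summarizing replications.
- liblinear with seed-derived `random_state` everywhere; results are pure
  functions of (configuration, master seed).
- BH adjustment delegates to statsmodels; the t-test statistic is computed
  vectorized (sparse-aware) and the t distribution comes from scipy.
- Known limitations: no clone-count/abundance modeling (unique sequences
  only), no nucleotide level, one signal per dataset, no insertion-style
  implantation (lengths conserved), background realism limited to
  configurable length/residue/terminal-position distributions.
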