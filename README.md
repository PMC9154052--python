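# airrbench

Synthetic benchmarks for machine-learning classification of adaptive immune
receptor repertoires (AIRRs).

Predicting an individual's immune state from their repertoire of T-/B-cell
receptor CDR3 sequences is a multiple-instance learning problem: a
positive-class repertoire contains a small fraction of "witness" sequences
carrying an immune-state–associated pattern, buried among up to hundreds of
thousands of background sequences. Because real immune signals are unknown,
method development needs benchmarks with *known* ground truth. airrbench
builds them end to end:

- **simulate** CDR3-like amino-acid repertoires (configurable length and
  residue distributions, pooled/meta and subsampled sources, import hook
  for externally generated sequences, AIRR Rearrangement TSV I/O);
- **implant** a signal of k-mer motifs (2–5 residues, optionally with one
  wildcard gap `*`) at an exact witness rate inside IMGT junction positions
  108–111, with a complete ground-truth implant log;
- **encode** repertoires as L2-normalized k-mer frequency matrices with
  leakage-safe train-fold standardization;
- **train and evaluate** sparse classifiers under 5×5 nested
  cross-validation — the baseline is L1-penalized logistic regression,
  minimizing the negative log-likelihood L plus λ·Σ|β_j| with C = λ⁻¹
  (grid {0.05, 0.1, 1, 5}), with linear SVC (L1/L2), random forest and a
  t-test feature-selection classifier as comparators — reporting balanced
  accuracy ½(TP/(TP+FN) + TN/(TN+FP)) as mean ± sd over replications;
- **diagnose** what was learned: per-k-mer disturbance t-tests with
  Benjamini–Hochberg correction (q < 0.05), overlap stratification against
  the implanted motifs, coefficient tables, and the sparse-theory
  sample-complexity ratio s·log(p)/n;
- **orchestrate** the full benchmark grid (1,008 datasets across 17
  property rows; exact bookkeeping via `enumerate_plan`) with a scale knob
  for desk-size runs and a boundary map (mean ≥ 0.7 AND sd ≤ 0.1).

See `docs/methods.md` for the model, its assumptions and its limits.

## Worked example

Implant three 4-mers in 10 of 2,000 sequences (witness rate 0.5%) of each
positive repertoire, train the baseline, and check it found the truth:

```python
import airrbench as ab

signal = ab.Signal((ab.Motif("LDGY"), ab.Motif("WQPF"), ab.Motif("AECN")))
spec = ab.ImplantingSpec(witness_rate=0.5)  # percent => 10 witnesses / 2,000
dataset = ab.build_labeled_dataset(
    n_examples=100, repertoire_size=2000, signal=signal, spec=spec, seed=7
)
encoded = ab.encode_dataset(dataset, k=4)
result = ab.nested_cv(encoded, ab.TrainingConfig(seed=7), y=dataset.labels,
                      return_models=True)
print(result.mean_balanced_accuracy)
table = ab.coefficient_overlap_table(result.models[0], encoded.feature_index,
                                     signal.motifs)
```

Output:

```
100 repertoires, 50 positive, 500 implants logged
feature matrix: 100 x 160000 observed 4-mers
mean balanced accuracy: 1.000
chosen C per outer fold: [0.1, 0.05, 0.1, 0.05, 0.05]
kmer  coefficient  overlap
WQPF     0.869474        4
LDGY     0.671550        4
AECN     0.506008        4
BH-significant 4-mers: 3 (implanted motifs among them: ['AECN', 'LDGY', 'WQPF'])
```

The model classifies the repertoires perfectly, its only nonzero
coefficients are exactly the three implanted motifs (overlap 4 = identity),
and the independent univariate disturbance test flags the same three
4-mers — the two diagnostics agree on what the signal was.

A command-line interface mirrors the library
(`airrbench simulate|implant|encode|train|run-experiment|diagnose|plan-stats`),
taking YAML configs plus `--seed`, `--scale` and `--outdir`.

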