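"""Statistical and model-introspection diagnostics.

Two independent views of what a trained model should have learned:

* *disturbance testing* — a per-k-mer two-sample Student's t-test comparing
  the per-repertoire relative k-mer frequencies of the positive and
  negative classes, Benjamini–Hochberg corrected across all k-mers
  (significance at q < 0.05), with each significant k-mer stratified by how
  much it overlaps an implanted ground-truth motif;
* *coefficient inspection* — the nonzero coefficients of a fitted linear
  model annotated with the same overlap levels.

Also provides the sparse-model sample-complexity ratio s·log(p)/n used to
relate empirical performance to sparse recovery theory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from statsmodels.stats.multitest import multipletests

from .features import FeatureIndex, encode_dataset
from .models import two_sample_ttest
from .signals import GAP, LabeledRepertoireDataset, Motif

__all__ = [
    "DisturbanceResult",
    "SampleComplexityPoint",
    "motif_overlap",
    "bh_adjust",
    "disturbance_test",
    "overlap_stratified_counts",
    "coefficient_overlap_table",
    "sample_complexity_ratio",
]


def _match(a: str, b: str) -> bool:
    """Character-wise equality where the gap wildcard matches anything."""
    return all(x == y or x == GAP or y == GAP for x, y in zip(a, b))


def motif_overlap(kmer_a: str, kmer_b: str) -> int:
    """Largest shift-overlap between two k-mers (0..k).

    Returns k when identical; otherwise the largest m < k such that a
    length-m prefix of one equals a length-m suffix of the other — the
    longest overlap that could arise from two adjacent windows over one
    sequence.  For unequal lengths, full containment of the shorter in the
    longer counts as overlap equal to the shorter length.  Wildcard gaps
    match any residue.
    """
    kmer_a, kmer_b = str(kmer_a), str(kmer_b)
    la, lb = len(kmer_a), len(kmer_b)
    if la != lb:
        short, long_ = (kmer_a, kmer_b) if la < lb else (kmer_b, kmer_a)
        if any(
            _match(short, long_[i : i + len(short)])
            for i in range(len(long_) - len(short) + 1)
        ):
            return len(short)
    elif _match(kmer_a, kmer_b):
        return la
    for m in range(min(la, lb) - 1, 0, -1):
        if _match(kmer_a[-m:], kmer_b[:m]) or _match(kmer_b[-m:], kmer_a[:m]):
            return m
    return 0


def max_motif_overlap(kmer: str, motifs) -> int:
    patterns = [m.pattern if isinstance(m, Motif) else str(m) for m in motifs]
    return max((motif_overlap(kmer, p) for p in patterns), default=0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DisturbanceResult:
    """Per-k-mer disturbance test table.

    ``table`` columns: ``kmer``, ``t``, ``p``, ``q``, ``significant``
    (q < threshold) and ``overlap`` (0..k vs the implanted motifs).
    """

    table: pd.DataFrame
    k: int
    q_threshold: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def disturbance_test(
    dataset: LabeledRepertoireDataset,
    k: int = 4,
    implanted_motifs=None,
    q_threshold: float = 0.05,
) -> DisturbanceResult:
    """Test every observed k-mer for a class difference in frequency.

    Frequencies are per-repertoire relative k-mer frequencies (count over
    total k-mers in the repertoire) — the interpretable scale, before any
    L2 normalization or standardization.  One two-sided pooled-variance
    t-test per k-mer, BH correction across all tested k-mers.
    """
    labels = np.asarray(dataset.labels, dtype=int)
    pos_mask = labels == 1
    if pos_mask.sum() < 2 or (~pos_mask).sum() < 2:
        raise ValueError("each class needs at least 2 repertoires")
    if implanted_motifs is None and dataset.signal is not None:
        implanted_motifs = dataset.signal.motifs
    implanted_motifs = implanted_motifs or ()

    encoded = encode_dataset(dataset, k, normalize=False)
    counts = encoded.values.tocsr()
    totals = np.asarray(counts.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    freqs = counts.multiply(1.0 / totals[:, None]).tocsr()

    t, p = two_sample_ttest(freqs, pos_mask)
    q = bh_adjust(p)
    significant = q < q_threshold
    kmers = list(encoded.feature_index.kmers)
    overlaps = np.fromiter(
        (max_motif_overlap(km, implanted_motifs) for km in kmers),
        dtype=int,
        count=len(kmers),
    )
    table = pd.DataFrame(
        {
            "kmer": kmers,
            "t": t,
            "p": p,
            "q": q,
            "significant": significant,
            "overlap": overlaps,
        }
    )
    return DisturbanceResult(table=table, k=k, q_threshold=q_threshold)


def overlap_stratified_counts(
    result: DisturbanceResult, n_implanted: int
) -> pd.Series:
    """Significant k-mers per overlap level, scaled per implanted motif."""
    if n_implanted < 1:
        raise ValueError("n_implanted must be >= 1")
    sig = result.significant
    counts = (
        sig.groupby("overlap").size().reindex(range(result.k + 1), fill_value=0)
    )
    return counts / n_implanted


def coefficient_overlap_table(
    model, feature_index: FeatureIndex, implanted_motifs
) -> pd.DataFrame:
    """Nonzero linear-model coefficients annotated with motif overlap."""
    if isinstance(model, Pipeline):
        model = model.named_steps["clf"]
    coef = getattr(model, "coef_", None)
    if coef is None:
        raise ValueError("coefficient table requires a fitted linear model")
    coef = np.asarray(coef).ravel()
    if coef.size != len(feature_index):
        raise ValueError("coefficient vector does not match the feature index")
    nonzero = np.flatnonzero(coef)
    kmers = [feature_index.kmer(int(j)) for j in nonzero]
    return pd.DataFrame(
        {
            "kmer": kmers,
            "coefficient": coef[nonzero],
            "overlap": [max_motif_overlap(km, implanted_motifs) for km in kmers],
        }
    )


@dataclass(frozen=True)
class SampleComplexityPoint:
    """One cell of the sparse-theory s·log(p)/n grid.

    ``n`` — minority-class training examples; ``p`` — total predictors;
    ``s`` — expected nonzero coefficients (number of implanted motifs).
    """

    n: int
    p: int
    s: int

    def __post_init__(self) -> None:
        if self.n <= 0 or self.p <= 0 or self.s < 0:
            raise ValueError("n and p must be positive; s non-negative")

    @property
    def ratio(self) -> float:
        return sample_complexity_ratio(self.s, math.log(self.p), self.n)


def sample_complexity_ratio(s: float, log_p: float, n: float) -> float:
    """s·log(p)/n, the sparse-model sample-complexity ratio."""
    if n <= 0:
        raise ValueError("n must be positive")
    return s * log_p / n
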