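"""k-mer frequency encoding of repertoires.

Each repertoire is decomposed into overlapping contiguous k-mers summed
over all its sequences; the resulting count vector is L2-normalized (note
that L2-normalizing raw counts and L2-normalizing relative frequencies give
the same vector, so no explicit division by the total is needed).  Feature
columns are, by default, the k-mers observed in the encoded data, in
lexicographic order; the full 20^k space is available as an option.
Standardization (mean 0 / sd 1 per column) is a separate, fold-aware step:
it must be fit on training rows only and then applied to held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import normalize as _sk_normalize

from .repertoires import AMINO_ACIDS, Repertoire, _CODE_LUT

__all__ = [
    "FeatureIndex",
    "FeatureMatrix",
    "kmer_counts",
    "l2_normalize",
    "encode_dataset",
    "Standardizer",
    "fit_standardizer",
    "apply_standardizer",
]

_N_AA = len(AMINO_ACIDS)
_SEPARATOR_CODE = _N_AA  # marks sequence boundaries in the concatenated code array


def _sequence_kmer_ids(sequences: list[str], k: int) -> np.ndarray:
    """Integer ids (base-20 codes) of all overlapping k-mers in a repertoire.

    Sequences shorter than ``k`` contribute nothing.  Raises on residues
    outside the 20-letter alphabet.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not sequences:
        return np.empty(0, dtype=np.int64)
    joined = "\n".join(sequences).encode("ascii")
    raw = np.frombuffer(joined, dtype=np.uint8)
    codes = _CODE_LUT[raw].astype(np.int64)
    codes[raw == ord("\n")] = _SEPARATOR_CODE
    if (codes == 255).any():
        bad = chr(raw[codes == 255][0])
        raise ValueError(f"unknown residue {bad!r} in sequences")
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    ids = np.zeros(n - k + 1, dtype=np.int64)
    crosses_boundary = np.zeros(n - k + 1, dtype=bool)
    for j in range(k):
        window = codes[j : n - k + 1 + j]
        ids = ids * _N_AA + window
        crosses_boundary |= window == _SEPARATOR_CODE
    return ids[~crosses_boundary]


def _id_to_kmer(kmer_id: int, k: int) -> str:
    letters = []
    for _ in range(k):
        kmer_id, rem = divmod(kmer_id, _N_AA)
        letters.append(AMINO_ACIDS[rem])
    return "".join(reversed(letters))


def _kmer_to_id(kmer: str) -> int:
    value = 0
    for ch in kmer:
        value = value * _N_AA + AMINO_ACIDS.index(ch)
    return value


@dataclass(frozen=True)
class FeatureIndex:
    """Bijective ordered mapping k-mer string → column id."""

    kmers: tuple[str, ...]
    k: int

    def __post_init__(self) -> None:
        if any(len(km) != self.k for km in self.kmers):
            raise ValueError(f"all index k-mers must have length {self.k}")
        if len(set(self.kmers)) != len(self.kmers):
            raise ValueError("feature index must be bijective (duplicate k-mers)")

    @classmethod
    def from_kmers(cls, kmers, k: int | None = None) -> "FeatureIndex":
        kmers = tuple(kmers)
        if k is None:
            if not kmers:
                raise ValueError("cannot infer k from an empty index")
            k = len(kmers[0])
        return cls(kmers=kmers, k=k)

    @classmethod
    def full(cls, k: int) -> "FeatureIndex":
        """All 20^k possible k-mers, lexicographically ordered."""
        kmers = tuple(_id_to_kmer(i, k) for i in range(_N_AA**k))
        return cls(kmers=kmers, k=k)

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self._mapping

    @property
    def _mapping(self) -> dict[str, int]:
        # built lazily; frozen dataclass, so cache on the instance dict
        cached = self.__dict__.get("_mapping_cache")
        if cached is None:
            cached = {km: i for i, km in enumerate(self.kmers)}
            self.__dict__["_mapping_cache"] = cached
        return cached

    @property
    def _ids(self) -> np.ndarray:
        cached = self.__dict__.get("_ids_cache")
        if cached is None:
            cached = np.array([_kmer_to_id(km) for km in self.kmers], dtype=np.int64)
            self.__dict__["_ids_cache"] = cached
        return cached

    def column(self, kmer: str) -> int:
        return self._mapping[kmer]

    def kmer(self, column: int) -> str:
        return self.kmers[column]


@dataclass
class FeatureMatrix:
    """Examples × k-mer features matrix with its feature index."""

    values: sp.csr_matrix
    row_ids: list[str]
    feature_index: FeatureIndex
    l2_normalized: bool = False
    standardized: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def kmer_counts(repertoire: Repertoire | list[str], k: int) -> dict[str, int]:
    """Count every overlapping k-mer summed over all sequences."""
    sequences = (
        repertoire.sequences if isinstance(repertoire, Repertoire) else list(repertoire)
    )
    ids = _sequence_kmer_ids(sequences, k)
    uniq, counts = np.unique(ids, return_counts=True)
    return {_id_to_kmer(int(i), k): int(c) for i, c in zip(uniq, counts)}


def l2_normalize(vector: np.ndarray) -> np.ndarray:
    """Scale to unit Euclidean norm; the zero vector maps to itself."""
    v = np.asarray(vector, dtype=float)
    norm = np.linalg.norm(v)
    return v if norm == 0 else v / norm


def encode_dataset(
    dataset,
    k: int,
    feature_index: FeatureIndex | None = None,
    full_space: bool = False,
    normalize: bool = True,
) -> FeatureMatrix:
    """Encode repertoires as L2-normalized k-mer frequency rows.

    ``dataset`` may be a :class:`LabeledRepertoireDataset` or a list of
    :class:`Repertoire`.  With no ``feature_index`` the columns are the
    union of k-mers observed in the encoded data (or all 20^k with
    ``full_space=True``); with an index, k-mers absent from it are dropped.
    """
    repertoires = getattr(dataset, "repertoires", dataset)
    per_rep: list[tuple[np.ndarray, np.ndarray]] = []
    for rep in repertoires:
        ids = _sequence_kmer_ids(rep.sequences, k)
        uniq, counts = np.unique(ids, return_counts=True)
        per_rep.append((uniq, counts))

    if feature_index is not None:
        if feature_index.k != k:
            raise ValueError("feature index was built for a different k")
        index = feature_index
        # map observed ids into the (possibly unsorted) index column order
        index_ids = index._ids
        order = np.argsort(index_ids, kind="stable")
        sorted_ids = index_ids[order]
    elif full_space:
        index = FeatureIndex.full(k)
        sorted_ids = index._ids
        order = np.arange(len(index))
    else:
        observed = (
            np.unique(np.concatenate([u for u, _ in per_rep]))
            if per_rep
            else np.empty(0, dtype=np.int64)
        )
        index = FeatureIndex.from_kmers(
            tuple(_id_to_kmer(int(i), k) for i in observed), k
        )
        sorted_ids = observed
        order = np.arange(len(index))

    rows, cols, vals = [], [], []
    for row, (uniq, counts) in enumerate(per_rep):
        pos = np.searchsorted(sorted_ids, uniq)
        pos = np.clip(pos, 0, max(len(sorted_ids) - 1, 0))
        known = (
            (sorted_ids[pos] == uniq) if len(sorted_ids) else np.zeros_like(uniq, bool)
        )
        cols.append(order[pos[known]])
        vals.append(counts[known])
        rows.append(np.full(int(known.sum()), row))

    n_rows = len(per_rep)
    matrix = sp.csr_matrix(
        (
            np.concatenate(vals) if vals else [],
            (np.concatenate(rows) if rows else [], np.concatenate(cols) if cols else []),
        ),
        shape=(n_rows, len(index)),
        dtype=float,
    )
    if normalize:
        matrix = _sk_normalize(matrix, norm="l2", copy=False)
    return FeatureMatrix(
        values=matrix,
        row_ids=[rep.repertoire_id for rep in repertoires],
        feature_index=index,
        l2_normalized=normalize,
    )


class Standardizer(TransformerMixin, BaseEstimator):
    """Per-column standardization fit on training rows only.

    Uses the population (ddof=0) standard deviation; zero-variance columns
    transform to 0.  With ``with_mean=True`` (default) the output is dense
    with column mean 0 and sd 1.  With ``with_mean=False`` columns are only
    scaled to unit variance and sparsity is preserved — the standard
    treatment of sparse matrices; for a linear model with a free intercept
    the two are equivalent up to an intercept reparametrization.
    """

    def __init__(self, with_mean: bool = True):
        self.with_mean = with_mean

    def fit(self, X, y=None):
        X = X.values if isinstance(X, FeatureMatrix) else X
        if X.shape[0] < 2:
            raise ValueError("standardizer needs at least 2 training rows")
        if sp.issparse(X):
            mean = np.asarray(X.mean(axis=0)).ravel()
            mean_sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
        else:
            X = np.asarray(X, dtype=float)
            mean = X.mean(axis=0)
            mean_sq = (X**2).mean(axis=0)
        var = np.clip(mean_sq - mean**2, 0.0, None)
        self.mean_ = mean
        self.scale_ = np.sqrt(var)
        return self

    def transform(self, X):
        X = X.values if isinstance(X, FeatureMatrix) else X
        if not self.with_mean:
            inv = np.where(self.scale_ > 0, 1.0 / np.where(self.scale_ > 0, self.scale_, 1.0), 0.0)
            if sp.issparse(X):
                return (X @ sp.diags(inv)).tocsr()
            return np.asarray(X, dtype=float) * inv
        dense = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
        centered = dense - self.mean_
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(self.scale_ > 0, centered / self.scale_, 0.0)
        return out


def fit_standardizer(train_matrix) -> Standardizer:
    return Standardizer().fit(train_matrix)


def apply_standardizer(standardizer: Standardizer, matrix) -> np.ndarray:
    return standardizer.transform(matrix)
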