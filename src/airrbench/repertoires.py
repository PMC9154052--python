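"""Synthetic CDR3-like amino-acid repertoire generation.

A repertoire is a list of junction amino-acid sequences (``junction_aa``
semantics) belonging to one individual.  Repertoires can be generated from
several sources:

* ``random`` — independent residues drawn from a configurable residue
  frequency vector, with lengths drawn from a configurable length
  distribution (default: discretized Gaussian, mean 15, sd 2, clipped to
  [8, 23], which is in the range of typical TCRβ CDR3 length profiles);
* ``meta_pool`` — uniform samples without replacement from a large pooled
  collection of sequences (a surrogate for pooling experimentally observed
  CDR3s across donors);
* ``subsampled`` — a uniform subsample of an existing repertoire;
* ``imported`` — sequences read from plain text or AIRR TSV, so output of
  external V(D)J-recombination generators can be used verbatim.

All generators are pure functions of their parameters and an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "LengthDistribution",
    "SequenceModel",
    "Repertoire",
    "sample_length",
    "sample_lengths",
    "generate_sequence",
    "generate_repertoire",
    "build_meta_pool",
    "build_meta_repertoires",
    "subsample_repertoire",
    "imgt_start_index",
]

#: The 20 standard amino acids, in alphabetical one-letter-code order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_N_AA = len(AMINO_ACIDS)
_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)

# Lookup from byte value to residue code; 255 flags a non-alphabet byte.
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _aa in enumerate(AMINO_ACIDS):
    _CODE_LUT[ord(_aa)] = _i


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class LengthDistribution:
    """Discrete distribution over sequence lengths (in amino acids)."""

    support: tuple[int, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.support) == 0:
            raise ConfigurationError("length distribution support is empty")
        if len(self.support) != len(self.probabilities):
            raise ConfigurationError("support and probabilities differ in length")
        if any(l < 1 for l in self.support):
            raise ConfigurationError("all lengths must be >= 1")
        if any(p < 0 for p in self.probabilities):
            raise ConfigurationError("probabilities must be non-negative")
        if abs(sum(self.probabilities) - 1.0) > 1e-9:
            raise ConfigurationError("probabilities must sum to 1 within 1e-9")

    @classmethod
    def default(
        cls,
        mean: float = 15.0,
        sd: float = 2.0,
        min_length: int = 8,
        max_length: int = 23,
    ) -> "LengthDistribution":
        """Discretized Gaussian over ``[min_length, max_length]``."""
        support = tuple(range(min_length, max_length + 1))
        weights = np.array(
            [math.exp(-((l - mean) ** 2) / (2.0 * sd**2)) for l in support]
        )
        probs = weights / weights.sum()
        return cls(support=support, probabilities=tuple(probs))

    @classmethod
    def point_mass(cls, length: int) -> "LengthDistribution":
        return cls(support=(length,), probabilities=(1.0,))

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.probabilities))

    @property
    def variance(self) -> float:
        m = self.mean
        return float(np.dot((np.asarray(self.support) - m) ** 2, self.probabilities))


def _uniform_frequencies() -> np.ndarray:
    return np.full(_N_AA, 1.0 / _N_AA)


@dataclass(frozen=True)
class SequenceModel:
    """Generative model for individual CDR3-like amino-acid sequences.

    Residues are drawn independently from ``residue_frequencies``;
    ``positional_frequencies`` optionally overrides the residue distribution
    at specific positions (non-negative keys count from the sequence start,
    negative keys from the end, as in Python indexing).  This is how the
    pooled "meta" source acquires positional biases distinguishing it from
    the fully random source.
    """

    residue_frequencies: tuple[float, ...] = field(
        default_factory=lambda: tuple(_uniform_frequencies())
    )
    length_distribution: LengthDistribution = field(
        default_factory=LengthDistribution.default
    )
    source_kind: str = "random"
    positional_frequencies: tuple[tuple[int, tuple[float, ...]], ...] = ()

    def __post_init__(self) -> None:
        freqs = np.asarray(self.residue_frequencies, dtype=float)
        if freqs.shape != (_N_AA,):
            raise ConfigurationError(
                f"residue_frequencies must have {_N_AA} entries (one per amino acid)"
            )
        if abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
            raise ConfigurationError("residue_frequencies must be a probability vector")
        for pos, pf in self.positional_frequencies:
            pfa = np.asarray(pf, dtype=float)
            if pfa.shape != (_N_AA,) or abs(pfa.sum() - 1.0) > 1e-9 or (pfa < 0).any():
                raise ConfigurationError(
                    f"positional frequencies at {pos} must be a length-{_N_AA} "
                    "probability vector"
                )
        if self.source_kind not in {"random", "meta_pool", "imported", "subsampled"}:
            raise ConfigurationError(f"unknown source_kind {self.source_kind!r}")


@dataclass
class Repertoire:
    """A set of junction amino-acid sequences with provenance."""

    sequences: list[str]
    repertoire_id: str
    seed: int
    source_kind: str = "random"

    def __len__(self) -> int:
        return len(self.sequences)


def sample_lengths(
    dist: LengthDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    return rng.choice(
        np.asarray(dist.support), size=n, p=np.asarray(dist.probabilities)
    )


def sample_length(dist: LengthDistribution, rng: np.random.Generator) -> int:
    """Draw one sequence length from ``dist``."""
    return int(sample_lengths(dist, 1, rng)[0])


def _generate_codes(
    lengths: np.ndarray, model: SequenceModel, rng: np.random.Generator
) -> np.ndarray:
    total = int(lengths.sum())
    codes = rng.choice(
        _N_AA, size=total, p=np.asarray(model.residue_frequencies)
    ).astype(np.uint8)
    if model.positional_frequencies:
        starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
        for pos, pf in model.positional_frequencies:
            if pos >= 0:
                valid = lengths > pos
                idx = starts[valid] + pos
            else:
                valid = lengths >= -pos
                idx = starts[valid] + lengths[valid] + pos
            if idx.size:
                codes[idx] = rng.choice(_N_AA, size=idx.size, p=np.asarray(pf))
    return codes


def _codes_to_strings(codes: np.ndarray, lengths: np.ndarray) -> list[str]:
    buf = _AA_BYTES[codes].tobytes()
    out = []
    offset = 0
    for length in lengths:
        out.append(buf[offset : offset + length].decode("ascii"))
        offset += length
    return out


def generate_sequence(
    length: int, model: SequenceModel | None = None, rng: np.random.Generator | None = None
) -> str:
    """Generate one amino-acid string of exactly ``length`` residues."""
    if length < 1:
        raise ValueError("sequence length must be >= 1")
    model = model or SequenceModel()
    rng = rng if rng is not None else np.random.default_rng(0)
    lengths = np.array([length])
    return _codes_to_strings(_generate_codes(lengths, model, rng), lengths)[0]


def generate_repertoire(
    model: SequenceModel | None = None,
    size: int = 100_000,
    repertoire_id: str = "repertoire",
    seed: int = 0,
) -> Repertoire:
    """Generate a repertoire of ``size`` sequences (default 100,000).

    Deterministic: the same ``(model, size, seed)`` always yields the same
    repertoire.
    """
    if size < 1:
        raise ValueError("repertoire size must be >= 1")
    model = model or SequenceModel()
    rng = np.random.default_rng(seed)
    lengths = sample_lengths(model.length_distribution, size, rng)
    sequences = _codes_to_strings(_generate_codes(lengths, model, rng), lengths)
    return Repertoire(
        sequences=sequences,
        repertoire_id=repertoire_id,
        seed=seed,
        source_kind=model.source_kind,
    )


def biased_pool_model(
    length_distribution: LengthDistribution | None = None,
) -> SequenceModel:
    """Positionally biased sequence model used for the pooled meta source.

    CDR3 junctions carry strong germline-encoded biases at their termini
    (canonically starting with a cysteine and ending with phenylalanine or
    tryptophan).  The pool model mimics that: the first two and last two
    positions use skewed residue distributions so the meta source is
    distributionally distinct from the uniform random source.
    """

    def skew(letter_weights: dict[str, float]) -> tuple[float, ...]:
        remaining = 1.0 - sum(letter_weights.values())
        base = remaining / (_N_AA - len(letter_weights))
        freqs = np.full(_N_AA, base)
        for letter, w in letter_weights.items():
            freqs[AMINO_ACIDS.index(letter)] = w
        return tuple(freqs)

    return SequenceModel(
        length_distribution=length_distribution or LengthDistribution.default(),
        source_kind="meta_pool",
        positional_frequencies=(
            (0, skew({"C": 0.90})),
            (1, skew({"A": 0.55, "S": 0.25})),
            (-2, skew({"Y": 0.35, "E": 0.15})),
            (-1, skew({"F": 0.80, "W": 0.12})),
        ),
    )


def build_meta_pool(pool_size: int = 1_000_000, seed: int = 0) -> list[str]:
    """Generate the default pooled sequence collection for the meta source."""
    rep = generate_repertoire(
        biased_pool_model(), size=pool_size, repertoire_id="meta_pool", seed=seed
    )
    return rep.sequences


def build_meta_repertoires(
    pool: list[str], n_repertoires: int, size: int, seed: int = 0
) -> list[Repertoire]:
    """Sample repertoires uniformly (without replacement) from a pool."""
    if len(pool) < size:
        raise ValueError(
            f"pool of {len(pool)} sequences cannot supply repertoires of size {size}"
        )
    seeds = _spawn_seeds(seed, n_repertoires)
    out = []
    for i in range(n_repertoires):
        rng = np.random.default_rng(seeds[i])
        idx = rng.choice(len(pool), size=size, replace=False)
        out.append(
            Repertoire(
                sequences=[pool[j] for j in idx],
                repertoire_id=f"meta_{i:04d}",
                seed=int(seeds[i]),
                source_kind="meta_pool",
            )
        )
    return out


def subsample_repertoire(rep: Repertoire, target_size: int, seed: int = 0) -> Repertoire:
    """Uniform subsample without replacement down to ``target_size``."""
    if target_size > len(rep):
        raise ValueError(
            f"target size {target_size} exceeds repertoire size {len(rep)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rep), size=target_size, replace=False)
    return Repertoire(
        sequences=[rep.sequences[j] for j in idx],
        repertoire_id=f"{rep.repertoire_id}_sub{target_size}",
        seed=seed,
        source_kind="subsampled",
    )


def imgt_start_index(seq_length: int, imgt_pos: int) -> int:
    """Map an IMGT junction position (105–117) to a 0-based sequence index.

    CDR3 loops vary in length, so IMGT numbering places gaps in the loop
    middle: positions 105–111 are anchored at the left end of the sequence
    (index = position − 105) and positions 112–117 at the right end
    (index = length − (118 − position)).  Motif implantation only uses
    108–111, i.e. the left-anchored branch.
    """
    if not 105 <= imgt_pos <= 117:
        raise ValueError(f"IMGT position {imgt_pos} outside the CDR3 range 105..117")
    if imgt_pos <= 111:
        index = imgt_pos - 105
    else:
        index = seq_length - (118 - imgt_pos)
    if index < 0 or index >= seq_length:
        raise ValueError(
            f"IMGT position {imgt_pos} does not resolve inside a sequence of "
            f"length {seq_length}"
        )
    return index


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` child seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]
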