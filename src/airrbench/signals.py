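"""Immune-signal definition and k-mer motif implantation.

The immune state–associated signal is a small set of short amino-acid
motifs (k-mers, optionally containing one wildcard gap ``*``).  A labeled
benchmark dataset is built by implanting the signal into a fraction of the
sequences of each positive-class repertoire — the *witness rate*, expressed
as a percent of the repertoire size — inside the middle of the CDR3 loop
(IMGT positions 108–111) so the germline-encoded flanks are untouched.
Negative-class repertoires optionally receive the same signal at a lower
*noise rate* without flipping their label.

Every implant is recorded in a ground-truth log used by the diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .repertoires import (
    AMINO_ACIDS,
    Repertoire,
    SequenceModel,
    generate_repertoire,
    imgt_start_index,
    _spawn_seeds,
)

__all__ = [
    "GAP",
    "Motif",
    "Signal",
    "ImplantingSpec",
    "ImplantRecord",
    "LabeledRepertoireDataset",
    "random_signal",
    "witness_count",
    "instantiate_motif",
    "implant_in_sequence",
    "implant_signal",
    "build_labeled_dataset",
]

#: Wildcard gap character: any amino acid with equal probability.
GAP = "*"

DEFAULT_IMGT_WINDOW: tuple[int, ...] = (108, 109, 110, 111)


@dataclass(frozen=True)
class Motif:
    """A short motif over the amino-acid alphabet plus an optional gap.

    The gap counts toward the motif length; at most one gap is allowed, and
    it must sit at an interior position (a terminal gap would degenerate to
    a shorter contiguous motif).
    """

    pattern: str

    def __post_init__(self) -> None:
        if not 2 <= len(self.pattern) <= 5:
            raise ValueError(f"motif length must be in 2..5, got {self.pattern!r}")
        n_gaps = self.pattern.count(GAP)
        if n_gaps > 1:
            raise ValueError(f"at most one gap allowed per motif: {self.pattern!r}")
        if n_gaps and (self.pattern[0] == GAP or self.pattern[-1] == GAP):
            raise ValueError(f"gap must be interior: {self.pattern!r}")
        for ch in self.pattern:
            if ch != GAP and ch not in AMINO_ACIDS:
                raise ValueError(f"invalid motif character {ch!r} in {self.pattern!r}")

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def has_gap(self) -> bool:
        return GAP in self.pattern


@dataclass(frozen=True)
class Signal:
    """A set of same-length motifs jointly defining one immune signal."""

    motifs: tuple[Motif, ...]
    signal_id: str = "signal"

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("signal must contain at least one motif")
        lengths = {m.length for m in self.motifs}
        if len(lengths) > 1:
            raise ValueError("all motifs within one signal must have the same length")

    @property
    def motif_length(self) -> int:
        return self.motifs[0].length


def random_signal(
    n_motifs: int,
    k: int,
    gapped: bool = False,
    seed: int | np.random.Generator = 0,
    signal_id: str = "signal",
) -> Signal:
    """Draw ``n_motifs`` distinct random motifs of length ``k``.

    With ``gapped=True`` each motif carries one wildcard gap at an interior
    position drawn uniformly once, at signal-construction time.
    """
    if gapped and k < 3:
        raise ValueError("a gapped motif needs length >= 3 (interior gap)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    patterns: set[str] = set()
    tries = 0
    while len(patterns) < n_motifs:
        tries += 1
        if tries > 1000 * n_motifs:
            raise ValueError(
                f"cannot draw {n_motifs} distinct motifs of length {k}"
            )
        letters = [AMINO_ACIDS[c] for c in rng.integers(0, len(AMINO_ACIDS), size=k)]
        if gapped:
            letters[int(rng.integers(1, k - 1))] = GAP
        patterns.add("".join(letters))
    return Signal(tuple(Motif(p) for p in sorted(patterns)), signal_id=signal_id)


@dataclass(frozen=True)
class ImplantingSpec:
    """Implantation parameters for one labeled dataset.

    Rates are percent of sequences per repertoire: a witness rate of 0.005
    with repertoire size 100,000 means 5 implanted sequences per
    positive-class repertoire.
    """

    witness_rate: float
    noise_rate: float = 0.0
    positive_fraction: float = 0.5
    imgt_window: tuple[int, ...] = DEFAULT_IMGT_WINDOW

    def __post_init__(self) -> None:
        if not 0.0 <= self.witness_rate <= 100.0:
            raise ValueError("witness_rate must be in [0, 100] percent")
        if not 0.0 <= self.noise_rate <= 100.0:
            raise ValueError("noise_rate must be in [0, 100] percent")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must be in (0, 1)")
        for pos in self.imgt_window:
            if not 105 <= pos <= 117:
                raise ValueError(f"IMGT window position {pos} outside 105..117")


@dataclass(frozen=True)
class ImplantRecord:
    """Ground truth for a single motif implantation event."""

    repertoire_id: str
    sequence_index: int
    motif: str
    instantiated: str
    imgt_position: int
    start_index: int


@dataclass
class LabeledRepertoireDataset:
    """Repertoires with binary immune-state labels and an implant log."""

    repertoires: list[Repertoire]
    labels: np.ndarray  # 1 = positive (signal implanted), 0 = negative
    implant_log: list[ImplantRecord]
    signal: Signal | None = None
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.repertoires) != len(self.labels):
            raise ValueError("labels must align 1:1 with repertoires")
        self.labels = np.asarray(self.labels, dtype=int)

    def __len__(self) -> int:
        return len(self.repertoires)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def witness_count(witness_rate_percent: float, repertoire_size: int) -> int:
    """Number of sequences per repertoire that receive an implant.

    ``round(rate/100 × size)`` with half-away-from-zero rounding, so a
    witness rate of 0.005% in a repertoire of 100,000 sequences gives
    exactly 5 implanted sequences.
    """
    if witness_rate_percent < 0:
        raise ValueError("witness rate must be non-negative")
    if repertoire_size < 1:
        raise ValueError("repertoire size must be >= 1")
    return _round_half_away(witness_rate_percent / 100.0 * repertoire_size)


def instantiate_motif(motif: Motif, rng: np.random.Generator) -> str:
    """Resolve the gap (if any) to a uniformly drawn amino acid."""
    if not motif.has_gap:
        return motif.pattern
    letter = AMINO_ACIDS[int(rng.integers(0, len(AMINO_ACIDS)))]
    return motif.pattern.replace(GAP, letter)


def implant_in_sequence(seq: str, instantiated: str, start_index: int) -> str:
    """Overwrite ``seq[start_index : start_index+len(instantiated)]``."""
    if start_index < 0 or start_index + len(instantiated) > len(seq):
        raise ValueError(
            f"motif {instantiated!r} at index {start_index} overruns a sequence "
            f"of length {len(seq)}"
        )
    return seq[:start_index] + instantiated + seq[start_index + len(instantiated) :]


def _admissible_positions(
    seq_length: int, motif_length: int, imgt_window: tuple[int, ...]
) -> list[int]:
    """IMGT start positions in the window at which the motif fits.

    The motif must *start* inside the window; it may extend past the window
    (needed for 5-mers in the 4-position default window) but not past the
    sequence end.
    """
    positions = []
    for pos in imgt_window:
        try:
            start = imgt_start_index(seq_length, pos)
        except ValueError:
            continue
        if start + motif_length <= seq_length:
            positions.append(pos)
    return positions


def implant_signal(
    rep: Repertoire,
    signal: Signal,
    witness_rate: float,
    imgt_window: tuple[int, ...] = DEFAULT_IMGT_WINDOW,
    rng: np.random.Generator | None = None,
) -> tuple[Repertoire, list[ImplantRecord]]:
    """Implant the signal into ``witness_count`` distinct sequences.

    Per witness sequence: one motif drawn uniformly (with replacement) from
    the signal, instantiated (gap resolved), and written at an IMGT start
    position drawn uniformly among the admissible window positions.  If no
    window position admits the motif for a drawn sequence, a replacement
    sequence is drawn.  Repertoire size and all sequence lengths are
    preserved.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    n_witnesses = witness_count(witness_rate, len(rep))
    if n_witnesses > len(rep):
        raise ValueError("witness count exceeds repertoire size")
    if n_witnesses == 0:
        return rep, []

    sequences = list(rep.sequences)
    order = rng.permutation(len(sequences))
    log: list[ImplantRecord] = []
    chosen = 0
    cursor = 0
    while chosen < n_witnesses:
        if cursor >= len(order):
            raise ValueError(
                "no sequences long enough to receive the motif inside the "
                "IMGT window"
            )
        seq_idx = int(order[cursor])
        cursor += 1
        seq = sequences[seq_idx]
        positions = _admissible_positions(len(seq), signal.motif_length, imgt_window)
        if not positions:
            continue  # draw a new sequence
        motif = signal.motifs[int(rng.integers(0, len(signal.motifs)))]
        instantiated = instantiate_motif(motif, rng)
        imgt_pos = positions[int(rng.integers(0, len(positions)))]
        start = imgt_start_index(len(seq), imgt_pos)
        sequences[seq_idx] = implant_in_sequence(seq, instantiated, start)
        log.append(
            ImplantRecord(
                repertoire_id=rep.repertoire_id,
                sequence_index=seq_idx,
                motif=motif.pattern,
                instantiated=instantiated,
                imgt_position=imgt_pos,
                start_index=start,
            )
        )
        chosen += 1

    new_rep = replace(rep, sequences=sequences)
    return new_rep, log


def build_labeled_dataset(
    n_examples: int,
    repertoire_size: int,
    signal: Signal,
    spec: ImplantingSpec,
    model: SequenceModel | None = None,
    seed: int = 0,
    dataset_id: str = "dataset",
    repertoires: list[Repertoire] | None = None,
) -> LabeledRepertoireDataset:
    """Simulate a labeled benchmark dataset.

    ``round(positive_fraction × n_examples)`` repertoires receive the signal
    at the witness rate and are labeled positive; the rest receive it at the
    (usually zero) noise rate and are labeled negative.  ``repertoires``
    may supply pre-generated reference repertoires (e.g. imported ones);
    otherwise repertoires are generated from ``model``.  Fully reproducible
    from ``seed``.
    """
    if n_examples < 2:
        raise ValueError("a labeled dataset needs at least 2 examples")
    if repertoires is not None and len(repertoires) != n_examples:
        raise ValueError(
            f"{len(repertoires)} repertoires supplied for {n_examples} examples"
        )
    n_positive = _round_half_away(spec.positive_fraction * n_examples)
    labels = np.zeros(n_examples, dtype=int)
    labels[:n_positive] = 1

    seeds = _spawn_seeds(seed, 2 * n_examples)
    out_reps: list[Repertoire] = []
    log: list[ImplantRecord] = []
    for i in range(n_examples):
        if repertoires is not None:
            rep = replace(
                repertoires[i], repertoire_id=f"{dataset_id}_rep{i:04d}"
            )
        else:
            rep = generate_repertoire(
                model,
                size=repertoire_size,
                repertoire_id=f"{dataset_id}_rep{i:04d}",
                seed=seeds[2 * i],
            )
        rate = spec.witness_rate if labels[i] == 1 else spec.noise_rate
        if rate > 0:
            rep, rep_log = implant_signal(
                rep,
                signal,
                rate,
                spec.imgt_window,
                np.random.default_rng(seeds[2 * i + 1]),
            )
            log.extend(rep_log)
        out_reps.append(rep)

    config = {
        "dataset_id": dataset_id,
        "n_examples": n_examples,
        "repertoire_size": repertoire_size,
        "witness_rate": spec.witness_rate,
        "noise_rate": spec.noise_rate,
        "positive_fraction": spec.positive_fraction,
        "imgt_window": list(spec.imgt_window),
        "signal": [m.pattern for m in signal.motifs],
        "seed": seed,
    }
    return LabeledRepertoireDataset(
        repertoires=out_reps,
        labels=labels,
        implant_log=log,
        signal=signal,
        config=config,
    )
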