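"""Motif definition and witness-rate implantation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import airrbench as ab
from airrbench.signals import _admissible_positions


class TestWitnessCount:
    @pytest.mark.parametrize(
        "rate,size,expected",
        [
            (0.005, 100_000, 5),
            (0.002, 100_000, 2),
            (0.0, 100_000, 0),
            (0.001, 12_000, 0),  # 0.12 rounds down
            (0.5, 1_000, 5),
            (0.1, 2_500, 3),  # 2.5 rounds half away from zero
        ],
    )
    def test_rounding_rule(self, rate, size, expected):
        assert ab.witness_count(rate, size) == expected

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ab.witness_count(-0.1, 100)


class TestMotif:
    @pytest.mark.parametrize("pattern", ["ACDE", "A*C", "KL*MN", "AC"])
    def test_valid_patterns(self, pattern):
        motif = ab.Motif(pattern)
        assert motif.length == len(pattern)

    @pytest.mark.parametrize("pattern", ["*AC", "AC*", "A**C", "A", "ACDEFG", "AB"])
    def test_invalid_patterns_rejected(self, pattern):
        with pytest.raises(ValueError):
            ab.Motif(pattern)

    def test_signal_requires_uniform_motif_length(self):
        with pytest.raises(ValueError):
            ab.Signal((ab.Motif("ACDE"), ab.Motif("ACD")))

    def test_random_signal_draws_distinct_motifs(self):
        signal = ab.random_signal(5, 4, seed=0)
        patterns = [m.pattern for m in signal.motifs]
        assert len(set(patterns)) == 5
        assert all(len(p) == 4 for p in patterns)

    def test_random_gapped_signal_has_interior_gap(self):
        signal = ab.random_signal(10, 4, gapped=True, seed=1)
        for motif in signal.motifs:
            assert motif.pattern.count("*") == 1
            assert motif.pattern[0] != "*" and motif.pattern[-1] != "*"


class TestInstantiation:
    def test_ungapped_motif_unchanged(self):
        assert ab.instantiate_motif(ab.Motif("ACDE"), np.random.default_rng(0)) == "ACDE"

    def test_gap_resolves_to_single_amino_acid(self):
        rng = np.random.default_rng(1)
        seen = set()
        for _ in range(500):
            inst = ab.instantiate_motif(ab.Motif("A*C"), rng)
            assert len(inst) == 3
            assert inst[0] == "A" and inst[2] == "C"
            assert inst[1] in ab.AMINO_ACIDS
            seen.add(inst)
        assert len(seen) == 20  # one instantiation per amino acid


class TestImplantInSequence:
    def test_substitution_preserves_flanks(self):
        assert ab.implant_in_sequence("CASSLGQAYEQYF", "ACDE", 3) == "CASACDEAYEQYF"

    def test_identical_substring_is_a_no_op(self):
        assert ab.implant_in_sequence("CASSL", "SS", 2) == "CASSL"

    def test_overrun_rejected(self):
        with pytest.raises(ValueError):
            ab.implant_in_sequence("CASSL", "ACDE", 3)

    @settings(derandomize=True, max_examples=50)
    @given(
        seq=st.text(alphabet=ab.AMINO_ACIDS, min_size=8, max_size=23),
        motif=st.text(alphabet=ab.AMINO_ACIDS, min_size=2, max_size=5),
        data=st.data(),
    )
    def test_length_preserved_and_changes_local(self, seq, motif, data):
        start = data.draw(st.integers(0, len(seq) - len(motif)))
        out = ab.implant_in_sequence(seq, motif, start)
        assert len(out) == len(seq)
        diffs = [i for i, (a, b) in enumerate(zip(seq, out)) if a != b]
        assert all(start <= i < start + len(motif) for i in diffs)


class TestImplantSignal:
    def setup_method(self):
        self.rep = ab.generate_repertoire(size=1000, repertoire_id="r", seed=0)
        self.signal = ab.random_signal(3, 4, seed=2)

    def test_exact_witness_count_with_distinct_sequences(self):
        out, log = ab.implant_signal(
            self.rep, self.signal, 0.5, rng=np.random.default_rng(3)
        )
        assert len(log) == 5
        assert len({r.sequence_index for r in log}) == 5
        assert len(out) == len(self.rep)

    def test_zero_rate_is_identity(self):
        out, log = ab.implant_signal(
            self.rep, self.signal, 0.0, rng=np.random.default_rng(4)
        )
        assert out.sequences == self.rep.sequences
        assert log == []

    def test_implants_start_inside_imgt_window(self):
        out, log = ab.implant_signal(
            self.rep, self.signal, 2.0, rng=np.random.default_rng(5)
        )
        for record in log:
            assert record.imgt_position in (108, 109, 110, 111)
            assert record.start_index == record.imgt_position - 105

    def test_lengths_conserved_and_changes_inside_window(self):
        out, log = ab.implant_signal(
            self.rep, self.signal, 2.0, rng=np.random.default_rng(6)
        )
        k = self.signal.motif_length
        touched = {r.sequence_index for r in log}
        for i, (before, after) in enumerate(zip(self.rep.sequences, out.sequences)):
            assert len(before) == len(after)
            if i not in touched:
                assert before == after
            else:
                diffs = [j for j, (a, b) in enumerate(zip(before, after)) if a != b]
                lo = ab.imgt_start_index(len(before), 108)
                hi = ab.imgt_start_index(len(before), 111) + k
                assert all(lo <= j < hi for j in diffs)

    def test_implanted_substring_matches_log(self):
        out, log = ab.implant_signal(
            self.rep, self.signal, 1.0, rng=np.random.default_rng(7)
        )
        for record in log:
            seq = out.sequences[record.sequence_index]
            start = record.start_index
            assert seq[start : start + len(record.instantiated)] == record.instantiated

    def test_admissible_positions_respect_motif_fit(self):
        # a 5-mer starting at IMGT 111 needs length >= 11
        assert _admissible_positions(10, 5, (108, 109, 110, 111)) == [108, 109, 110]
        assert 111 in _admissible_positions(11, 5, (108, 109, 110, 111))


class TestLabeledDataset:
    def _build(self, n, pf, witness=1.0, noise=0.0, seed=0):
        signal = ab.random_signal(3, 4, seed=99)
        spec = ab.ImplantingSpec(
            witness_rate=witness, noise_rate=noise, positive_fraction=pf
        )
        return ab.build_labeled_dataset(
            n_examples=n, repertoire_size=50, signal=signal, spec=spec, seed=seed
        )

    @pytest.mark.parametrize("n,pf,expected", [(200, 0.5, 100), (200, 0.2, 40)])
    def test_positive_label_count(self, n, pf, expected):
        assert self._build(n, pf).n_positive == expected

    def test_negatives_untouched_without_noise(self):
        ds = self._build(20, 0.5, witness=2.0, noise=0.0, seed=1)
        for rep, label in zip(ds.repertoires, ds.labels):
            if label == 0:
                regenerated = ab.generate_repertoire(
                    None, size=50, repertoire_id=rep.repertoire_id, seed=rep.seed
                )
                assert rep.sequences == regenerated.sequences

    def test_noise_implants_do_not_flip_labels(self):
        ds = self._build(20, 0.5, witness=2.0, noise=2.0, seed=2)
        assert ds.n_positive == 10
        noisy_ids = {r.repertoire_id for r in ds.implant_log}
        negative_ids = {
            rep.repertoire_id
            for rep, label in zip(ds.repertoires, ds.labels)
            if label == 0
        }
        assert noisy_ids & negative_ids  # negatives received implants, labels kept

    def test_reproducible_from_seed(self):
        a = self._build(10, 0.5, seed=3)
        b = self._build(10, 0.5, seed=3)
        assert [r.sequences for r in a.repertoires] == [r.sequences for r in b.repertoires]
        assert (a.labels == b.labels).all()
        assert a.implant_log == b.implant_log

    def test_per_positive_log_matches_witness_count(self):
        ds = self._build(10, 0.5, witness=4.0, seed=4)
        expected = ab.witness_count(4.0, 50)
        per_rep = {}
        for record in ds.implant_log:
            per_rep[record.repertoire_id] = per_rep.get(record.repertoire_id, 0) + 1
        positives = [
            rep.repertoire_id
            for rep, label in zip(ds.repertoires, ds.labels)
            if label == 1
        ]
        assert all(per_rep[rid] == expected for rid in positives)
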