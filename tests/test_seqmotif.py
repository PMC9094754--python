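"""Motif scanning: ARE/CPE/PAS counting, positional CPE calls, mutagenesis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arecpe.seqmotif import (
    ARE_MOTIF,
    CPE_MOTIFS,
    InvalidAlphabetError,
    MotifMatch,
    PositionalConfig,
    UTRRecord,
    classify_cpe_positional,
    count_are,
    count_cpe,
    find_cpe_matches,
    find_pas,
    inactivate_motifs,
    is_are_containing,
    normalize_sequence,
    select_longest_utr,
)


def random_sequences(n, length, seed):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGTN"))
    # AT-rich composition so motif hits are frequent
    probs = [0.3, 0.1, 0.1, 0.45, 0.05]
    return ["".join(rng.choice(bases, size=length, p=probs)) for _ in range(n)]


def brute_force_count(seq, motif):
    return sum(seq[i:i + len(motif)] == motif for i in range(len(seq)))


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("auuua", "ATTTA"),
            ("AUUUAUUUA", "ATTTATTTA"),
            ("acgtn", "ACGTN"),
        ],
    )
    def test_case_and_rna_mapping(self, raw, expected):
        assert normalize_sequence(raw) == expected

    def test_invalid_character_names_position(self):
        with pytest.raises(InvalidAlphabetError, match="position 1"):
            normalize_sequence("AXTTA")

    def test_empty_rejected(self):
        with pytest.raises(InvalidAlphabetError):
            normalize_sequence("")

    def test_idempotent(self):
        for seq in random_sequences(50, 80, seed=1):
            assert normalize_sequence(normalize_sequence(seq)) == normalize_sequence(seq)

    @given(st.text(alphabet="ACGTNUacgtnu", min_size=1, max_size=200))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_canonical_output_is_fixed_point(self, raw):
        seq = normalize_sequence(raw)
        assert set(seq) <= set("ACGTN")
        assert normalize_sequence(seq) == seq

    @given(st.text(alphabet="ACGTNUacgtnu", min_size=1, max_size=120))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_counters_invariant_under_normalisation(self, raw):
        seq = normalize_sequence(raw)
        assert count_are(seq) == count_are(normalize_sequence(seq))
        assert count_cpe(seq) == sum(
            brute_force_count(seq, m) for m in CPE_MOTIFS
        )


class TestCountAre:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATTTA", 1),
            ("ATTTATTTA", 2),
            ("GCGCGC", 0),
            ("ATTTATTTATTTATTTATTTATTTA", 6),
            ("", 0),
        ],
    )
    def test_examples(self, seq, expected):
        assert count_are(seq) == expected

    @pytest.mark.parametrize("k", range(1, 9))
    def test_overlapping_run_counts_k(self, k):
        assert count_are("A" + "TTTA" * k) == k

    def test_matches_bruteforce(self):
        for seq in random_sequences(300, 150, seed=2):
            assert count_are(seq) == brute_force_count(seq, ARE_MOTIF)

    def test_n_never_matches(self):
        assert count_are("ATTNA" * 10) == 0


class TestCpeMatching:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("TTTTAAT", [("TTTTAAT", 0)]),
            ("TTGGGAT", []),  # the inactivated reporter motif
            ("TTTTATTTTGT", [("TTTTAT", 0), ("TTTTGT", 5)]),
        ],
    )
    def test_find_examples(self, seq, expected):
        got = [(m.motif, m.start) for m in find_cpe_matches(seq)]
        assert got == expected

    @pytest.mark.parametrize(
        "seq,expected",
        [("TTTTAT", 1), ("TTTTATTTTAT", 2), ("AAAAAA", 0)],
    )
    def test_count_examples(self, seq, expected):
        assert count_cpe(seq) == expected

    def test_matches_bruteforce(self):
        for seq in random_sequences(300, 150, seed=3):
            expected = sum(brute_force_count(seq, m) for m in CPE_MOTIFS)
            assert count_cpe(seq) == expected

    def test_pairwise_start_exclusivity(self):
        """No two distinct CPE motifs can match at the same offset."""
        for seq in random_sequences(200, 150, seed=4):
            starts = [m.start for m in find_cpe_matches(seq)]
            assert len(starts) == len(set(starts))

    def test_matches_are_sorted_and_consistent(self):
        for seq in random_sequences(50, 120, seed=5):
            matches = find_cpe_matches(seq)
            assert all(
                seq[m.start:m.end] == m.motif for m in matches
            )
            assert [m.start for m in matches] == sorted(m.start for m in matches)


class TestPas:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AATAAA", [("AATAAA", 0)]),
            ("GGGGGG", []),
            # ATTAAA starts at offset 5 (AATAA|ATTAAA share the middle A)
            ("AATAAATTAAA", [("AATAAA", 0), ("ATTAAA", 5)]),
        ],
    )
    def test_examples(self, seq, expected):
        got = [(m.motif, m.start) for m in find_pas(seq)]
        assert got == expected


class TestPositionalCpe:
    def test_cpe_within_window_of_pas(self):
        seq = "C" * 10 + "TTTTAT" + "C" * 24 + "AATAAA" + "C" * 10
        flag, reason = classify_cpe_positional(seq, PositionalConfig())
        assert flag and "30 nt upstream" in reason

    def test_cpe_without_pas_required(self):
        seq = "C" * 10 + "TTTTAT" + "C" * 30
        flag, _ = classify_cpe_positional(seq, PositionalConfig(require_pas=True))
        assert not flag
        flag, _ = classify_cpe_positional(seq, PositionalConfig(require_pas=False))
        assert flag

    def test_cpe_too_far_from_pas(self):
        seq = "C" * 10 + "TTTTGT" + "C" * 394 + "AATAAA" + "C" * 10
        flag, _ = classify_cpe_positional(seq, PositionalConfig(max_distance_nt=100))
        assert not flag

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PositionalConfig(max_distance_nt=0)
        with pytest.raises(ValueError):
            PositionalConfig(pas_motifs=())


class TestAreContaining:
    @pytest.mark.parametrize("n,expected", [(0, False), (1, False), (2, True), (5, True)])
    def test_two_or_more_rule(self, n, expected):
        assert is_are_containing(n) is expected


class TestInactivateMotifs:
    def test_single_cpe_destroyed(self):
        rec = UTRRecord("g", "TTTTAAT")
        out = inactivate_motifs(rec, [MotifMatch("TTTTAAT", 0, 7)], seed=0)
        assert out.length == 7 and count_cpe(out.sequence) == 0

    def test_second_reporter_motif(self):
        rec = UTRRecord("g", "TTTTACT")
        out = inactivate_motifs(rec, [MotifMatch("TTTTACT", 0, 7)], seed=1)
        assert count_cpe(out.sequence) == 0 and out.length == 7

    def test_zero_targets_identity(self):
        rec = UTRRecord("g", "TTTTAATGGG")
        assert inactivate_motifs(rec, [], seed=0) == rec

    def test_deterministic_given_seed(self):
        rec = UTRRecord("g", "CCTTTTAATCCATTTACC")
        targets = [MotifMatch("TTTTAAT", 2, 9)]
        assert inactivate_motifs(rec, targets, seed=7) == inactivate_motifs(
            rec, targets, seed=7
        )

    def test_absent_target_rejected(self):
        rec = UTRRecord("g", "GGGGGGG")
        with pytest.raises(ValueError):
            inactivate_motifs(rec, [MotifMatch("TTTTAAT", 0, 7)], seed=0)

    def test_rescan_properties_on_generated_utrs(self):
        """Inactivating all CPEs keeps length, removes the targeted matches,
        never creates new ARE/CPE matches."""
        from arecpe.synthetic import generate_utr

        for seed in range(5):
            rec = generate_utr(3, 3, 400, seed=seed, gene_id=f"g{seed}")
            before = find_cpe_matches(rec.sequence)
            n_are_before = count_are(rec.sequence)
            out = inactivate_motifs(rec, before, seed=seed)
            assert out.length == rec.length
            assert count_cpe(out.sequence) == 0
            assert count_are(out.sequence) <= n_are_before
            total_before = n_are_before + len(before)
            total_after = count_are(out.sequence) + count_cpe(out.sequence)
            assert total_after < total_before


class TestSelectLongest:
    def test_longest_isoform_wins(self):
        recs = [
            UTRRecord("g1", "A" * 100, "tx_a"),
            UTRRecord("g1", "A" * 200, "tx_b"),
        ]
        assert select_longest_utr(recs)[0].transcript_id == "tx_b"

    def test_single_isoform_identity(self):
        rec = UTRRecord("g1", "ACGT", "tx1")
        assert select_longest_utr([rec]) == [rec]

    def test_tie_breaks_lexicographically(self):
        recs = [
            UTRRecord("g1", "A" * 150, "tx2"),
            UTRRecord("g1", "C" * 150, "tx1"),
        ]
        assert select_longest_utr(recs)[0].transcript_id == "tx1"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_longest_utr([])

    def test_one_record_per_gene_sorted(self):
        recs = [
            UTRRecord("g2", "ACGT", "t3"),
            UTRRecord("g1", "ACGTACGT", "t1"),
            UTRRecord("g1", "ACGT", "t2"),
        ]
        out = select_longest_utr(recs)
        assert [r.gene_id for r in out] == ["g1", "g2"]
        assert out[0].transcript_id == "t1"
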