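import random

import pytest
from hypothesis import given, settings, strategies as st

from nanodemux.align import (
    DEFAULT_SCHEME,
    ScoringScheme,
    encode_sequence,
    local_align,
    reverse_complement,
)
from nanodemux._kernel import sw_best

from .oracles import biopython_best, enum_best, rec_best

dna = st.text(alphabet="ACGT", min_size=1, max_size=8)
dna_n = st.text(alphabet="ACGTN", min_size=1, max_size=14)

SCHEMES = [
    DEFAULT_SCHEME,
    ScoringScheme(match=2, mismatch=-3, gap=-2),
    ScoringScheme(match=1, mismatch=0, gap=-1),
    ScoringScheme(match=3, mismatch=-1, gap=0),
    ScoringScheme(match=1, mismatch=-1, gap=-1, run_bonus=2, run_min=3),
    ScoringScheme(match=1, mismatch=-2, gap=-1, run_bonus=3, run_min=4),
]


class TestScoringScheme:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(match=0), dict(mismatch=1), dict(gap=1), dict(run_bonus=-1),
         dict(run_min=1)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScoringScheme(**kwargs)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected", [("ACGT", "ACGT"), ("AAAC", "GTTT"), ("N", "N")]
    )
    def test_known_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(st.text(alphabet="ACGTN", max_size=100))
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestLocalAlign:
    def test_perfect_match(self):
        res = local_align("ACGT", "ACGT")
        assert (res.score, res.read_start, res.read_end) == (4, 1, 4)
        assert res.ops == "MMMM"

    def test_barcode_embedded_at_offset_47(self, embed_read, builtin24):
        bc = builtin24[0]
        read = embed_read(bc.sequence, 47)
        res = local_align(bc.sequence, read.sequence[:110])
        assert res.score == len(bc.sequence) == 24
        assert res.read_start == 47
        assert res.read_end == 47 + 23

    def test_small_example_matches_enumeration(self):
        for scheme in SCHEMES:
            mine = local_align("ACCA", "ATTTTCCTTTTA", scheme)
            expected = enum_best("ACCA", "ATTTTCCTTTTA", scheme)
            assert (mine.score if mine else 0) == expected

    def test_no_positive_alignment_returns_none(self):
        assert local_align("AAAA", "TTTT") is None
        assert local_align("", "ACGT") is None
        assert local_align("ACGT", "") is None

    def test_ops_self_consistency(self):
        rng = random.Random(7)
        for _ in range(300):
            scheme = rng.choice(SCHEMES)
            q = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 10)))
            t = "".join(rng.choice("ACGTN") for _ in range(rng.randint(1, 20)))
            res = local_align(q, t, scheme)
            if res is not None:
                assert res.score_from_ops(scheme) == res.score
                assert 1 <= res.read_start <= res.read_end <= len(t)
                assert 1 <= res.barcode_start <= res.barcode_end <= len(q)

    def test_local_optimality_no_negative_affixes(self):
        # every prefix and suffix of the op string contributes >= 0
        rng = random.Random(11)
        from .oracles import score_ops

        for _ in range(200):
            scheme = rng.choice(SCHEMES)
            q = "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 8)))
            t = "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 14)))
            res = local_align(q, t, scheme)
            if res is None:
                continue
            for cut in range(1, len(res.ops)):
                assert score_ops(res.ops[:cut], scheme) >= 0
                assert res.score - score_ops(res.ops[:cut], scheme) >= 0


class TestOracleEquivalence:
    def test_recursion_oracle_agrees_with_path_enumeration(self):
        # validates the fast oracle itself on tiny cases, incl. run bonus
        rng = random.Random(3)
        for _ in range(60):
            scheme = rng.choice(SCHEMES)
            q = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
            t = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
            assert rec_best(q, t, scheme) == enum_best(q, t, scheme)

    @given(q=dna, t=dna_n, scheme=st.sampled_from(SCHEMES))
    @settings(max_examples=400)
    def test_score_matches_recursion_oracle(self, q, t, scheme):
        res = local_align(q, t, scheme)
        assert (res.score if res else 0) == rec_best(q, t, scheme)

    def test_score_matches_biopython_on_linear_schemes(self):
        rng = random.Random(5)
        linear = [s for s in SCHEMES if s.is_linear]
        for _ in range(1000):
            scheme = rng.choice(linear)
            q = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            t = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 20)))
            res = local_align(q, t, scheme)
            assert (res.score if res else 0) == biopython_best(q, t, scheme)


class TestKernelEquivalence:
    @given(q=dna, t=dna_n, scheme=st.sampled_from([s for s in SCHEMES if s.is_linear]))
    @settings(max_examples=500)
    def test_kernel_matches_reference_dp(self, q, t, scheme):
        """Score, start and end (incl. tie-breaks) agree with the reference."""
        res = local_align(q, t, scheme)
        got = sw_best(
            encode_sequence(q), encode_sequence(t),
            scheme.match, scheme.mismatch, scheme.gap,
        )
        want = (res.score, res.read_start, res.read_end) if res else (0, 0, 0)
        assert tuple(int(x) for x in got) == want


class TestAlignmentProperties:
    @given(q=st.text(alphabet="ACGT", min_size=2, max_size=8),
           t=st.text(alphabet="ACGT", min_size=1, max_size=12))
    def test_score_monotone_under_target_extension(self, q, t):
        """Appending an exact copy of the query never lowers the score."""
        base = local_align(q, t)
        extended = local_align(q, t + q)
        assert extended is not None
        assert extended.score >= (base.score if base else 0)
        assert extended.score >= len(q)

    @given(q=st.text(alphabet="AG", min_size=4, max_size=8),
           k=st.integers(min_value=1, max_value=10))
    def test_coordinates_shift_with_target_prefix(self, q, k):
        """A C-run pad before an A/G-only target shifts coordinates by k."""
        base = local_align(q, q)
        assert (base.score, base.read_start, base.read_end) == (len(q), 1, len(q))
        shifted = local_align(q, "C" * k + q)
        assert shifted.score == base.score
        assert shifted.read_start == base.read_start + k
        assert shifted.read_end == base.read_end + k

    def test_n_in_target_scores_as_mismatch(self):
        res = local_align("ACGTACGT", "ACGTNCGT")
        # N forces a mismatch or gaps; either way score < 8
        assert res.score == 6
        assert res.ops.count("M") == 7

    def test_run_bonus_zero_is_classic_smith_waterman(self):
        rng = random.Random(13)
        plain = ScoringScheme(match=2, mismatch=-1, gap=-2)
        with_state = ScoringScheme(match=2, mismatch=-1, gap=-2,
                                   run_bonus=0, run_min=5)
        for _ in range(200):
            q = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8)))
            t = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 14)))
            a = local_align(q, t, plain)
            b = local_align(q, t, with_state)
            assert (a.score if a else 0) == (b.score if b else 0)
            assert (a.score if a else 0) == biopython_best(q, t, plain)

    def test_run_bonus_rewards_contiguous_matches(self):
        # 8 matches split by one read insertion: one run of 4+ on each side
        scheme = ScoringScheme(run_bonus=2, run_min=4)
        res = local_align("ACGTACCA", "ACGTGACCA", scheme)
        # MMMM I MMMM = 8 matches - 1 gap + 2 bonuses = 11
        assert res.score == 11
        assert res.ops == "MMMMIMMMM"
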