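import random

import pytest
from hypothesis import given, strategies as st

from nanodemux.align import AlignmentResult, DEFAULT_SCHEME, ScoringScheme
from nanodemux.classify import (
    DEFAULT_WINDOW_MAP,
    WindowMap,
    WindowTier,
    decide,
    scan_read,
    window_for_score,
)

from .conftest import make_read, random_dna


def aln(barcode_id, score, start, end=None):
    return AlignmentResult(
        barcode_id=barcode_id, score=score, read_start=start,
        read_end=end if end is not None else start + 23,
    )


class TestWindowForScore:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (12, None),
            (13, (36, 51)),
            (14, (30, 75)),
            (15, (5, 85)),
            (20, (5, 85)),
            (24, (5, 85)),
        ],
    )
    def test_default_tier_selection(self, score, expected):
        assert window_for_score(score, DEFAULT_WINDOW_MAP) == expected

    def test_from_string_round_trip(self):
        parsed = WindowMap.from_string("13:36:51,14:30:75,15:5:85")
        assert parsed.tiers == DEFAULT_WINDOW_MAP.tiers
        for score in range(10, 30):
            assert window_for_score(score, parsed) == window_for_score(
                score, DEFAULT_WINDOW_MAP
            )

    def test_invalid_maps_rejected(self):
        with pytest.raises(ValueError):
            WindowMap.from_string("13:51:36")
        with pytest.raises(ValueError):
            WindowMap(tiers=())
        with pytest.raises(ValueError):
            WindowMap(tiers=(WindowTier(14, 30, 75), WindowTier(13, 36, 51)))


class TestDecide:
    def test_clear_winner_assigned(self):
        d = decide([aln("BC01", 16, 40), aln("BC02", 10, 60)])
        assert d.status == "assigned"
        assert d.barcode_id == "BC01"
        assert d.runner_up_score == 10
        assert d.reject_reason == "none"

    def test_margin_of_one_rejected(self):
        d = decide([aln("BC01", 16, 40), aln("BC02", 15, 60)])
        assert d.status == "unclassified"
        assert d.reject_reason == "margin_too_small"

    def test_margin_of_exactly_two_passes(self):
        d = decide([aln("BC01", 16, 40), aln("BC02", 14, 60)])
        assert d.status == "assigned"

    def test_equal_top_scores_never_assigned(self):
        d = decide([aln("BC01", 20, 40), aln("BC02", 20, 41)])
        assert d.status == "unclassified"
        assert d.reject_reason == "margin_too_small"

    def test_same_barcode_does_not_compete_with_itself(self):
        # two hits of BC01 collapse to the best; margin is vs BC02 only
        d = decide([aln("BC01", 16, 40), aln("BC01", 15, 70), aln("BC02", 10, 60)])
        assert d.status == "assigned"
        assert d.runner_up_score == 10

    @pytest.mark.parametrize(
        "score,start,assigned",
        [
            (13, 35, False), (13, 36, True), (13, 51, True), (13, 52, False),
            (14, 30, True), (14, 76, False), (15, 5, True), (15, 85, True),
        ],
    )
    def test_positional_filter_boundaries(self, score, start, assigned):
        d = decide([aln("BC01", score, start)])
        assert (d.status == "assigned") == assigned
        if not assigned:
            assert d.reject_reason == "outside_window"

    def test_below_floor_rejected(self):
        d = decide([aln("BC01", 12, 40)])
        assert d.reject_reason == "below_min_score"

    def test_empty_alignment_list(self):
        d = decide([])
        assert d.status == "unclassified"
        assert d.reject_reason == "no_alignment"

    def test_decision_object_enforces_reason_consistency(self):
        from nanodemux.classify import ClassificationDecision

        with pytest.raises(ValueError):
            ClassificationDecision(status="assigned", barcode_id="BC01",
                                   reject_reason="outside_window")
        with pytest.raises(ValueError):
            ClassificationDecision(status="unclassified")

    @given(
        scores=st.lists(
            st.tuples(st.integers(min_value=1, max_value=30),
                      st.integers(min_value=1, max_value=90)),
            min_size=0, max_size=8,
        ),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_permutation_invariance(self, scores, seed):
        alignments = [aln(f"BC{i:02d}", s, p) for i, (s, p) in enumerate(scores)]
        base = decide(alignments)
        shuffled = alignments[:]
        random.Random(seed).shuffle(shuffled)
        other = decide(shuffled)
        assert (base.status, base.barcode_id, base.reject_reason) == (
            other.status, other.barcode_id, other.reject_reason
        )

    @given(
        score=st.integers(min_value=13, max_value=24),
        bump=st.integers(min_value=0, max_value=10),
    )
    def test_window_monotone_in_score(self, score, bump):
        """Raising a winning score never flips assigned -> outside_window."""
        start = 40  # inside every default tier window
        before = decide([aln("BC01", score, start)])
        after = decide([aln("BC01", score + bump, start)])
        if before.status == "assigned":
            assert after.status == "assigned"

    def test_prefilter_variant_can_promote_runner_up(self):
        # winner at an invalid position is dropped before ranking
        alignments = [aln("BC01", 13, 70), aln("BC02", 13, 40)]
        default = decide(alignments)
        assert default.reject_reason == "margin_too_small"
        pre = decide(alignments, prefilter_positions=True)
        assert pre.status == "assigned"
        assert pre.barcode_id == "BC02"


class TestScanRead:
    def test_short_read_scanned_whole(self, builtin24):
        bc = builtin24[3]
        read = make_read("r", "ACG" + bc.sequence)  # 27 nt < 110
        hits = scan_read(read, builtin24)
        best = max(hits, key=lambda a: a.score)
        assert best.barcode_id == bc.barcode_id
        assert best.score == 24
        assert best.read_start == 4

    def test_adversarial_homopolymer_read_scores_below_floor(self, builtin24):
        read = make_read("r", "T" * 200)
        hits = scan_read(read, builtin24)
        assert all(h.score < 13 for h in hits)

    def test_barcode_at_47_wins_with_perfect_score(self, embed_read, builtin24):
        bc = builtin24[7]
        read = embed_read(bc.sequence, 47)
        hits = scan_read(read, builtin24)
        best = max(hits, key=lambda a: a.score)
        assert (best.barcode_id, best.score, best.read_start) == (
            bc.barcode_id, 24, 47
        )
        d = decide(hits)
        assert d.status == "assigned" and d.barcode_id == bc.barcode_id

    def test_only_first_110_bases_scanned(self, builtin24):
        bc = builtin24[0]
        rng = random.Random(1)
        read = make_read("r", random_dna(rng, 300) + bc.sequence)
        hits = {h.barcode_id: h for h in scan_read(read, builtin24)}
        hit = hits.get(bc.barcode_id)
        assert hit is None or hit.score < 24

    def test_revcomp_scan_finds_flipped_barcode(self, embed_read, builtin24):
        from nanodemux.align import reverse_complement

        bc = builtin24[0]
        read = embed_read(reverse_complement(bc.sequence), 47)
        fwd = {h.barcode_id: h.score for h in scan_read(read, builtin24)}
        assert fwd.get(bc.barcode_id, 0) < 24
        both = {h.barcode_id: h for h in scan_read(read, builtin24, scan_revcomp=True)}
        assert both[bc.barcode_id].score == 24
        assert both[bc.barcode_id].strand == "-"

    def test_nonlinear_scheme_routes_through_reference_dp(self, embed_read, builtin24):
        scheme = ScoringScheme(run_bonus=2, run_min=4)
        bc = builtin24[2]
        read = embed_read(bc.sequence, 47)
        hits = {h.barcode_id: h for h in scan_read(read, builtin24, scheme=scheme)}
        assert hits[bc.barcode_id].score == 24 + 2  # one 24-match run
        assert hits[bc.barcode_id].read_start == 47
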