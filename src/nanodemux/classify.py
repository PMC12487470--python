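"""Per-read barcode classification.

A read is assigned to a barcode only if three checks pass in order:

1. **score floor** — the best barcode's local-alignment score reaches the
   minimum (default 13, i.e. better than half of an intact 24-nt barcode
   under the default +1/-1/-1 scheme);
2. **margin rule** — the best score exceeds the second-best *distinct*
   barcode's score by at least the margin (default 2), so near-ties are
   never assigned;
3. **positional filter** — the winning alignment's start position on the
   read falls inside a window that depends on the score tier.  In the rapid
   barcoding read layout the barcode starts around position 47, so a
   marginal score is only believed near there, while higher-scoring hits
   may sit in a wider window.

The default window map is ``13:36:51, 14:30:75, 15:5:85`` (min_score:start:end,
1-based inclusive): score 13 must start in [36, 51], score 14 in [30, 75],
and scores of 15 or more in [5, 85].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._kernel import sw_best
from .align import AlignmentResult, DEFAULT_SCHEME, ScoringScheme, encode_sequence, local_align, reverse_complement
from .io import BarcodeRecord, ReadRecord

__all__ = [
    "WindowTier",
    "WindowMap",
    "ClassificationDecision",
    "window_for_score",
    "scan_read",
    "decide",
    "DEFAULT_WINDOW_MAP",
]


@dataclass(frozen=True)
class WindowTier:
    min_score: int
    window_start: int  # 1-based inclusive
    window_end: int

    def __post_init__(self) -> None:
        if self.window_start > self.window_end:
            raise ValueError(
                f"tier {self.min_score}: empty window "
                f"({self.window_start} > {self.window_end})"
            )


@dataclass(frozen=True)
class WindowMap:
    """Score-tiered valid start windows for winning alignments."""

    tiers: tuple[WindowTier, ...]
    min_score_floor: int = 13

    def __post_init__(self) -> None:
        if not self.tiers:
            raise ValueError("window map needs at least one tier")
        if list(self.tiers) != sorted(self.tiers, key=lambda t: t.min_score):
            raise ValueError("tiers must be sorted by min_score ascending")

    @classmethod
    def from_string(cls, text: str, min_score_floor: int = 13) -> "WindowMap":
        """Parse tier triples ``min_score:start:end`` separated by commas."""
        tiers = []
        for part in text.split(","):
            fields = part.strip().split(":")
            if len(fields) != 3:
                raise ValueError(f"bad window tier {part!r} (want min_score:start:end)")
            tiers.append(WindowTier(*(int(f) for f in fields)))
        tiers.sort(key=lambda t: t.min_score)
        return cls(tuple(tiers), min_score_floor)


DEFAULT_WINDOW_MAP = WindowMap(
    tiers=(
        WindowTier(13, 36, 51),
        WindowTier(14, 30, 75),
        WindowTier(15, 5, 85),
    ),
    min_score_floor=13,
)


def window_for_score(score: int, window_map: WindowMap = DEFAULT_WINDOW_MAP
                     ) -> Optional[tuple[int, int]]:
    """Valid start window for a given score, or None below the floor.

    Returns the window of the highest tier whose min_score the score
    reaches, both ends inclusive.
    """
    if score < window_map.min_score_floor:
        return None
    chosen = None
    for tier in window_map.tiers:
        if score >= tier.min_score:
            chosen = (tier.window_start, tier.window_end)
    return chosen


@dataclass
class ClassificationDecision:
    """Per-read verdict with the evidence that produced it."""

    status: str  # assigned | unclassified | too_short
    barcode_id: Optional[str] = None
    best: Optional[AlignmentResult] = None
    runner_up_score: Optional[int] = None
    reject_reason: str = "none"  # below_min_score | margin_too_small |
    # outside_window | no_alignment | read_too_short | none

    def __post_init__(self) -> None:
        if self.status == "assigned" and self.reject_reason != "none":
            raise ValueError("assigned decision cannot carry a reject reason")
        if self.status != "assigned" and self.reject_reason == "none":
            raise ValueError(f"{self.status} decision needs a reject reason")


def scan_read(
    read: ReadRecord,
    barcodes: Sequence[BarcodeRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    scan_window: int = 110,
    scan_revcomp: bool = False,
) -> list[AlignmentResult]:
    """Best alignment of every barcode within the read's leading window.

    Only the first ``scan_window`` bases of the (untrimmed) read are
    scanned; shorter reads are scanned whole.  Returns one result per
    barcode whose best alignment scores above zero.  With
    ``scan_revcomp`` each barcode is additionally aligned as its reverse
    complement and the better orientation is kept (forward wins ties).
    """
    prefix = read.sequence[: scan_window]
    if not prefix:
        return []
    tcodes = encode_sequence(prefix)
    results: list[AlignmentResult] = []
    for bc in barcodes:
        hit = _best_for_barcode(bc.sequence, bc.codes, tcodes, prefix, scheme, bc.barcode_id, "+")
        if scan_revcomp:
            rc = reverse_complement(bc.sequence)
            rc_hit = _best_for_barcode(
                rc, encode_sequence(rc), tcodes, prefix, scheme, bc.barcode_id, "-"
            )
            if rc_hit is not None and (hit is None or rc_hit.score > hit.score):
                hit = rc_hit
        if hit is not None:
            results.append(hit)
    return results


def _best_for_barcode(query, qcodes, tcodes, prefix, scheme, barcode_id, strand):
    if scheme.is_linear:
        score, start, end = sw_best(
            qcodes, tcodes, scheme.match, scheme.mismatch, scheme.gap
        )
        if score <= 0:
            return None
        return AlignmentResult(
            barcode_id=barcode_id,
            score=int(score),
            read_start=int(start),
            read_end=int(end),
            strand=strand,
        )
    res = local_align(query, prefix, scheme, barcode_id=barcode_id)
    if res is not None:
        res.strand = strand
    return res


def decide(
    alignments: Sequence[AlignmentResult],
    window_map: WindowMap = DEFAULT_WINDOW_MAP,
    margin: int = 2,
    prefilter_positions: bool = False,
) -> ClassificationDecision:
    """Turn per-barcode alignments into one classification decision.

    The default is rank-then-filter: rank candidates by score, apply the
    margin rule against the best distinct runner-up, then apply the
    positional filter to the winner only.  ``prefilter_positions`` instead
    drops every candidate failing its own score-tier window before
    ranking (an alternative reading of the procedure, off by default).

    The decision is independent of the order of ``alignments``: ties are
    broken by barcode id, and the verdict never depends on input order.
    """
    # collapse to one best alignment per distinct barcode (a barcode
    # competing with itself is not ambiguity)
    per_barcode: dict[str, AlignmentResult] = {}
    for aln in alignments:
        cur = per_barcode.get(aln.barcode_id)
        if cur is None or (aln.score, -aln.read_start) > (cur.score, -cur.read_start):
            per_barcode[aln.barcode_id] = aln
    candidates = sorted(
        per_barcode.values(), key=lambda a: (-a.score, a.barcode_id)
    )
    if prefilter_positions:
        candidates = [
            a
            for a in candidates
            if (w := window_for_score(a.score, window_map)) is not None
            and w[0] <= a.read_start <= w[1]
        ]
    if not candidates:
        return ClassificationDecision(status="unclassified", reject_reason="no_alignment")
    best = candidates[0]
    runner_up = candidates[1].score if len(candidates) > 1 else None
    if best.score < window_map.min_score_floor:
        return ClassificationDecision(
            status="unclassified", best=best, runner_up_score=runner_up,
            reject_reason="below_min_score",
        )
    if runner_up is not None and best.score - runner_up < margin:
        return ClassificationDecision(
            status="unclassified", best=best, runner_up_score=runner_up,
            reject_reason="margin_too_small",
        )
    window = window_for_score(best.score, window_map)
    if window is None or not (window[0] <= best.read_start <= window[1]):
        return ClassificationDecision(
            status="unclassified", best=best, runner_up_score=runner_up,
            reject_reason="outside_window",
        )
    return ClassificationDecision(
        status="assigned", barcode_id=best.barcode_id, best=best,
        runner_up_score=runner_up,
    )
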