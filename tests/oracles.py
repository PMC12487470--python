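"""Independent alignment oracles for the test suite.

Three oracles of increasing speed and decreasing generality, kept
deliberately independent of the production dynamic program:

* :func:`enum_best` — explicit enumeration of every alignment path between
  every substring pair (tiny inputs only);
* :func:`rec_best` — a start-anchored memoized recursion over suffixes,
  carrying the match-run state, so it also scores the run-bonus mode;
* :func:`biopython_best` — Bio.Align.PairwiseAligner in local mode, for
  linear-gap schemes at scale.
"""

from __future__ import annotations

from functools import lru_cache

from nanodemux.align import ScoringScheme

_ACGT = set("ACGT")


def _is_match(a: str, b: str) -> bool:
    return a == b and a in _ACGT and b in _ACGT


def score_ops(ops: str, scheme: ScoringScheme) -> int:
    """Score an explicit op string (M/X/I/D) including run bonuses."""
    score = 0
    run = 0
    for op in ops:
        if op == "M":
            score += scheme.match
            run += 1
        else:
            if run >= scheme.run_min:
                score += scheme.run_bonus
            run = 0
            score += scheme.mismatch if op == "X" else scheme.gap
    if run >= scheme.run_min:
        score += scheme.run_bonus
    return score


def enum_best(query: str, target: str, scheme: ScoringScheme) -> int:
    """Best local score by explicit enumeration of all alignment paths.

    Exponential; intended for query <= 4, target <= 6.  Returns 0 when no
    alignment scores above zero.
    """
    best = 0

    def walk(i: int, j: int, ops: list[str]) -> None:
        nonlocal best
        if ops:
            s = score_ops("".join(ops), scheme)
            if s > best:
                best = s
        if i < len(query) and j < len(target):
            ops.append("M" if _is_match(query[i], target[j]) else "X")
            walk(i + 1, j + 1, ops)
            ops.pop()
        if i < len(query):
            ops.append("D")
            walk(i + 1, j, ops)
            ops.pop()
        if j < len(target):
            ops.append("I")
            walk(i, j + 1, ops)
            ops.pop()

    for qs in range(len(query)):
        for ts in range(len(target)):
            walk(qs, ts, [])
    return best


def rec_best(query: str, target: str, scheme: ScoringScheme) -> int:
    """Best local score via a start-anchored suffix recursion.

    Carries the current match-run length (capped at ``run_min``) so the
    run bonus is banked exactly once per maximal run, including the run
    ended by stopping.  Returns 0 when no alignment scores above zero.
    """
    cap = scheme.run_min

    @lru_cache(maxsize=None)
    def go(i: int, j: int, run: int) -> int:
        closed = scheme.run_bonus if run >= cap else 0
        best = closed  # stop here
        if i < len(query) and j < len(target):
            if _is_match(query[i], target[j]):
                best = max(best, scheme.match + go(i + 1, j + 1, min(run + 1, cap)))
            else:
                best = max(best, closed + scheme.mismatch + go(i + 1, j + 1, 0))
        if i < len(query):
            best = max(best, closed + scheme.gap + go(i + 1, j, 0))
        if j < len(target):
            best = max(best, closed + scheme.gap + go(i, j + 1, 0))
        return best

    best = 0
    for qs in range(len(query)):
        for ts in range(len(target)):
            best = max(best, go(qs, ts, 0))
    go.cache_clear()
    return best


def biopython_best(query: str, target: str, scheme: ScoringScheme) -> int:
    """Best local score from Bio.Align (linear-gap schemes only)."""
    from Bio import Align

    if not scheme.is_linear:
        raise ValueError("biopython oracle only covers linear schemes")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap
    aligner.extend_gap_score = scheme.gap
    return int(aligner.score(query, target))
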