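"""Local alignment of short barcode queries against read prefixes.

The scoring model is classic Smith-Waterman with linear gap costs, plus an
optional *run bonus*: a fixed reward added once for every maximal run of
consecutive matches of length >= ``run_min``.  The bonus rewards alignments
whose matches come in contiguous blocks — the situation produced by a real
barcode interrupted by the 1-base insertions and deletions that dominate
nanopore error profiles — without changing the classic SW behaviour when it
is disabled (the default).

Coordinates in :class:`AlignmentResult` are 1-based and inclusive on both
sequences, the convention used throughout the package for positions reported
to users and consumed by the positional filter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "DEFAULT_SCHEME",
    "local_align",
    "reverse_complement",
    "encode_sequence",
]

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

# base codes: A=0 C=1 G=2 T=3, anything else (N, IUPAC ambiguity) = 4.
# Code 4 never equals a barcode code, so ambiguous read bases score as a
# mismatch against every barcode base.
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string (IUPAC letters supported)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters.

    match : reward per matched base (> 0)
    mismatch : penalty per mismatched base (<= 0)
    gap : penalty per gapped base, linear (<= 0)
    run_bonus : reward added once per maximal match run of length >= run_min
        (0 disables the non-linear mode)
    run_min : minimum run length that earns the bonus (>= 2)
    """

    match: int = 1
    mismatch: int = -1
    gap: int = -1
    run_bonus: int = 0
    run_min: int = 4

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0:
            raise ValueError("mismatch penalty must be <= 0")
        if self.gap > 0:
            raise ValueError("gap penalty must be <= 0")
        if self.run_bonus < 0:
            raise ValueError("run_bonus must be >= 0")
        if self.run_min < 2:
            raise ValueError("run_min must be >= 2")

    @property
    def is_linear(self) -> bool:
        """True when the scheme reduces to classic SW (no run bonus)."""
        return self.run_bonus == 0


DEFAULT_SCHEME = ScoringScheme()
# With match=+1 a perfect 24-nt barcode scores 24, so the default score
# floor of 13 demands better than half of an intact barcode.


@dataclass
class AlignmentResult:
    """Best local alignment of a barcode within a read prefix.

    ``ops`` is an alignment operation string over M (match), X (mismatch),
    I (insertion in the read, i.e. a read base not in the barcode) and
    D (deletion from the barcode).  Batch scanning leaves ``ops`` (and the
    barcode-side coordinates) as ``None`` for speed; :func:`local_align`
    always fills them in.
    """

    barcode_id: str
    score: int
    read_start: int
    read_end: int
    barcode_start: Optional[int] = None
    barcode_end: Optional[int] = None
    ops: Optional[str] = None
    strand: str = "+"

    def score_from_ops(self, scheme: ScoringScheme) -> int:
        """Recompute the score from the operation string (self-consistency)."""
        if self.ops is None:
            raise ValueError("alignment has no operation string")
        score = 0
        run = 0
        for op in self.ops:
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


def local_align(
    query: str,
    target: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    barcode_id: str = "",
) -> Optional[AlignmentResult]:
    """Maximum-scoring local alignment of ``query`` inside ``target``.

    Returns ``None`` when no alignment scores above zero.  When several
    alignments attain the maximum score, the one with the smallest
    ``read_start`` is returned, then the smallest ``read_end`` — a
    deterministic, input-order-independent tie-break.

    This is the reference dynamic program: it carries an explicit
    match-run state so the run bonus (when enabled) is banked exactly once
    per maximal run, including a run cut short by the end of the alignment.
    With ``run_bonus == 0`` it is classic Smith-Waterman with linear gaps.
    """
    m, n = len(query), len(target)
    if m == 0 or n == 0:
        return None
    q = encode_sequence(query)
    t = encode_sequence(target)
    cap = scheme.run_min  # run-state r in 0..cap; r == cap means "run >= run_min"
    bonus = scheme.run_bonus
    NEG = -(1 << 30)

    # H[r][j] for current row i; orig[r][j] = minimal 1-based read start
    # among optimal paths into the cell.  Backpointers kept per cell/state.
    width = n + 1
    nstate = cap + 1
    H_prev = [[NEG] * width for _ in range(nstate)]
    O_prev = [[0] * width for _ in range(nstate)]
    # bp[i][j][r] = (pi, pj, pr, op) or None for a fresh start
    bp: list[list[list[object]]] = [
        [[None] * nstate for _ in range(width)] for _ in range(m + 1)
    ]

    best_final = 0
    best = None  # (i, j, r)
    best_orig = 0

    for i in range(1, m + 1):
        H_cur = [[NEG] * width for _ in range(nstate)]
        O_cur = [[0] * width for _ in range(nstate)]
        qi = q[i - 1]
        for j in range(1, n + 1):
            tj = t[j - 1]
            is_match = qi == tj and qi < 4
            sub = scheme.match if is_match else scheme.mismatch
            if is_match:
                # extend (or start) a match run: from any state r' at
                # (i-1, j-1) to state min(r'+1, cap); fresh start -> state 1.
                for rp in range(nstate):
                    vp = H_prev[rp][j - 1]
                    if vp <= NEG:
                        continue
                    r = min(rp + 1, cap)
                    v = vp + sub
                    o = O_prev[rp][j - 1]
                    if v > H_cur[r][j] or (v == H_cur[r][j] and o < O_cur[r][j]):
                        H_cur[r][j] = v
                        O_cur[r][j] = o
                        bp[i][j][r] = (i - 1, j - 1, rp, "M")
                v = sub  # fresh start consuming (qi, tj)
                if v > H_cur[1][j] or (v == H_cur[1][j] and j < O_cur[1][j]):
                    H_cur[1][j] = v
                    O_cur[1][j] = j
                    bp[i][j][1] = None
            else:
                # mismatch / gaps close the current run (banking the bonus
                # if it qualified) and land in state 0.
                bv = NEG
                bo = 0
                bbp: object = None
                for rp in range(nstate):
                    closed = bonus if rp == cap else 0
                    vp = H_prev[rp][j - 1]
                    if vp > NEG:
                        v = vp + closed + sub
                        o = O_prev[rp][j - 1]
                        if v > bv or (v == bv and o < bo):
                            bv, bo, bbp = v, o, (i - 1, j - 1, rp, "X")
                    vp = H_prev[rp][j]  # gap consuming query base (D)
                    if vp > NEG:
                        v = vp + closed + scheme.gap
                        o = O_prev[rp][j]
                        if v > bv or (v == bv and o < bo):
                            bv, bo, bbp = v, o, (i - 1, j, rp, "D")
                    vp = H_cur[rp][j - 1]  # gap consuming read base (I)
                    if vp > NEG:
                        v = vp + closed + scheme.gap
                        o = O_cur[rp][j - 1]
                        if v > bv or (v == bv and o < bo):
                            bv, bo, bbp = v, o, (i, j - 1, rp, "I")
                v = sub  # fresh start on a mismatch
                if v > bv or (v == bv and j < bo):
                    bv, bo, bbp = v, j, None
                H_cur[0][j] = bv
                O_cur[0][j] = bo
                bp[i][j][0] = bbp
            # mismatch branch also needs D/I transitions into state 0 when
            # the current column IS a match column (a gap may follow a match)
            if is_match:
                bv = H_cur[0][j]
                bo = O_cur[0][j]
                bbp = bp[i][j][0]
                for rp in range(nstate):
                    closed = bonus if rp == cap else 0
                    vp = H_prev[rp][j]
                    if vp > NEG:
                        v = vp + closed + scheme.gap
                        o = O_prev[rp][j]
                        if v > bv or (v == bv and o < bo):
                            bv, bo, bbp = v, o, (i - 1, j, rp, "D")
                    vp = H_cur[rp][j - 1]
                    if vp > NEG:
                        v = vp + closed + scheme.gap
                        o = O_cur[rp][j - 1]
                        if v > bv or (v == bv and o < bo):
                            bv, bo, bbp = v, o, (i, j - 1, rp, "I")
                H_cur[0][j] = bv
                O_cur[0][j] = bo
                bp[i][j][0] = bbp
            # global best over final scores (bank the trailing run's bonus)
            for r in range(nstate):
                v = H_cur[r][j]
                if v <= NEG:
                    continue
                final = v + (bonus if r == cap else 0)
                o = O_cur[r][j]
                if (
                    final > best_final
                    or (final == best_final and best is not None and o < best_orig)
                    or (
                        final == best_final
                        and best is not None
                        and o == best_orig
                        and (j, i) < (best[1], best[0])
                    )
                ):
                    best_final = final
                    best = (i, j, r)
                    best_orig = o
        H_prev, O_prev = H_cur, O_cur

    if best is None or best_final <= 0:
        return None

    # traceback; end coordinates come from the last op that consumes each
    # sequence (a zero-cost trailing gap must not inflate read_end)
    i, j, r = best
    ops_rev = []
    qend = None
    tend = None
    while True:
        step = bp[i][j][r]
        if step is None:
            break
        pi, pj, pr, op = step
        ops_rev.append(op)
        if tend is None and op in "MXI":
            tend = j
        if qend is None and op in "MXD":
            qend = i
        i, j, r = pi, pj, pr
    # the fresh-start cell itself consumed one diagonal step
    ops_rev.append("M" if q[i - 1] == t[j - 1] and q[i - 1] < 4 else "X")
    if tend is None:
        tend = j
    if qend is None:
        qend = i
    ops = "".join(reversed(ops_rev))
    return AlignmentResult(
        barcode_id=barcode_id,
        score=best_final,
        read_start=j,
        read_end=tend,
        barcode_start=i,
        barcode_end=qend,
        ops=ops,
    )


def realign(result: AlignmentResult, query: str, target: str,
            scheme: ScoringScheme = DEFAULT_SCHEME) -> AlignmentResult:
    """Fill in ops/barcode coordinates for a batch-scanned result."""
    if result.ops is not None:
        return result
    full = local_align(query, target, scheme, barcode_id=result.barcode_id)
    if full is None:  # pragma: no cover - batch scan only keeps positive scores
        raise RuntimeError("batch result could not be realigned")
    return replace(full, strand=result.strand)
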