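"""Seeded generator of barcoded nanopore-like reads with ground truth.

Each positive read follows the rapid-barcoding layout the classifier
expects: a random leader (default 46 nt, so the barcode starts at position
47), the barcode, a fixed flanking adapter-like constant, and a random
genomic-like insert.  Errors are applied per position, independently, as
mutually exclusive substitution / insertion-after / deletion events — a
deliberately simple error model that exercises the classifier's indel
tolerance without emulating homopolymer or signal-level effects.  Negative
controls are pure random sequence with no barcode structure at all.

Everything is a pure function of (parameters, seed): identical inputs give
byte-identical FASTQ and truth files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .io import BarcodeRecord, ReadRecord, load_barcode_set, write_reads

__all__ = [
    "SimParams",
    "SimTruth",
    "FLANK",
    "apply_errors",
    "simulate_reads",
    "generate_dataset",
    "generate_negative",
    "write_truth",
    "read_truth",
]

#: fixed 30-nt adapter-like constant placed after the barcode.  A synthetic
#: stand-in sequence (real kit adapters are neither public nor needed to
#: exercise the algorithm); fixed so trimming tests know the exact suffix.
FLANK = "GCTTGGGTGTTTAACCTTAGCAATACGTAA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Synthetic read generation parameters.

    ``leader_length`` defaults to 46 so the barcode starts at read
    position 47; ``insert_length`` defaults to 1000 nt so reads clear the
    550-nt length filter; ``q_const`` is the constant Phred score written
    for every base (default 12, a typical nanopore mean).
    """

    n_reads: int = 100
    barcode_set: Union[str, tuple[BarcodeRecord, ...]] = "builtin24"
    leader_length: int = 46
    flank: str = FLANK
    insert_length: int = 1000
    p_sub: float = 0.0
    p_ins: float = 0.0
    p_del: float = 0.0
    q_const: int = 12
    seed: int = 0
    start_jitter: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0 or self.leader_length < 0 or self.insert_length < 0:
            raise ValueError("counts and lengths must be >= 0")
        for p in (self.p_sub, self.p_ins, self.p_del):
            if not 0.0 <= p <= 1.0:
                raise ValueError("error probabilities must be in [0, 1]")
        if self.p_sub + self.p_ins + self.p_del > 1.0:
            raise ValueError("p_sub + p_ins + p_del must be <= 1")
        if self.start_jitter < 0 or self.start_jitter > self.leader_length:
            raise ValueError("start_jitter must be in [0, leader_length]")

    def barcodes(self) -> list[BarcodeRecord]:
        if isinstance(self.barcode_set, str):
            return load_barcode_set(self.barcode_set)
        return list(self.barcode_set)


@dataclass
class SimTruth:
    """Ground truth for one simulated read (pre-error template coordinates)."""

    read_id: str
    true_barcode: str  # barcode_id or "none"
    barcode_start: int  # 1-based; 0 for negative reads
    barcode_end: int


def _random_dna(rng: np.random.Generator, length: int) -> str:
    if length == 0:
        return ""
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def apply_errors(
    sequence: str,
    p_sub: float,
    p_ins: float,
    p_del: float,
    rng: np.random.Generator,
) -> str:
    """Corrupt a sequence with per-position substitution/insertion/deletion.

    At each position exactly one of the three events may fire (mutually
    exclusive, probabilities summing to at most 1): substitution replaces
    the base with a different one, insertion keeps the base and appends a
    random base after it, deletion drops the base.  With all rates zero the
    input is returned unchanged; the expected length change is
    ``len * (p_ins - p_del)``.
    """
    if not sequence or (p_sub == 0.0 and p_ins == 0.0 and p_del == 0.0):
        return sequence
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    n = codes.shape[0]
    u = rng.random(n)
    sub_mask = u < p_sub
    ins_mask = (u >= p_sub) & (u < p_sub + p_ins)
    del_mask = (u >= p_sub + p_ins) & (u < p_sub + p_ins + p_del)
    # substitute: add 1..3 steps around the A/C/G/T wheel so the base changes
    if sub_mask.any():
        idx = np.where(sub_mask)[0]
        lut = np.zeros(256, dtype=np.int64)
        for k, b in enumerate("ACGT"):
            lut[ord(b)] = k
        cur = lut[codes[idx]]
        new = (cur + rng.integers(1, 4, size=idx.shape[0])) % 4
        codes[idx] = _BASES[new]
    out = []
    ins_bases = rng.integers(0, 4, size=int(ins_mask.sum()))
    ins_at = 0
    for i in range(n):
        if del_mask[i]:
            continue
        out.append(codes[i])
        if ins_mask[i]:
            out.append(_BASES[ins_bases[ins_at]])
            ins_at += 1
    return bytes(out).decode("ascii")


def simulate_reads(
    params: SimParams, negative: bool = False
) -> tuple[list[ReadRecord], list[SimTruth]]:
    """Generate reads and their ground truth in memory.

    Positive reads are leader + barcode + flank + insert with errors
    applied to the whole template; barcodes are assigned round-robin over
    the set so per-barcode counts are exact.  Negative reads are pure
    random sequence of the same overall length, truth ``none``.
    """
    rng = np.random.default_rng(params.seed)
    barcodes = params.barcodes() if not negative else []
    qual_char = chr(params.q_const + 33)
    reads: list[ReadRecord] = []
    truths: list[SimTruth] = []
    for k in range(params.n_reads):
        if negative:
            length = (
                params.leader_length + len(params.flank) + params.insert_length + 24
            )
            seq = apply_errors(
                _random_dna(rng, length),
                params.p_sub, params.p_ins, params.p_del, rng,
            )
            read_id = f"neg{k:06d}"
            truths.append(SimTruth(read_id, "none", 0, 0))
        else:
            bc = barcodes[k % len(barcodes)]
            leader_len = params.leader_length
            if params.start_jitter:
                leader_len += int(
                    rng.integers(-params.start_jitter, params.start_jitter + 1)
                )
            leader = _random_dna(rng, leader_len)
            insert = _random_dna(rng, params.insert_length)
            template = leader + bc.sequence + params.flank + insert
            seq = apply_errors(
                template, params.p_sub, params.p_ins, params.p_del, rng
            )
            read_id = f"sim{k:06d}"
            truths.append(
                SimTruth(read_id, bc.barcode_id, leader_len + 1,
                         leader_len + len(bc.sequence))
            )
        reads.append(
            ReadRecord(read_id=read_id, sequence=seq, quality=qual_char * len(seq))
        )
    return reads, truths


def write_truth(truths: Sequence[SimTruth], path: Union[str, Path]) -> None:
    """Write the ground-truth table as TSV with a header line."""
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write("read_id\ttrue_barcode\tbarcode_start\tbarcode_end\n")
        for t in truths:
            fh.write(f"{t.read_id}\t{t.true_barcode}\t{t.barcode_start}\t{t.barcode_end}\n")


def read_truth(path: Union[str, Path]) -> dict[str, str]:
    """Read a truth TSV back as a read_id -> true_barcode mapping."""
    mapping: dict[str, str] = {}
    with open(path, encoding="ascii") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        id_col = header.index("read_id")
        bc_col = header.index("true_barcode")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            mapping[fields[id_col]] = fields[bc_col]
    return mapping


def generate_dataset(
    params: SimParams,
    out_fastq: Union[str, Path],
    out_truth: Union[str, Path],
) -> dict[str, int]:
    """Write a positive dataset (FASTQ + truth TSV); returns counts per barcode."""
    reads, truths = simulate_reads(params, negative=False)
    write_reads(reads, out_fastq)
    write_truth(truths, out_truth)
    manifest: dict[str, int] = {}
    for t in truths:
        manifest[t.true_barcode] = manifest.get(t.true_barcode, 0) + 1
    return manifest


def generate_negative(
    params: SimParams,
    out_fastq: Union[str, Path],
    out_truth: Optional[Union[str, Path]] = None,
) -> int:
    """Write a barcode-free negative-control FASTQ; returns the read count."""
    reads, truths = simulate_reads(params, negative=True)
    write_reads(reads, out_fastq)
    if out_truth is not None:
        write_truth(truths, out_truth)
    return len(reads)
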