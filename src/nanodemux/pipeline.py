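"""End-to-end demultiplexing: stream, length-filter, classify, trim, route.

Every input read lands in exactly one routing class:

* ``too_short`` — raw length below the minimum (default 550 nt), set aside
  before any alignment so that downstream length/quality expectations hold;
* ``assigned`` to a barcode — written twice, once adapter-trimmed (the
  sequence after the barcode hit plus any configured adapter tail) and once
  as the full original record for quality control;
* ``unclassified`` — everything else, written untrimmed.

Outputs are byte-deterministic: a fixed input discovery order, order-
preserving parallelism and zeroed gzip timestamps make repeat runs (and
runs with different worker counts) produce identical files.
"""

from __future__ import annotations

import logging
import math
import sys
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

from .align import AlignmentResult, DEFAULT_SCHEME, ScoringScheme
from .classify import (
    ClassificationDecision,
    DEFAULT_WINDOW_MAP,
    WindowMap,
    decide,
    scan_read,
)
from .io import (
    BarcodeRecord,
    BarcodeSetError,
    ReadRecord,
    iter_reads,
    load_barcode_set,
    open_fastq_writer,
    format_record,
)

__all__ = [
    "DemuxConfig",
    "SummaryRow",
    "DemuxSummary",
    "trim_read",
    "demux",
    "summarize",
]

logger = logging.getLogger("nanodemux")

_CHUNK = 2000  # reads per worker chunk; invisible in the output


@dataclass(frozen=True)
class DemuxConfig:
    """All tunable demultiplexing parameters.

    Defaults follow the rapid-barcoding layout: scan the first 110 nt,
    require a score of 13 and a margin of 2, keep reads of at least 550 nt,
    and apply the tiered positional windows of
    :data:`~nanodemux.classify.DEFAULT_WINDOW_MAP`.
    """

    scan_window: int = 110
    min_score_floor: int = 13
    margin: int = 2
    min_length: int = 550
    window_map: WindowMap = DEFAULT_WINDOW_MAP
    scheme: ScoringScheme = DEFAULT_SCHEME
    adapter_tail: int = 0
    threads: int = 1
    scan_revcomp: bool = False
    prefilter_positions: bool = False
    qc_prefix_only: bool = False

    def __post_init__(self) -> None:
        for name in ("scan_window", "margin", "min_length", "adapter_tail"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.scan_window < 1:
            raise ValueError("scan_window must be >= 1")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if self.window_map.min_score_floor != self.min_score_floor:
            object.__setattr__(
                self,
                "window_map",
                replace(self.window_map, min_score_floor=self.min_score_floor),
            )


@dataclass
class SummaryRow:
    """One row of the run summary (per barcode, unclassified, too_short)."""

    label: str
    n_reads: int
    fraction: float
    total_bases: int
    mean_length: float
    mean_quality: float


class DemuxSummary(list):
    """Summary rows plus run counters.

    Behaves as a list of :class:`SummaryRow`; also carries ``n_input``,
    ``n_aligned`` (reads that reached the aligner — never includes
    too-short reads) and ``n_empty_trim`` (assigned reads whose trimmed
    sequence came out empty).
    """

    n_input: int = 0
    n_aligned: int = 0
    n_empty_trim: int = 0


def trim_read(
    read: ReadRecord, best: AlignmentResult, adapter_tail: int = 0
) -> tuple[ReadRecord, ReadRecord]:
    """Split an assigned read at the end of its barcode hit.

    Returns ``(trimmed, qc)``: ``trimmed`` is the suffix after
    ``best.read_end + adapter_tail`` (clamped to the read length) with its
    qualities; ``qc`` is the untouched original record.  The leading
    ``cut`` bases plus ``trimmed.sequence`` always reconstruct the
    original sequence exactly.
    """
    cut = min(best.read_end + adapter_tail, len(read.sequence))
    trimmed = ReadRecord(
        read_id=read.read_id,
        sequence=read.sequence[cut:],
        quality=read.quality[cut:],
        comment=read.comment,
        source=read.source,
    )
    return trimmed, read


def _qc_record(read: ReadRecord, best: AlignmentResult, adapter_tail: int,
               prefix_only: bool) -> ReadRecord:
    if not prefix_only:
        return read
    cut = min(best.read_end + adapter_tail, len(read.sequence))
    return ReadRecord(
        read_id=read.read_id,
        sequence=read.sequence[:cut],
        quality=read.quality[:cut],
        comment=read.comment,
        source=read.source,
    )


@dataclass
class _ClassStats:
    n_reads: int = 0
    total_bases: int = 0
    sum_err: float = 0.0

    def add(self, record: ReadRecord) -> None:
        self.n_reads += 1
        self.total_bases += len(record.sequence)
        self.sum_err += sum(10.0 ** (-(ord(c) - 33) / 10.0) for c in record.quality)


def _mean_quality(stats: _ClassStats) -> float:
    # Phred of the mean per-base error probability, the convention of
    # common long-read QC tools (not the mean of per-base Phred scores).
    if stats.total_bases == 0:
        return 0.0
    p = stats.sum_err / stats.total_bases
    if p <= 0.0:
        return 0.0
    return -10.0 * math.log10(p)


def summarize(
    stats: dict[str, _ClassStats],
    barcode_ids: Sequence[str],
    n_input: int,
) -> list[SummaryRow]:
    """Build summary rows from per-class routing statistics.

    One row per barcode (zero-count barcodes included), then
    ``unclassified`` and ``too_short``.  Fractions are relative to the
    total input read count and are defined as 0 for an empty run.
    """
    rows = []
    for label in [*barcode_ids, "unclassified", "too_short"]:
        s = stats.get(label, _ClassStats())
        rows.append(
            SummaryRow(
                label=label,
                n_reads=s.n_reads,
                fraction=(s.n_reads / n_input) if n_input else 0.0,
                total_bases=s.total_bases,
                mean_length=(s.total_bases / s.n_reads) if s.n_reads else 0.0,
                mean_quality=_mean_quality(s),
            )
        )
    return rows


def _classify_chunk(chunk, barcodes, config):
    out = []
    for read in chunk:
        alignments = scan_read(
            read, barcodes, config.scheme, config.scan_window, config.scan_revcomp
        )
        out.append(
            decide(
                alignments,
                config.window_map,
                config.margin,
                config.prefilter_positions,
            )
        )
    return out


def _chunks(iterable: Iterable[ReadRecord], size: int) -> Iterator[list[ReadRecord]]:
    chunk: list[ReadRecord] = []
    for item in iterable:
        chunk.append(item)
        if len(chunk) >= size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk


def demux(
    input_path: Union[str, Path, Iterable[ReadRecord]],
    barcodes: Union[str, Path, Sequence[BarcodeRecord]],
    config: DemuxConfig = DemuxConfig(),
    out_dir: Union[str, Path] = "demux_out",
) -> DemuxSummary:
    """Demultiplex reads into per-barcode, unclassified and too-short files.

    ``input_path`` may be a FASTQ file, a directory of FASTQ files, or any
    iterable of :class:`ReadRecord`.  ``barcodes`` may be a FASTA path, a
    built-in set name, or a loaded barcode list.  Writes
    ``<id>.trimmed.fastq.gz``, ``<id>.untrimmed.fastq.gz``,
    ``unclassified.fastq.gz``, ``too_short.fastq.gz`` and ``summary.tsv``
    into ``out_dir`` and returns the summary rows.
    """
    if isinstance(barcodes, (str, Path)):
        barcode_set = load_barcode_set(barcodes)
    else:
        barcode_set = list(barcodes)
        if not barcode_set:
            raise BarcodeSetError("empty barcode set")
    longest = max(len(b.sequence) for b in barcode_set)
    if config.scan_window < longest:
        raise ValueError(
            f"scan_window {config.scan_window} is shorter than the longest "
            f"barcode ({longest} nt)"
        )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(input_path, (str, Path)):
        reads: Iterable[ReadRecord] = iter_reads(input_path)
    else:
        reads = input_path

    stats: dict[str, _ClassStats] = {}
    summary = DemuxSummary()
    writers = {}
    try:
        for bc in barcode_set:
            writers[(bc.barcode_id, "trimmed")] = open_fastq_writer(
                out / f"{bc.barcode_id}.trimmed.fastq.gz"
            )
            writers[(bc.barcode_id, "untrimmed")] = open_fastq_writer(
                out / f"{bc.barcode_id}.untrimmed.fastq.gz"
            )
        writers["unclassified"] = open_fastq_writer(out / "unclassified.fastq.gz")
        writers["too_short"] = open_fastq_writer(out / "too_short.fastq.gz")

        def handle(read: ReadRecord, decision: Optional[ClassificationDecision]):
            summary.n_input += 1
            if decision is None:  # too short, never aligned
                writers["too_short"].write(format_record(read))
                stats.setdefault("too_short", _ClassStats()).add(read)
                return
            summary.n_aligned += 1
            if decision.status == "assigned":
                trimmed, _ = trim_read(read, decision.best, config.adapter_tail)
                if len(trimmed.sequence) == 0:
                    summary.n_empty_trim += 1
                qc = _qc_record(
                    read, decision.best, config.adapter_tail, config.qc_prefix_only
                )
                writers[(decision.barcode_id, "trimmed")].write(format_record(trimmed))
                writers[(decision.barcode_id, "untrimmed")].write(format_record(qc))
                stats.setdefault(decision.barcode_id, _ClassStats()).add(trimmed)
            else:
                writers["unclassified"].write(format_record(read))
                stats.setdefault("unclassified", _ClassStats()).add(read)

        def split(stream: Iterable[ReadRecord]):
            # peel off too-short reads before they can reach the aligner
            for read in stream:
                if len(read.sequence) < config.min_length:
                    handle(read, None)
                else:
                    yield read

        long_reads = split(reads)
        if config.threads == 1:
            for chunk in _chunks(long_reads, _CHUNK):
                for read, decision in zip(
                    chunk, _classify_chunk(chunk, barcode_set, config)
                ):
                    handle(read, decision)
        else:
            # bounded in-order pipeline: submit up to 2x threads chunks,
            # drain the oldest first so output order equals input order
            from collections import deque

            with ThreadPoolExecutor(max_workers=config.threads) as pool:
                pending: deque = deque()
                chunk_iter = _chunks(long_reads, _CHUNK)
                done = False
                while pending or not done:
                    while not done and len(pending) < 2 * config.threads:
                        chunk = next(chunk_iter, None)
                        if chunk is None:
                            done = True
                            break
                        pending.append(
                            (chunk, pool.submit(_classify_chunk, chunk, barcode_set, config))
                        )
                    if pending:
                        chunk, future = pending.popleft()
                        for read, decision in zip(chunk, future.result()):
                            handle(read, decision)
    finally:
        for w in writers.values():
            w.close()

    summary.extend(
        summarize(stats, [b.barcode_id for b in barcode_set], summary.n_input)
    )
    with open(out / "summary.tsv", "w", encoding="ascii", newline="\n") as fh:
        fh.write("label\tn_reads\tfraction\ttotal_bases\tmean_length\tmean_quality\n")
        for row in summary:
            fh.write(
                f"{row.label}\t{row.n_reads}\t{row.fraction:.6f}\t"
                f"{row.total_bases}\t{row.mean_length:.2f}\t{row.mean_quality:.2f}\n"
            )
    for row in summary:
        if row.label in ("unclassified", "too_short") or row.n_reads:
            logger.info(
                "%s: %d reads (%.2f%%)", row.label, row.n_reads, 100 * row.fraction
            )
    return summary
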