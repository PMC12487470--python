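"""Reading and writing the formats the demultiplexer touches.

Barcode reference sets are FASTA; reads are FASTQ (plain or gzipped, single
file or a directory of files); ground-truth tables are TSV with a header.
Parsing goes through pysam's FastxFile with an extra validation layer,
because htslib tolerates some truncated records that must be hard errors
here (a silently dropped read would break the partition guarantee of the
pipeline).
"""

from __future__ import annotations

import gzip
import io as _io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pysam

from .align import encode_sequence

__all__ = [
    "BarcodeRecord",
    "ReadRecord",
    "DemuxError",
    "BarcodeSetError",
    "FastqParseError",
    "BUILTIN_SETS",
    "load_barcode_set",
    "iter_reads",
    "write_reads",
    "open_fastq_writer",
]

#: file-name suffixes recognised as FASTQ input (case-insensitive)
FASTQ_SUFFIXES = (".fastq", ".fq", ".fastq.gz", ".fq.gz")

#: names of the bundled barcode sets.  These are synthetic stand-ins for a
#: rapid-kit barcode reference: deterministic 24-mers with bounded pairwise
#: similarity, not the proprietary kit sequences.
BUILTIN_SETS = {
    "builtin24": "synthetic_rapid24.fasta",
    "builtin96": "synthetic_rapid96.fasta",
}


class DemuxError(Exception):
    """Base class for fatal demultiplexer errors."""


class BarcodeSetError(DemuxError):
    """Invalid barcode reference set."""


class FastqParseError(DemuxError):
    """Malformed or truncated FASTQ input."""


@dataclass(frozen=True)
class BarcodeRecord:
    """One named barcode sequence from a reference set."""

    barcode_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise BarcodeSetError(f"barcode {self.barcode_id!r}: empty sequence")
        if any(b not in "ACGT" for b in seq):
            raise BarcodeSetError(
                f"barcode {self.barcode_id!r}: sequence contains non-ACGT characters"
            )
        if not self.barcode_id:
            raise BarcodeSetError("barcode with empty id")

    @property
    def codes(self):
        """int8 base codes for the alignment kernel (cached)."""
        if not hasattr(self, "_codes"):
            object.__setattr__(self, "_codes", encode_sequence(self.sequence))
        return self._codes


@dataclass
class ReadRecord:
    """One FASTQ read.

    ``quality`` is the Phred+33 ASCII string, same length as ``sequence``;
    ``comment`` is the header text after the first whitespace, preserved
    verbatim on output; ``source`` names the originating file.
    """

    read_id: str
    sequence: str
    quality: str
    comment: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise FastqParseError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def quality_scores(self) -> list[int]:
        """Per-base Phred scores as integers."""
        return [ord(c) - 33 for c in self.quality]


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_barcode_set(path_or_name: Union[str, os.PathLike]) -> list[BarcodeRecord]:
    """Load an ordered barcode set from FASTA or a built-in set name.

    Built-in names are the keys of :data:`BUILTIN_SETS` (``builtin24``,
    ``builtin96``).  Sequences are upper-cased; order follows the file.
    Duplicate ids, empty or non-ACGT sequences are fatal errors naming the
    offending record.
    """
    key = str(path_or_name)
    if key in BUILTIN_SETS:
        path = _data_path(BUILTIN_SETS[key])
    else:
        path = Path(path_or_name)
        if not path.exists():
            raise BarcodeSetError(
                f"barcode set {key!r}: no such file and not one of "
                f"{sorted(BUILTIN_SETS)}"
            )
    records: list[BarcodeRecord] = []
    seen: set[str] = set()
    try:
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                if entry.sequence is None:
                    raise BarcodeSetError(
                        f"{path}: record {entry.name!r} has no sequence"
                    )
                if entry.name in seen:
                    raise BarcodeSetError(f"{path}: duplicate barcode id {entry.name!r}")
                seen.add(entry.name)
                records.append(BarcodeRecord(entry.name, entry.sequence))
    except OSError as exc:
        raise BarcodeSetError(f"{path}: cannot parse as FASTA ({exc})") from exc
    if not records:
        raise BarcodeSetError(f"{path}: no barcode records found")
    return records


def _is_fastq_name(name: str) -> bool:
    return name.lower().endswith(FASTQ_SUFFIXES)


def _iter_one_file(path: Path) -> Iterator[ReadRecord]:
    index = 0
    try:
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                if entry.quality is None:
                    raise FastqParseError(
                        f"{path}: truncated FASTQ record near record {index + 1} "
                        f"({entry.name!r}: missing quality line)"
                    )
                yield ReadRecord(
                    read_id=entry.name,
                    sequence=entry.sequence,
                    quality=entry.quality,
                    comment=entry.comment or "",
                    source=path.name,
                )
                index += 1
    except ValueError as exc:
        # htslib reports mid-file truncation as ValueError
        raise FastqParseError(
            f"{path}: truncated FASTQ record near record {index + 1} ({exc})"
        ) from exc
    except OSError as exc:
        raise FastqParseError(f"{path}: cannot read FASTQ ({exc})") from exc


def iter_reads(path: Union[str, os.PathLike]) -> Iterator[ReadRecord]:
    """Stream reads from a FASTQ file or a directory of FASTQ files.

    Directories are scanned non-recursively for ``.fastq``, ``.fq``,
    ``.fastq.gz`` and ``.fq.gz`` (case-insensitive) and processed in
    lexicographic name order, so multi-file runs are deterministic.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(
            (f for f in p.iterdir() if f.is_file() and _is_fastq_name(f.name)),
            key=lambda f: f.name,
        )
        if not files:
            raise FastqParseError(
                f"{p}: directory contains no files matching {FASTQ_SUFFIXES}"
            )
        for f in files:
            yield from _iter_one_file(f)
    elif p.is_file():
        yield from _iter_one_file(p)
    else:
        raise FastqParseError(f"{p}: no such file or directory")


def open_fastq_writer(path: Union[str, os.PathLike]):
    """Open a text handle for FASTQ output; ``.gz`` paths are gzipped.

    Gzip members are written with a zeroed mtime so identical record
    streams produce byte-identical files.
    """
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    if p.name.lower().endswith(".gz"):
        raw = open(p, "wb")
        gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
        return _io.TextIOWrapper(gz, encoding="ascii", newline="\n")
    return open(p, "w", encoding="ascii", newline="\n")


def format_record(record: ReadRecord) -> str:
    """One FASTQ record as a 4-line string block."""
    header = record.read_id
    if record.comment:
        header = f"{header} {record.comment}"
    return f"@{header}\n{record.sequence}\n+\n{record.quality}\n"


def write_reads(records: Iterable[ReadRecord], path: Union[str, os.PathLike]) -> int:
    """Write records to a FASTQ file (gzipped if the path ends in .gz).

    Returns the number of records written.  Records violating the
    quality/sequence length invariant are rejected before anything is
    written for them.
    """
    count = 0
    with open_fastq_writer(path) as out:
        for record in records:
            if len(record.quality) != len(record.sequence):
                raise FastqParseError(
                    f"read {record.read_id!r}: quality/sequence length mismatch"
                )
            out.write(format_record(record))
            count += 1
    return count
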