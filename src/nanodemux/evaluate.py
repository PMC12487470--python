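"""Scoring demultiplexer output against ground truth or negative controls.

Two evaluation modes:

* **truth scoring** — compare per-read calls with a truth table; reports
  the classification rate (assigned / total), per-barcode recovery and a
  confusion matrix keyed (truth, call);
* **negative control** — on a read set known to contain no barcodes, any
  assignment is a false positive.  The total FPR is assigned / total; the
  per-barcode FPR is conventionally the total divided by the number of
  barcodes, and the empirical per-barcode breakdown is reported alongside
  because uniform division hides skew.

``head_crop`` implements the negative-control construction: removing a
fixed number of leading bases destroys any residual barcode/adapter
content at the read start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd

from .io import ReadRecord

__all__ = [
    "EvalReport",
    "crop_read",
    "head_crop",
    "score_against_truth",
    "negative_control_fpr",
]


class EvaluationError(Exception):
    """Inconsistent evaluation inputs."""


@dataclass
class EvalReport:
    """Evaluation summary; ``confusion`` is keyed (truth, call)."""

    n_total: int
    n_classified: int
    classification_rate: float
    confusion: pd.DataFrame
    n_correct: int = 0
    accuracy: float = 0.0  # fraction of all reads assigned to their true barcode

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_classified": self.n_classified,
            "classification_rate": self.classification_rate,
            "n_correct": self.n_correct,
            "accuracy": self.accuracy,
            "confusion": {
                truth: {
                    call: int(v) for call, v in row.items() if v
                }
                for truth, row in self.confusion.to_dict(orient="index").items()
            },
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def crop_read(read: ReadRecord, n: int) -> Optional[ReadRecord]:
    """Drop the first ``n`` bases of one read; None if nothing remains."""
    if n <= 0:
        return read
    if len(read.sequence) <= n:
        return None
    return ReadRecord(
        read_id=read.read_id,
        sequence=read.sequence[n:],
        quality=read.quality[n:],
        comment=read.comment,
        source=read.source,
    )


def head_crop(
    reads: Iterable[ReadRecord], n: int, dropped: Optional[list] = None
) -> Iterator[ReadRecord]:
    """Remove the first ``n`` bases from every read in a stream.

    Reads left empty are dropped; pass a list as ``dropped`` to collect a
    tally (one appended read id per dropped read).
    """
    for read in reads:
        cropped = crop_read(read, n)
        if cropped is None:
            if dropped is not None:
                dropped.append(read.read_id)
            continue
        yield cropped


def score_against_truth(
    assignments: Mapping[str, str],
    truth: Mapping[str, str],
) -> EvalReport:
    """Score per-read calls against a truth table.

    ``assignments`` maps read_id to a barcode id or ``"unclassified"``;
    ``truth`` maps read_id to the true barcode id (or ``"none"``).  Every
    assigned read must appear in the truth table.  Results are independent
    of mapping iteration order.
    """
    missing = [r for r in assignments if r not in truth]
    if missing:
        raise EvaluationError(
            f"{len(missing)} read ids missing from truth (e.g. {missing[0]!r})"
        )
    labels = sorted(
        {v for v in truth.values()} | {v for v in assignments.values()} | {"unclassified"}
    )
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    n_total = len(assignments)
    n_classified = 0
    n_correct = 0
    for read_id in sorted(assignments):
        call = assignments[read_id]
        true = truth[read_id]
        confusion.loc[true, call] += 1
        if call != "unclassified":
            n_classified += 1
            if call == true:
                n_correct += 1
    return EvalReport(
        n_total=n_total,
        n_classified=n_classified,
        classification_rate=(n_classified / n_total) if n_total else 0.0,
        confusion=confusion,
        n_correct=n_correct,
        accuracy=(n_correct / n_total) if n_total else 0.0,
    )


def negative_control_fpr(
    assignments: Mapping[str, str],
    n_barcodes: int,
) -> tuple[float, float, dict[str, float]]:
    """False-positive rates on a barcode-free read set.

    Returns ``(fpr_total, fpr_per_barcode, empirical)``: the total FPR
    (assigned / total), the conventional per-barcode FPR (total divided by
    the number of barcodes) and the empirical assigned fraction per
    barcode actually hit.  Exact rational arithmetic is used internally so
    ``fpr_total * total`` is the integer count of assigned reads.
    """
    total = len(assignments)
    if total == 0:
        raise EvaluationError("negative control contains no reads")
    if n_barcodes <= 0:
        raise EvaluationError("n_barcodes must be positive")
    assigned = {r: c for r, c in assignments.items() if c != "unclassified"}
    fpr_total = Fraction(len(assigned), total)
    per_calls: dict[str, int] = {}
    for call in assigned.values():
        per_calls[call] = per_calls.get(call, 0) + 1
    empirical = {
        call: count / total for call, count in sorted(per_calls.items())
    }
    return (
        float(fpr_total),
        float(fpr_total / n_barcodes),
        empirical,
    )
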