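"""Simulate a small barcoded run, demultiplex it, and print the summary.

Generates 240 nanopore-like reads (10 per barcode of the bundled 24-set,
2% substitution/insertion/deletion errors), routes them through the full
pipeline and prints the per-class read counts.  With error rates this low
every read should land on its true barcode; the unclassified and
too_short rows should be empty.
"""

import tempfile
from pathlib import Path

from nanodemux import DemuxConfig, SimParams, demux, simulate_reads

reads, truths = simulate_reads(
    SimParams(n_reads=240, p_sub=0.02, p_ins=0.02, p_del=0.02, seed=7)
)
out_dir = Path(tempfile.mkdtemp(prefix="nanodemux_example_"))
summary = demux(reads, "builtin24", DemuxConfig(), out_dir)

print(f"outputs written to {out_dir}")
print(f"{'label':<14}{'reads':>6}{'fraction':>10}{'mean_len':>10}{'mean_q':>8}")
for row in summary:
    if row.n_reads or row.label in ("unclassified", "too_short"):
        print(f"{row.label:<14}{row.n_reads:>6}{row.fraction:>10.3f}"
              f"{row.mean_length:>10.1f}{row.mean_quality:>8.1f}")
print(f"\n{summary.n_input} reads in; every read is in exactly one class.")
print("mean_len for barcode rows is the trimmed length (flank + insert);")
print("a zero unclassified row means every read passed score, margin and")
print("positional checks for its true barcode.")
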