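import random

import pytest
from hypothesis import settings

from nanodemux.io import BarcodeRecord, ReadRecord, load_barcode_set

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def builtin24():
    return load_barcode_set("builtin24")


@pytest.fixture(scope="session")
def builtin96():
    return load_barcode_set("builtin96")


@pytest.fixture
def tiny_barcodes():
    """Three dissimilar hand-picked barcodes for targeted scenarios."""
    return [
        BarcodeRecord("BC01", "ACGTACCAGGTTACGGATTGCCAA"),
        BarcodeRecord("BC02", "TTGGCACCTTAACGCAGATCGTAC"),
        BarcodeRecord("BC03", "GATCCGGTTGTGCATAACTGCGAT"),
    ]


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def make_read(read_id: str, sequence: str, q: int = 20, comment: str = "") -> ReadRecord:
    return ReadRecord(
        read_id=read_id, sequence=sequence, quality=chr(q + 33) * len(sequence),
        comment=comment,
    )


@pytest.fixture
def embed_read():
    """Factory: read with a barcode embedded at a given 1-based start."""

    def _make(barcode: str, start: int, total: int = 800, seed: int = 0,
              read_id: str = "r"):
        rng = random.Random(seed)
        lead = random_dna(rng, start - 1)
        tail = random_dna(rng, max(0, total - len(lead) - len(barcode)))
        return make_read(read_id, lead + barcode + tail)

    return _make
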