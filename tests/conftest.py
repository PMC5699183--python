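import numpy as np
import pytest

from orgextract.io_preprocess import ReadPair, ReadRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode()


def make_read(seq: str, read_id: str = "r", qual_char: str = "I",
              mate_index: int = 0) -> ReadRecord:
    return ReadRecord(read_id, seq, qual_char * len(seq), mate_index)


def tile_reads(seq: str, read_len: int = 100, step: int = 10,
               copies: int = 1) -> list[str]:
    """Error-free reads tiling a sequence; `copies` repeats each read."""
    out = []
    for _ in range(copies):
        out.extend(seq[i:i + read_len]
                   for i in range(0, len(seq) - read_len + 1, step))
    return out


def write_fastq_file(path, records):
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{r.quals}\n")
    return str(path)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def unpaired(rng):
    return [ReadPair(make_read(random_seq(rng, 100), f"read{i}"))
            for i in range(10)]
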