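"""Small shared helpers: sequence encoding, assembly stats, seeding, FASTA/FASTQ output."""

from __future__ import annotations

import zlib
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

#: Integer codes used for bases throughout the simulator. 4 marks N / invalid.
BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case


def encode_seq(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_seq`."""
    return BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


def n50(lengths: Iterable[int]) -> int:
    """Length-weighted median: the length L such that pieces >= L hold half the total."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("n50 of an empty length set is undefined")
    half = arr.sum() / 2
    return int(arr[np.searchsorted(np.cumsum(arr), half)])


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (35.25 -> 35.3), matching printed-table precision."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def derive_seed(seed: int, stage: str) -> int:
    """Fan a global seed out to a per-stage seed via a stable stage-name hash."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def write_fasta(path, records: Sequence[tuple[str, str]], width: int = 70) -> None:
    """Write (name, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path, names: Sequence[str], seqs: Sequence[str], qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in zip(names, seqs):
            fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")
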