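"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: byte -> 2-bit code; 255 marks N / unknown
BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODE[_b] = _i
    BASE_CODE[_b + 32] = _i  # lowercase

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 array of 2-bit codes (255 for non-ACGT)."""
    return BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode("ascii")


def random_seq(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA of length ``n``."""
    return decode(rng.integers(0, 4, size=n, dtype=np.uint8))


def check_alphabet(seq: str, *, allow_n: bool = True) -> None:
    codes = encode(seq)
    if allow_n:
        bad = np.flatnonzero((codes == 255) & ~np.isin(
            np.frombuffer(seq.encode("ascii"), dtype=np.uint8), np.frombuffer(b"Nn", dtype=np.uint8)))
    else:
        bad = np.flatnonzero(codes == 255)
    if bad.size:
        raise ValueError(f"non-ACGTN character {seq[bad[0]]!r} at position {bad[0]}")
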