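"""Small sequence utilities shared across modules."""

from __future__ import annotations

import numpy as np

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte code per base; N and anything else maps to 4
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_RC)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes A=0 C=1 G=2 T=3, other=4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-base run in ``seq`` (0 for empty)."""
    best = 0
    run = 0
    prev = None
    for ch in seq:
        if ch == prev:
            run += 1
        else:
            run = 1
            prev = ch
        if run > best:
            best = run
    return best


def kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    """Map each k-mer of ``seq`` to its sorted list of start positions.

    Kmers containing 'N' are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        out.setdefault(km, []).append(i)
    return out
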