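"""Small shared DNA helpers (plain ACGT alphabet, 1-based inclusive coordinates)."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# uint8 codes for vectorised comparisons
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement; N (any case) maps to N."""
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    """GC content as a fraction of sequence length."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def encode(seq: str) -> np.ndarray:
    """Map a DNA string onto uint8 codes A=0 C=1 G=2 T=3; anything else 255."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """I.i.d. nucleotides at the requested GC fraction."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"GC fraction must be in [0,1], got {gc}")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))
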