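"""Low-level sequence helpers shared across modules.

All coordinates in this package are 0-based half-open unless a function
explicitly converts for an external format (GFF3, AGP: 1-based inclusive).
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtnRYKMSWBDHVrykmswbdhv",
                            "TGCANtgcanYRMKSWVHDByrmkswvhdb")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement, tolerant of N and IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform i.i.d. A/C/G/T sequence of the given length."""
    if length <= 0:
        return ""
    idx = rng.integers(0, 4, size=length)
    return _BASES[idx].tobytes().decode("ascii")


def seq_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length strings (ungapped)."""
    if len(a) != len(b):
        raise ValueError("seq_identity requires equal-length sequences")
    if not a:
        return 0.0
    aa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    return float((aa == bb).mean() * 100.0)
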