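"""Base <-> integer code conversions shared across modules.

Bases are coded A=0, C=1, G=2, T=3.  With this coding a transition is
``code ^ 2`` (A<->G, C<->T), which the simulator and spectrum code rely on.
"""
from __future__ import annotations

import numpy as np

BASES = np.array(list("ACGT"))
BASE_TO_CODE = {b: i for i, b in enumerate("ACGT")}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: complement in code space (A<->T, C<->G)
COMPLEMENT_CODE = np.array([3, 2, 1, 0], dtype=np.int8)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int8 code array."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in BASE_TO_CODE.items():
        codes[arr == ord(base)] = code
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode an int8 code array back to an ACGT string."""
    return "".join(BASES[np.asarray(codes)])
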