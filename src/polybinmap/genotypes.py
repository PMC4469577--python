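"""Genotype codes shared across the pipeline.

Integer codes are used internally (compact int8 matrices); single-character
codes appear in all on-disk genotype matrices:

* ``A`` — homozygous for the parent-1 allele
* ``B`` — homozygous for the parent-2 allele
* ``H`` — heterozygous
* ``-`` — missing
"""

from __future__ import annotations

import numpy as np

A: int = 0
H: int = 1
B: int = 2
MISSING: int = -1

#: on-disk single-character codes, indexed by internal code (MISSING == -1 wraps)
CODE_CHARS = np.array(["A", "H", "B", "-"], dtype="U1")

CHAR_TO_CODE = {"A": A, "H": H, "B": B, "-": MISSING}


def to_chars(codes: np.ndarray) -> np.ndarray:
    """Map an integer genotype array to its character representation."""
    return CODE_CHARS[np.asarray(codes)]


def from_chars(chars: np.ndarray) -> np.ndarray:
    """Map a character genotype array back to integer codes."""
    arr = np.asarray(chars, dtype="U1")
    out = np.full(arr.shape, MISSING, dtype=np.int8)
    for ch, code in CHAR_TO_CODE.items():
        out[arr == ch] = code
    return out
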