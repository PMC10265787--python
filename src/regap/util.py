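"""Small shared helpers: sequence manipulation and Phred conversions."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMP)[::-1]


def phred_to_prob(q) -> np.ndarray:
    """Error probability for Phred score(s), clipped away from 0 and 1."""
    p = np.power(10.0, -np.asarray(q, dtype=float) / 10.0)
    return np.clip(p, 1e-6, 0.75)


def qual_string(quals) -> str:
    """Encode integer Phred scores as a Phred+33 string."""
    return "".join(chr(int(q) + 33) for q in quals)


def parse_quals(qual_str: str) -> list[int]:
    """Decode a Phred+33 string into integer scores."""
    return [ord(c) - 33 for c in qual_str]


def match_with_softclip(a: str, b: str, clip: int = 15) -> bool:
    """Whether two sequences agree allowing soft-clips at both ends.

    Up to ``clip`` bases may be ignored at each end of each sequence; the
    remaining cores must be identical and non-empty.  This is the standard
    criterion for calling a gap correctly closed.
    """
    if a == b:
        return True
    for s1 in range(min(clip, len(a)) + 1):
        for e1 in range(min(clip, len(a) - s1) + 1):
            core = a[s1 : len(a) - e1]
            if not core:
                continue
            for s2 in range(min(clip, len(b)) + 1):
                e2 = len(b) - s2 - len(core)
                if 0 <= e2 <= clip and b[s2 : s2 + len(core)] == core:
                    return True
    return False


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (numpy rounds half to even)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)
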