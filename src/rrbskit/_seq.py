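"""Low-level sequence helpers shared across the package.

Coordinates are 0-based, half-open everywhere.  A CpG site is identified by
the forward-strand position of its C.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_C2T = str.maketrans("C", "T")
_G2A = str.maketrans("G", "A")

# numeric base codes used by the generators (index into "ACGT")
A, C, G, T = 0, 1, 2, 3
BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T(/N) string."""
    return seq.translate(_COMP)[::-1]


def c_to_t(seq: str) -> str:
    """Three-letter bisulfite image of the top strand (every C becomes T)."""
    return seq.translate(_C2T)


def g_to_a(seq: str) -> str:
    """Three-letter bisulfite image of the bottom strand viewed on forward
    coordinates (every G becomes A)."""
    return seq.translate(_G2A)


def check_sequence(seq: str) -> None:
    """Raise ``ValueError`` if *seq* contains characters outside A/C/G/T."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)!r}")


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array of codes 0..3."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(raw.size, 255, dtype=np.uint8)
    for code, byte in enumerate(b"ACGT"):
        codes[raw == byte] = code
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return BASE_BYTES[codes].tobytes().decode("ascii")


def cpg_positions(seq: str) -> np.ndarray:
    """Sorted forward-strand positions of the C of every CG dinucleotide."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if raw.size < 2:
        return np.empty(0, dtype=np.int64)
    mask = (raw[:-1] == ord("C")) & (raw[1:] == ord("G"))
    return np.flatnonzero(mask).astype(np.int64)


def phred_to_scores(qual: str) -> np.ndarray:
    """Decode a Phred+33 quality string into integer scores."""
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33


def scores_to_phred(scores) -> str:
    return "".join(chr(int(q) + 33) for q in scores)
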