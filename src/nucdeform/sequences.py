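"""Widom 601 construct sequences and the string-index -> dyad-position map.

The 152-bp Widom 601 construct used for deoxyinosine (DI) nucleosomes carries
the lesion on the bottom strand ("damaged strand").  Four variants place a
single inosine (``I``) so that, in the dyad-centred frame, it sits at
positions -30, -50, -53 and -55.  The affine map from 1-based bottom-strand
string index to frame position is position = index - 78 (dyad at index 78);
fitting that map to all four variants is integer-exact, which pins down the
numbering convention used everywhere in this package.
"""

from __future__ import annotations

import numpy as np

WIDOM601_TOP = (
    "CCTGGAGAATCCCGGTGCCGAGGCCGCTCAATTGGTCGTAGACAGCTCTAGCACCGCTTAAACGCACGTACGCG"
    "CTGTCCCCCGCGTTTTAACCGCCAAGGGGATTACTCCCTAGTCTCCAGGCACGTGTCAGATATATACATCCTGTGCAT"
)

# Bottom strands, 5'->3'; the single inosine is the character 'I'.
WIDOM601_BOTTOM_DI = {
    -30: (
        "ATGCACAGGATGTATATATCTGACACGTGCCTGGAGACTAGGGAGTAITCCCCTTGGCGGTTAAAACGCGGGGG"
        "ACAGCGCGTACGTGCGTTTAAGCGGTGCTAGAGCTGTCTACGACCAATTGAGCGGCCTCGGCACCGGGATTCTCCAGG"
    ),
    -50: (
        "ATGCACAGGATGTATATATCTGACACGIGCCTGGAGACTAGGGAGTAATCCCCTTGGCGGTTAAAACGCGGGGG"
        "ACAGCGCGTACGTGCGTTTAAGCGGTGCTAGAGCTGTCTACGACCAATTGAGCGGCCTCGGCACCGGGATTCTCCAGG"
    ),
    -53: (
        "ATGCACAGGATGTATATATCTGACICGTGCCTGGAGACTAGGGAGTAATCCCCTTGGCGGTTAAAACGCGGGGG"
        "ACAGCGCGTACGTGCGTTTAAGCGGTGCTAGAGCTGTCTACGACCAATTGAGCGGCCTCGGCACCGGGATTCTCCAGG"
    ),
    -55: (
        "ATGCACAGGATGTATATATCTGICACGTGCCTGGAGACTAGGGAGTAATCCCCTTGGCGGTTAAAACGCGGGGG"
        "ACAGCGCGTACGTGCGTTTAAGCGGTGCTAGAGCTGTCTACGACCAATTGAGCGGCCTCGGCACCGGGATTCTCCAGG"
    ),
}

#: Dyad nucleotide of the bottom strand sits at this 1-based string index.
BOTTOM_DYAD_INDEX = 78
#: Dyad nucleotide of the top strand (partner convention i <-> -i).
TOP_DYAD_INDEX = 75


def inosine_index(bottom_strand: str) -> int:
    """1-based index of the single inosine in a bottom-strand string."""
    i = bottom_strand.find("I")
    if i < 0 or bottom_strand.find("I", i + 1) >= 0:
        raise ValueError("expected exactly one 'I' in the bottom strand")
    return i + 1


def bottom_index_to_position(index: int) -> int:
    """Map a 1-based bottom-strand string index to a dyad-relative position."""
    return index - BOTTOM_DYAD_INDEX


def top_index_to_position(index: int) -> int:
    """Map a 1-based top-strand string index to a dyad-relative position."""
    return index - TOP_DYAD_INDEX


def fit_affine_index_map(
    variants: dict[int, str] | None = None,
) -> tuple[float, float, float]:
    """Least-squares affine fit position = a*index + b over the DI variants.

    Returns ``(slope, intercept, max_abs_residual)``.  On the four printed
    strands the fit is integer-exact (slope 1, intercept -78, residual 0).
    """
    variants = WIDOM601_BOTTOM_DI if variants is None else variants
    idx = np.array([inosine_index(s) for s in variants.values()], dtype=float)
    pos = np.array(list(variants.keys()), dtype=float)
    A = np.column_stack([idx, np.ones_like(idx)])
    (a, b), *_ = np.linalg.lstsq(A, pos, rcond=None)
    resid = np.max(np.abs(A @ np.array([a, b]) - pos))
    return float(a), float(b), float(resid)


_COMPLEMENT = str.maketrans("ACGTI", "TGCAC")


def complement(base: str) -> str:
    """Watson-Crick complement; inosine is read as pairing with cytosine."""
    return base.translate(_COMPLEMENT)
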