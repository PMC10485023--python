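"""Small DNA-string helpers shared across modules."""

from __future__ import annotations

import re

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC nucleotide codes -> the set of bases they match
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC nucleotide pattern into a regex."""
    parts = []
    for ch in pattern.upper():
        try:
            bases = IUPAC[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def iupac_match(seq: str, pattern: str) -> bool:
    """True iff ``seq`` matches the IUPAC ``pattern`` exactly (same length)."""
    if len(seq) != len(pattern):
        return False
    for base, code in zip(seq.upper(), pattern.upper()):
        if base not in IUPAC.get(code, ""):
            return False
    return True


def validate_acgt(seq: str, what: str = "sequence") -> None:
    if not seq or any(c not in "ACGT" for c in seq):
        raise ValueError(f"{what} must be non-empty and contain only A/C/G/T: {seq!r}")
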