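"""Restriction enzyme definitions and IUPAC site scanning.

Recognition sites are matched on the top strand only.  The built-in
enzymes are palindromic, or effectively so for pattern presence (the
reverse complement of GANTC is GANTC), so top-strand scanning finds
every double-stranded site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition site plus top-strand cut offset.

    ``cut_offset`` is the number of recognition-site bases left of the cut,
    so PacI (TTAAT^TAA) has offset 5 and NlaIII (CATG^) has offset 4.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition or any(b not in IUPAC for b in self.recognition):
            raise ValueError(f"recognition site {self.recognition!r} is not IUPAC")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut offset outside recognition site")

    @property
    def pattern(self) -> re.Pattern[str]:
        # lookahead so overlapping occurrences are all reported
        return re.compile("(?=" + "".join(IUPAC[b] for b in self.recognition) + ")")


# Cut offsets are table data: they only affect fragment lengths.
BUILTIN_ENZYMES = {
    e.name: e
    for e in (
        Enzyme("PacI", "TTAATTAA", 5),
        Enzyme("NlaIII", "CATG", 4),
        Enzyme("HinfI", "GANTC", 1),
        Enzyme("EcoRI", "GAATTC", 1),
    )
}


def get_enzyme(name: str) -> Enzyme:
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; known: {sorted(BUILTIN_ENZYMES)}") from None


def scan_sites(sequence: str, enzyme: Enzyme | str) -> list[int]:
    """Return 1-based start positions of every recognition-site match.

    Overlapping matches are all reported.  The input must be plain ACGT;
    ambiguity codes in the *sequence* are rejected.
    """
    if isinstance(enzyme, str):
        enzyme = get_enzyme(enzyme)
    if re.search("[^ACGT]", sequence):
        raise ValueError("sequence contains non-ACGT characters")
    return [m.start() + 1 for m in enzyme.pattern.finditer(sequence)]


def cut_positions(sequence: str, enzyme: Enzyme | str) -> list[int]:
    """Top-strand cut positions: number of bases to the left of each cut."""
    if isinstance(enzyme, str):
        enzyme = get_enzyme(enzyme)
    return [s - 1 + enzyme.cut_offset for s in scan_sites(sequence, enzyme)]
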