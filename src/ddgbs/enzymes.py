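"""Restriction enzyme definitions and IUPAC motif utilities.

A :class:`RestrictionEnzyme` is a named double-stranded recognition motif
(IUPAC DNA alphabet, ambiguity codes allowed) together with the cut offset
on the top strand, measured in bases from the start of the motif.  The
seven enzymes commonly screened for reduced-representation libraries in
birds and other vertebrate genomes ship as a built-in registry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: Expansion of each IUPAC DNA code into the set of concrete bases it matches.
IUPAC_DNA: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse-complement an IUPAC DNA string (ambiguity codes preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def motif_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC motif into an overlapping-match (lookahead) regex.

    Motif ``N`` matches any genome character (including assembly ``N`` runs);
    every other code matches only the concrete A/C/G/T bases it expands to,
    so ambiguity characters in the *genome* never produce spurious sites.
    """
    parts = []
    for ch in motif:
        if ch not in IUPAC_DNA:
            raise ValueError(f"unknown IUPAC code {ch!r} in motif {motif!r}")
        parts.append("." if ch == "N" else "[" + IUPAC_DNA[ch] + "]")
    return re.compile("(?=" + "".join(parts) + ")")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease: recognition motif plus top-strand cut offset.

    ``cut_offset`` is the number of bases from the start of the motif to the
    point where the top strand is severed (``G^AATTC`` has offset 1).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not (4 <= len(self.recognition) <= 8):
            raise ValueError(
                f"{self.name}: recognition motif must be 4-8 bases, "
                f"got {self.recognition!r}"
            )
        for ch in self.recognition:
            if ch not in IUPAC_DNA:
                raise ValueError(
                    f"{self.name}: unknown IUPAC code {ch!r} in motif "
                    f"{self.recognition!r}"
                )
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise ValueError(
                f"{self.name}: cut_offset {self.cut_offset} outside motif"
            )

    @property
    def is_palindromic(self) -> bool:
        """True when the motif equals its own reverse complement (as written)."""
        return reverse_complement(self.recognition) == self.recognition

    @property
    def remnant(self) -> str:
        """Motif residue left at the 5' end of the downstream fragment."""
        return self.recognition[self.cut_offset:]

    def __str__(self) -> str:  # e.g. "EcoRI (G^AATTC)"
        r = self.recognition
        return f"{self.name} ({r[:self.cut_offset]}^{r[self.cut_offset:]})"


#: Built-in registry of the seven screened enzymes (^ marks the cut).
REGISTRY: dict[str, RestrictionEnzyme] = {
    e.name: e
    for e in [
        RestrictionEnzyme("EcoRI", "GAATTC", 1),    # G^AATTC
        RestrictionEnzyme("HinP1I", "GCGC", 1),     # G^CGC
        RestrictionEnzyme("ApeKI", "GCWGC", 1),     # G^CWGC
        RestrictionEnzyme("PstI", "CTGCAG", 5),     # CTGCA^G
        RestrictionEnzyme("MseI", "TTAA", 1),       # T^TAA
        RestrictionEnzyme("MspI", "CCGG", 1),       # C^CGG
        RestrictionEnzyme("BglII", "AGATCT", 1),    # A^GATCT
    ]
}


def get_enzyme(name: str) -> RestrictionEnzyme:
    """Look up a registry enzyme by name, tolerant of spaces and case."""
    key = name.replace(" ", "").replace("-", "").upper()
    for enz in REGISTRY.values():
        if enz.name.upper() == key:
            return enz
    raise KeyError(
        f"unknown enzyme {name!r}; known: {', '.join(REGISTRY)}"
    )
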