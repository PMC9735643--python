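"""Restriction endonuclease definitions.

An enzyme is described by its recognition sequence and the offset of the
top-strand cut within that sequence (e.g. AluI cuts AG^CT, offset 2).
Recognition sequences are plain ACGT strings; IUPAC ambiguity codes are not
expanded, and genomic bases outside {A,C,G,T} never match (conservative
behaviour on draft assemblies containing N runs).
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease with a fixed-offset top-strand cut.

    Parameters
    ----------
    name : str
        Short display name, e.g. ``"AluI"``.
    recognition : str
        Recognition sequence over {A, C, G, T}.
    cut_offset : int
        0-based position of the cut within the recognition sequence
        (``0 <= cut_offset <= len(recognition)``); the enzyme cleaves
        between ``site_start + cut_offset - 1`` and ``site_start + cut_offset``.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError(f"{self.name}: empty recognition sequence")
        if set(self.recognition) - set("ACGT"):
            raise ValueError(
                f"{self.name}: recognition sequence must be over ACGT, "
                f"got {self.recognition!r}"
            )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(
                f"{self.name}: cut_offset {self.cut_offset} outside "
                f"0..{len(self.recognition)}"
            )

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == reverse_complement(self.recognition)


# The three enzymes used throughout the worked examples: a frequent 4-cutter
# (AluI, AG^CT) and two rare 6-cutters (EcoRI G^AATTC, PstI CTGCA^G).
BUILTIN_ENZYMES: dict[str, Enzyme] = {
    "AluI": Enzyme("AluI", "AGCT", 2),
    "EcoRI": Enzyme("EcoRI", "GAATTC", 1),
    "PstI": Enzyme("PstI", "CTGCAG", 5),
}


def get_enzyme(name_or_enzyme: str | Enzyme) -> Enzyme:
    """Resolve a built-in enzyme by name, or pass an Enzyme through."""
    if isinstance(name_or_enzyme, Enzyme):
        return name_or_enzyme
    try:
        return BUILTIN_ENZYMES[name_or_enzyme]
    except KeyError:
        known = ", ".join(sorted(BUILTIN_ENZYMES))
        raise KeyError(
            f"unknown enzyme {name_or_enzyme!r}; built-ins are {known}. "
            "Pass an Enzyme(name, recognition, cut_offset) for others."
        ) from None
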