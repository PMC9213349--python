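"""Synthetic stand-ins for collagen type I reference chains.

The published mammoth work maps observed peptides onto the mature col1a1
(1058 residues) and col1a2 (1040 residues) chains of *Loxodonta africana*.
Those database entries cannot be bundled here, so this module constructs
SYNTHETIC chains of the same length whose published trait regions — the
tryptic windows where the reported sequence differences live — are placed
at their literature coordinates, with deterministic Gly-Xaa-Yaa filler
elsewhere.  Alignments against these chains therefore reproduce the
reported edit coordinates exactly, while everything outside the trait
windows is artificial.
"""

from __future__ import annotations

from .evidence import ReferenceSequence

__all__ = [
    "synthetic_col1a1",
    "synthetic_col1a2",
    "COL1A1_TRAITS",
    "COL1A2_TRAITS",
    "OBSERVED_COL1A1_PEPTIDES",
    "OBSERVED_COL1A2_PEPTIDES",
]

# Reference trait windows (1-based start -> reference-side sequence).
# col1a1: the VS trait at 174/175, the missing-G region near 400, and the
# windows containing positions 746 and 989; marker positions 701/795/857.
COL1A1_TRAITS: dict[int, str] = {
    162: "GNDGATGAAGPPVSPTGPAGPPGFPGAVGAK",  # 162-192, VS at 174-175
    393: "TGPPGPAQDGRPGPPGPPGAR",            # 393-413, G missing after 399
    723: "VGPPGPSGNAGPPGPPGPAGKEGGK",        # 723-747, G at 746
    982: "GPPGSAGAPGKDGLNGLPGPIGPPGPR",      # 982-1008, A at 989
    701: "P",                                  # Elephantidae marker (Mammut: A)
    795: "G",
    857: "A",
}

# col1a2: window containing position 305; marker position 781.
COL1A2_TRAITS: dict[int, str] = {
    303: "GSSGEAGSAGPAGPPGLR",  # 303-320, S at 305
    781: "T",                    # Elephantidae marker (Mammut: S)
}

# Peptides whose sequences are published outright (de novo reads of the
# mammoth sample) and map onto the trait windows above.
OBSERVED_COL1A1_PEPTIDES: tuple[str, ...] = (
    "GNDGATGAAGPPGPTGPAGPPGFPGAVGAK",   # V deletion @174 + S175->G
    "VGPPGPSGNAGPPGPPGPAGKEGAK",        # G746->A
    "GPPGSAGTPGKDGLNGLPGPIGPPGPR",      # A989->T
)
OBSERVED_COL1A2_PEPTIDES: tuple[str, ...] = (
    "GSDGEAGSAGPAGPPGLR",               # S305->D
)

_FILLER = "GPA"  # neutral Gly-Xaa-Yaa filler triplet


def _build_chain(length: int, traits: dict[int, str], accession: str) -> ReferenceSequence:
    chars = [_FILLER[i % 3] for i in range(length)]
    for start, fragment in traits.items():
        if start + len(fragment) - 1 > length:
            raise ValueError(f"trait at {start} exceeds chain length {length}")
        chars[start - 1 : start - 1 + len(fragment)] = list(fragment)
    # a tryptic boundary just before each multi-residue trait window
    for start, fragment in traits.items():
        if len(fragment) > 1 and start >= 2:
            chars[start - 2] = "R"
    return ReferenceSequence(
        accession=accession,
        description=f"{accession} synthetic collagen-like chain",
        residues="".join(chars),
        numbering_offset=1,
    )


def synthetic_col1a1() -> ReferenceSequence:
    """Synthetic 1058-residue col1a1-like chain with published trait windows."""
    return _build_chain(1058, COL1A1_TRAITS, "SYN_COL1A1")


def synthetic_col1a2() -> ReferenceSequence:
    """Synthetic 1040-residue col1a2-like chain with published trait windows."""
    return _build_chain(1040, COL1A2_TRAITS, "SYN_COL1A2")
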