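"""Marker-peptide protein classification for authentication.

Identified proteins are sorted into groups by the species sets of their
peptides, looked up in a reference panel (an offline, I/L-normalised
replacement for a BLASTp survey of each peptide):

* ``endogenous_specific`` — carries at least one marker peptide found
  only in the target clade's species;
* ``shared_non_human`` — peptides match several species but never human;
* ``shared_including_human`` — some peptide's species set includes human
  (possible modern contamination);
* ``contaminant`` — accession appears in the contaminant (c-RAP-like)
  list, or a shared-with-human protein whose own deamidation profile
  matches the contaminant population (the conservative keratin rule);
* ``not_identified`` — fewer than two peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .taxonomy import normalize_il

logger = logging.getLogger(__name__)

__all__ = [
    "ReferencePanel",
    "ProteinCall",
    "classify_protein",
    "classify_proteins",
    "conservative_contaminant_flag",
    "CLASS_ENDOGENOUS",
    "CLASS_SHARED_NON_HUMAN",
    "CLASS_SHARED_HUMAN",
    "CLASS_CONTAMINANT",
    "CLASS_NOT_IDENTIFIED",
]

CLASS_ENDOGENOUS = "endogenous_specific"
CLASS_SHARED_NON_HUMAN = "shared_non_human"
CLASS_SHARED_HUMAN = "shared_including_human"
CLASS_CONTAMINANT = "contaminant"
CLASS_NOT_IDENTIFIED = "not_identified"


@dataclass
class ReferencePanel:
    """I/L-normalised peptide -> set of species labels."""

    mapping: dict[str, set[str]]
    species: set[str]
    human_label: str = "Homo sapiens"

    @classmethod
    def from_pairs(
        cls, pairs: list[tuple[str, str]], human_label: str = "Homo sapiens"
    ) -> "ReferencePanel":
        mapping: dict[str, set[str]] = {}
        species: set[str] = set()
        for pep, sp in pairs:
            mapping.setdefault(normalize_il(pep), set()).add(sp)
            species.add(sp)
        return cls(mapping, species, human_label)

    @classmethod
    def from_table(
        cls, path: str | Path, human_label: str = "Homo sapiens"
    ) -> "ReferencePanel":
        """Read a 2-column TSV: peptide, semicolon-joined species labels."""
        df = pd.read_csv(path, sep="\t", comment="#", names=["peptide", "species"], dtype=str)
        pairs = [
            (row.peptide, sp)
            for row in df.itertuples(index=False)
            for sp in str(row.species).split(";")
        ]
        return cls.from_pairs(pairs, human_label)

    def to_table(self, path: str | Path) -> None:
        rows = [
            (pep, ";".join(sorted(sps)))
            for pep, sps in sorted(self.mapping.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    def lookup(self, peptide: str) -> set[str] | None:
        return self.mapping.get(normalize_il(peptide))


@dataclass(frozen=True)
class ProteinCall:
    accession: str
    n_peptides: int
    class_label: str
    marker_peptides: tuple[str, ...] = ()
    indeterminate: bool = False
    note: str = ""


def classify_protein(
    accession: str,
    peptides: list[str],
    panel: ReferencePanel,
    contaminants: set[str],
    target_clade: set[str],
) -> ProteinCall:
    """Classify one protein from its attributed peptides.

    ``target_clade`` is the set of species labels counted as endogenous
    (e.g. the Elephantidae members).  Peptides absent from the panel are
    unresolvable: logged and ignored for the class decision.
    """
    if accession in contaminants:
        return ProteinCall(accession, len(peptides), CLASS_CONTAMINANT)
    if len(peptides) < 2:
        return ProteinCall(accession, len(peptides), CLASS_NOT_IDENTIFIED)
    markers: list[str] = []
    any_human = False
    n_unresolved = 0
    for pep in peptides:
        species = panel.lookup(pep)
        if species is None:
            n_unresolved += 1
            continue
        if species and species <= target_clade:
            markers.append(pep)
        if panel.human_label in species:
            any_human = True
    if n_unresolved:
        logger.warning(
            "%s: %d peptide(s) not in reference panel, ignored", accession, n_unresolved
        )
    if markers:
        label = CLASS_ENDOGENOUS
    elif any_human:
        label = CLASS_SHARED_HUMAN
    else:
        label = CLASS_SHARED_NON_HUMAN
    return ProteinCall(
        accession,
        len(peptides),
        label,
        marker_peptides=tuple(markers),
        note=f"{n_unresolved} unresolvable peptide(s)" if n_unresolved else "",
    )


def classify_proteins(
    attributions: dict[str, list[str]],
    panel: ReferencePanel,
    contaminants: set[str],
    target_clade: set[str],
) -> list[ProteinCall]:
    """Classify every protein in an accession -> peptides attribution map."""
    return [
        classify_protein(acc, peps, panel, contaminants, target_clade)
        for acc, peps in sorted(attributions.items())
    ]


def conservative_contaminant_flag(
    call: ProteinCall,
    protein_deamidation_pct: float | None,
    original_ci: tuple[float, float],
    contaminant_ci: tuple[float, float],
) -> ProteinCall:
    """Reclassify a shared-with-human protein whose modification profile
    matches the contaminant population.

    Keratins shared between the target species and human cannot be
    attributed by sequence alone; as a precaution they are called
    contaminants when the protein's own peptide deamidation point
    estimate lies inside the contaminant group's CI and outside the
    original group's CI.  A protein without N/Q evidence
    (``protein_deamidation_pct=None``) is returned unchanged, flagged
    indeterminate.
    """
    if call.class_label != CLASS_SHARED_HUMAN:
        return call
    if protein_deamidation_pct is None:
        return replace(call, indeterminate=True, note="no N/Q sites for deamidation profile")
    in_contaminant = contaminant_ci[0] <= protein_deamidation_pct <= contaminant_ci[1]
    in_original = original_ci[0] <= protein_deamidation_pct <= original_ci[1]
    if in_contaminant and not in_original:
        return replace(
            call,
            class_label=CLASS_CONTAMINANT,
            note=(
                f"deamidation {protein_deamidation_pct:.1f}% matches contaminant "
                f"profile {contaminant_ci}"
            ),
        )
    return call
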