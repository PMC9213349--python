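"""Monoisotopic peptide mass arithmetic with modification deltas.

Residue masses come from the standard monoisotopic table (via
:mod:`pyteomics.mass`); modification deltas ship as a versioned TSV
resource (``data/modifications.tsv``) and can be overridden with a custom
table.  Hydroxyproline is modelled as ``oxidation`` targeted at P rather
than as a 21st residue letter.  All masses are in daltons; m/z in Thomson.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from pyteomics import mass as _pmass

__all__ = [
    "ModificationSpec",
    "load_modification_table",
    "DEFAULT_MODIFICATIONS",
    "PROTON_MASS",
    "WATER_MASS",
    "peptide_mass",
    "mz_to_neutral_mass",
    "neutral_mass_to_mz",
    "match_mass",
    "infer_modification_counts",
]

#: Monoisotopic mass of a proton, Da.
PROTON_MASS = 1.00727646688
#: Monoisotopic mass of water, Da.
WATER_MASS = 18.0105646837

#: Standard monoisotopic residue masses (20-letter alphabet).
RESIDUE_MASSES: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

# N-terminal attachment is encoded as position 0 in a modification list.
NTERM = "nterm"


@dataclass(frozen=True)
class ModificationSpec:
    """A named modification with its target residues and mass delta."""

    name: str
    targets: frozenset[str]
    delta_mass: float

    def applies_to(self, residue: str) -> bool:
        return residue in self.targets


def load_modification_table(path: str | Path | None = None) -> dict[str, ModificationSpec]:
    """Load a modification table from TSV (name, targets, delta_da).

    With ``path=None`` the packaged default table is used.  Lines starting
    with ``#`` are comments.
    """
    if path is None:
        text = (
            resources.files("paleopept").joinpath("data/modifications.tsv").read_text()
        )
    else:
        text = Path(path).read_text()
    table: dict[str, ModificationSpec] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, targets, delta = line.split("\t")
        table[name] = ModificationSpec(
            name=name,
            targets=frozenset(t.strip() for t in targets.split(",")),
            delta_mass=float(delta),
        )
    return table


DEFAULT_MODIFICATIONS: dict[str, ModificationSpec] = load_modification_table()


def peptide_mass(
    seq: str,
    mods: list[tuple[int, str]] | None = None,
    mod_table: dict[str, ModificationSpec] | None = None,
) -> float:
    """Monoisotopic neutral mass of a (modified) peptide.

    Parameters
    ----------
    seq:
        Uppercase amino-acid string over the 20-letter alphabet.
    mods:
        List of ``(position, mod_name)`` with 1-based positions into
        ``seq`` (0 denotes the N-terminus).
    mod_table:
        Modification table; defaults to the packaged one.

    Raises
    ------
    ValueError
        On an unknown residue, an unknown modification name, or a
        modification placed on a residue it does not target.
    """
    if not seq:
        raise ValueError("empty peptide sequence")
    table = mod_table if mod_table is not None else DEFAULT_MODIFICATIONS
    total = WATER_MASS
    for i, res in enumerate(seq, start=1):
        try:
            total += RESIDUE_MASSES[res]
        except KeyError:
            raise ValueError(f"unknown residue {res!r} at position {i}") from None
    for pos, name in mods or ():
        try:
            spec = table[name]
        except KeyError:
            raise ValueError(f"unknown modification {name!r} at position {pos}") from None
        if pos == 0:
            if NTERM not in spec.targets:
                raise ValueError(f"modification {name!r} not applicable to N-terminus")
        elif 1 <= pos <= len(seq):
            res = seq[pos - 1]
            if not spec.applies_to(res) and NTERM not in spec.targets:
                raise ValueError(
                    f"modification {name!r} not applicable to {res} at position {pos}"
                )
        else:
            raise ValueError(f"modification position {pos} outside peptide")
        total += spec.delta_mass
    return total


def mz_to_neutral_mass(mz: float, charge: int) -> float:
    """Neutral monoisotopic mass from an observed m/z and charge state.

    ``M = z * (m/z) - z * m_proton``
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return charge * mz - charge * PROTON_MASS


def neutral_mass_to_mz(neutral_mass: float, charge: int) -> float:
    """Observed m/z of a neutral mass at a given positive charge state."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def match_mass(
    seq: str,
    mods: list[tuple[int, str]] | None,
    mz: float,
    charge: int,
    tol_ppm: float = 15.0,
    mod_table: dict[str, ModificationSpec] | None = None,
) -> tuple[bool, float]:
    """Check an observed precursor against a modified sequence.

    Returns ``(matches, ppm_error)`` where the error is signed
    ``(observed - theoretical) / theoretical * 1e6``.
    """
    theoretical = peptide_mass(seq, mods, mod_table)
    observed = mz_to_neutral_mass(mz, charge)
    ppm = (observed - theoretical) / theoretical * 1e6
    return abs(ppm) <= tol_ppm, ppm


def infer_modification_counts(
    seq: str,
    target_mass: float,
    tol_da: float = 0.01,
    max_oxidations: int = 8,
    max_deamidations: int | None = None,
) -> tuple[int, int] | None:
    """Smallest (oxidation, deamidation) multiplicity matching a printed mass.

    Published collagen peptide masses often encode hydroxyproline counts
    only typographically; this searches non-negative combinations of
    +15.99491 (oxidation) and +0.98402 (deamidation) whose total, added to
    the unmodified sequence mass, reproduces ``target_mass`` within
    ``tol_da``.  Returns ``None`` when no combination fits.
    """
    base = peptide_mass(seq)
    if max_deamidations is None:
        max_deamidations = sum(seq.count(r) for r in "NQ")
    best: tuple[int, int] | None = None
    for n_ox in range(max_oxidations + 1):
        for n_deam in range(max_deamidations + 1):
            m = base + n_ox * 15.99491 + n_deam * 0.98402
            if abs(m - target_mass) <= tol_da:
                cand = (n_ox, n_deam)
                if best is None or sum(cand) < sum(best):
                    best = cand
    return best
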