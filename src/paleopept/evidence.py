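"""Reading, validating, filtering and writing peptide evidence tables.

The evidence dialect is a documented TSV subset of a MaxQuant
``evidence.txt``: columns Sequence, Modified sequence, Modifications,
Charge, m/z, Intensity, Score, Proteins, Raw file (names remappable
through :class:`EvidenceDialect` to absorb schema drift between search
engine versions).  Modification annotations are parsed primarily from the
modified-sequence string, whose site tags (``N(de)``, ``M(ox)`` ...) are
normalised to canonical modification names; unmapped names are preserved
verbatim and ignored by downstream statistics with a logged warning.

Coordinates are 1-based inclusive throughout; position 0 denotes the
peptide N-terminus.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "EvidenceRecord",
    "ReferenceSequence",
    "EvidenceDialect",
    "EvidenceParseError",
    "read_evidence",
    "write_evidence",
    "filter_records",
    "assign_groups",
    "read_fasta",
    "read_contaminant_list",
    "count_missed_cleavages",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

GROUP_ORIGINAL = "original"
GROUP_CONTAMINANT = "contaminant"
GROUP_UNASSIGNED = "unassigned"

#: Engine spellings of modification names -> canonical table names.
MOD_NAME_ALIASES: dict[str, str] = {
    "de": "deamidation",
    "deamidation": "deamidation",
    "deamidation (nq)": "deamidation",
    "ox": "oxidation",
    "oxidation": "oxidation",
    "oxidation (m)": "oxidation",
    "oxidation (p)": "oxidation",
    "oxidation (mp)": "oxidation",
    "hydroxyproline": "oxidation",
    "2ox": "dioxidation",
    "dioxidation": "dioxidation",
    "trioxidation": "trioxidation",
    "trioxidation (c)": "trioxidation",
    "ac": "acetyl",
    "acetyl": "acetyl",
    "acetyl (k)": "acetyl",
    "cam": "carbamidomethyl",
    "carbamidomethyl": "carbamidomethyl",
    "carbamidomethyl (c)": "carbamidomethyl",
    "gq": "pyro-glu-q",
    "gln->pyro-glu": "pyro-glu-q",
    "ge": "pyro-glu-e",
    "glu->pyro-glu": "pyro-glu-e",
    "kyn": "kynurenine",
    "trp->kynurenin": "kynurenine",
    "trp->kynurenine": "kynurenine",
    "trp->oxolactone": "oxolactone",
    "tyr->dopaquinone": "dopaquinone",
    "iodination": "iodination",
    "iodo": "iodination",
    "diiodination": "diiodination",
    "diiodo": "diiodination",
}


def normalize_mod_name(raw: str) -> str:
    """Map an engine spelling to a canonical modification name.

    Unknown spellings pass through verbatim (lowercased); downstream
    statistics ignore names absent from the modification table.
    """
    key = raw.strip().lower()
    return MOD_NAME_ALIASES.get(key, key)


class EvidenceParseError(ValueError):
    """Structured parse failure: names the offending column or row."""


@dataclass(frozen=True)
class EvidenceRecord:
    """One peptide-spectrum/feature row of an evidence table."""

    peptide_seq: str
    mod_list: tuple[tuple[int, str], ...] = ()
    charge: int = 2
    mz: float = 0.0
    intensity: float | None = None
    score: float = 0.0
    accessions: tuple[str, ...] = ()
    sample_id: str = ""
    group: str = GROUP_UNASSIGNED

    def __post_init__(self) -> None:
        if not self.peptide_seq:
            raise ValueError("peptide_seq must be non-empty")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        for pos, name in self.mod_list:
            if not 0 <= pos <= len(self.peptide_seq):
                raise ValueError(
                    f"modification {name!r} position {pos} outside peptide"
                )

    def count_residue(self, residues: str) -> int:
        return sum(self.peptide_seq.count(r) for r in residues)

    def count_modified(self, residues: str, mod_name: str) -> int:
        n = 0
        for pos, name in self.mod_list:
            if name == mod_name and pos >= 1 and self.peptide_seq[pos - 1] in residues:
                n += 1
        return n


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference protein chain with its mature-chain numbering offset."""

    accession: str
    description: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{self.accession}: invalid residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def position(self, index_0based: int) -> int:
        """Mature-chain coordinate of a 0-based string index."""
        return self.numbering_offset + index_0based


@dataclass(frozen=True)
class EvidenceDialect:
    """Column-name mapping of the evidence TSV dialect."""

    sequence: str = "Sequence"
    modified_sequence: str = "Modified sequence"
    modifications: str = "Modifications"
    charge: str = "Charge"
    mz: str = "m/z"
    intensity: str = "Intensity"
    score: str = "Score"
    proteins: str = "Proteins"
    raw_file: str = "Raw file"
    group: str = "Group"
    #: Columns that must be present; the rest are optional.
    required: tuple[str, ...] = ("sequence", "score")

    def required_columns(self) -> list[str]:
        return [getattr(self, f) for f in self.required]


DEFAULT_DIALECT = EvidenceDialect()

_MODSEQ_SITE = re.compile(r"([A-Z])\(([^)]+)\)|\(([^)]+)\)")


def parse_modified_sequence(modseq: str) -> tuple[str, tuple[tuple[int, str], ...]]:
    """Split a modified-sequence string into plain sequence and mod list.

    Accepts MaxQuant-style strings such as ``_GN(de)DGM(ox)K_`` (leading
    parenthesis group = N-terminal modification, position 0).
    """
    s = modseq.strip().strip("_")
    seq_chars: list[str] = []
    mods: list[tuple[int, str]] = []
    i = 0
    while i < len(s):
        c = s[i]
        if c == "(":
            j = s.index(")", i)
            mods.append((len(seq_chars), normalize_mod_name(s[i + 1 : j])))
            i = j + 1
        else:
            seq_chars.append(c.upper())
            i += 1
    return "".join(seq_chars), tuple(mods)


def format_modified_sequence(seq: str, mods: tuple[tuple[int, str], ...]) -> str:
    """Inverse of :func:`parse_modified_sequence` (canonical names kept)."""
    by_pos: dict[int, list[str]] = {}
    for pos, name in mods:
        by_pos.setdefault(pos, []).append(name)
    out = ["_"]
    for name in by_pos.get(0, []):
        out.append(f"({name})")
    for i, c in enumerate(seq, start=1):
        out.append(c)
        for name in by_pos.get(i, []):
            out.append(f"({name})")
    out.append("_")
    return "".join(out)


def _parse_modifications_column(seq: str, text: str) -> tuple[tuple[int, str], ...]:
    """Fallback parser for a summary Modifications column.

    Entries look like ``2 Deamidation (NQ)`` or ``Oxidation (M)``.  Site
    positions are not encoded, so modifications are placed on the leftmost
    eligible residues; per-record counts (all the estimator uses) are
    unaffected by this localisation choice.
    """
    if not text or text.strip().lower() in {"", "unmodified", "nan"}:
        return ()
    mods: list[tuple[int, str]] = []
    for entry in text.split(","):
        entry = entry.strip()
        if not entry:
            continue
        m = re.match(r"^(\d+)\s+(.*)$", entry)
        count = int(m.group(1)) if m else 1
        name_raw = m.group(2) if m else entry
        name = normalize_mod_name(name_raw)
        targets = re.search(r"\(([A-Z]+)\)", name_raw)
        eligible = (
            [i for i, c in enumerate(seq, 1) if c in set(targets.group(1))]
            if targets
            else list(range(1, len(seq) + 1))
        )
        if count > len(eligible):
            logger.warning(
                "modification %r count %d exceeds eligible sites in %s",
                name_raw, count, seq,
            )
            count = len(eligible)
        mods.extend((eligible[k], name) for k in range(count))
    return tuple(sorted(mods))


def read_evidence(
    path: str | Path, dialect: EvidenceDialect = DEFAULT_DIALECT
) -> list[EvidenceRecord]:
    """Read an evidence TSV into a list of :class:`EvidenceRecord`.

    Raises :class:`EvidenceParseError` naming the missing column or the
    malformed row (1-based data row number).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in dialect.required_columns():
        if col not in df.columns:
            raise EvidenceParseError(f"missing required column {col!r}")
    records: list[EvidenceRecord] = []
    for rownum, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            records.append(_row_to_record(rowd, dialect))
        except (ValueError, KeyError) as exc:
            raise EvidenceParseError(f"row {rownum}: {exc}") from exc
    logger.info("read %d evidence records from %s", len(records), path)
    return records


def _row_to_record(row: dict[str, str], dialect: EvidenceDialect) -> EvidenceRecord:
    seq = row.get(dialect.sequence, "").strip().upper()
    modseq = row.get(dialect.modified_sequence, "").strip()
    if modseq:
        parsed_seq, mods = parse_modified_sequence(modseq)
        if seq and parsed_seq != seq:
            raise ValueError(
                f"modified sequence {modseq!r} inconsistent with sequence {seq!r}"
            )
        seq = parsed_seq
    else:
        mods = _parse_modifications_column(seq, row.get(dialect.modifications, ""))
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residue(s) {sorted(bad)} in {seq!r}")
    intensity_raw = row.get(dialect.intensity, "").strip()
    intensity = float(intensity_raw) if intensity_raw not in {"", "NaN", "nan"} else None
    charge_raw = row.get(dialect.charge, "").strip()
    proteins_raw = row.get(dialect.proteins, "").strip()
    group_raw = row.get(dialect.group, "").strip().lower()
    return EvidenceRecord(
        peptide_seq=seq,
        mod_list=mods,
        charge=int(float(charge_raw)) if charge_raw else 2,
        mz=float(row.get(dialect.mz, "") or 0.0),
        intensity=intensity,
        score=float(row.get(dialect.score, "") or 0.0),
        accessions=tuple(p for p in proteins_raw.split(";") if p),
        sample_id=row.get(dialect.raw_file, "").strip(),
        group=group_raw if group_raw in {GROUP_ORIGINAL, GROUP_CONTAMINANT} else GROUP_UNASSIGNED,
    )


def write_evidence(
    records: list[EvidenceRecord],
    path: str | Path,
    dialect: EvidenceDialect = DEFAULT_DIALECT,
) -> None:
    """Write records back to the evidence TSV dialect (round-trip safe)."""
    rows = []
    for r in records:
        rows.append(
            {
                dialect.sequence: r.peptide_seq,
                dialect.modified_sequence: format_modified_sequence(
                    r.peptide_seq, r.mod_list
                ),
                dialect.modifications: "",
                dialect.charge: r.charge,
                dialect.mz: repr(r.mz),
                dialect.intensity: "" if r.intensity is None else repr(r.intensity),
                dialect.score: repr(r.score),
                dialect.proteins: ";".join(r.accessions),
                dialect.raw_file: r.sample_id,
                dialect.group: r.group,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def count_missed_cleavages(seq: str, proline_rule: bool = True) -> int:
    """Number of uncut internal tryptic sites (K/R not at the C-terminus).

    With ``proline_rule`` a K/R followed by P is not a cleavage site.
    """
    n = 0
    for i in range(len(seq) - 1):
        if seq[i] in "KR" and not (proline_rule and seq[i + 1] == "P"):
            n += 1
    return n


def filter_records(
    records: list[EvidenceRecord],
    min_score: float = 40.0,
    require_intensity: bool = True,
    max_missed_cleavages: int | None = 3,
    proline_rule: bool = True,
) -> list[EvidenceRecord]:
    """Apply the standard search-output filters, preserving record order.

    Keeps rows with score >= ``min_score``; with intensity present and
    positive when ``require_intensity``; and with at most
    ``max_missed_cleavages`` uncut internal K/R sites (``None`` disables
    the digestion check).  Idempotent.
    """
    kept = []
    for r in records:
        if r.score < min_score:
            continue
        if require_intensity and (r.intensity is None or r.intensity <= 0):
            continue
        if (
            max_missed_cleavages is not None
            and count_missed_cleavages(r.peptide_seq, proline_rule) > max_missed_cleavages
        ):
            continue
        kept.append(r)
    logger.info(
        "filter_records: kept %d of %d (min_score=%s, require_intensity=%s, max_missed=%s)",
        len(kept), len(records), min_score, require_intensity, max_missed_cleavages,
    )
    return kept


def assign_groups(
    records: list[EvidenceRecord], contaminants: set[str]
) -> list[EvidenceRecord]:
    """Label records original/contaminant by their protein accessions.

    A record whose accessions intersect the contaminant list is a
    contaminant; records with accessions are otherwise original; records
    without any accession stay unassigned.
    """
    out = []
    for r in records:
        if any(a in contaminants for a in r.accessions):
            group = GROUP_CONTAMINANT
        elif r.accessions:
            group = GROUP_ORIGINAL
        else:
            group = GROUP_UNASSIGNED
        out.append(replace(r, group=group))
    return out


def read_fasta(path: str | Path, numbering_offset: int = 1) -> list[ReferenceSequence]:
    """Read reference protein sequences from FASTA.

    Sequences are uppercased; ``*`` and gap characters are rejected, as
    are duplicate accessions.
    """
    seqs: list[ReferenceSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate accession {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if "*" in residues or "-" in residues or "." in residues:
            raise ValueError(f"{rec.id}: stop/gap characters not allowed")
        seqs.append(
            ReferenceSequence(
                accession=rec.id,
                description=rec.description,
                residues=residues,
                numbering_offset=numbering_offset,
            )
        )
    return seqs


def read_contaminant_list(path: str | Path) -> set[str]:
    """Read a plain-text contaminant accession list ('#' comments ignored)."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out
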