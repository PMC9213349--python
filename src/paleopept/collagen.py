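"""Collagen alpha-chain characterisation from observed peptides.

Covers in-silico tryptic digestion, substitution/indel-tolerant placement
of observed peptides on a reference chain, coverage computation,
diagnostic-site reporting and Gly-Xaa-Yaa triplet validation.  Collagen's
triple-helical domain requires glycine at every third position, so a
candidate substitution or indel that breaks the triplet frame is more
plausibly a database error than a real variant — the triplet report makes
that check explicit.

Alignment model: the peptide is aligned end-to-end against a local window
of the reference (match +1, mismatch -1, gap -2), with deterministic
tie-breaking (fewest indels, then leftmost placement; diagonal moves
preferred in traceback).  Edits are reported in mature-chain coordinates
(1-based, honouring the reference's numbering offset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evidence import ReferenceSequence

logger = logging.getLogger(__name__)

__all__ = [
    "DigestProduct",
    "Edit",
    "PeptideAlignment",
    "CoverageReport",
    "TripletReport",
    "tryptic_digest",
    "map_peptide",
    "coverage",
    "validate_triplets",
    "diagnostic_sites",
]

GAP_PENALTY = -2
MATCH_SCORE = 1
MISMATCH_SCORE = -1


@dataclass(frozen=True)
class DigestProduct:
    """A tryptic peptide with its 1-based inclusive coordinates."""

    peptide: str
    start: int
    end: int
    missed: int


def cleavage_sites(seq: str, proline_rule: bool = True) -> list[int]:
    """0-based indices *after* which trypsin cleaves (K/R, optionally not
    before P)."""
    return [
        i
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and not (proline_rule and seq[i + 1] == "P")
    ]


def tryptic_digest(
    seq: str,
    max_missed: int = 3,
    min_len: int = 1,
    max_len: int | None = None,
    proline_rule: bool = True,
) -> list[DigestProduct]:
    """All tryptic products with up to ``max_missed`` internal sites.

    Cleavage occurs after K or R; with ``proline_rule`` (the default
    dialect) not when the next residue is proline.  Coordinates are
    1-based inclusive in ``seq``.  Products are ordered by start position,
    then by missed-cleavage count.
    """
    sites = cleavage_sites(seq, proline_rule)
    # fragment boundaries: 0-based half-open [b[i], b[i+1])
    bounds = [0] + [s + 1 for s in sites] + [len(seq)]
    out: list[DigestProduct] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for missed in range(max_missed + 1):
            j = i + missed + 1
            if j > n_frag:
                break
            start, end = bounds[i], bounds[j]
            pep = seq[start:end]
            if len(pep) < min_len or (max_len is not None and len(pep) > max_len):
                continue
            out.append(DigestProduct(pep, start + 1, end, missed))
    return out


@dataclass(frozen=True)
class Edit:
    """One difference between observed peptide and reference.

    ``type`` is substitution / deletion (reference residue absent from the
    peptide) / insertion (extra observed residue; ``ref_position`` is the
    reference position *before* the inserted residue).
    """

    type: str
    ref_position: int
    ref_residue: str
    obs_residue: str


@dataclass(frozen=True)
class PeptideAlignment:
    peptide_seq: str
    accession: str
    ref_start: int
    ref_end: int
    edits: tuple[Edit, ...]
    score: int
    ambiguous: bool = False

    @property
    def n_indels(self) -> int:
        return sum(1 for e in self.edits if e.type != "substitution")


def _traceback(
    pep: str, ref: str, dp: np.ndarray, end_j: int
) -> tuple[int, list[tuple[str, int, str, str]]]:
    """Follow one optimal path back from (len(pep), end_j).

    Returns (start_j, ops) where ops are (type, ref_index_0based,
    ref_residue, obs_residue) in left-to-right order.  Ties prefer the
    diagonal move, then the gap-in-peptide (reference deletion) move.
    """
    i, j = len(pep), end_j
    ops: list[tuple[str, int, str, str]] = []
    while i > 0:
        here = dp[i, j]
        if j > 0:
            diag = dp[i - 1, j - 1] + (
                MATCH_SCORE if pep[i - 1] == ref[j - 1] else MISMATCH_SCORE
            )
            if here == diag:
                if pep[i - 1] != ref[j - 1]:
                    ops.append(("substitution", j - 1, ref[j - 1], pep[i - 1]))
                i, j = i - 1, j - 1
                continue
            if here == dp[i, j - 1] + GAP_PENALTY:
                ops.append(("deletion", j - 1, ref[j - 1], "-"))
                j -= 1
                continue
        # gap in reference: inserted observed residue after ref position j
        ops.append(("insertion", j - 1, "-", pep[i - 1]))
        i -= 1
    ops.reverse()
    return j, ops


def map_peptide(
    peptide: str,
    reference: ReferenceSequence,
    max_edits: int = 2,
    min_len: int = 6,
) -> PeptideAlignment | None:
    """Best placement of an observed peptide on a reference chain.

    The peptide is aligned in full against a local reference window
    (semi-global dynamic programming).  Returns ``None`` when the best
    alignment needs more than ``max_edits`` substitutions/indels, or when
    the peptide is shorter than ``min_len``.  Equally optimal placements
    are resolved by fewest indels, then leftmost start; a residual tie is
    flagged ``ambiguous``.
    """
    if len(peptide) < min_len:
        logger.warning("peptide %r shorter than %d: skipped", peptide, min_len)
        return None
    ref = reference.residues
    m, n = len(peptide), len(ref)
    dp = np.empty((m + 1, n + 1), dtype=np.int32)
    dp[0, :] = 0  # alignment may start anywhere in the reference
    dp[1:, 0] = GAP_PENALTY * np.arange(1, m + 1)
    pep_arr = np.frombuffer(peptide.encode(), dtype=np.uint8)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    for i in range(1, m + 1):
        match = np.where(ref_arr == pep_arr[i - 1], MATCH_SCORE, MISMATCH_SCORE)
        diag = dp[i - 1, :-1] + match
        up = dp[i - 1, 1:] + GAP_PENALTY
        row = np.maximum(diag, up)
        # left moves need a sequential pass
        prev = dp[i, 0]
        for j in range(1, n + 1):
            prev = max(row[j - 1], prev + GAP_PENALTY)
            dp[i, j] = prev
    best = dp[m, :].max()
    candidates = []
    for end_j in np.flatnonzero(dp[m, :] == best):
        start_j, ops = _traceback(peptide, ref, dp, int(end_j))
        n_indels = sum(1 for op in ops if op[0] != "substitution")
        candidates.append((n_indels, start_j, int(end_j), ops))
    candidates.sort(key=lambda c: (c[0], c[1]))
    n_indels, start_j, end_j, ops = candidates[0]
    ambiguous = (
        len(candidates) > 1
        and (candidates[1][0], candidates[1][1]) == (n_indels, start_j)
        and candidates[1][3] != ops
    )
    if len(ops) > max_edits:
        return None
    edits = tuple(
        Edit(
            type=t,
            ref_position=reference.position(jj),
            ref_residue=rr,
            obs_residue=oo,
        )
        for t, jj, rr, oo in ops
    )
    return PeptideAlignment(
        peptide_seq=peptide,
        accession=reference.accession,
        ref_start=reference.position(start_j),
        ref_end=reference.position(end_j - 1),
        edits=edits,
        score=int(best),
        ambiguous=ambiguous,
    )


@dataclass(frozen=True)
class CoverageReport:
    accession: str
    covered_positions: frozenset[int]
    pct_covered: float
    n_fragments: int


def coverage(
    alignments: list[PeptideAlignment], reference: ReferenceSequence
) -> CoverageReport:
    """Union coverage of a reference chain by aligned peptides.

    A reference position counts as covered when an observed residue is
    aligned to it — substituted positions are covered, deleted reference
    positions are not, insertions add nothing.
    """
    covered: set[int] = set()
    n = 0
    for aln in alignments:
        if aln.accession != reference.accession:
            raise ValueError(
                f"alignment against {aln.accession}, expected {reference.accession}"
            )
        n += 1
        deleted = {e.ref_position for e in aln.edits if e.type == "deletion"}
        covered.update(
            p for p in range(aln.ref_start, aln.ref_end + 1) if p not in deleted
        )
    pct = 100.0 * len(covered) / len(reference)
    return CoverageReport(reference.accession, frozenset(covered), pct, n)


@dataclass(frozen=True)
class TripletViolation:
    triplet_index: int
    ref_position: int
    residue: str


@dataclass(frozen=True)
class TripletReport:
    region_start: int
    region_end: int
    frame: int
    violations: tuple[TripletViolation, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_triplets(
    region: str, frame: int | None = None, region_start: int = 1
) -> TripletReport:
    """Check the Gly-Xaa-Yaa repeat of a collagen sequence region.

    With an explicit ``frame`` (0-2), every third residue from that offset
    must be glycine; with ``frame=None`` the frame minimising violations
    is chosen (lowest frame on ties).  ``region_start`` sets the reported
    reference coordinates.
    """
    if len(region) < 3:
        raise ValueError("region must be at least one triplet long")

    def violations_for(f: int) -> tuple[TripletViolation, ...]:
        out = []
        for t_idx, i in enumerate(range(f, len(region), 3)):
            if region[i] != "G":
                out.append(
                    TripletViolation(t_idx, region_start + i, region[i])
                )
        return tuple(out)

    if frame is not None:
        chosen, viol = frame, violations_for(frame)
    else:
        scored = [(len(violations_for(f)), f) for f in range(3)]
        _, chosen = min(scored)
        viol = violations_for(chosen)
    return TripletReport(
        region_start=region_start,
        region_end=region_start + len(region) - 1,
        frame=chosen,
        violations=viol,
    )


def diagnostic_sites(
    observed: dict[int, str],
    panel: dict[str, ReferenceSequence],
) -> pd.DataFrame:
    """Tabulate observed residues against a panel of reference chains.

    ``observed`` maps mature-chain positions to the residues called in the
    sample (typically substitution calls from :func:`map_peptide` plus
    positions of interest).  A site is *diagnostic* when the observed
    residue differs from every panel member; sites where panel members
    disagree among themselves are also reported (they separate panel
    species even without an observed difference).
    """
    rows = []
    for pos in sorted(observed):
        obs = observed[pos]
        panel_res = {}
        for name, ref in panel.items():
            idx = pos - ref.numbering_offset
            panel_res[name] = (
                ref.residues[idx] if 0 <= idx < len(ref.residues) else "-"
            )
        present = [r for r in panel_res.values() if r != "-"]
        row = {"position": pos, "observed": obs}
        row.update(panel_res)
        row["diagnostic"] = bool(present) and all(r != obs for r in present)
        row["separates_panel"] = len(set(present)) > 1
        rows.append(row)
    return pd.DataFrame(rows)
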