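"""Lowest-common-ancestor taxonomic profiling of peptides.

A peptide observed in a metaproteomic sample may occur in the proteomes of
many taxa; its most specific defensible assignment is the lowest common
ancestor (LCA) of that taxon set over a rooted taxonomy.  Peptide counts
are then summarised per clade, each node's percentage expressed relative
to its parent's subtree count (the parent is 100%).

The taxonomy input is a minimal NCBI-dump-like dialect: either a single
4-column TSV (taxon_id, parent_id, rank, name) or separate nodes/names
tables.  Trees need not be fully ranked; missing intermediate ranks are
tolerated.  Peptide sequences are I/L-normalised before lookup, the
standard convention for tryptic peptides whose MS/MS spectra cannot
distinguish leucine from isoleucine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonomyTree",
    "PeptideTaxonMap",
    "CladeSummary",
    "AssignmentResult",
    "normalize_il",
    "lca",
    "assign_peptides",
    "treeview",
]


def normalize_il(seq: str) -> str:
    """Collapse isoleucine onto leucine (I/L indistinguishable by MS)."""
    return seq.upper().replace("I", "L")


@dataclass
class TaxonomyTree:
    """Rooted taxonomy: ``taxon_id -> (parent_id, rank, name)``.

    The root's parent is itself (or None in the input).  Construction
    validates that there is exactly one root, every parent exists, and
    there are no cycles.
    """

    parent: dict[int, int]
    rank: dict[int, str]
    name: dict[int, str]
    root: int = field(init=False)

    def __post_init__(self) -> None:
        roots = [t for t, p in self.parent.items() if p == t]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._children: dict[int, list[int]] = {t: [] for t in self.parent}
        for t, p in self.parent.items():
            if p not in self.parent:
                raise ValueError(f"parent {p} of taxon {t} not in tree")
            if t != self.root:
                self._children[p].append(t)
        for kids in self._children.values():
            kids.sort()
        self._depth: dict[int, int] = {}
        for t in self.parent:
            d, node, seen = 0, t, set()
            while node != self.root:
                if node in seen:
                    raise ValueError(f"cycle detected at taxon {node}")
                seen.add(node)
                node = self.parent[node]
                d += 1
                if d > len(self.parent):
                    raise ValueError(f"cycle detected at taxon {t}")
            self._depth[t] = d

    @classmethod
    def from_table(cls, path: str | Path) -> "TaxonomyTree":
        """Read a 4-column TSV: taxon_id, parent_id, rank, name."""
        df = pd.read_csv(
            path, sep="\t", comment="#",
            names=["taxon_id", "parent_id", "rank", "name"],
            dtype={"taxon_id": int, "rank": str, "name": str},
        )
        parent, rank, name = {}, {}, {}
        for row in df.itertuples(index=False):
            tid = int(row.taxon_id)
            pid = tid if pd.isna(row.parent_id) else int(row.parent_id)
            parent[tid], rank[tid], name[tid] = pid, row.rank, row.name
        return cls(parent, rank, name)

    def to_table(self, path: str | Path) -> None:
        rows = [
            (t, self.parent[t], self.rank[t], self.name[t])
            for t in sorted(self.parent)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    def children(self, taxon_id: int) -> list[int]:
        return self._children[taxon_id]

    def depth(self, taxon_id: int) -> int:
        return self._depth[taxon_id]

    def path_to_root(self, taxon_id: int) -> list[int]:
        """Taxa from ``taxon_id`` up to and including the root."""
        if taxon_id not in self.parent:
            raise KeyError(f"unknown taxon {taxon_id}")
        path = [taxon_id]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def is_ancestor(self, ancestor: int, node: int) -> bool:
        return ancestor in self.path_to_root(node)

    def subtree(self, taxon_id: int) -> set[int]:
        out, stack = set(), [taxon_id]
        while stack:
            t = stack.pop()
            out.add(t)
            stack.extend(self._children[t])
        return out

    def to_newick(self, counts: dict[int, int] | None = None) -> str:
        """Newick string of the tree (optionally annotated with counts)."""
        def label(t: int) -> str:
            base = self.name[t].replace(" ", "_").replace(",", "_")
            if counts is not None:
                base += f"_{counts.get(t, 0)}"
            return base

        def render(t: int) -> str:
            kids = self._children[t]
            if not kids:
                return label(t)
            return "(" + ",".join(render(k) for k in kids) + ")" + label(t)

        return render(self.root) + ";"


@dataclass
class PeptideTaxonMap:
    """I/L-normalised peptide sequence -> set of taxon ids."""

    mapping: dict[str, set[int]]

    @classmethod
    def from_pairs(
        cls, pairs: list[tuple[str, int]], tree: TaxonomyTree | None = None
    ) -> "PeptideTaxonMap":
        mapping: dict[str, set[int]] = {}
        for seq, tid in pairs:
            if tree is not None and tid not in tree:
                raise ValueError(f"taxon {tid} not in tree")
            mapping.setdefault(normalize_il(seq), set()).add(tid)
        return cls(mapping)

    @classmethod
    def from_table(
        cls, path: str | Path, tree: TaxonomyTree | None = None
    ) -> "PeptideTaxonMap":
        """Read a 2-column TSV: peptide, semicolon-joined taxon ids."""
        df = pd.read_csv(path, sep="\t", comment="#", names=["peptide", "taxa"], dtype=str)
        pairs = [
            (row.peptide, int(t))
            for row in df.itertuples(index=False)
            for t in str(row.taxa).split(";")
        ]
        return cls.from_pairs(pairs, tree)

    def get(self, seq: str) -> set[int] | None:
        return self.mapping.get(normalize_il(seq))


@dataclass(frozen=True)
class CladeSummary:
    """Per-node peptide counts in depth-first order."""

    taxon_id: int
    name: str
    rank: str
    depth: int
    n_peptides_direct: int
    n_peptides_subtree: int
    pct_of_parent: float


@dataclass
class AssignmentResult:
    assignments: dict[str, int]
    unassigned: list[str]
    excluded: dict[str, str]


def lca(tree: TaxonomyTree, taxa: set[int]) -> int:
    """Deepest node ancestral to (or equal to) every taxon in ``taxa``.

    A singleton set returns its element; a set spanning unrelated clades
    climbs to the root ("organism").
    """
    if not taxa:
        raise ValueError("taxa set must be non-empty")
    it = iter(taxa)
    common = tree.path_to_root(next(it))
    for t in it:
        anc = set(tree.path_to_root(t))
        common = [x for x in common if x in anc]
    return common[0]


def assign_peptides(
    tree: TaxonomyTree,
    pmap: PeptideTaxonMap,
    peptides: list[str],
    exclusion_groups: dict[str, int] | None = None,
) -> AssignmentResult:
    """Assign each peptide to the LCA of its taxon set.

    ``exclusion_groups`` maps group names to subtree-root taxon ids of
    disjoint reference databases (e.g. Proboscidea / Viridiplantae /
    Bacteria+Nematoda); a peptide whose taxa fall in two or more groups is
    not a valid identification and is excluded with a reason.  Peptides
    absent from the map land in the unassigned bucket.
    """
    group_members: dict[str, set[int]] = {}
    if exclusion_groups:
        for gname, groot in exclusion_groups.items():
            if groot not in tree:
                raise ValueError(f"exclusion group root {groot} not in tree")
            group_members[gname] = tree.subtree(groot)
    assignments: dict[str, int] = {}
    unassigned: list[str] = []
    excluded: dict[str, str] = {}
    for pep in peptides:
        taxa = pmap.get(pep)
        if not taxa:
            unassigned.append(pep)
            continue
        hit_groups = sorted(
            g for g, members in group_members.items() if taxa & members
        )
        if len(hit_groups) >= 2:
            excluded[pep] = "spans reference groups: " + ", ".join(hit_groups)
            continue
        assignments[pep] = lca(tree, taxa)
    if unassigned:
        logger.info("%d peptides absent from the taxon map", len(unassigned))
    if excluded:
        logger.info("%d peptides excluded as cross-group matches", len(excluded))
    return AssignmentResult(assignments, unassigned, excluded)


def treeview(tree: TaxonomyTree, assignments: dict[str, int]) -> list[CladeSummary]:
    """Per-clade peptide counts with parent-relative percentages.

    A node's subtree count includes peptides assigned to the node itself
    or to any descendant; ``pct_of_parent`` is
    ``100 * count(node) / count(parent)`` with the root fixed at 100%.
    Nodes with empty subtrees are omitted.  Deterministic depth-first
    order (children by taxon id).
    """
    direct: dict[int, int] = {}
    for pep, tid in assignments.items():
        if tid not in tree:
            raise ValueError(f"assignment to unknown taxon {tid}")
        direct[tid] = direct.get(tid, 0) + 1

    subtree_counts: dict[int, int] = {}

    def accumulate(t: int) -> int:
        total = direct.get(t, 0) + sum(accumulate(k) for k in tree.children(t))
        subtree_counts[t] = total
        return total

    accumulate(tree.root)

    out: list[CladeSummary] = []

    def visit(t: int, parent_total: int) -> None:
        total = subtree_counts[t]
        if total == 0:
            return
        pct = 100.0 if t == tree.root else 100.0 * total / parent_total
        out.append(
            CladeSummary(
                taxon_id=t,
                name=tree.name[t],
                rank=tree.rank[t],
                depth=tree.depth(t),
                n_peptides_direct=direct.get(t, 0),
                n_peptides_subtree=total,
                pct_of_parent=pct,
            )
        )
        for k in tree.children(t):
            visit(k, total)

    visit(tree.root, subtree_counts[tree.root])
    return out
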