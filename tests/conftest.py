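"""Shared fixtures: a small multi-kingdom taxonomy, hand-written evidence
tables, and the synthetic collagen reference chains."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from paleopept.evidence import EvidenceRecord

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")
from paleopept.taxonomy import TaxonomyTree
from paleopept.synthetic_references import synthetic_col1a1, synthetic_col1a2


def build_fixture_tree() -> TaxonomyTree:
    """A ~40-node rooted taxonomy spanning Eukaryota / Elephantidae /
    Viridiplantae / Bacteria / Nematoda with a human lineage."""
    nodes = {
        # id: (parent, rank, name)
        1: (1, "no rank", "organism"),
        2: (1, "domain", "Eukaryota"),
        3: (1, "domain", "Bacteria"),
        10: (2, "kingdom", "Metazoa"),
        11: (2, "kingdom", "Viridiplantae"),
        20: (10, "class", "Mammalia"),
        21: (10, "phylum", "Nematoda"),
        30: (20, "superorder", "Afrotheria"),
        31: (20, "order", "Primates"),
        40: (30, "order", "Proboscidea"),
        41: (40, "family", "Elephantidae"),
        42: (41, "genus", "Loxodonta"),
        43: (41, "genus", "Elephas"),
        44: (41, "genus", "Mammuthus"),
        45: (42, "species", "Loxodonta africana"),
        46: (43, "species", "Elephas maximus"),
        47: (44, "species", "Mammuthus primigenius"),
        48: (40, "family", "Mammutidae"),
        49: (48, "species", "Mammut americanum"),
        50: (31, "family", "Hominidae"),
        51: (50, "species", "Homo sapiens"),
        60: (11, "phylum", "Streptophyta"),
        61: (11, "phylum", "Chlorophyta"),
        62: (60, "class", "Magnoliopsida"),
        63: (62, "family", "Brassicaceae"),
        64: (63, "species", "Arabidopsis thaliana"),
        65: (62, "clade", "Petrosaviidae"),
        66: (65, "species", "Oryza sativa"),
        67: (61, "species", "Chlamydomonas reinhardtii"),
        70: (3, "phylum", "Proteobacteria"),
        71: (3, "phylum", "Firmicutes"),
        72: (3, "phylum", "Tenericutes"),
        73: (70, "species", "Escherichia coli"),
        74: (71, "species", "Bacillus subtilis"),
        75: (72, "species", "Mesoplasma florum"),
        80: (21, "order", "Rhabditida"),
        81: (80, "genus", "Caenorhabditis"),
        82: (81, "species", "Caenorhabditis elegans"),
        83: (80, "infraorder", "Spirurina"),
    }
    return TaxonomyTree(
        parent={t: v[0] for t, v in nodes.items()},
        rank={t: v[1] for t, v in nodes.items()},
        name={t: v[2] for t, v in nodes.items()},
    )


@pytest.fixture(scope="session")
def fixture_tree() -> TaxonomyTree:
    return build_fixture_tree()


@pytest.fixture(scope="session")
def col1a1():
    return synthetic_col1a1()


@pytest.fixture(scope="session")
def col1a2():
    return synthetic_col1a2()


def make_record(
    seq: str,
    mods=(),
    intensity: float | None = 1000.0,
    score: float = 90.0,
    group: str = "original",
    sample_id: str = "trunk",
    accessions=("P1",),
) -> EvidenceRecord:
    return EvidenceRecord(
        peptide_seq=seq,
        mod_list=tuple(mods),
        charge=2,
        mz=500.0,
        intensity=intensity,
        score=score,
        accessions=tuple(accessions),
        sample_id=sample_id,
        group=group,
    )


def random_tree(rng: np.random.Generator, n_nodes: int) -> TaxonomyTree:
    """Random rooted tree: each node's parent is an earlier node."""
    parent = {1: 1}
    for t in range(2, n_nodes + 1):
        parent[t] = int(rng.integers(1, t))
    return TaxonomyTree(
        parent=parent,
        rank={t: "no rank" for t in parent},
        name={t: f"n{t}" for t in parent},
    )


def brute_force_lca(tree: TaxonomyTree, taxa: set[int]) -> int:
    """Independent LCA oracle: intersect root paths, take the deepest."""
    common = set(tree.path_to_root(next(iter(taxa))))
    for t in taxa:
        common &= set(tree.path_to_root(t))
    return max(common, key=tree.depth)
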