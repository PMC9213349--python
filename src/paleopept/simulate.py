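"""Synthetic data generation for end-to-end pipeline testing.

Everything the pipeline consumes can be generated here with known ground
truth: collagen-like reference chains (Gly-Xaa-Yaa repeats with tryptic
sites), a small multi-kingdom taxonomy with a peptide->species reference
panel, and evidence tables emulating the two peptide populations of a
paleoproteomic sample — endogenous "ancient" peptides with high N/Q
deamidation (per-site probability drawn from 0.35-0.63 per sample) and
elevated oxidation, against modern contaminants with deamidation around
5%.  MS1 intensities are log-normal, search scores a two-component
mixture so the score>=40 filter is exercised, and deamidation is
simulated per-site as independent Bernoulli draws with no sequence
context.  Identical config + seed gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evidence import EvidenceRecord, ReferenceSequence
from .classify import ReferencePanel
from .masses import neutral_mass_to_mz, peptide_mass
from .collagen import tryptic_digest
from .taxonomy import PeptideTaxonMap, TaxonomyTree

__all__ = [
    "SimulationConfig",
    "TaxonomySpec",
    "SyntheticTaxonomy",
    "SimulationResult",
    "make_collagen_reference",
    "make_protein_reference",
    "make_taxonomy",
    "simulate_evidence",
]

# Typical vertebrate amino-acid frequencies (UniProt-wide averages),
# used for globular "cellular protein" references.
GLOBULAR_FREQS = {
    "A": 0.083, "C": 0.014, "D": 0.055, "E": 0.067, "F": 0.039,
    "G": 0.071, "H": 0.023, "I": 0.059, "K": 0.058, "L": 0.097,
    "M": 0.024, "N": 0.040, "P": 0.047, "Q": 0.047, "R": 0.055,
    "S": 0.067, "T": 0.054, "V": 0.069, "W": 0.011, "Y": 0.029,
}

# Xaa/Yaa composition of the collagen triple-helical domain: proline-rich,
# with charged residues (K/R providing tryptic sites) and modest N/Q.
COLLAGEN_XY_FREQS = {
    "P": 0.30, "A": 0.14, "S": 0.08, "E": 0.07, "K": 0.07, "D": 0.06,
    "R": 0.05, "Q": 0.05, "L": 0.05, "V": 0.04, "T": 0.04, "N": 0.03,
    "I": 0.02, "F": 0.02, "M": 0.02, "G": 0.02, "H": 0.01, "Y": 0.01,
    "W": 0.005, "C": 0.005,
}

_OXIDATION_MOD = {"M": "oxidation", "P": "oxidation", "W": "oxidation",
                  "Y": "oxidation", "C": "trioxidation"}


def _draw_sequence(rng: np.random.Generator, length: int, freqs: dict[str, float]) -> str:
    letters = sorted(freqs)
    p = np.array([freqs[a] for a in letters])
    p = p / p.sum()
    return "".join(rng.choice(letters, size=length, p=p))


def make_collagen_reference(
    n_triplets: int,
    seed: int | np.random.Generator = 0,
    accession: str = "SIM_COLLAGEN",
    xy_freqs: dict[str, float] | None = None,
) -> ReferenceSequence:
    """A collagen-like chain of ``n_triplets`` Gly-Xaa-Yaa triplets.

    Xaa/Yaa positions are drawn proline-enriched (with K/R providing
    tryptic cleavage sites); glycine sits at every triplet start, so the
    chain passes triplet validation at frame 0 with zero violations.
    """
    if n_triplets < 1:
        raise ValueError("n_triplets must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xy = _draw_sequence(rng, 2 * n_triplets, xy_freqs or COLLAGEN_XY_FREQS)
    chain = "".join("G" + xy[2 * i : 2 * i + 2] for i in range(n_triplets))
    return ReferenceSequence(
        accession=accession,
        description=f"{accession} simulated collagen-like chain",
        residues=chain,
        numbering_offset=1,
    )


def make_protein_reference(
    length: int,
    seed: int | np.random.Generator = 0,
    accession: str = "SIM_PROT",
    freqs: dict[str, float] | None = None,
) -> ReferenceSequence:
    """A globular-protein-like random chain at typical AA frequencies."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return ReferenceSequence(
        accession=accession,
        description=f"{accession} simulated protein",
        residues=_draw_sequence(rng, length, freqs or GLOBULAR_FREQS),
        numbering_offset=1,
    )


@dataclass
class TaxonomySpec:
    """Clades and species of the synthetic taxonomy.

    The default mirrors a Proboscidea / Viridiplantae / Bacteria+Nematoda
    reference-database split with a human lineage for the contamination
    rules.
    """

    clades: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "Elephantidae": (
                "Loxodonta africana",
                "Mammuthus primigenius",
                "Elephas maximus",
            ),
            "Hominidae": ("Homo sapiens",),
            "Viridiplantae": ("Arabidopsis thaliana", "Oryza sativa"),
            "Bacteria": ("Mesoplasma florum", "Escherichia coli"),
            "Nematoda": ("Caenorhabditis elegans",),
        }
    )
    human_species: str = "Homo sapiens"
    #: fractions of panel peptides that are species/clade-unique, shared
    #: among non-human species, or shared with human
    clade_unique_fraction: float = 0.6
    shared_non_human_fraction: float = 0.25
    human_shared_fraction: float = 0.15
    peptides_per_species: int = 40
    protein_length: int = 400


@dataclass
class SyntheticTaxonomy:
    tree: TaxonomyTree
    panel: ReferencePanel
    peptide_map: PeptideTaxonMap
    species_taxid: dict[str, int]
    clade_taxid: dict[str, int]


def make_taxonomy(
    spec: TaxonomySpec | None = None, seed: int | np.random.Generator = 0
) -> SyntheticTaxonomy:
    """Build a rooted taxonomy plus peptide->species reference panel.

    Per-species reference proteins are digested; each tryptic peptide is
    then assigned a species set according to the spec's sharing fractions
    (unique to its species, shared within/across non-human clades, or
    shared including human).  An empty spec yields a root-only tree.
    """
    spec = spec or TaxonomySpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parent = {1: 1}
    rank = {1: "no rank"}
    name = {1: "organism"}
    species_taxid: dict[str, int] = {}
    clade_taxid: dict[str, int] = {}
    next_id = 2
    for clade in sorted(spec.clades):
        clade_taxid[clade] = next_id
        parent[next_id], rank[next_id], name[next_id] = 1, "clade", clade
        cid = next_id
        next_id += 1
        for sp in spec.clades[clade]:
            species_taxid[sp] = next_id
            parent[next_id], rank[next_id], name[next_id] = cid, "species", sp
            next_id += 1
    tree = TaxonomyTree(parent, rank, name)

    pairs: list[tuple[str, str]] = []
    all_species = [sp for clade in sorted(spec.clades) for sp in spec.clades[clade]]
    non_human = [sp for sp in all_species if sp != spec.human_species]
    species_clade = {
        sp: clade for clade, members in spec.clades.items() for sp in members
    }
    for sp in all_species:
        ref = make_protein_reference(
            spec.protein_length, rng, accession=f"SIM_{sp.replace(' ', '_')}"
        )
        products = [
            d.peptide
            for d in tryptic_digest(ref.residues, max_missed=1, min_len=7, max_len=30)
        ]
        rng.shuffle(products)
        for pep in products[: spec.peptides_per_species]:
            u = rng.random()
            if u < spec.clade_unique_fraction or sp == spec.human_species:
                pairs.append((pep, sp))
            elif u < spec.clade_unique_fraction + spec.shared_non_human_fraction:
                pairs.append((pep, sp))
                others = [
                    o for o in non_human
                    if o != sp and species_clade[o] == species_clade[sp]
                ] or [o for o in non_human if o != sp]
                pairs.append((pep, others[int(rng.integers(len(others)))]))
            else:
                pairs.append((pep, sp))
                pairs.append((pep, spec.human_species))
    panel = ReferencePanel.from_pairs(pairs, human_label=spec.human_species)
    pmap = PeptideTaxonMap.from_pairs(
        [(pep, species_taxid[sp]) for pep, sp in pairs], tree
    )
    return SyntheticTaxonomy(tree, panel, pmap, species_taxid, clade_taxid)


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic evidence generator.

    Deamidation probabilities are per-site Bernoulli parameters: the
    ancient default is drawn once per sample from the uniform band
    0.35-0.63, the modern default is 0.05.  Intensities are log-normal in
    natural log space; scores are a mixture of a "true match" and a
    "noise" normal so the score>=40 filter retains a realistic fraction.
    """

    seed: int = 0
    n_ancient: int = 500
    n_contaminant: int = 500
    samples: tuple[str, ...] = ("trunk",)
    deamidation_prob_ancient: float | None = None  # None -> U[0.35, 0.63] per sample
    deamidation_band: tuple[float, float] = (0.35, 0.63)
    deamidation_prob_modern: float = 0.05
    oxidation_probs_ancient: dict[str, float] = field(
        default_factory=lambda: {"M": 0.25, "P": 0.30, "W": 0.10, "Y": 0.05, "C": 0.05}
    )
    oxidation_probs_modern: dict[str, float] = field(
        default_factory=lambda: {"M": 0.05, "P": 0.02, "W": 0.01, "Y": 0.01, "C": 0.01}
    )
    intensity_lognormal: tuple[float, float] = (16.0, 1.0)
    score_true: tuple[float, float] = (80.0, 15.0)
    score_noise: tuple[float, float] = (30.0, 8.0)
    noise_fraction: float = 0.1
    min_len: int = 7
    max_len: int = 30
    max_missed: int = 3
    n_collagen_triplets: int = 340
    n_globular_refs: int = 2
    globular_length: int = 400
    intensity_mod_coupling: float = 0.0  # >0 couples intensity to deamidation


@dataclass
class SimulationResult:
    records: list[EvidenceRecord]
    truth: pd.DataFrame
    contaminants: set[str]
    references: list[ReferenceSequence]
    deamidation_prob_by_sample: dict[str, float]


def _peptide_pool(config: SimulationConfig, rng: np.random.Generator, group: str):
    refs: list[ReferenceSequence] = []
    if group == "original":
        refs.append(
            make_collagen_reference(
                config.n_collagen_triplets, rng, accession="SIM_MAMMOTH_COL1A1"
            )
        )
        for i in range(config.n_globular_refs):
            refs.append(
                make_protein_reference(
                    config.globular_length, rng, accession=f"SIM_MAMMOTH_PROT{i+1}"
                )
            )
    else:
        for i in range(2):
            refs.append(
                make_protein_reference(
                    config.globular_length, rng, accession=f"CON_KERATIN{i+1}"
                )
            )
    pool: list[tuple[str, str]] = []
    for ref in refs:
        for d in tryptic_digest(
            ref.residues,
            max_missed=config.max_missed,
            min_len=config.min_len,
            max_len=config.max_len,
        ):
            pool.append((d.peptide, ref.accession))
    if not pool:
        raise ValueError("empty peptide pool; increase reference sizes")
    return pool, refs


def simulate_evidence(config: SimulationConfig) -> SimulationResult:
    """Generate a labelled synthetic evidence table.

    Returns evidence records (parseable by the evidence reader with zero
    dropped rows), a ground-truth table (group, source protein, true
    modified-site counts), the contaminant accession set, and the
    reference chains the peptides were drawn from.
    """
    rng = np.random.default_rng(config.seed)
    pool_orig, refs_orig = _peptide_pool(config, rng, "original")
    pool_cont, refs_cont = _peptide_pool(config, rng, "contaminant")
    contaminants = {r.accession for r in refs_cont}

    records: list[EvidenceRecord] = []
    truth_rows: list[dict] = []
    p_by_sample: dict[str, float] = {}
    mu_i, sigma_i = config.intensity_lognormal
    lo, hi = config.deamidation_band
    for sample in config.samples:
        if config.deamidation_prob_ancient is None:
            p_ancient = float(lo + (hi - lo) * rng.random())
        else:
            p_ancient = config.deamidation_prob_ancient
        p_by_sample[sample] = p_ancient
        for group, n_rec, pool, p_deam, ox_probs in (
            ("original", config.n_ancient, pool_orig, p_ancient,
             config.oxidation_probs_ancient),
            ("contaminant", config.n_contaminant, pool_cont,
             config.deamidation_prob_modern, config.oxidation_probs_modern),
        ):
            for _ in range(n_rec):
                pep, acc = pool[int(rng.integers(len(pool)))]
                mods: list[tuple[int, str]] = []
                k_deam = 0
                for i, res in enumerate(pep, start=1):
                    if res in "NQ" and rng.random() < p_deam:
                        mods.append((i, "deamidation"))
                        k_deam += 1
                    elif res in ox_probs and rng.random() < ox_probs[res]:
                        mods.append((i, _OXIDATION_MOD[res]))
                charge = int(rng.choice([2, 3, 4], p=[0.5, 0.4, 0.1]))
                mz = neutral_mass_to_mz(peptide_mass(pep, mods), charge)
                log_i = rng.normal(mu_i, sigma_i)
                if config.intensity_mod_coupling:
                    frac = k_deam / max(1, sum(pep.count(r) for r in "NQ"))
                    log_i += config.intensity_mod_coupling * frac
                intensity = float(np.exp(log_i))
                if rng.random() < config.noise_fraction:
                    score = rng.normal(*config.score_noise)
                else:
                    score = rng.normal(*config.score_true)
                records.append(
                    EvidenceRecord(
                        peptide_seq=pep,
                        mod_list=tuple(sorted(mods)),
                        charge=charge,
                        mz=float(mz),
                        intensity=intensity,
                        score=float(score),
                        accessions=(acc,),
                        sample_id=sample,
                        group=group,
                    )
                )
                truth_rows.append(
                    {
                        "sample_id": sample,
                        "group": group,
                        "peptide_seq": pep,
                        "accession": acc,
                        "p_deamidation": p_deam,
                        "n_nq_sites": sum(pep.count(r) for r in "NQ"),
                        "k_deamidated": k_deam,
                    }
                )
    return SimulationResult(
        records=records,
        truth=pd.DataFrame(truth_rows),
        contaminants=contaminants,
        references=refs_orig + refs_cont,
        deamidation_prob_by_sample=p_by_sample,
    )
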