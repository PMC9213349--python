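# Methods

## Modification-level estimation

For a residue type *r* (one letter, or a pooled set such as N+Q) and a
modification *m*, the level in a set of evidence records is

  level% = 100 · Σᵢ Iᵢ·kᵢ / Σᵢ Iᵢ·nᵢ ,

summing over records *i* that contain *r* (nᵢ > 0) and have a positive
MS1 intensity Iᵢ; kᵢ is the number of *r* positions in record *i*
carrying *m*. This is intensity-weighted site pooling: a record
contributes in proportion to its signal and to how many target residues
it bears. The estimator is scale-invariant in intensity, is a convex
combination of the per-record modified fractions, and converges to the
per-site modification probability when sites are independent Bernoulli
draws. An unweighted per-site variant (`weighting="unweighted"`) is
available because the aggregation rule of the widely used deamidation
screening scripts is not fully specified in the literature; the weighted
form is the default. Records with missing intensity are excluded, not
imputed. Samples and groups (original vs. contaminant) are never pooled.

Confidence intervals are percentile bootstrap over whole records
(default B = 1000, mandatory seed). Resampling records rather than sites
respects the within-peptide correlation of sites sharing one intensity.
Degenerate inputs behave predictably: a single record yields a
zero-width interval; a set of identical records likewise. A record set
without the residue raises an undefined-estimate error — deliberately
distinct from an estimate of 0%, which is evidence of absence of the
modification rather than absence of evidence.

With n = 500 records per group and realistic intensity dispersion
(log-normal, σ_ln = 1.0), the standard error of a pooled N+Q deamidation
estimate near 50% is ≈ 2.5–3.5 percentage points: the effective site
count is roughly n · exp(−σ²) · (sites per record). Consumers should not
expect sub-point accuracy at that scale; the group *contrast* (ancient
≫ modern) is far better resolved than the absolute level, and the 95%
CIs of the two groups separate essentially always under the default
simulation conditions.

## Evidence dialect and filters

The evidence reader consumes a TSV subset of a MaxQuant-style
`evidence.txt` (Sequence, Modified sequence, Modifications, Charge, m/z,
Intensity, Score, Proteins, Raw file); the column map is a config object
so schema drift between engine versions is absorbed without code
changes. Modification sites are parsed from the modified-sequence
string; engine spellings ("Deamidation (NQ)", "Oxidation (M)") are
normalised to canonical names, and unmapped names pass through verbatim,
ignored by the statistics with a logged warning. When only a summary
Modifications column is available, sites are placed on the leftmost
eligible residues; per-record counts — all the estimator consumes — are
unaffected by that localisation choice. Standard filters: score ≥ 40
(metaproteomic) or ≥ 50 (collagen searches), intensity present and
positive ("over the engine threshold" is operationalised this way since
engines do not publish the internal cutoff), and at most 3 missed
tryptic cleavages. Coordinates are 1-based inclusive throughout;
position 0 denotes the peptide N-terminus.

## Mass arithmetic

Monoisotopic residue masses come from the standard table (via
pyteomics); water 18.010565 Da, proton 1.007276 Da. Modification deltas
ship as a versioned TSV resource (oxidation +15.99491, deamidation
+0.98402, pyro-Glu from Q −17.02655, from E −18.01056, acetyl-K
+42.01057, Trp→kynurenine +3.99491, iodination +125.89664, etc.).
Trp→oxolactone and Tyr→dopaquinone are assigned +13.97926 Da (O − 2H) as
a convention, since no numeric value is standard. Hydroxyproline is
represented as oxidation targeted at P, not as a 21st letter. Published
collagen peptide masses often encode hydroxyproline counts only
typographically; `infer_modification_counts` recovers the smallest
(oxidation, deamidation) multiset reproducing a printed mass within
tolerance (default 0.01 Da). Agreement tolerances: 0.01 Da for
sequence-level checks, 0.005 Da for m/z conversion — printed literature
values differ from exact recomputation by up to ~3 mDa.

## LCA profiling

The taxonomy is a rooted tree in a minimal NCBI-dump-like TSV dialect
(taxon_id, parent_id, rank, name); ranks may be missing — the algorithm
only uses topology. The LCA of a taxon set is the deepest node on the
intersection of all root paths; depth ties cannot occur in a tree.
Peptides are I/L-normalised before lookup. Peptides matching two or more
of the configured disjoint reference groups (subtree roots, e.g.
Proboscidea / Viridiplantae / Bacteria+Nematoda) are excluded as invalid
identifications, mirroring the practice of discarding peptides shared
between separately searched databases. Clade summaries count peptides
assigned to a node or any descendant; each node's percentage is relative
to its parent's subtree count (root = 100%), the convention used by
tree-view metaproteomics displays.

## Marker classification

BLASTp species surveys are replaced by exact I/L-normalised lookup in a
reference panel (peptide → species labels): offline, deterministic, and
synthesisable. A protein needs ≥2 peptides to count as identified.
Classification order: contaminant-list accession → not_identified (<2
peptides) → endogenous_specific (≥1 marker peptide whose species set is
contained in the configured target clade) → shared_including_human →
shared_non_human. The conservative keratin rule formalises the
qualitative "similar modification profile" judgment: a
shared-with-human protein is reclassified contaminant when its own
peptide deamidation point estimate lies inside the contaminant group's
CI and outside the original group's CI; with no N/Q evidence the call is
left unchanged and flagged indeterminate. The CI-overlap criterion is
one admissible formalisation; both CIs are explicit inputs so callers
can substitute their own bands.

## Collagen mapping

Digestion cleaves after K/R, by default not before P (flag for the
cleave-anyway dialect), products up to 3 missed cleavages, coordinates
1-based. Peptide placement uses a semi-global dynamic program: the
peptide aligns end-to-end against a local reference window, match +1,
mismatch −1, gap −2, default edit budget 2. The scoring is deliberately
small-edit: it reproduces homology-search placements for near-identical
sequences without attempting general cross-species alignment. Ties are
broken by fewest indels, then leftmost placement; traceback prefers
diagonal moves, so a deletion adjacent to a substitution is reported as
(deletion, then substitution) in reference order; residual ties set an
`ambiguous` flag. Edits are reported in mature-chain coordinates via the
reference's numbering offset. Coverage counts reference positions with
an aligned observed residue: substituted positions covered, deleted
positions not, insertions contribute nothing — whether substituted or
deleted positions should count as "characterised" is genuinely open;
this choice is fixed here and documented. Where an observed D aligns to
a reference N, the D may be a deamidated N; the alignment reports the
substitution and downstream interpretation should carry that caveat.
Triplet validation checks glycine at every third position from a frame
(explicit, or chosen to minimise violations); a substitution or indel
whose acceptance would break the Gly-Xaa-Yaa repeat is more plausibly a
database-entry error than a real collagen variant.

The bundled reference chains in `synthetic_references.py` are synthetic:
correct published lengths (1058 / 1040 mature residues) with the
published trait windows placed at their literature coordinates and
neutral Gly-Pro-Ala filler elsewhere. Alignments against them reproduce
published edit coordinates, but chain-wide quantities (e.g. coverage
percentages over full fragment inventories) are not meaningful against
filler and are only computed for the observed trait peptides.

## Synthetic data generator

The generator emulates the statistical structure of an ancient-sample
evidence table; defaults are the study conditions used throughout the
tests:

* two peptide populations, n = 500 each: "original" peptides drawn from
  a collagen-like chain (340 Gly-Xaa-Yaa triplets, Xaa/Yaa
  proline-enriched at 30%, K/R supplying tryptic sites) plus two
  globular references at typical vertebrate amino-acid frequencies;
  "contaminant" peptides from keratin-like globular references whose
  accessions populate the contaminant list;
* tryptic peptides, length 7–30, up to 3 missed cleavages;
* per-site independent Bernoulli deamidation: ancient probability drawn
  once per sample from the uniform band 0.35–0.63 (the range reported
  for genuinely ancient material), modern fixed at 0.05; no
  sequence-context effects are modelled;
* elevated ancient oxidation (P 0.30, M 0.25, W 0.10, Y/C 0.05) vs. low
  modern rates;
* log-normal MS1 intensities, μ_ln = 16, σ_ln = 1.0 (≈ 1.7 orders of
  magnitude 95% range, typical of MS1 feature intensities), independent
  of modification state by default (a coupling knob exists for
  robustness experiments);
* scores from a two-component normal mixture (true matches N(80, 15),
  10% noise at N(30, 8)) so the score ≥ 40 filter genuinely removes
  rows;
* m/z computed from the true modified peptide mass at charge 2–4.

Identical config + seed gives byte-identical output, and generated
tables round-trip through the evidence reader with zero dropped rows.
What passing tests on these data do **not** show: real spectra have
correlated modification sites, retention-time and length-dependent
intensity structure, sequence-context deamidation kinetics (e.g. NG
motifs deamidate faster), and search-engine score/intensity biases —
none of which the generator models. Parameter-recovery results here
certify the estimator, not the chemistry.

## Known limitations

* The deamidation-contrast experiment (estimates inside the 35–63% band
  in ≥95 of 100 runs) is variance-limited at n = 500/group: with the
  defaults above the point estimate's SE is ~3 points, so draws near a
  band edge leave the band in roughly 8–10% of runs and the realised
  success rate is ~85–93/100. The CI-separation half of the contrast
  holds in 100/100 runs. Tightening would require larger n, more N/Q
  sites per peptide, or lower intensity dispersion than we consider
  realistic.
* Percentile bootstrap CIs slightly under-cover the nominal 95% at
  these sizes (observed ~91–96% coverage).
* The aligner's edit budget (2) suits near-reference mapping; distant
  homologs need a real cross-species search tool.
* Protein inference is accession-attribution only; no razor-peptide
  grouping is performed.
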