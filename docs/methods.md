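# Methods

`glyconet` implements a desk-scale, fully seeded version of the multi-omic
annotation workflow used to characterize glycosylated natural products in
sponge holobionts: tandem-MS molecular networking, declarative substructure
motifs, glycosidic neutral-loss annotation, feature-based molecular
networking (FBMN), congener quantification, microbiome diversity summaries,
and co-occurrence mining of metagenome bins. This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
data do and do not establish.

## Mass arithmetic

All masses are monoisotopic, computed from NIST atomic masses hard-coded to
at least six decimals. Ion m/z subtracts one electron mass per positive
charge; all adducts are [M+H]+ (the workflow operates in positive mode
only). Glycan residues are the dehydrated forms (hexose C6H10O5 162.0528,
pentose C5H8O4 132.0423, HexNAc C8H13NO5 203.0794, deoxyhexose C6H10O4
146.0579); a B-type oxocarbenium ion is the residue-chain sum plus a proton.

The modification-delta table holds the tailing reactions used for network
traversal: +O hydroxylation (+15.9949), +CH2 methylation (+14.0157), −H2
dehydrogenation, +H2 reduction, +CO methoxylation-with-dehydrogenation
(+27.9949), and +Br−H bromination (+77.9105). `classify_delta` matches the
magnitude of an observed precursor difference against the table and records
the direction; exact magnitude ties (dehydrogenation vs reduction) are
resolved by sign agreement, then table order. Both tables round-trip through
CSV so users can extend them.

Printed fragment values in the source literature follow two-decimal
*truncation* (421.3465 appears as 421.34), so the display helper defaults to
truncation; rounding is available. Whether the literature values are
theoretical or observed is not stated; the engine treats them as theory
targets at that display precision.

## Spectral networking

MS2 peaks below an intensity floor (default 500) are removed first. Scans
are grouped into consensus spectra by single-linkage chaining on precursor
m/z within 0.01 Da, processed in ascending precursor order; merged peak
lists are the tolerance-binned (0.05 Da) intensity-weighted union. The exact
iterative consensus procedure of MS-Cluster is not published in usable
detail; single-linkage-within-tolerance is the documented substitute.

Similarity is the modified cosine: peaks match directly (|Δm/z| ≤ 0.05 Da)
or shifted by the precursor delta, intensities are square-root scaled and
L2-normalized, and the one-to-one peak assignment maximizing the cosine is
found by maximum-weight bipartite matching (`scipy.optimize.
linear_sum_assignment`). A brute-force enumeration oracle in the test suite
confirms optimality on small spectra; a reference implementation (matchms)
is used as an independent cross-check on unambiguous cases. Edges require
cosine strictly above 0.7 and at least 5 matched peaks (classical) or 6
(FBMN) — the verbal thresholds "above 0.7", "more than 4" and "minimum of 6"
are interpreted strictly. Mutual-top-K pruning (K = 10) is applied once over
the candidate edge set; ranking ties break by the partner's lower precursor
m/z, making the network invariant to node input order, and the pruning is
idempotent.

## Feature pipeline

The package consumes centroided per-sample feature rows; chromatogram
building and deconvolution from raw profile signal are upstream and out of
scope (the generator emits their output contract directly; the associated
raw-signal constants "minimum time span 0.1 min" and "minimum intensity
1500" therefore do not appear as parameters). Stages and defaults:

* MS1 noise filter: minimum area 10,000.
* Deisotoping: rows at M + k·1.00336/z (k = 1, 2; z ≤ 3) within 15 ppm /
  0.1 min of a more intense row are absorbed; the representative is the most
  intense isotopologue.
* Alignment: 15 ppm / 0.1 min, seeds in descending intensity order so the
  result is independent of sample order; merged m/z and RT are
  intensity-weighted means.
* Duplicate removal: 5 ppm / 0.1 min.
* Gap filling: 15 ppm / 0.1 min from raw rows; never overwrites nonzero
  areas.
* MS2 pairing: 0.025 Da / 0.2 min, nearest m/z wins, RT breaks ties.
* FBMN: one node per MS2-bearing feature, representative spectrum = merged
  attached scans. Co-eluting isomers at one m/z remain distinct nodes.

An optional m/z range filter (e.g. 1280–1350) reproduces the saponin-window
demonstration but is not a default.

## Motifs and annotation

Motifs are declarative fragment/neutral-loss sets with a tolerance — the
analytic counterpart of MS2LDA motifs. Latent-topic *discovery* is out of
scope because downstream use is presence testing and propagation. Shipped
definitions are computed from glycan arithmetic: `motif_505` = HexNAc
oxocarbenium 204.0866 (conserved A-B2 pattern), `motif_668` = 498.1817
(B1-C-D chain with C = pentose; type-2 family), `motif_451` = {366.1395,
660.2346} (B1-C and A-B1-C-D with C = hexose; type-1 family). The melophlin
motifs `motif_437`/`motif_444`/`motif_660` have no published fragment
values; the shipped m/z values are model choices derived from tetramate
heterocycle ion formulas (C4H6NO2+, C5H8NO2+) and are flagged
`literature=False` in the exported CSV. A motif requires all of its ions by
default (`min_fraction = 1.0`), chosen for precision since no presence
threshold is published.

Glycosylation level is the longest chain of successive residue-mass neutral
losses walkable from the precursor through observed peaks (depth-first
search over the residue table, 0.01 Da tolerance). It counts residues, not
identities — a pentose-for-hexose swap changes the family label, not the
level. Pattern labels propagate from motifs to any node carrying them,
including singletons; nodes carrying both family motifs (451 and 668) are
flagged as conflicting rather than resolved, since the families are treated
as disjoint. Delta-edge annotation labels edges whose |precursor delta|
matches the modification table within 0.01 Da; |delta| ≤ tolerance is an
"isomer" edge. The alkyl-chain diagnostic looks for ≥ 4 peaks in 100–300
m/z forming an arithmetic chain at 14.0157 Da with 0.02 Da per-step
tolerance. Dereplication takes the nearest library [M+H]+ within 0.01 Da,
optionally requiring the library entry's expected motifs; equidistant
candidates are reported as ambiguous.

## Quantification and comparison

Congener heatmaps: areas are normalized within each natural-product family
to the family maximum, then −log10-transformed; absent congeners get a fixed
sentinel of 6, and values cap there. Base 10 is used because the sentinel 6
and a detected-congener floor near 4.4 are consistent with the log10 dynamic
range of LC/MS areas; normalizing to the family maximum makes the most
abundant congener map to 0. Feature overlap partitions features by the set
of sample groups in which they have nonzero area, with one-decimal
percentages. The volcano applies inter-quartile-range filtering (the bottom
quartile of per-feature IQR is dropped; the published description names the
filter but not its cutoff), per-feature pareto scaling (mean-center, divide
by √SD), and a two-sided Welch t-test; fold changes use unscaled group
means; classes are `up` (FC ≥ 3, p ≤ 0.05), `down` (FC ≤ 1/3), else `ns`.
p-values are uncorrected by default, switchable by the caller applying any
correction to the returned table. Shannon diversity is in bits (−Σ p log2 p),
the common amplicon convention. Phylum heatmaps aggregate ASV counts to
phylum, divide by the sample sum and apply −log10; zero-count phyla get a
sentinel of max-finite + 1.

## Metagenome mining

Inputs are pre-computed bin tables (scaffold GC/coverage/length; genes with
domain-pattern hits); HMM searching is upstream. The default category map
uses PF00494 (squalene synthase), PF08491 (squalene epoxidase),
PF13243/PF13249 (squalene cyclase) and PF00535 (glycosyltransferase);
sterol reductase/demethylase and the CAZy-style HexNAc and hexose/pentose
transferase categories have no canonical single pattern id and ship as
configurable placeholders. The screen passes a bin when it has ≥ 2 distinct
sterol categories with hits AND at least one hit in each required
glycosyltransferase category — "present together" is interpreted at the
bin (taxon) level, with physical clustering reported separately: the locus
report chains qualifying genes ≤ 20 kb apart on one scaffold into loci
(runs of ≥ 2), listing lone genes as dispersed. Coordinates are 1-based
inclusive (GFF convention). Relaxing the criterion can only grow the
candidate set, and category totals are invariant to how scaffolds are
partitioned into bins.

## Synthetic data: what it emulates, and what it does not

The generator is first-class, tested code and defines the study conditions.
Congener libraries cycle three families. Sarasinoside-like families carry a
type-1 pentasaccharide (pentose, HexNAc, HexNAc, hexose, hexose; outermost
last) truncated to levels 4..2, a type-2 variant (C ring = pentose) with a
net +CO tailing difference, hydroxylation/dehydrogenation/methylation
variants, and a planted 4-member isomer group (identical composition, 0.3
min RT spacing). Melophlin-like congeners have no glycans, a C5-methylation
dichotomy and a brominated member. The reference polyacetylene-like family
uses the C30H46O2 aglycone, whose mono- and diglycosides fall at m/z 601.41
and 763.46 and whose aglycone ions are 439.36/421.35.

Simulated spectra contain the Y-ion ladder, B ions for contiguous glycan
subchains, the A-B1-C-D branch ion for full-length doubly-HexNAc chains,
two aglycone ions (protonated aglycone and its water loss),
family-diagnostic ions (tetramate heterocycle ions; an 8-rung CH2 ladder),
Poisson-count uniform noise below 10% of the base peak, and log-normal
intensity jitter in tiers Y > B > aglycone > ladder. True fragment intensity
distributions for these compound classes are unpublished; the tiers are
model choices recorded in the run manifest. The m/z error is 2 ppm (1 sd) —
calibrated high-resolution TOF accuracy, and the level consistent with the
0.01 Da precursor tolerances the downstream workflow presumes at m/z ~1300.
RT jitter is 0.02 min (1 sd).

Feature tables emit 3-isotopologue envelopes (spacing 1.00336/z, relative
intensities 1/0.35/0.08) and one linked MS2 scan per detectable congener.
ASV tables draw multinomial counts from Dirichlet-perturbed archetype
weights: the HMA-like archetype spreads weight over eight phyla
(Chloroflexi, Proteobacteria, Acidobacteria, Actinobacteria dominant), the
LMA-like archetype concentrates 0.75 on Thaumarchaeota. Metagenomes place
per-bin GC/coverage centroids with small within-bin spread and plant exactly
one positive bin carrying a sterol locus and a glycosyltransferase locus on
*different* scaffolds; decoys are GT-rich (≤ 1 sterol category), sterol-
partial (missing the HexNAc GT category), or unannotated.

Not modeled: raw profile-mode signal, chimeric/contaminant spectra, RT
drift requiring warping, adducts beyond [M+H]+, real taxonomic sequence
content. Passing tests therefore demonstrate the correctness and internal
consistency of the algorithms under a faithful fragmentation/abundance
model — not performance on real instrument data, where isolation
interference, co-fragmentation and calibration drift add failure modes the
generator does not produce.

## Problem sizes and determinism

The default end-to-end run uses 3 congener families (22 congeners), 4
samples in 2 groups, 10 metagenome bins and 20,000-read ASV tables, and
completes in a few seconds on one CPU; statistical properties are checked
at 200 congeners / 200 features / 10–20 seeds. All randomness flows from
`numpy.random.default_rng` seeded from the run seed (per-stage sub-seeds
derived by hashing), and identical configurations reproduce output tables
byte-for-byte.

## Known limitations

* Consensus clustering is single-linkage: a dense precursor ladder can
  chain across more than the pairwise tolerance.
* The glycosylation walk can, in noisy spectra, route through a noise peak;
  at the default noise model this affects < 5% of congeners.
* Deisotoping keeps only the representative isotopologue's area (matching
  the upstream tool's behavior) rather than summing the envelope.
* The volcano's IQR cutoff (bottom quartile) and the mining criterion's
  "≥ 2 sterol categories" quantification are reasonable readings of verbal
  descriptions; both are configurable.
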