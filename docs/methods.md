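# Methods

## The block-fingerprint model

The package treats an NMN deamidase sequence as a linear arrangement of
short conserved blocks separated by unconstrained linkers. Each block is a
degenerate consensus pattern over the 20-letter amino-acid alphabet with
four position types: strictly conserved (written `G!`; a mismatch vetoes a
hit), majority (`G`; counts toward the score without vetoing), alternative
sets (`[TD]`), physicochemical classes (`c` charged {D,E,K,R,H}, `h`
hydrophobic {A,V,L,I,M,F,W,C,Y}, `p` small polar {S,T,N,Q,G}; the class
memberships are a package choice, fixed once in `pncc.motif.RESIDUE_CLASSES`)
and wildcards (`x`). A match's score is the fraction of non-wildcard
positions satisfied; the default acceptance threshold of 0.7 admits one
mismatch in short blocks while rejecting most chance hits, and is exposed
everywhere as a parameter. An `X` in the input counts as a mismatch at any
non-wildcard position — conservative, because functionality calls hinge on
individual residues.

The catalog (`src/pncc/data/block_catalog.tsv`) holds the canonical blocks
M-I..M-VII (MocF domain), i-I/i-II (interdomain) and P-I..P-IX (CinA
domain), the per-lineage variant forms of the degraded blocks, and the key
active-site residues as pattern-relative offsets. Offsets rather than
absolute positions are stored because residue numbering drifts between
homologs; the 2A9S, 3KBQ and O. iheyensis numbering systems are derived
views (`CINA_KEY_RESIDUES_2A9S` etc.). Two typographic uncertainties in the
source material are resolved in the catalog and noted in the entries: the
leading glycine of M-I is treated as majority rather than strict, and the
inactive-lineage P-II forms carry their strict markers (`D!T!P!`,
`A![DP][EQ]`).

## Block placement and architecture

A sequence is scanned against every catalog entry; a canonical block counts
as present when its canonical pattern or any lineage variant matches. Since
several blocks are short and degenerate (`PxL`, `G![AS]S`, `Rxx[VI]R`),
isolated hits are unreliable; all decisions therefore run over an
*ordered chain*: the dynamic program selects at most one placement per
canonical block such that placements are non-overlapping and follow
canonical order, maximizing first the number of blocks placed and then the
total match score. Exact ties are broken toward canonical entries over
variants, more informative (more specific) patterns over weaker ones, and
leftmost positions — in that order. This resolves almost all ambiguity from
chance hits; the irreducible remainder is quantified below.

Architecture is then called from chain presence: MocF present iff ≥ 4 of
its 7 blocks chain (threshold `min_mocf_blocks`), CinA present iff ≥ 5 of 9
(`min_cina_blocks`). Both domains, MocF upstream → `MOCF_CINA` (chance
MocF-pattern hits inside the CinA region are tolerated by re-counting only
upstream placements). CinA alone is subdivided by the length of the
N-terminal extension before the first CinA block: ≤ 30 residues →
`CINA_ONLY`, 31–80 → `CINA_NEXT_SHORT`, > 80 → `CINA_NEXT_LONG`; a gap of
≥ 40 residues between chained blocks within two canonical ranks of each
other → `SPLIT_CINA` (the rank condition keeps multi-block loss from
masquerading as a split). The numeric cutoffs operationalize the family's
qualitative length classes (~160–170 aa single-domain, ~220 aa extended,
~420 aa two-domain) and are all configurable in `ClassifierConfig`; the
family literature states no numeric detection criteria, so these are this
package's choices, calibrated once against the generator's length classes.

## Functionality and signatures

Functionality is a ten-residue checklist over six CinA blocks (P-I S31;
P-II G46, S48; P-III Y58, N60, K63; P-VI S/T105, G106; P-VII G120; P-VIII
R145). Each block is located preferentially by its chain placement;
otherwise it is searched between its neighbouring placed blocks (falling
back to next-nearest neighbours if the narrow window is empty, since an
immediate neighbour may itself be a chance hit), first with strictness
enforced, then relaxed. `active` requires all ten checks to pass; any fired
inactivating signature gives `inactive`; anything else — including an
unresolved `X` at a key position — is `indeterminate`. A record can never
be active with a fired signature (asserted at construction).

Three documented inactivating signatures are implemented: *YdeJ-like*
(Y58F + N60D in P-III, with P-II replaced by the DTP form), *YfaY-like*
(blocks P-III, P-V, P-VII deleted; P-I/P-II present only as degraded
variants) and *fungal-split* (alanine at the S31-homologous position of
P-I). Absence tests are anchored on a chain over the six block families
that survive in every lineage, and each potentially deleted block is sought
only in the interval between its anchors — otherwise a chance 3-mer
elsewhere in a 400-residue sequence would mask a real deletion.

## Lineage assignment

The decision table: `MOCF_ONLY` → 1.3; `MOCF_CINA` + inactive → 2.2.1.2;
`CINA_ONLY` + inactive → 2.2.2.2; short/long extension → 2.2.3.2 / 2.2.3.3;
`SPLIT_CINA` → 2.2.3.4. The remaining active sets — {1.1, 1.2, 2.1,
2.2.1.1, 2.2.2.3} for two-domain and {2.2.2.1, 2.2.3.1} for single-domain —
are scored by lineage-variant fingerprints, but these lineages are
distinguished phylogenetically rather than by block sequence, so the
scores tie in practice. Ties fall to an optional taxonomy hint (an external
annotation, never inferred from sequence: e.g. firmicutes → 1.2,
mycobacterium → 2.2.2.3), then to the nearest supplied exemplar sequence by
global-alignment identity, then to `unassigned` with zero confidence.
Confidence is the margin between the top two fingerprint scores (1.0 for
architecture-determined branches). This is an honest limitation, not a
defect: without a tree or taxonomy, the two-domain active lineages are not
separable from blocks alone.

## Conservation and block detection

Column information is R = log₂20 − H with H the Shannon entropy of the
observed residue frequencies, gaps excluded from the denominator; columns
more than half gaps score 0, and the optional small-sample correction
(s−1)/(2·ln2·n), s = 20, is off by default so worked examples are exact.
Blocks are maximal runs of columns with R ≥ 2.0 bits tolerating at most one
interior sub-threshold column, minimum three columns (defaults
`min_bits=2.0`, `max_low_cols=1`, `min_len=3`; chosen so that on the
generator's alignments — ~20 rows, 5% substitution noise, conserved
columns near 3.9–4.3 bits against ~0.5–0.9 bits in linkers — detection
reproduces the 7-block MocF and 9-block CinA structure with boundaries
exactly at the generated block coordinates). Consensus rendering uses
strict ≥ 0.95, majority ≥ 0.6 per column; detected blocks are labelled by
best positional agreement with catalog patterns (allowed-set intersection,
sliding to absorb boundary shifts), ties resolved to keep canonical order
increasing.

## Phylogeny

Pairwise alignment is an affine-gap Gotoh dynamic program, global and
local, defaulting to BLOSUM62 with gap open 11 / extend 1 (a gap of length
k costs 11 + k, the BLAST convention, chosen because the family's reported
identities come from BLAST) and deterministic traceback (diagonal, then up,
then left at ties). Distances from an MSA are p-distances (default;
mismatches over columns ungapped in both rows) or Poisson-corrected
−ln(1−p). Neighbor joining is the Saitou–Nei Q-criterion agglomeration
with lowest-index tie-breaking and negative branch lengths clamped to zero
(flagged); on additive matrices the tree reproduces the input path lengths
exactly, which the tests verify against brute-force-generated random trees
and against scikit-bio's independent implementation. Bootstrap resamples
alignment columns with replacement; supports are the percentage of
replicates containing each internal bipartition of the point tree, with
taxa canonicalized by name so results do not depend on input order.

## Kinetics

Initial-rate framework only (the assays report initial velocities):
v = kcat·E0·S/(Km+S) and v = Vmax·Sⁿ/(S0.5ⁿ+Sⁿ). Units: Km in mM (MM) or
S0.5 in µM (Hill), kcat s⁻¹, E0 µM. Fits are scipy nonlinear least squares
initialized from the double-reciprocal (MM) or Hill-plot (Hill)
linearizations; asymptotic standard errors come from the covariance of the
fit. The coupled glutamate-dehydrogenase assay converts A360 slopes via
ε = 4320 M⁻¹cm⁻¹ (one unit = 1 µmol NADPH/min); kcat from a mass loading
uses the 47.32 kDa subunit mass. Ligand efficiency is LE1 = docking score /
heavy-atom count, reported to three decimals with round-half-even; heavy
atoms come from shipped molecular formulas (NMN C11H15N2O8P → 22;
ADP-ribose C15H23N5O14P2 → 36). For ADP-ribose the exact division is
−3.27564, which this package rounds to −3.276; the originally printed
−3.275 appears to be a truncation, and the package does not reproduce it.

## The synthetic-data generator

`pncc.synth` emulates the family's statistical structure: per lineage, a
sequence is a sampled leader, block realizations joined by uniform-random
linkers, and a tail. Block templates are realized once per panel (so
wildcard and class positions are conserved within a panel, as they are
within a clade of close homologs) and diverge by per-sequence substitution
noise at a default rate of 5% — a realistic within-lineage divergence for
conserved enzyme families. Strict positions, key active-site residues and
signature-defining residues are never mutated, modelling purifying
selection on catalytic function; without this, functionality calls would
degrade at positions the biology holds fixed. Inactive lineages realize
their documented variants (2.2.2.2: DTP, F·D-mutated P-III, variant
P-IV/P-VI, P-VIII lost; 2.2.1.2: P-III/P-V/P-VII deleted, degraded
P-I/P-II/P-IV/P-VI; 2.2.3.4: fungal variants plus a 52–68-residue spacer
inside the CinA series). Linker length ranges are tuned so the four length
classes centre on ~165/~220/~420/~170 residues with every draw inside ±15%
of its class target. Indels default off so truth alignments are exact by
construction; an indel mode perturbs linker lengths only. Each record
carries a truth row (lineage, architecture, functionality, taxonomy hint,
block coordinates), and single-lineage panels yield exact known-truth
alignments by padding each construction segment to its panel maximum.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: tree-structured sequence evolution (no substitution
model down a phylogeny; clades arise only from independent template
realizations), realistic linker composition (uniform over 20 residues),
insertions/deletions inside blocks, and annotation noise. One measured
consequence of uniform-random linkers: a canonical block motif occasionally
re-forms by chance inside a deletion gap of an inactive-lineage sequence
(~0.3–0.4% of draws), making that sequence genuinely look partially intact;
the classifier then reports `indeterminate`, which is the honest call for
such a sequence. Across a 40-seed sweep of 13-lineage panels this produced
one zero-noise disagreement in 2600 draws; at 5% noise, lineage and
functionality recovery stayed ≥ 96.9% on every seed.

## Problem sizes

The shipped analyses use panels of 10–20 sequences per lineage (130 for the
13-lineage confusion matrix), alignments of ~150–160 columns, 200 bootstrap
replicates on 10 taxa, and 8-concentration × 3-replicate kinetic datasets
with a 100-replicate bias study — sizes chosen so every analysis and the
full test suite run in well under a minute while leaving the statistical
conclusions (block counts, recovery rates, support values, parameter
recovery within printed uncertainties) stable across seeds.

## Known limitations

Lineages 2.1 vs 2.2.1.1 (and the other fingerprint-degenerate active sets)
require taxonomy hints or exemplars; profile-HMM sensitivity is out of
scope (the motif scanner is not a PSSM and will not find remote homologs);
gapped motif matching is unsupported; the NJ/bootstrap machinery is exact
but quadratic-to-cubic and intended for the study's desk-scale trees, not
thousands of taxa.
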