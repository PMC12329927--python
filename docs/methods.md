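# Methods

This note documents the models, parameter choices, and numerical decisions
behind `mockeval`, and what the synthetic benchmark does and does not say
about real data.

## Study design being emulated

The package reproduces, on synthetic data, the design of a mock-community
evaluation of ITS metabarcoding: 37 defined mock communities (DMCs) of
five species each, drawn from a pool of ≥51 species in 35 genera, with
genomic DNA pooled in equal quantities so every member has a theoretical
read fraction of 20%.  All communities draw their five members from five
distinct genera except four (communities 1, 18, 19 and 34), which contain
a within-genus pair; the last two communities are technical replicates
with identical composition.  Classification quality is scored per
DATABASE–SOFTWARE–SETTING combination, at species and genus level, per
marker (ITS1, ITS2) and for a two-marker consensus.

## Synthetic data generator

**Taxonomy and markers.** Species are synthetic binomials
(`Genus07 species2`); the genus is the first whitespace token, and a
deterministic nesting of genus indices supplies the higher ranks.  Each
genus receives an independent random ancestral marker per region with
length ~ N(280, 40) clipped to [180, 380] bp — inside the empirical ITS1/
ITS2 length range, with the upper clip chosen so that two quality-trimmed
250-bp reads still overlap (trimming removes roughly the last tenth of a
read under the default quality profile).  Species sequences mutate away
from the genus ancestor at an intra-genus rate of 0.08 substitutions per
site, which puts congeners at ~0.15 pairwise distance: well above the 0.03
OTU cutoff (so default species are separable) yet far below the ~0.4
distance between genera.

**Confusable groups.** A confusable group forces congeners within a
pairwise distance `d_conf`: members are mutated from a common group leader
by at most ⌊L·d_conf/2⌋ sites, which bounds every within-group distance by
`d_conf` without alignment heuristics.  `d_conf = 0` plants *identical*
markers across the group, modelling congeners indistinguishable in the
sequenced region — the mechanism behind tied equal-identity top hits and
depressed naive-Bayes bootstrap values.

**Databases.** A reference database draws a seeded subsample of species
(`completeness`), truncates a seeded fraction of entries at genus with the
`"Genus sp"` placeholder (`unannotated_fraction`), and can store entries
under an alternate binomial while recording the pair in a symmetric
synonym map.  This reproduces the three database pathologies that matter
for scoring: missing species, entries unannotated at the requested rank,
and nomenclature mismatches.

**Reads.** Amplicon = 25-base 5′ anchor + marker + 25-base 3′ anchor; the
fixed anchors stand in for the conserved rRNA/primer regions and make
marker extraction an exact, testable flank-trimming step (HMM-based
boundary detection is out of scope).  Forward and reverse reads are the
two amplicon ends (reverse strand for R2) at 250 bp.  Per-species read
counts are multinomial on theoretical abundance, optionally skewed by
per-species marker copy-number weights drawn log-uniform in [0.5, 2] —
a modest default for a bias whose real magnitude is unknown.  Base
qualities decay linearly from Q38 to Q18 along the read; substitution
probability per base is proportional to 10^(−Q/10), rescaled so its mean
equals the configured substitution rate (default 0.002).  Errors are
substitutions only — there is no indel or PCR-stutter model, a documented
limitation that in turn justifies ungapped pair merging.  A configured
fraction of reads (default 1%) are chimeras: a prefix of one member's
amplicon joined to the suffix of another at a uniform interior breakpoint.
Every read carries its true species and chimera status in a sidecar truth
table.

The paper-style design fixes community layout and abundances but not
sequencing depth; the default of 1,000 read pairs per community/marker was
chosen once as a desk-scale depth at which multinomial noise is a few
percent per member, and is configurable.

**Reproducibility.** Every generator is a pure function of (parameters,
seed); each operation derives its own RNG stream from
(seed, operation name, entity id), so regenerating one community or one
species is independent of generation order.

## Pipeline

**Trimming** follows LEADING(10) → TRAILING(10) → SLIDINGWINDOW(4, 20) →
MINLEN(10), the published tool's documented order; the read is cut at the
start of the first 4-base window whose mean quality falls below 20.

**Merging** scans every ungapped dovetail offset of the
reverse-complemented mate along the forward read and keeps the overlap
(≥10 bases) maximizing matches − mismatches.  An accepted overlap must
score at least half its length (≥75% identity); this threshold, our own
choice, is what distinguishes a real overlap from the best chance overlap
of unrelated reads.  Overlap mismatches resolve to the higher-quality
base; quality ties become `N`.

**Marker extraction** trims the flank anchors, each allowing ≤2
mismatches.  A 5′ anchor eroded from its start is still accepted down to
15 of its 25 bases, emulating residual conserved bases surviving boundary
detection; the threshold is configurable.

**Screening** removes sequences with >10 non-ACGT symbols or a single-base
run >10 (both inclusive-keep at exactly 10).

**Pre-clustering** processes dereplicated sequences by decreasing weight
(ties: lexicographically smaller sequence first); each sequence merges
into the first retained sequence within 2 mismatches (Hamming, or best
ungapped overlay with the length difference counted).

**Chimera detection** visits queries in ascending weight and tests all
ordered pairs of parents with ≥2× the query's weight.  A query is flagged
when some prefix+suffix model at one crossover explains it with ≥4 fewer
mismatches than the best single parent and each side shows ≥80% identity
to its parent segment.  The 2×/≥4/80% thresholds are deliberate
simplifications of the de novo tool's scoring and are configurable.

**Distances.** Distance = 1 − identity from a global alignment with
terminal gaps excluded; identity counts matches over aligned columns with
each maximal run of internal gap columns as a single difference.  The
aligner is an affine Needleman–Wunsch (match +1, mismatch −1, gap open −2,
extend −1, stored as ×10 integers) in which terminal gap columns carry a
token cost of 0.1 match per column.  Strictly free terminal gaps would let
two unrelated sequences collapse onto a few-base chance dovetail (identity
1.0, distance 0); the token cost anchors the optimum to a spanning core
while terminal gaps remain excluded from identity, so distances between
related sequences are unchanged.  Among co-optimal alignments the counted
identity can differ by a few percent between implementations; the test
suite therefore compares against its independent pure-Python DP oracle
exactly on near-identical pairs and within 0.05 on unrelated pairs (scores
are compared exactly everywhere).

**Clustering** at cutoff 0.03 is an MCC-optimizing scheme: starting from
singletons, sequences are swept in deterministic order (weight descending,
then id) and moved to whichever neighbouring cluster (or a fresh
singleton) maximizes the Matthews correlation between "pairs co-clustered"
and "pairs within the cutoff", until a sweep makes no change (cap: 100
sweeps).  A greedy abundance-sorted complete-linkage baseline exists for
comparison; on seeded sets the optimizer's MCC is never lower.

**Rare-OTU filtering** removes singleton OTUs and OTUs at ≤0.05% of reads.
The threshold comparison is inclusive (≤), matching the sweep semantics;
the boundary case (an OTU at exactly 0.05%) is removed.  Sanger-style
in-silico mixes (all weights 1) skip this filter entirely.  Sweeps re-apply
the filter at thresholds 0–1% in 0.05% steps (21 grid points) and
re-adjudicate the survivors; classification results are computed per OTU
and are independent of which other OTUs survive, so re-adjudication is a
restriction.

## Classifiers

**Top-hit search** aligns the query to every reference (match +2, mismatch
−3, gap open −5, extend −2, free-ish end gaps as above), discards hits
with <80% query coverage or <95% per-column identity, and keeps the
equivalence group of hits tied with the best on (identity, score).  No
E-value is computed: with a fixed scoring scheme, "equal E-value and equal
identity" reduces to exact ties on (score, identity).

**Naive Bayes (Wang)** builds per-species 8-mer presence models with the
standard smoothing (word prior (n_i + 0.5)/(N + 1); species likelihood
(m_i + prior)/(M + 1)).  The full-data posterior picks the species; 100
bootstrap rounds each rescore a random eighth of the query's k-mers, and
per-rank confidence is the fraction of rounds agreeing with the full-data
lineage at that rank (aggregated upward, so confidence is monotone toward
the root).  The lineage is truncated below the deepest rank reaching the
80% cutoff; truncation at the kingdom flags the whole call unclassified.
When a bootstrap subsample scores several species *exactly* equally the
vote is drawn uniformly among them (seeded): a deterministic first-index
tie-break would hide exactly the confusable-congener uncertainty the
bootstrap exists to expose.

**1-NN** assigns the full lineage of the nearest reference by the
clustering distance (alignment-based, for internal consistency); ties
break to higher identity, then accession order, and are recorded.  It
never abstains on an annotated database.

**Placeholders.** A name ending in `sp` or `unclassified` at the requested
rank makes the call unclassified at that rank and all deeper ranks.

## Adjudication and metrics

Calls are adjudicated per OTU at species and genus level under two
settings.  *Strict*: after collapsing the leading equivalence group at the
evaluated rank, a single remaining name that is a truth member
(post-synonym) is a TP; a single non-member is an FP; several distinct
names, or an abstention, count as unclassified (FN).  Collapsing at rank
matters: three tied congeners are an FN at species level but a single —
correct — genus at genus level.  *Loose*: any truth member inside the
group is a TP; a group with no member is an FP booked under a seeded
random group member (reproducible per OTU × combination).  Synonym maps
are closed symmetrically and transitively and applied to both call and
truth; genus names derive from the canonicalized species name, so synonyms
crossing genera resolve correctly.

The *subgeneric* step rescues a species-level non-TP when every
equivalence-group member maps to the same section/series/species-complex
as a truth member, using a user-supplied mapping table (automated
subgeneric taxonomy inference is a non-goal); unmapped names leave the
call unchanged and are noted.

The *consensus* rule works at the taxon level (OTUs of different markers
cannot be linked read-wise): a taxon is a consensus TP only when both
markers call it correctly at the same level; a taxon called in at least
one marker that is neither consensus-TP nor a truth member is a consensus
FP; truth members missing from the consensus TP set count toward FN.
Same-level agreement is required — a species-level hit in one marker and a
genus-level hit in the other do not form a species consensus.

Metrics use the formulas quoted in the README per DMC; DMCs where a
metric's denominator is zero are excluded from that metric's mean and
standard deviation (sample sd, n−1).  The counting unit is the OTU, so a
truth member with no surviving OTU contributes no FN under the default
counting; such members are visible in the consensus FN sets and in
reports.  L1 excludes reads of unclassified OTUs and renormalizes the
remainder to a probability vector (renormalization keeps L1 within its
printed [0, 2] range; whether the original analysis renormalized is not
stated, so this is documented as our choice).

## Problem sizes and what the tests show

The packaged end-to-end checks run 37 communities × 500 error-free read
pairs on one marker (~20 s each on one CPU); the error-bearing sweep check
uses 6 communities × 400 pairs; unit oracles use 30–300-sequence
constructions.  These sizes were chosen so the whole suite and the
acceptance script each finish in about a minute while still exercising the
full study layout.

Passing tests show that the *measurement machinery* — adjudication rules,
metrics, filters, classifiers, and their interactions — behaves exactly as
specified on data with known truth.  They do not certify performance on
real sequencing data: the simulator has no indels, no per-cycle error
structure, no primer bias, no intragenomic ITS variation, and its
reference databases are right or wrong by construction rather than by
curation history.  Real-data precision/recall tables are
database- and run-dependent and are deliberately out of scope.

## Known limitations

* Substitution-only error model; ungapped merging and Hamming-style
  pre-clustering inherit this assumption.
* The chimera detector is a simplified two-parent single-crossover model;
  multi-crossover chimeras and reference-based modes are not implemented.
* The MCC clusterer is a reimplementation from the method's description;
  it matches the cited behaviour (deterministic, cutoff-driven,
  MCC-improving) but is not bug-for-bug identical to any released tool.
* Alignment identity among co-optimal alignments is implementation-
  dependent at the few-percent level on unrelated sequences (see
  Distances).
* Databases are desk-scale (tens of entries per marker); no indexing or
  heuristic seeding is provided for large references.
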