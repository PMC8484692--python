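# Methods

This note documents the models, rules and numerical choices behind
`strainspec`, and what the synthetic-data experiments do and do not show.

## Ortholog clustering and similarity

Similarity edges are computed by local alignment (Smith–Waterman via
Biopython's `PairwiseAligner`) with unit match/mismatch scores and a gap
penalty of −2.  A substitution matrix is deliberately not used: the
synthetic sequences the package is validated on are not evolutionarily
realistic, and the scoring is configurable for real data.

*Identity* is defined as matched positions over the length of the shorter
sequence, not over aligned columns.  With local alignment, two unrelated
sequences always share some short high-scoring segment; normalizing by the
shorter sequence keeps unrelated pairs near the background (a random pair
of length-100 proteins scores well under 40% identity) while near-complete
homologs stay close to 100%.  *Coverage* is the aligned span over the full
sequence length, per side; where a single coverage number is needed
(KO thresholds) the conservative `min(query, subject)` is used, and this
choice is recorded in output metadata.

Clustering edges are computed on **nucleotide** sequences by default.  The
generator's substitution process operates per nucleotide site, and the
default method-A identity threshold (95%) is calibrated on that scale: at
mutation rate 0.01 two within-group copies diverge by ≈ 2% of sites, so
within-group edges sit near 98% identity and the threshold separates them
cleanly from background.  Protein-level identity drops roughly three times
faster per nucleotide substitution, which would put within-group edges on
top of the threshold; protein-level comparison remains available via
`pairwise_similarity(..., level="protein")` and is what the KO annotator
uses internally against its reference.  At mutation rate 0.02 the expected
within-group nucleotide identity (~96%) approaches the 95% threshold, and
two-member groups can occasionally split under method A; recovery is exact
for rates ≤ 0.01, the regime the validation studies use.

Method A is single-linkage over thresholded edges; method B keeps, per
ordered (gene, other-strain) pair, only the best-scoring hit (ties broken
by identity, then lowest gene id) and links mutual best hits.  Both
partition the full gene universe; singletons form singleton groups.  Group
ids are assigned by sorting components on their smallest member, so they
are stable under permutation of the input strain order.

The two in-repo strategies play the role of two independent ortholog
finders whose agreement gates downstream calls; they are transparent
re-implementations of that consensus design, not re-runs of any external
tool.

## Specificity rules

A group is specific to target set *T* if (presence rule) its members occur
only in *T* and — by default, `require_all_targets=True` — in every strain
of *T*; or (KO rule) it contains a KO label whose genome-wide carriers are
exactly the strains of *T*.  Whether partial presence within *T* should
count is genuinely open; both behaviours are implemented behind the flag.

Consensus matching pairs calls across methods by Jaccard overlap of member
genes restricted to target strains, greedy highest-overlap first, with a
default threshold of 0.5 (configurable).  Unpaired calls are reported as
method-exclusive rather than dropped — the situation where one clusterer's
group has no counterpart in the other's partition is informative.

Adjacency blocks are maximal runs of called groups at consecutive
gene indices per strain (length-1 blocks included).  Circular-chromosome
wraparound is not treated as adjacent.

## Read QC

The cascade order is: N filter, PhiX-like decoy, adapter + quality
trimming, length ≥ 50, mean quality > 25, host-like decoy, orphan removal.
Order matters and is honoured: a read that would fail the mean-quality
test before trimming but passes after is kept, because trimming precedes
the test.  "Consecutively ≤ 17" tail-cutting is implemented as removing
the maximal all-≤17 3' suffix, the quality-trim convention of standard
adapter trimmers at `-q 17`.  Mean quality uses the post-trim read and the
discard rule is inclusive ("25 or less").

Decoy matching is shared-k-mer containment (k = 21, both strands indexed;
a read matches when at least half of its distinct k-mers — rounded up —
occur in the decoy), a deterministic stand-in for alignment-based mapping
that is exact for planted contaminants and has negligible false-positive
probability at read length 150.  The packaged decoys are fixed synthetic
sequences, not real PhiX or human genome extracts, and are labelled as
such.

Report arithmetic: totals are exact integer sums; per-sample averages are
rounded half away from zero for display; base pairs are reads × nominal
read length at fixed-length stages and summed post-trim lengths otherwise.

## Quantification

Reads vote with their k-mers (k = 31, both strands indexed); the gene(s)
with the plurality share one count equally.  There is no EM redistribution
of multi-mapped reads: on the synthetic pan-genomes, ambiguity arises only
between within-group copies, and fractional splitting is exact at the
ortholog-group level after aggregation.  For large simulation studies the
voter may subsample a fixed number of evenly spaced k-mers per read
(`max_kmers_per_read`); reads are exact gene substrings there, so two
k-mers already identify the source group.  Effective length equals full
gene length (no fragment-length model).  Each mate counts once, so a pair
contributes two counts.  Ortholog abundance is the **sum** of member-gene
TPM (a mean is available behind a flag); genes missing from the clustering
are reported as unassigned, never silently dropped.

## Cohort statistics

The differential-abundance test draws, per Monte-Carlo instance, each
sample's composition from Dirichlet(counts + 0.5), applies the centred
log-ratio transform, and runs a two-sided Wilcoxon rank-sum test per
feature; the reported p value is the mean over instances (default 128),
with BH q values over features.  This expected-p aggregation is mildly
conservative: for features whose counts are small enough that Dirichlet
resampling noise is non-negligible, instance-to-instance jitter pushes
borderline p values above the threshold asymmetrically.  On null genus
tables at the generator's default depth (30,000 reads, 60 genera) the
realized type-I rate is a little below the nominal 0.05 (around 0.04);
the plain rank-sum test itself attains 0.047 at n = 20 vs 15.  This is a
property of the estimator, not a bug, and it is the behaviour of the
corresponding published method as well.

Wilcoxon p values are exact (full null enumeration, computed by dynamic
programming) when both groups have ≤ 25 observations and there are no
ties, otherwise the normal approximation with tie and continuity
corrections.  Spearman p values are exact by permutation for n ≤ 9.  Log2
fold changes are ratios of group median relative abundances, with half the
smallest positive value in the table as pseudo-abundance when a median is
zero.  PERMANOVA uses seeded label permutations with
p = (1 + #{F* ≥ F}) / (1 + N); the default N is 9,999.  PCoA reports
negative eigenvalues unchanged rather than correcting them.  Shannon
diversity defaults to base 2.  Significance is flagged at two-sided
p < 0.05 everywhere, with BH q values reported alongside.

## Phylogeny

K2P uses pairwise deletion of gap/N columns (the default of the commonly
cited implementation; complete deletion is a flag away) and raises a
saturation error when the log arguments are non-positive rather than
returning NaN.  Neighbor joining breaks Q-matrix ties deterministically at
the lowest index pair and clamps negative branch-length estimates to zero
with a warning; on additive matrices it is exact (verified against random
additive trees up to 8 leaves).  Bootstrap replicates that saturate are
skipped and counted, and supports are percentages over the effective
replicates.  Ambiguity codes other than N are rejected.

## Synthetic-data model and its limits

Gene sequences are i.i.d. stop-free codons with lengths uniform in the
configured range (default 300–900 nt); within-group copies differ by an
i.i.d. per-site substitution process.  Reads are exact substrings (no
sequencing-error, indel or quality-recalibration model); qualities are
truncated normal around a sample mean, with contaminant classes for
PhiX-like, host-like, adapter read-through, N-containing and low-quality
tail reads.  Genus tables follow a log-normal/multinomial compositional
model with planted fold-changes and a Gaussian-copula score covariate.

Passing the validation studies therefore demonstrates the correctness of
the pipeline's logic and arithmetic on data satisfying those assumptions;
it does not demonstrate robustness to real sequencing error, paralogy,
rearrangement or tool-specific clustering behaviour.  Likewise the
localization classifier is a hydropathy-window heuristic honouring the
same three-way output contract as membrane-topology HMMs (≥ 1 predicted
helix ⇒ transmembrane; otherwise an N-terminal hydrophobic signal-like
stretch ⇒ extracellular, else intracellular); its calls on real proteins
will not match a trained HMM and are labelled as stand-in.

## Validation study sizes

The studies run by the test suite and `scripts/acceptance.py` use problem
sizes chosen to exercise the full pipeline at desk scale: the specificity
recovery study uses 12 strains with 30 core groups and 368 planted
specific groups (4 shared by a pair of strains, of which 3 adjacent; 150
and 214 exclusive to single strains) at mutation rate 0.01; the power
study fixes one 12-strain pan-genome and draws 200 independent cohorts of
20 vs 15 samples at 2,000 read pairs per sample with effect size 4 —
at that depth each planted ortholog receives tens of reads per healthy
sample, so the 4-fold group difference dwarfs counting noise and power is
estimated stably; null calibrations use 5,000 CLR feature-tests and 500
PERMANOVA runs at 999 permutations.  Seeds fan out from one global seed
via a fixed counter scheme (`stage_seed`), and identical configuration and
seed reproduce byte-identical outputs.
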