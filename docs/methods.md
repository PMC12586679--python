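# Methods

`pbinkit` reconstructs and analyzes phage-bacteria interaction networks
(PBINs) from the genomic traces that infections leave behind, and relates
the topology of that network to bacterial and viral diversity measured at
genus, species and strain resolution. Everything is exercised against a
synthetic community generator that plants the assumed statistical structure
with known ground truth; this note records the models, the parameter
choices, and what the synthetic results do and do not establish.

## The interaction network and its topology

**Evidence and linkage.** Two independent signals link a viral OTU (vOTU) to
a bacterial OTU (bOTU). (1) CRISPR spacers: a spacer extracted from a
bacterial genome records a past infection by the phage carrying the matching
protospacer. Spacers are accepted only from arrays of the highest detection
evidence level, and spacers from metagenome-assembled genomes (bMAGs) are
discarded when fewer than 10% of the bMAGs in the same bOTU carry a
CRISPR-Cas locus — such orphan arrays are characteristic of contig
mis-binning. Isolate genomes cannot be mis-binned and are exempt (and are
excluded from the fraction's numerator and denominator). Matching is an
ungapped full-length scan of the spacer and its reverse complement along
every viral sequence, accepting windows at Hamming distance ≤ 2; any
ambiguous base (N) counts as a mismatch. (2) Genome homology: an alignment
of a viral genome to a bacterial genome with ANI > 90% and > 50% of the
viral query aligned is a host link; > 80% aligned additionally marks an
integrated prophage. Alignment fraction is always measured on the viral
query — a prophage call only makes sense query-side.

**OTU formation.** Genomes are clustered from pairwise ANI/alignment-fraction
tables: bacteria at 95% ANI, viruses at 95% ANI + 85% AF with single
linkage (connected components of the thresholded similarity graph). An
average-linkage mode (agglomerative on mean pairwise similarity, stopping
when no cluster pair passes both thresholds on average) is provided; single
linkage defines the final OTUs. Representatives are the longest genome in
the best quality tier, ties broken lexicographically.

**Modularity.** The binary bOTU-side-genome × vOTU incidence matrix is
partitioned by LP-BRIM: synchronous bipartite label propagation seeds
candidate modules, then BRIM alternation (fix one side's modules, assign
each node of the other side to the module maximizing its contribution to
Barber's bipartite modularity Q; swap; iterate to convergence at 1e-12)
refines them. Restarts alternate three seedings — label propagation, one
module per node, and random partitions of random width — because BRIM from
any single seeding family can miss the optimum on small dense graphs; the
best of 20 restarts is kept (on every random 4×4 instance tried, 50
restarts reach the exhaustively enumerated maximum). If no candidate beats
the single-module baseline the trivial partition is returned with Q = 0.
Genome-level modules are collapsed to bOTUs by majority vote, ties broken
toward the module sharing the most vOTU interactions, then the lowest id.

**Nestedness.** NODF: for each ordered row pair with strictly decreasing,
nonzero fill, the paired term is 100·|overlap|/k_j; likewise over columns;
the sum is divided by R(R−1)/2 + C(C−1)/2. Significance is assessed against
a probabilistic-degree null: each cell is Bernoulli with probability equal
to the mean of its row and column fill fractions. This null preserves the
overall fill exactly in expectation; per-row/column sums are preserved in
expectation only for degree-homogeneous matrices (the expected row sum is
(k_i + m/R)/2), which is the behavior of the soft-margin model family. The
empirical two-sided p doubles the smaller tail with the +1 permutation
correction and is Bonferroni-adjusted over the modules tested; modules with
a single row or column are excluded. Because the observed matrix is
conditionally much closer to its own margins than the soft null is, the
test is conservative: its measured type-I error on unstructured
Bernoulli(0.5) matrices is ≈ 0.02–0.03 at α = 0.05 (module-shaped 8×30
matrices, 1000 nulls) — a known property of probabilistic-degree nulls, not
an implementation artifact.

**Neighborhood purity.** On an auxiliary proteome-sharedness network, each
node's neighborhood is every node within the first percentile of the global
multiset of finite pairwise shortest-path lengths (computed globally, not
per focal node); purity is the fraction of the neighborhood sharing the
focal node's module.

## Strain-resolved diversity

**Presence.** A bOTU is present in a sample when median coverage > 5× and
breadth > 0.5 (both strict); a vOTU when breadth ≥ 0.7 (no separate
coverage floor); genus presence is the union over the genus's bOTUs.

**Nucleotide diversity.** Per site, π = 1 − Σ f² over the four base
frequencies, computed where coverage ≥ 5 and averaged over qualifying sites
per genome per sample. Sites below the floor leave both numerator and
denominator; a genome with no qualifying site has *missing* π, which is
deliberately distinct from 0 (monomorphic). The plug-in estimator carries
the standard multinomial bias of −π/coverage (≈ 2% of π at 50×), far inside
the site-sampling Monte-Carlo error at genome scale; no bias correction is
applied, matching common practice.

**popANI.** The same genome in two samples is compared at positions covered
≥ 5× in both; a position is identical when the samples share at least one
detected allele, an allele being detected at ≥ 2 reads and ≥ 5% frequency.
The detection rule is this package's own default (the upstream tools leave
it to internals); both thresholds are arguments. popANI = 100 × identical /
compared.

**Dissimilarity.** Jaccard distances on presence/absence at genus, species
(bOTU) and vOTU level. Strain-level distance between two samples is the
fraction of bOTUs *not* shared at the strain level: the denominator is the
union of bOTUs present in either sample, and a bOTU is shared only when
present in both and its popANI ≥ 99.9% (threshold swept 96–99.99% for
robustness; distances are non-decreasing in the threshold by construction).
The union denominator makes strain distance ≥ species distance for every
pair, reproducing the observed ordering. Pairs with an empty union are
undefined (NaN), not zero.

## Diversity statistics

Faith's PD is the branch length of the subtree spanning a sample's present
bOTU tips, including the path to the root (a single tip scores its
root-to-tip distance); root inclusion is switchable. Within-module
diversity is PD × mean genome π over the module's bOTUs present in the
sample (present bOTUs only; missing π values are excluded from the mean and
counted); viral within-module diversity is the richness of present module
vOTUs. Mantel tests use the rank (Spearman) statistic over lower-triangle
entries with 10,000 seeded permutations, one-sided "greater" by default
since a positive association is the hypothesis; the module-matched analysis
computes the statistic for every (bacterial module, viral module) pair with
Benjamini-Hochberg correction, restricted to modules whose bacteria and
phages each occur in ≥ 15 samples. Viral richness is regressed on PD and
mean π jointly by Huber M-estimation; standard errors come from a sandwich
using the converged ψ-weights (bread (XᵀWX)⁻¹, meat Xᵀdiag((wᵢrᵢ)²)X),
since no packaged heteroskedasticity-consistent covariance exists for
M-estimators here; Wald z and two-sided normal p are reported per
predictor.

## The synthetic generator

The generator plants, per module: a rank-threshold nested block (phage of
rank j infects the top max(1, round(B·(1−(j−1)/P)^θ)) bacteria; θ = 1 is a
strict triangle), degraded by symmetric within-module Bernoulli noise ε and
cross-module insertions δ; a module-monophyletic random binary phylogeny
with exponential branch lengths (mean 0.1); per-sample strain pools
(Bernoulli occupancy per strain, Dirichlet(1) abundances) whose allele
tables are multinomial draws at Poisson depth over planted strain
haplotypes (reference = strain 1; a variant site carries one alternative
allele in a random nonempty subset of the other strains, so with two
strains every variant site separates them); phage occurrence that is a
function of susceptible-strain occurrence (strain rank k is susceptible to
the ⌈kP/S⌉ broadest phages of its module, so generalists both infect more
hosts and occur in more samples) thinned by a dropout probability; spacer
and homology evidence realized from the planted edges (spacers are 32-mers
copied from the phage with 0–2 planted mismatches; homology rows draw
ANI ~ U(90.5, 99.5), AF ~ U(55, 100)); detector score tables whose
expected retained set is recorded; and a proteome-sharedness edge list
among vOTUs (within-module pairs connected with probability 0.6,
cross-module 0.02) on which the pipeline evaluates neighborhood purity.
Decoys (3-mismatch spacers, sub-threshold homology) are off by default and
labeled when emitted.
Identical configurations, including the seed, give byte-identical outputs;
each stage derives its RNG from the master seed.

Default scale: 3 modules × 6 bacteria × 8 phages, 3 strains per species, 20
samples, 1 kb genomes at 50× coverage with 2% of sites variable. Six
bacteria per module matches the real system's granularity (53 species over
9 modules); phage counts and genome lengths are scaled down for desk-scale
runs, and 50× coverage sits far enough above the 5× presence cutoff that
the planted presence pattern is recoverable. Viral contigs are 12 kb so
planted contigs pass the ≥ 10 kb screen. At this size a noise-free module's
nested signal is detectable against 1000 nulls at Bonferroni-corrected
α = 0.05; smaller blocks (4×6) are not — a power fact of NODF at that size.

Two study conditions are fixed for the recovery experiments. The *coupling*
condition (5 strains per species at 50% occupancy, zero dropout, zero
noise, 30 samples, 10 phages per module) makes a species absent from only
~3% of samples — reproducing the real contrast between conserved
species-level and variable strain-level composition — and makes phage
occurrence a deterministic function of host-strain occurrence. Under it,
the same-module Mantel statistic exceeds the different-module one in ≥ 90%
of replicates, and the strain-level statistic exceeds the species-level one
on average (the per-replicate contrast is noisier: species absences, though
rare, are individually influential). The *gradient* condition (5 modules
spanning strain occupancies 0.2–0.8, zero dropout) plants a between-module
diversity gradient, under which module-mean composite diversity and
module-mean viral richness correlate strongly; with the gradient off,
modules are exchangeable and that correlation is centered at zero.

**What the generator does not emulate.** Read-level artifacts (no FASTQ;
coverage and allele tables are emitted directly), assembly and binning
error beyond the CRISPR mis-binning filter's input, uneven coverage along
genomes, sequencing error in allele counts, within-species recombination,
multiple vMAGs per vOTU (the pipeline's viral clustering is identity on the
generator's one-contig-per-vOTU output; the clusterer itself is tested on
constructed tables), and genus structure beyond one genus per module.
Passing recovery tests therefore establishes internal consistency of the
inference chain under the planted model, not robustness to real
metagenomic noise.

## Numerical choices and degenerate inputs

BRIM convergence tolerance 1e-12 on Q; argmax ties resolve to the first
(lowest-id) module; label-propagation ties are drawn from the seeded RNG.
Empty networks are errors for partitioning and modularity; all-zero
matrices are errors for NODF; null matrices that come out all-zero score
NODF 0. Distance matrices carry NaN for undefined pairs and Mantel refuses
incomplete matrices (the pipeline restricts module-matched comparisons to
samples where both sides' modules occur). A constant distance vector has no
rank correlation and yields NaN rather than a value. Spacer scanning
refuses nothing: a spacer longer than its target simply has no windows.
Regression requires ≥ 10 complete records and non-collinear predictors
(condition-number guard at 1e10).

## Known limitations

The nestedness test's conservatism (above) means marginally nested modules
need more contrast to reach significance than under a fixed-margin null;
the LP-BRIM optimality check is exhaustive only at 4×4 scale; popANI's
leniency (any shared allele) means strain sharedness saturates when many
strains co-occur in both samples; and the within-module alpha-diversity
correlation is weak at desk scale (25 samples, 4 species per module) even
under planted coupling — its sign stabilizes only across replicates.
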