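# Methods

This note documents the statistical procedures implemented in
rhizopipe, their assumptions, the defaults that matter, and the design
choices made where the methodology was genuinely open.

## qPCR eukaryote:prokaryote contribution

For each sample the 16S and 18S cycle thresholds are transformed to
template values v = 2^(−Ct), assuming ideal amplification efficiency
(one doubling per cycle). Because a fraction f ∈ [0, 1] of 18S
amplicons can originate from the host plant rather than from microbial
eukaryotes, the 18S value is scaled by (1 − f) before use; f is taken
from sequencing of the same amplicon pool (in the pipeline, from the
host-removal report of the 18S library). The eukaryote contribution is

    %euk = 100 · v18·(1−f) / (v16 + v18·(1−f)).

No absolute quantification is attempted: 16S/18S operon copy numbers,
extraction and primer biases affect all samples alike, so only
sample-to-sample comparison of the contribution is meaningful. The
estimator is exactly invertible: on noise-free Ct values it recovers
the generating eukaryote fraction to machine precision for any host
fraction below 1 (verified to 1e-9 in the acceptance suite).

Group comparisons use one-way ANOVA plus all pairwise two-sided Welch
t-tests with Bonferroni adjustment (raw p × number of pairs, capped at
1). Welch was chosen over the pooled-variance t because group variances
of ratio data are rarely equal; the comparison family is the set of
pairwise tests within one panel. Degenerate groups (zero variance on
both sides) take the limit convention p = 1 for equal means and p = 0
otherwise, avoiding NaNs.

## Preprocessing order

The order is fixed and logged: host/organelle OTU removal →
depth standardization → relative abundance (100% per sample) →
square-root transform. Host removal operates on raw counts so that the
removed fractions are interpretable as fractions of the original
library, and the 18S host fraction can feed the qPCR correction.

"Standardizing to an upper threshold" is implemented as rarefaction:
samples above the threshold are subsampled without replacement (a
multivariate hypergeometric draw), which is unbiased for composition;
samples at or below the threshold are kept unchanged by default, with a
`drop` policy available. Truncation was rejected because it biases
towards whatever order reads happen to be stored in. Each sample uses
its own RNG stream derived from (seed, sample id), so sample order
cannot change any result. Per-library default thresholds are 10,000
(16S), 5,000 (18S), 3,000 (fungal ITS1) and 2,000 (oomycete ITS1)
reads.

The square-root transform damps dominant taxa so that distance-based
analyses are sensitive to sub-dominant community members.

## Core membership

An OTU is stably associated with (core for) a species when, for every
genotype line of that species, it is present in at least
⌈0.25 · n_replicates⌉ of that line's biological replicates. The ceiling
is deliberate: "at least 25% of replicates" is a lower bound on the
realized prevalence, so for 7 replicates 2 presences are required
(1/7 ≈ 14% would not witness the bound). Presence means count > 0
after depth standardization; evaluating presence before rarefaction is
exposed as an option but not the default, keeping membership consistent
with every downstream abundance figure. Venn regions partition the
union of cores: each OTU falls in exactly one region (the set of
species whose cores contain it), and region abundance shares are
computed per sample and then averaged, never by pooling reads, so they
are consistent with the per-sample 100% standardization.

## Distances, PCoA, PERMANOVA, CAP

Bray–Curtis dissimilarity on square-root-transformed percentages is the
default metric (Euclidean and Jaccard are selectable); the statistical
machinery is metric-agnostic. PCoA eigendecomposes the Gower-centred
matrix G = −½ J D² J. Negative eigenvalues (semi-metric distances) are
reported but their axes excluded from coordinates, and the proportion
explained is taken over the positive part; no Lingoes/Cailliez
correction is applied by default, preferring transparency over silent
distortion of the distances. Axis signs are fixed deterministically by
making each axis's largest-magnitude loading positive.

PERMANOVA supports an ordered list of factors with optional nesting
written `child(parent)`. With hat matrices H of the cumulative dummy
designs (SVD-based projectors, so overparameterized and nested designs
project exactly), sequential sums of squares are
SS_j = tr(H₁..ⱼ G) − tr(H₁..ⱼ₋₁ G) and marginal (Type III) sums are
tr(H_full G) − tr(H₋ⱼ G). Degrees of freedom are rank increments;
Type I SS plus residual add to tr(G) exactly and dfs add to n − 1. The
pseudo-F denominator is the residual mean square for every term (a
next-nested denominator is not offered; the single-denominator table
matches how multi-factor pseudo-F values are usually reported).
Significance uses permutation of residuals under the reduced model,
realized as Freedman–Lane on the Gower matrix: with H_red the
reduced-model hat, R = (I−H_red) G (I−H_red) is row/column-permuted by
the same permutation, H_red G H_red added back, and pseudo-F
recomputed. For a nested term, permutations are restricted to the
parent stratum, mirroring designs where genotypes are exchangeable only
within their species. The p convention is (1 + #{F* ≥ F}) / (1 + m),
valid and never zero; samples are canonicalized into sorted-id order
before permuting so p cannot depend on input ordering. For a single
factor on Euclidean distances of univariate data, the pseudo-F equals
the classical one-way ANOVA F exactly — the primary oracle of the test
suite, together with exhaustive permutation enumeration at n ≤ 7 and a
cross-check against an independent one-way implementation.

CAP retains m PCoA axes and performs the eigen-analysis of
Q_m' H_group Q_m on the orthonormal axis basis; when m is not forced it
is chosen to maximize leave-one-out allocation success of a
nearest-centroid classifier, taking the smallest m on ties (parsimony,
deterministic). The trace statistic is tested by permutation of group
labels. Ordinary PCA of a taxa table is provided through the same eigen
machinery as PCoA of Euclidean distances (covariance scaling on
standardized percentages).

Model terms that a reduced line panel leaves single-level or fully
aliased with preceding terms are dropped by the pipeline with a log
note; calling `permanova` directly with an aliased term is an error
naming the offending term.

## Synthetic community generator

The generator emulates the study design: 22 wheat genotype lines
(4 bread wheat, 3 pasta wheat, 4 wild goat grass, 3 wild emmer, 4
synthetic hexaploid, 4 F1 crosses) with their species, ancestry class,
ploidy and D-genome origin, plus unplanted bulk-soil controls, in
rhizosphere and/or root fractions. Per library, each OTU receives a
lineage from a weighted phylum pool, with designated Glomeromycetes
(class with its four orders), Nematoda, Cyanobacteria, host-plant
(18S) and organelle (16S) OTUs. Baseline expected proportions apply
log-normal rank-abundance jitter within each phylum block and
renormalize the block to its pool weight, so taxon-group baseline
shares are exact by construction (e.g. Nematoda ≈ 2% of the 18S
community, matching unplanted soil).

Per sample, the expected composition multiplies the baseline by the
configured fold effects of matching taxon groups and factor levels and
renormalizes; effects act multiplicatively on relative abundance
because fold changes are how such shifts are described and measured.
Default effects encode the study conditions: niche enrichment of
Proteobacteria (rhizosphere 3×, root 10×), Cyanobacteria in bread wheat
(8×), and wild-D-genome enrichment of Nematoda (4×, mixed D 2×) and
Glomeromycetes (3×, mixed D 2×) — the Nematoda–Glomeromycetes
correlation arises solely from this shared driver, with no
within-sample coupling. In the 18S library, planted samples receive a
host-plant share drawn uniformly from [0.14, 0.75]; 16S planted
samples receive a small organelle share (0.5–3%).

Counts are Dirichlet-multinomial: p ~ Dirichlet(c · composition) with
concentration c = 200 by default (biological overdispersion matters for
PERMANOVA calibration; a plain multinomial would be unrealistically
tight), then a multinomial draw at a depth sampled log-normal around
twice the library threshold (log-sd 0.25), so the rarefaction path is
exercised and ≥ 90% of samples exceed the threshold by construction.
qPCR tables are generated by inverting the estimator: a value pair with
the true eukaryote share e (bulk 5.4%, planted 6.8%, sd 0.005), 18S
inflated by 1/(1 − host fraction), and Gaussian Ct noise (sd 0.25
cycles) added. Within-genotype variance parameters are free choices of
the generator, not calibrated to any survey; all randomness fans out
from one seed through per-sample streams keyed by stable labels.

What the generator does *not* emulate: sequence-level artifacts
(chimeras, PCR bias, clustering errors), spatial or temporal structure,
taxon-taxon interaction networks, and residual correlation between
taxa beyond shared design drivers. Passing tests therefore demonstrate
correctness of the analysis machinery under a realistic compositional
sampling model, not robustness to raw-read processing artifacts.

## Problem sizes and numerical choices

The test and acceptance suites run at deliberately modest sizes chosen
to exercise every code path: null-calibration uses 500 datasets of 4
lines × 5 replicates at 50 OTUs with 199 permutations; parameter
recovery uses the full 22-line panel at 8 replicates per line and 80
OTUs over 100 replicates; the factor-ranking check uses 9 lines in two
fractions over 100 replicates. Eigenvalue positivity uses a relative
tolerance of 1e-12 on the largest eigenvalue; design ranks use a
1e-10 relative singular-value cutoff; permutation F comparisons use a
1e-8 relative tie tolerance so exhaustive enumeration and Monte-Carlo
agree on ties. Empty samples (all reads removed or zero depth) are
flagged and excluded from distances rather than carried as zero
columns, since Bray–Curtis is undefined for them.

## Known limitations

* PERMANOVA offers only the residual mean square as denominator; for
  strongly unbalanced nested designs a term-specific denominator can be
  more appropriate.
* CAP's leave-one-out classifier reuses the full-data PCoA axes rather
  than re-embedding each left-out sample; with many axes and few
  samples the allocation success is slightly optimistic.
* The compact letter display is built by insert-and-absorb over the
  pairwise significance graph; letters are deterministic (levels
  ordered by decreasing mean) but, like all letter displays, are a
  lossy summary of the pairwise p matrix.
* The qPCR model assumes equal amplification efficiency for 16S and
  18S targets; no standard-curve or efficiency correction is provided.
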