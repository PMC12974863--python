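# Methods

## The model

`ecocline` simulates haploid bacterial populations forward in time under an
explicit (non-Wright–Fisher) life cycle and asks which evolutionary forces
can produce a *backboned* phylogeny — a tree in which a single connected
path of internal branches carries a large fraction of the total internal
branch length — together with a dominant, reproducible first principal
component of genetic variation. The central hypothesis the simulator
interrogates is a **bacterial ecocline**: a continuous gradient of allele
frequencies maintained by diversifying selection on an additive polygenic
trait, balanced against homogenizing horizontal gene transfer (HGT), rather
than by geography.

Each genome is a sparse map from site to derived mutation relative to an
empty ancestral chromosome. Two neutral mutation types, m1 and m2, arise
with equal probability at a per-site rate *u*. Under selection, genome *g*
has trait value

    score(g) = sum_{i in m1(g)} c_i  -  sum_{j in m2(g)} c_j

with per-site effect magnitudes *c* either all one (uniform model, where the
score reduces to #m1 − #m2) or drawn once per run from a Gamma distribution
with mean one (shape × scale = 1). Fitness is a normalized power function of
the deviation from the current population mean score μ:

    fitness_i = 2 + A * |score_i - mu|^k / (max_j |score_j - mu|^k + eps)

with amplitude A = 1.0 and exponent k = 5 (range [2, 3)) in the uniform
model, and A = 0.5, k = 10 (range [2, 2.5)) in the refined Gamma model;
eps = 1e-6 guards the flat case, where every fitness is exactly 2. Offspring
numbers are Poisson(fitness), or Poisson(2) during the neutral phase; a hard
carrying capacity then keeps each (sub)population at its nominal size by
uniform down-sampling of the offspring pool. μ is recomputed from the
current population every generation.

Every individual receives one HGT event per generation (five in the
full-scale refined model): a contiguous tract of fixed length is copied from
a uniformly chosen other individual, replacing the recipient's variants in
the tract. Tracts are half-open, 0-based, and **wrap around** the chromosome
end inside the simulator, because the modelled chromosome is circular; a
linear-truncation variant of the raw `hgt_event` operation remains available
(omit `genome_length`). Wrapping matters: with truncation, sites near the
origin are covered by roughly half as many tract starts, and the resulting
recombination cold spot accumulates spurious PC1 loading peaks.

Six scenarios share this machinery: `neutral`; `stepping_stone` (a linear
chain of demes exchanging a fixed number of migrants per generation, HGT
confined within demes); `hotspot` (80% of tract starts forced onto three
fixed coordinates); `mutation_het` (heritable p1/p2 labels in one panmictic
population, de novo mutation disabled in p1, donors drawn 50/50 by label);
and `selective_uniform` / `selective_gamma` (neutral first half of the run,
diversifying selection from the selection-start generation onwards).

## Diagnostics

**Binary encoding.** Populations are converted to a strains × sites binary
matrix in which the *minor* allele — the second most frequent state at the
site, counting the ancestral no-mutation state as an allele — is 1 and all
other states (including third/fourth-ranked alleles at multi-allelic sites)
are 0. Frequency ties resolve toward the smaller internal allele identifier
(ancestral < m1 < m2), which makes the coding deterministic. Monomorphic
sites are dropped; sites with minor-allele frequency below 2% are removed
before any PCA; LD pruning then greedily removes the later-positioned member
of any within-window pair with R² > 0.1.

**PCA and loadings.** Strain loadings are left singular vectors of the
column-centred pruned matrix scaled by the square root of the covariance
eigenvalues (the standard loading definition; an eigenvalue-scaled variant
is available behind `scaling="eigenvalue"` for replication experiments, and
correlations are insensitive to the choice). Per-variant loadings are the
product of the strain-loading matrix with the MAF-filtered (not pruned)
binary matrix, one value per site — their squared PC1 column is the genome
scan used to locate loading peaks. Because strain-loading columns have zero
mean, centring the matrix in this product is immaterial.

**Clone removal.** Before half-matching, non-selective populations are
deduplicated: a greedy pass keeps strains whose pairwise Hamming distance
exceeds half the expected pairwise diversity, N·u·L SNPs (500 at desk
scale, 2,000 for a full-scale N=2,000 run). Without this step, recent
clonal families produce genuine genome-wide structure that makes PC1
"reproducible" even under strict neutrality — which is precisely the
artifact the step exists to remove. Under the desk-scale selective
scenarios the population consists of a few internally clonal trait
clusters, so distance deduplication would delete the structure under study;
clone removal is therefore skipped there, and the PCA/LD/tree stages always
run on the full population so that cross-scenario comparisons stay matched.

**Half-matching.** Three reproducibility tests for PC1: defining PC1 on one
strain group and projecting the other (both directions); independent PCA on
the two chromosome halves; and independent PCA on low- versus high-loading
site sets, where sites are classed by the windowed maximum of squared PC1
loadings (lower tertile = low, upper decile = high by default — the source
analysis states no numeric cutoffs, so these defaults keep both sets
populated while isolating the peaks). Correlations are reported as |Pearson
r|; significance uses a 200-permutation strain-label null at α = 0.01, since
no analytic test accompanies projected components. Half-strain matching is
counted as reproducible only when both directions are significant; the
strain partition for simulated data is the sign of a preliminary
full-data PC1 (standing in for the tree-backbone split used on real data),
with a median fallback for degenerate splits. When the trait distribution
is strongly bimodal — as desk-scale uniform-effect selection tends to be —
this partition separates the two trait clusters themselves, and the
within-group trait signal that the test relies on can be weak. Note
that even byte-identical strain halves give |r| slightly below 1 in the
half-strain test: the defining group's PCA sees only pruned sites while the
projection passes through every MAF-filtered site, so the projected score
is a slightly rotated copy of the component.

**LD.** R² between binary columns is computed from joint frequencies,
R² = (f_ij − f_i f_j)² / (f_i f_i' f_j f_j'), identical to the squared
Pearson correlation of the columns (asserted to 1e-10 in the tests). Decay
curves average R² in 10 bp distance bins up to a 30 kb cap (scaled at desk
size); no MAF or equilibrium filtering is applied inside the LD
computation. The high-loading analysis computes the full R² matrix among
variants above a squared-loading cutoff (300 on the full-scale analysis;
a top-0.5% quantile at desk scale, where absolute loading magnitudes differ)
and cuts a complete-linkage dendrogram on 1 − R² into a requested number of
blocks — complete linkage keeps blocks tight, and a count-based cut is used
because a height rule is not identifiable from the source analysis.

**Trees.** Neighbor joining (scikit-bio) on raw Hamming distances, with
negative branch estimates clamped to zero — the goal is tree-shape
diagnostics on binary simulated data, not substitution-model inference.
The backbone score is the weighted diameter of the internal-branch subtree
divided by the total internal branch length: 1 for a caterpillar, 0 for a
star, invariant under tip relabeling and uniform branch scaling. No
threshold is imposed; classification is left to the user.

## Scales and defaults

Full scale mirrors the source conditions: 1 Mb genome (5 Mb refined model),
*u* = 1e-6/site/generation, N = 10,000, 10,000 generations with selection
from generation 5,001, tract lengths 1–100 kb, hotspots at 250/500/750 kb,
Gamma scales up to 5e6.

The desk preset used by the tests and worked examples is a
ratio-preserving miniature: L = 100 kb, N = 500, 2,000 generations with
selection from 1,001, tract lengths {0.1, 2, 10} kb (scaling 1/20/100 kb by
the genome ratio), *u* = 1e-5 so that the per-genome mutation rate stays at
one event per generation, and all bp-sized diagnostic windows (pruning, LD
decay cap, loading windows) scaled by the same genome ratio (50 kb → 5 kb,
30 kb → 3 kb). The desk Gamma preset uses shape 1e-4 and scale 1e4
(mean 1), the genome-ratio image of the full-scale 1 Mb batch at scale 1e5:
about ten sites carry nearly all of the trait, which is the smallest effect
count that still behaves polygenically. With a single dominant locus,
symmetric diversifying selection degenerates — at a balanced frequency every
individual has the same |score − μ| and fitness goes flat — so one-locus
Gamma tables (scale ≈ L) are not a useful miniature. Desk pipelines build
the tree from a deterministic stride subsample of at most 150 strains to
keep neighbor joining fast; backbone scores are ratios and robust to this.

## What the generator does and does not emulate

Simulated data are fully called (no missing genotypes), biallelic or
triallelic only, with known ancestral states, a single circular chromosome,
and no accessory genome, no sampling bias, and no clonal oversampling —
the non-redundant selection step exists for imported data but is largely a
no-op on simulated panmictic populations. Passing desk-scale tests shows
that the *mechanisms* (diversifying selection vs. drift, migration, or rate
heterogeneity) produce the claimed contrasts in backbone score, PC1
reproducibility, loading kurtosis and LD structure at matched per-genome
rates; it does not show that real-data quantities (for example a specific
PC1 variance share) are reproduced, since those depend on genome length,
sample structure and history outside the generator's scope.

At desk scale, drift is strong (N = 500), and PC1 loading peaks — while
consistently located at large-effect segregating sites — do not always rank
the largest-effect site first; occasionally a drift/LD peak with no
underlying effect outranks it. The identity of the top peak stabilizes with
population size and run length.

## Numerical choices

Seeding is explicit everywhere (`numpy` Generators); identical scenario
specifications give bit-identical outputs, and PCA signs are fixed by
forcing the largest-magnitude entry of each component positive. HGT events
are applied sequentially within a generation, so donors reflect earlier
same-generation transfers. A repeat mutation at an occupied site replaces
the resident record (finite-sites convention, one record per site). Zero
total offspring raises an extinction error rather than restarting silently.
The fitness ratio d/(d + eps) can round to exactly 1 in float64 for very
large deviations, so the open upper fitness bound is closed numerically.
Migration sends all emigrants simultaneously (sampled without replacement
per deme) before arrivals are merged. Degenerate diagnostic inputs (all
loadings equal, a fragment without polymorphic sites, an empty high-loading
set) raise informative errors rather than returning placeholder values.
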