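# Methods

This note records the models implemented in foxscape, the numerical and
design choices behind them, what the synthetic-data generator does and does
not emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model

Genotypes are diploid, multi-allelic, and may be missing; a call is either
a full unordered allele pair or absent. Missing data are handled everywhere
by pairwise deletion per locus — an individual missing a locus is excluded
from that locus's statistics only, never imputed. Allele labels are opaque
strings except where a stepwise mutation model is requested, which requires
integer repeat scores (`GenotypeTable.repeat_loci`).

Haplotype count tables may carry a declared per-row n and per-row diversity
mirroring a published summary table. Counts are authoritative; the declared
n is a checksum. A row whose counts disagree with its declared n is flagged
inconsistent, and the diversity-partition operation substitutes the
declared diversity for such rows (the packaged table has exactly one:
its contact-zone row prints n = 9 and diversity 0.593 while its counts sum
to 11 and imply 0.678 — a source-table inconsistency we preserve rather
than silently repair). Site inclusion for within-site means follows an
explicit inclusion list when the table carries one, else the rule
n ≥ 5 with a single known location.

All geometry is planar km. Longitude/latitude input is projected by a local
equirectangular projection about the site centroid; at a ~1000 km extent
the scale distortion is below ~1%, far smaller than the uncertainty of any
distance-based statistic here.

## Diversity and differentiation

Gene diversity is the **uncorrected** h = 1 − Σ pᵢ². The n/(n−1) unbiased
variant exists as an option but is not the default, because published
haplotype tables of this kind print the uncorrected quantity and the
package is designed to reproduce such tables from their counts.

The diversity partition is F_ST = 1 − h̄_S/h_T with h̄_S the unweighted mean
over included sites and h_T from the pooled counts. The haploid
Weir–Cockerham estimator is the indicator-variable ANOVA
θ = (MSP − MSG)/(MSP + (n_c − 1) MSG); the diploid multi-allelic θ is the
ratio of summed variance components Σa / Σ(a+b+c) over alleles and loci,
with a 95% CI from 1000 bootstrap-over-loci replicates. Pairwise estimates
may be negative and are preserved; clamping to zero happens only in the
linearized matrix F/(1−F), where values ≥ 0.999 become +inf and are
excluded (with a count) from regressions and Mantel inputs.

F_IS is the ratio-of-sums 1 − ΣHo/ΣHe across polymorphic loci with the
unbiased He in the denominator, so its expectation is ~0 under
Hardy–Weinberg (verified by simulation in the test suite). Allelic
richness uses exact hypergeometric rarefaction to a common gene count,
auto-lowered with a warning if it exceeds the smallest per-locus sample.

Permutation tests: Hardy–Weinberg permutes alleles among individuals
within a site (statistic |F_IS|, two-sided); gametic equilibrium permutes
single-locus genotypes among individuals (statistic the G log-likelihood
ratio of the genotype-pair contingency table). p = (1 + #extreme)/(n_perm
+ 1), so p ∈ [1/(n_perm+1), 1]. These tests are exact but discrete; at
small n the granularity of Ho makes the HWE test mildly conservative,
which is why the calibration test uses n = 100.

### Sex-biased gene flow

Under the island model with even sex ratio, nuclear F_ST = 1/(1 + 4N m̄)
with m̄ = (m_m + m_f)/2, and mitochondrial F_ST = 1/(1 + N m_f) (a haploid
marker carried by the N/2 females). Eliminating N gives

    m_m/m_f = [(1/F_nuc − 1)/2 − (1/F_mt − 1)] / (1/F_mt − 1).

Both internal consistency checks (symmetric migration ⇒ ratio 1; the
boundary where mtDNA structure implies all gene flow is female ⇒ ratio 0)
hold analytically and are tested. A negative implied male rate is clamped
to 0 and flagged. The estimate inherits all island-model assumptions:
equilibrium, equal deme sizes, island (not stepping-stone) migration, and
fourfold difference in effective copy number between markers.

## Effective size and bottleneck inference

**LD-Nₑ.** For every allele pair at every locus pair, the composite Burrows
disequilibrium Δ̂ = (n/(n−1))[mean(XY)/2 − 2p̂q̂] (X, Y allele doses) is
squared and normalized by (p(1−p)+D_A)(q(1−q)+D_B), the Hardy–Weinberg-
robust denominator. Alleles below the frequency cutoff (default 0.05) are
excluded. The sampling component 1/S + 3.19/S² (S ≥ 30; a different
empirical polynomial below 30) is subtracted from the mean r̂² and Nₑ is
obtained from the second-order inversion of E[r²_drift] ≈ 1/(3Nₑ),
assuming random mating. r²_drift ≤ 0 yields Nₑ = +inf, the estimator's
standard boundary behavior. The CI is a delete-one jackknife over locus
pairs on mean r̂², transformed to the Nₑ scale. Calibration: on
Wright–Fisher populations of true Nₑ = 50 sampled completely (S = 50, 13
loci) the jackknife CI covers the truth in a majority of 20 replicates and
the median point estimate is within a factor of two.

**Bottleneck test.** For each polymorphic locus with k alleles in n genes,
the equilibrium heterozygosity H_eq is simulated: a Kingman coalescent of n
genes, mutations Poisson on branches, under IAM (each mutation a new
allele), SMM (±1 steps), or the two-phase model (default 70% single steps;
multi-step sizes geometric with variance ≈ 30, the conventional default
since only the stepwise fraction is usually reported). The scaled mutation
rate is tuned by bisection so the mean simulated allele count matches k,
then replicates with exactly k alleles are retained (rejection
conditioning; a locus that cannot reach k within the batch budget is
dropped and logged). The observed unbiased He is compared to the H_eq
distribution per locus, and loci are combined by a two-tailed Wilcoxon
signed-rank on He − mean(H_eq), exact up to 25 loci. The simulation core is
numba-compiled; results are bit-reproducible under a fixed seed.

One ordering property worth stating: at a fixed allele count, H_eq under
SMM exceeds H_eq under IAM (stepwise homoplasy produces fewer alleles per
unit heterozygosity), which is precisely why SMM-based bottleneck tests
are the conservative ones. The test suite verifies this ordering by
simulation, and the type-I calibration (equilibrium coalescent samples,
12 loci) holds the nominal 5% level within binomial tolerance.

## Trees and ordination

Neighbor joining follows the standard Q-criterion; ties are broken by the
lexicographically smallest label pair (an internal node carries the
smallest leaf name of its subtree), so results are deterministic. A
negative branch length is set to zero and its magnitude transferred to the
sibling branch of the same join. On tree-additive matrices NJ recovers the
generating topology and branch lengths exactly (property-tested on random
instances up to 8 taxa, and cross-checked against an independent NJ
implementation). Bootstrap support resamples loci with replacement,
recomputes D_A and the tree, and reports for each original-tree
bipartition the percentage of replicates containing it (support attaches
to the original topology, not a consensus topology).

PCoA uses the per-locus allele-mismatch metric — the squared genotype
distance at a locus is half the squared difference of allele-count
vectors (0/1/2/3/4 for the five genotype-pair configurations) — summed
over shared loci and rescaled to the full locus count; pairs sharing no
typed locus receive the mean defined distance, with a logged count. Gower
double-centering of −D²/2 and an eigendecomposition follow; axes with
positive eigenvalues are returned, negative eigenvalues are reported. The
sum of eigenvalues equals the total centered inertia (tested to 1e-9).

## Admixture and cluster profiles

The sampler is the standard admixture Gibbs scheme over allele-copy
origins Z, cluster allele frequencies P (Dirichlet), and ancestry vectors
Q (Dirichlet(α)), with the common α updated by Metropolis steps. The
correlated-frequency (F-model) prior Dir(p_A(1−F_k)/F_k) is the default;
as a simplification the ancestral frequencies p_A are fixed at the pooled
empirical frequencies while each F_k is updated by Metropolis — a design
choice that keeps the update conjugate and has no visible effect on Q in
the regimes tested. ln P(D) is summarised as mean − var/2 of the data
log-likelihood over post-burn-in cycles and is used for comparison across
K only, never as a hard model-choice criterion.

Replicate runs are aligned by greedy maximum-correlation column matching
(approximate label-switching resolution). The cluster-profile hierarchy
records each individual's modal cluster at every K; a K→K′ transition is
nested when every K′ cluster's members derive ≥ 95% from a single K
cluster (tolerance configurable). Two operational rules complete the
procedure: a K level is **valid** only if its replicates align (mean
aligned-column correlation ≥ 0.9) and every cluster is modal for at least
one individual — without the occupancy rule a spurious extra cluster
would vacuously "nest" — and an invalid (multimodal) K is excluded from
the chain, with nesting then checked between consecutive valid levels.
chosen_K is the highest valid K reachable through nested transitions.
On hierarchical simulations (2 regions × 2 demes, 13 loci, 20 individuals
per deme, regional divergence stronger than deme divergence and one
regional split stronger than the other, as real hierarchies tend to be)
the procedure recovers K = 4 in ≥ 80% of replicates at desk-scale MCMC
(1000 cycles, 3 replicates per K). Defaults for real analyses are 20,000
cycles with 10,000 burn-in; the larger published-scale settings are a
config change.

Migrant classification is deterministic given Q: the home cluster of a
site is the modal cluster among its members (ties broken by higher mean
q, logged); an individual with q_max below the threshold (default 0.75)
is admixed; a strongly assigned individual whose modal cluster is another
site's home cluster is a first-generation migrant from there.

## Landscape genetics

The barrier/corridor surface regresses pairwise genetic distance on
Euclidean distance (OLS over the n(n−1)/2 site pairs), attaches each
residual to the pair midpoint, and interpolates by inverse-distance
weighting (default power 2, unlimited search radius, 100-cell grid over
the site bounding box plus 10% margin — all exposed, since no standard
values exist). An exact midpoint hit takes that residual; the surface is
bounded by the residual range by construction. The permutation null
relabels sites (simultaneous row/column permutation of the genetic
matrix, identity included as the first member) and rebuilds the surface,
yielding per-cell null quantiles and an exceedance map.

Effective resistance treats non-nodata raster cells as nodes with
4-neighbor edges of conductance equal to the mean of the two cells'
conductances (an explicit dialect choice; 8-neighbor variants exist in
other tools). Pairwise resistance comes from one sparse LU factorization
of the grounded Laplacian per raster component; disconnected pairs are
+inf and flagged. The implementation matches dense pseudoinverse oracles
to 1e-8 and the series/parallel closed forms exactly, and is a metric on
connected rasters. A suitability raster is converted to resistance as
1/s with a floor (default 1e-3), the simplest inversion consistent with
treating high-suitability habitat as low-resistance.

Mantel tests correlate off-diagonal upper triangles, with one-tailed
(positive-association) permutation p by default — the hypotheses here are
directional — and a two-tailed option. Euclidean and resistance matrices
are log-transformed when requested (strictly positive triangles only).
The partial test regresses both matrices on the conditioning matrix over
the triangle and permutes the residual matrix rows/columns. Non-finite
pairs (capped linearized F_ST, disconnected resistances) are dropped with
a count. Under the null the type-I rate is nominal within binomial
tolerance (500-replicate calibration), and a 4×4 exhaustive enumeration
matches an independent oracle exactly.

## Synthetic metapopulation generator

Non-overlapping generations, even sex ratio, random union of gametes
within site (monogamous pairing available for mating-system sensitivity),
census N per site. Founding draws `founder_pairs` pairs per site from a
shared source pool (default: Dirichlet(1) allele frequencies over 8
alleles at 13 loci, 10 haplotypes); each generation, a Binomial(N_sex, m)
set of each sex is replaced by immigrants drawn from other sites with
probability ∝ 1/resistance-distance (or 1/Euclidean distance without a
raster). Microsatellite mutation is SMM at 5e-4 by default, switched off
for calibration runs. Haplotypes ride with females; an immigrant male's
foreign maternal lineage, which he cannot transmit, is recorded as
unknown rather than entering the destination's haplotype pool — this
keeps the generator consistent with the mtDNA-gene-flow-is-female
assumption that the sex-bias estimator makes. Everything is driven by a
single seeded generator; fixed seed means bit-identical output.

What the generator emulates: independent founder events, founder
bottlenecks, drift over tens of generations, resistance-shaped sex-biased
migration, maternal haplotype inheritance. What it does not: overlapping
generations, territoriality and true monogamous pair fidelity across
years, natal-habitat-biased dispersal, landscape change over time,
genotyping error, and null alleles. Tests passing on simulated data
therefore validate estimator math and calibration, not robustness to
those real-data complications.

Calibration targets used in the suite (problem sizes chosen to keep the
default run a few minutes): a 16-island model with 4Nm = 4 run 300
generations, where the bootstrap CI of θ covers the infinite-island
expectation 0.2 (the finite-island expectation with d = 16 is
1/(1 + 4Nm·(d/(d−1))²) ≈ 0.18, also checked); 20 Wright–Fisher replicates
for LD-Nₑ; 20 hierarchical replicates for chosen_K; 20 replicates with
m_m/m_f = 4 for the dual-marker sex-bias recovery (accepted within ±50%,
reflecting the compounded variance of two F_ST estimates).

## Pipeline

`foxscape run --config file.ini` executes diversity → differentiation →
Nₑ/bottleneck → tree/PCoA → clustering/profiles/migrants → landscape,
writing CSV/raster/Newick artifacts and a JSON manifest (version, seed,
all parameters, warnings, per-stage status). Any stage failure halts the
run with the stage name; prior outputs are retained. Reruns with the same
config and seed are file-identical (tested).

## Known limitations

* The sex-bias ratio is an equilibrium island-model identity; founder
  effects and nonequilibrium dynamics bias it (the simulator recovery test
  quantifies the spread under near-equilibrium conditions only).
* The F-model's ancestral frequencies are fixed empirically, not sampled;
  α is a single shared Dirichlet parameter.
* The LD-Nₑ bias polynomials are empirical and tied to the random-mating
  assumption; with strong family structure the estimator is biased low.
* Label alignment across replicate runs is greedy, not optimal matching;
  with many clusters of similar size it can misalign, which the validity
  (agreement) check is designed to catch.
* Circuit resistance uses 4-neighbor connectivity only.
* The heterozygote-excess test conditions on the observed allele count by
  rejection; for very high allele counts at small n the acceptance rate,
  and hence the effective n_sim, can drop.
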