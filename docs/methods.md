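# Methods

This note documents the models, estimators and design choices behind
`amupopgen`, in the order the pipeline runs them.

## Data model

Genotypes are unordered pairs of integer allele sizes (base pairs) per
individual and locus, stored sorted ascending with 0 marking a missing
call; a call with either copy missing is treated as a missing pair. Allele
sizes are kept exactly as typed — fragment binning belongs upstream of this
package. Missing data are recorded and excluded locus-wise from every
estimator, never imputed; individuals missing more than a configurable
fraction of calls (default 20%) are dropped at read time with a log entry.
Folding a tiny sampling unit into a neighbour is an explicit alias map in
the reader, never automatic.

## Synthetic data

The simulator is a forward-in-time diploid Wright–Fisher model rather than
a coalescent one because the downstream analyses need genotype tables with
unit labels, geography and missingness, and because forward simulation
makes the true per-deme Ne explicit (it equals the diploid census size).
Per generation and deme: each offspring draws two parents, each parent's
deme of origin from the deme's row of the migration matrix (migration
before reproduction), then a uniform resident of that deme; each inherited
copy then mutates (mutation after reproduction) under a strict stepwise
model (±1 repeat of 2 bp, reflecting at the configured window edges) or a
k-allele model. Parents are whole individuals, so unlinked loci share the
drift of a finite parent pool — the signal the LD effective-size estimator
consumes. Defaults mirror the field design the package targets: 16 loci,
mutation 5·10⁻⁴, ≤5% missing calls, about 60 samples aimed for per unit,
and demes strung 15 km apart with a fixed jitter pattern (evenly spaced
lattices would make within-distance-class statistics degenerate; real units
never are). What the generator does **not** emulate: overlapping
generations, age structure, sex-biased dispersal, harem mating (harem
effects enter only through the demographic Ne formulas) and genotyping
artefacts other than uniform missingness and optionally injected null
alleles. Passing tests therefore show the estimators are correct under
drift–migration–mutation dynamics, not that field complications are
handled.

## Diversity statistics

He is Nei's sample-size-corrected estimator (2n/(2n−1))(1 − Σp²) per locus,
averaged over all loci including monomorphic ones; Ho is the typed
heterozygote fraction. Multi-locus Fis is 1 − mean(Ho)/mean(He) — the ratio
of locus averages, not the average of ratios, which is unstable at
near-monomorphic loci. Its CI is a percentile bootstrap over loci (default
1000 resamples). Allelic richness rarefies each locus to g gene copies via
the hypergeometric expectation Σₐ[1 − C(N−Nₐ, g)/C(N, g)]; the default g is
the smallest typed gene count over all (population, locus) cells, computed
once for the table. The Hardy–Weinberg test permutes the allele pool
(default 1000 times) and orders genotype arrays by their conditional
probability given the allele counts, arrays at most as probable as the
observed one (with a 10⁻⁹ log tolerance for ties) counting as extreme;
p = (b+1)/(n+1).

The allelic potential reads the curve 13.69 ln x + 38.685 (x = sampled
percentage of the census) as the expected *percentage* of alleles already
detected, so Na(p) = An·100/(13.69 ln x + 38.685). The ×100 reading is the
only one consistent with the reference values the package reproduces (the
worked examples in `amupopgen.reference`); the curve's domain requires
x > e^(−38.685/13.69) ≈ 0.059%.

The Brookfield null-allele estimator r = (He−Ho)/(1+He) is reported per
locus with a bootstrap-over-individuals CI and a significance flag (CI
excludes 0). A caveat documented by the estimator-recovery test: under the
observation model in which null/visible heterozygotes are scored as visible
homozygotes and null/null genotypes as missing, the apparent
heterozygosities obey He' = Hv and Ho' = Hv(1−r)/(1+r), so the estimator
converges to Hv·2r/((1+r)(1+Hv)) — an O(r) underestimate (≈0.15 for an
injected 0.2 at Hv = 0.875). It is a detection statistic and a small-r
approximation, not an unbiased estimator of large null frequencies.

## Differentiation and isolation by distance

Pairwise Fst is Weir–Cockerham θ: per-locus, per-allele variance components
a, b, c for two populations, summed over alleles and loci, θ = Σa/Σ(a+b+c).
Negative pair estimates are reported as computed — truncating at zero would
bias averages. Jost's D per locus uses the Nei–Chesser corrected
heterozygosities (harmonic-mean sample size ñ): Hs' = (2ñ/(2ñ−1))Hs,
Ht' = Ht + Hs'/(4ñ), D = 2(Ht'−Hs')/(1−Hs'); the multi-locus value is the
arithmetic mean over loci. Significance for both comes from a bootstrap
over loci (the locus, not the individual, is the unit of resampling for
differentiation). Distances between unit centroids are great-circle on a
6371-km sphere, which reproduces the reference survey's printed minimum and
maximum pair distances within 0.15%.

The Mantel statistic is the Pearson correlation of upper-triangle entries;
p comes from permuting the label order of one matrix, one-sided for
positive association, with the (b+1)/(n+1) correction — except that when
n! fits within the requested permutation count the exact enumeration is
used (identity included), making small-n p-values exact. The correlogram
is class-restricted: within each (lower, upper] distance class the Pearson
correlation of genetic and geographic distance over the member pairs, with
permutation p from relabelling the genetic matrix while the class
membership stays fixed. This form was chosen over the indicator-matrix
correlogram because a single class spanning all distances then reduces
exactly to the plain Mantel statistic; its cost is that classes need
within-class distance spread (hence the simulator's jittered geometry).
The largest class upper edge up to which classes are contiguously positive
with p < 0.05 is reported as the autocorrelation range.

## Clustering

The EM admixture model is the standard independent-frequency admixture
likelihood: each allele copy of individual i is drawn from cluster k with
probability q_ik, then from that cluster's allele frequency at the locus.
EM alternates copy-wise responsibilities with membership and frequency
updates (a 10⁻⁹ floor keeps frequencies off the boundary); the
log-likelihood is non-decreasing and convergence is a gain below tol.
It is a deterministic point-estimate counterpart of MCMC admixture
samplers — correlated allele frequencies, admixture priors and location
priors are deliberately not reproduced; externally produced Q-matrices can
be ingested where that fidelity matters. ΔK selection uses
|mean L(K+1) − 2 mean L(K) + mean L(K−1)|/sd(L(K)) over ≥3 replicate runs
per K; a numerically flat second difference reports "no structure signal"
rather than a K.

The DAPC-style clusterer one-hot-codes allele dosages (missing entries
take the column mean), centres, and runs PCA. K-means and its
BIC = n ln(WSS/n) + K ln(n) are computed in the full PC space — retaining
all components for the partitioning step is the cited practice, and in the
reduced space the BIC minimum drifts above the true K because splitting
noise still pays — while the discriminant step that converts the chosen
partition into posterior memberships uses the reduced space (default: PCs
explaining 90% of variance). ΔK tends to flag the top-level split and BIC
the finer partition; the analysis scripts therefore fit the admixture
Q-matrix at the finer of the two selections.

The hierarchical procedure re-clusters each modal-assignment subset
(ties to the lowest cluster index) and stops a branch when all its samples
share one sampling location, when the clustering run's mean best-cluster
membership falls below 80% (the low-confidence split is discarded), or when
fewer than ten individuals remain. "Average assignment" is the mean over
individuals of their maximum membership.

## Connectivity, regions, isolation

Connectivity between units A and B is 100·Σₖ min(prevA_k, prevB_k), the
overlap of their mean-membership (soft-count) prevalence vectors — a
bounded symmetric similarity with the right limits (identical prevalences
give 100, disjoint cluster use 0). The product kernel Σ p·q was rejected
because it cannot reach 100 for admixed units; the kernel is pluggable.
When several clustering methods contribute, connectivity is computed per
method in that method's own cluster space and the percentages averaged —
cluster spaces are never mixed. Only neighbour pairs within 40 km
(centre-to-centre) enter the downstream rules, matching the dispersal range
of young deer. The decay law y = a·x^b is fitted by least squares on
log–log scale (zero-connectivity pairs excluded and logged), with binned
means over (0,10], …, (30,40], (40,60], …, (180,200], (200,∞) km; pairs
deviating from the fitted value at their exact distance by ≥10 points are
classed higher/lower than expected. Neighbour pairs are linked when at
least two of three criteria hold strictly (clustering connectivity > 40,
DAPC connectivity > 40, Fst < 0.05); regions are connected components of
the link graph, i.e. merging is transitive. Isolation is classed by the
best combined connectivity among a unit's neighbours: ≥ 40 connected,
< 40 isolated, ≤ 20 highly isolated; a unit with no neighbour inside the
radius is isolated by default and flagged.

## Effective size and threat

The LD method estimates the Burrows composite disequilibrium Δ̂ (with the
S/(S−1) factor) for every inter-locus allele pair among individuals typed
at both loci, squares it against p(1−p) products, and averages r² weighted
by pair sample size, with S the harmonic mean over comparisons. Allele
screening removes alleles below Pcrit *and* single-copy alleles regardless
(removing singletons is the screening's purpose; at S = 50 a singleton sits
exactly at frequency 0.01 and would otherwise slip through the
Pcrit = 0.01 rule and inflate the estimate). Biallelic loci contribute one
allele to avoid duplicate comparisons. The sampling expectation
E[r²|S] = 1/S + 3.19/S² (S ≥ 30; the small-S coefficients otherwise) is
subtracted and Ne = (1/3 + √(1/9 − 2.76 r²'))/(2r²') for S ≥ 30 (0.308
coefficients below); non-positive r²' reports an infinite estimate,
flagged. Pcrit follows sample size: 0.02 below 50 genotyped individuals,
0.01 at 50 or more. On Wright–Fisher validation runs the median estimate
tracks true Ne within a factor of 1.6 across Ne ∈ {25, 50, 100}.

The demographic formulas are used exactly as printed — Wang's harem-
polygamy Ne = 4NmNf/(2Nm+Nf) and Caballero's lottery-polygyny
Ne = 4mfN/(1+m/n) — with all inputs (reproducing counts, sex proportions,
lifetime breeding success) supplied per unit as configuration, since they
come from management authorities, not from genotypes. Bookkeeping: the consensus
Ne is the three-way mean of Wang, Caballero and the LD estimate at the
rule's Pcrit; the "taken" Ne is the LD estimate only for isolated units
with Nc < 1000 (the LD method mistrusts substructured or large
populations), otherwise the consensus. Ne/Nc divides the consensus by the
census (2 decimals); the expected loss of heterozygosity per generation is
ELHG = 100/(2·Ne_taken) %.

Threat classification solves Ht = Ho(1−1/(2Ne))^t for the generations t
until heterozygosity reaches 0.54, the empirical 25% quantile of published
microsatellite heterozygosities; Ho at or below the threshold gives t = 0.
Classes use closed upper bounds: t ≤ 10 critically endangered, ≤ 50
endangered, ≤ 100 vulnerable, else not threatened. The class applies
directly only to isolated units; for connected units it is reported as
conditional on future isolation.

## Numerical and reproducibility choices

All randomness flows through numpy Generators seeded explicitly; a pipeline
seed expands into per-stage seeds through a counter scheme
(`default_rng([seed, stage])`), so stages are independently reproducible
and reruns are byte-identical. All CIs are percentile bootstrap intervals.
Rarefaction and the exact-test statistic use log-gamma arithmetic.
Genotype pairs are stored sorted; population order follows first
appearance, so label permutations of the input permute outputs coherently.

Problem sizes in the shipped tests and the worked example were chosen as
the smallest at which each property is statistically decisive: demes of
40–120 diploids, 16 loci, 20–150 generations, 20–50 replicates for
recovery and coverage checks.

## Known limitations

The EM admixture fit can lump weakly diverged demes at small K (ΔK prefers
top-level splits); the hierarchical procedure and the BIC clusterer
compensate but the choice of working K remains the analyst's. The LD
effective-size estimator is unreliable for very low-diversity units (few
polymorphic loci leave few r² comparisons) and for substructured or large
populations — exactly why the bookkeeping falls back to demographic values
there. The Brookfield estimator's large-r bias is documented above. The
connectivity kernel presumes the clustering resolves units at all; with a
single shared cluster everything looks connected.
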