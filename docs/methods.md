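# Methods

`admixscreen` evaluates high-throughput qpAdm/qpWave admixture screening on
two kinds of simulated population histories: random admixture graphs (AGS)
and two-dimensional stepping-stone landscapes (SSL). This note records the
models, the numerical choices, and what the synthetic data can and cannot
say about real analyses.

## The inference core

### f-statistics

f2-statistics are computed per physical genome block (default 4 Mb per
chromosome) from group allele frequencies with the standard finite-sample
correction: for a group with `n` called alleles and sample frequency `p`,
the term `p(1-p)/(n-1)` is subtracted once per group. For pseudohaploid
data each individual contributes one allele; with the
`adjust_pseudohaploid` flag off, calls are treated as diploid genotypes
(halving the correction), mirroring the two conventions used for diploid
and pseudohaploid pipelines. With `maxmiss = 0` only sites with data in
every group enter. f3 and f4 are linear combinations of f2 per block;
"allsnps" f4 is computed off the genotypes directly with per-quadruplet
site selection (f4 needs no bias correction, so the two modes coincide on
complete data for distinct quadruples, and differ when a group repeats).

Standard errors come from a weighted delete-one-block jackknife
(Busing-style): with block weights `m_j` (usable-site counts), total
`n = sum m_j`, `h_j = n/m_j`, leave-one-out estimates `theta_{-j}`, the
pseudovalues are `tau_j = h_j theta - (h_j - 1) theta_{-j}` and the
variance is `sum (tau_j - theta_J)^2 / (h_j - 1) / g`. The same formula,
generalised to vectors, yields the covariance `Q` of the f4 matrix.

FST is Hudson's estimator as a ratio of averages across sites (the
estimator choice is ours; it matters for the landscape-sparsity summaries,
so it is stated prominently). A group contributes at a site only with at
least two called chromosomes.

### qpWave and qpAdm

For left set L and right set R, the matrix
`x[i][j] = f4(l1, l_{i+1}; r1, r_{j+1})` is tested for rank r by fitting
the best rank-r matrix under the quadratic form defined by the inverse of
the jackknife covariance `Q` of `vec(x)` — alternating generalised least
squares over the two factors, initialised from the SVD of `x`, stopping at
a relative objective change below 1e-10 or 200 iterations. The statistic
is the minimised form, referred to chi-square with
`(L-1-r)(R-1-r)` degrees of freedom. `Q` is regularised with a ridge of
`1e-5 x mean(diag(Q))` before (pseudo)inversion, applied twice when the
upstream-compatibility flag (`fudge_twice`) is on; the flag exists because
the upstream regularisation semantics are not published, and both
behaviours are testable. Results are basis-invariant up to numerical
tolerance (permutation tests enforce 1e-9 agreement).

qpAdm fits an n-way model by the rank-(n-1) version of this test on
left = {target} + sources; the admixture weights are the unit-sum left
null vector of the fitted matrix (unconstrained — weights outside [0, 1]
are reported as estimated). Weight standard errors come from delete-one-
block refits that recompute the f4 matrix but hold `Q` fixed (refitting
`Q` per block would square the cost for negligible change at the block
counts used here). The model P-value has `R - n` degrees of freedom.

The chi-square reference assumes many more blocks than the dimension of
`vec(x)`. With few blocks the statistic is inflated (a Hotelling-type
effect) and P-values skew low; with physically adjacent small blocks,
linkage between blocks biases `Q` downward with the same effect. The
calibration studies therefore use genuinely unlinked blocks (separate
chromosomes) and at least ~20 of them; scaled-down SSL analyses (25 Mb,
1-Mb blocks) accept noisier covariances, which is acceptable for the
qualitative enrichment checks but not for calibration claims.

## Synthetic histories

### Random admixture graphs

A history has 13 sampled leaves and 10 pulse admixture events. A random
bifurcating scaffold is built by sequential random joins; every
demographic event (split, sampling, pulse) is assigned to an integer
"level", events at one level are tied to a single date, and adjacent
levels are separated by a gap drawn from U{20..120} generations, with the
whole chain constrained to the maximum depth (800 generations; deeper
setups scale all dates up, e.g. 3.75x for depth 3000). Levels no event
uses are compressed out, so adjacent event dates always differ by one gap.
If 200 rejection draws cannot fit the chain into the budget, the gap upper
bound is capped (construction fails outright if even 20-generation gaps do
not fit). Pulses connect two lineages alive at a common level (recipient
and donor drawn uniformly); proportions are U[0.10, 0.50] and per-lineage
diploid sizes U{1000..10000}. Leaves may be sampled at any level below
their formation, or all at the present (`extend_to_present`).

Genotypes are simulated with msprime: 100-Mb chromosomes at recombination
rate 2e-8 joined by 1-nt boundaries with rate log(2) (effectively free
recombination), binary mutations at 1.25e-8, and the discrete-time
Wright-Fisher model for the 25 most recent generations. Degradation to
archaeogenetic quality draws a single allele at heterozygous sites,
per-individual missing rates from U[0.05, 0.95], group sizes from
U{1..10}, and retries (budget 1000) until more than `min_sites` sites
remain polymorphic across the retained groups jointly.

### Stepping-stone landscapes

64 demes of 1000 diploids sit on a triangular lattice: complete hexagonal
rings around a central vertex (61 demes) plus a compact three-deme
boundary accretion chosen deterministically (most chosen neighbours first,
ties by central distance then polar angle). This layout has node degrees
3-6, lattice-step diameter exactly 9 and Euclidean diameter 8.54. All
demes arise by multifurcation 2520 generations before present and then
exchange migrants with nearest neighbours through three eras (1400, 350
and 770 generations); per-edge, per-direction rates are redrawn at each
era start — five times per era for the densest regime — from the regime's
range: uniform on [1e-5,1e-4], [1e-4,1e-3] or [1e-3,1e-2], or |N(0,
sigma)| truncated at 1e-2 for the mixed regime, with sigma = 2e-3 chosen
so the central 99% of realized |rates| spans roughly 1e-5 to 1e-2; this
places the mixed regime's median pairwise FST (~0.06) between the two
uniform extremes, at the subcontinental diversity level it is meant to
mimic. The ancestral population size is set to
the per-deme size (1000); it only matters for the sparsest regime, where
pre-multifurcation structure survives to the sampling epoch. Three
diploids per deme are sampled at 0, 100 and 300 generations before
present. The default genome is 500 Mb (rates 1e-8 and 1.25e-8); the test
and acceptance analyses use 25 Mb, which changes site counts but not FST
expectations.

## Screening protocols and feasibility

Rotating and nonrotating, distal and proximal screens are implemented as
in the archaeogenetic literature: rotating sets of 13 or 18 demes (every
non-source becomes a right group), or 10/15 fixed proxies plus 10/15
rights. Randomized experiments draw deme x slice units without
replacement per set (the same deme may appear at two slices); distal
protocols take targets from the present slice, and proximal rotating
draws never allow a target from the oldest slice. Systematic experiments
place the reference set on the 1st and 3rd lattice circles around a
central target; all 2^6 = 64 subsets of the six nearest neighbours define
one experiment series.

A composite feasibility criterion combines an EAF condition (strict:
`w +- 2 SE` inside (0,1); plain: `w` inside (0,1); loose: `w` inside
(-0.3, 1.3) — all intervals open, 1-way models pass trivially), a main
P-value threshold in {0.001, 0.01, 0.05, 0.1, 0.5}, and a trailing rule
(none, same threshold, or fixed 0.001 for main thresholds 0.05/0.5):
36 criteria in total. Trailing models of an n-way model are all simpler
models over its own target and sources with the target or the first
source as head, evaluated with the model's right set. Randomized
experiments compute all complexity levels and derive the stop level;
systematic experiments stop at the first feasible level.

## Evaluation layer

Source-target (ST) distances on the lattice are counted in lattice steps
(nearest neighbours 1, the maximum on the landscape 9); angles are
Euclidean, measured at the target between deme centres, and undefined
when a source occupies the target deme. The Euclidean reading of ST
distance was considered and rejected: the printed maximal distance of 9
is exactly the lattice-step diameter (the Euclidean diameter is 8.54) and
the unit-width distance bins of the reference analyses imply integer
distances. The minimal angle is normalised so that the maximal angle
(360/n degrees for an n-way model) maps to 9; distance-to-ideal is the
Euclidean distance to (1, 9) in the (max ST distance, normalised angle)
plane, and a model is optimal when it is at most 5 (an alternative rule
accepts only all-nearest-neighbour models). Prestudy odds, FPR, FNR, FDR
and PPV follow from the optimal/nonoptimal confusion counts, and
`FDR = FPR / (R - FNR*R + FPR)` is verified against count-based FDR.
An experiment's positive outcome is "misleading" when the best rejected
model beats the best accepted model by more than 8 in distance-to-ideal
(minimal ST distance comparison at 1-way stop levels); undefined-angle
models count toward positives but enter no distance comparison.

On graphs, 2-way models are classified TP/FP by five topological rules
evaluated on the simulated parameters and under ten branch-length/Ne
randomisations (a predicate is structural only if it holds on all):
cladality and symmetry use expected f4 values computed analytically with
per-segment drift `duration/(2 Ne)` (linear-drift approximation — exact
for structural zeros, proportional otherwise); target-to-proxy flow uses
ancestry-mass propagation through pulse chains; ancestry fractions
"derived from a true source" are measured at the top of the source's
exclusive lineage region (the segment just below where its scaffold chain
meets another true source's chain) — a definition that makes cladal
sister proxies count as full representatives. A proxy "represents" the
unique true source it is structurally closer to than to every other. The
40% threshold separates adequate from inadequate representation; proxies
standing in for a ghost (a true source no sampled group represents at
40%) fall under the unsampled-source rule rather than the 40% rule. Rules of this
kind resist full automation; the curated
fixture table in the test suite is the authority for edge cases.

PCA support projects the target centroid on the inter-source segment in
PC1-3 (supported within 3 target-cluster diameters, diameter = maximal
within-cluster distance); ancestry-component support implements the
published decision list over per-K component tables, one satisfying K
sufficing. LD pruning is windowed r^2 > 0.5 removal (2000-SNP windows,
step 100) before a 10-component PCA on standardised, mean-imputed
genotypes.

The geographic layer applies the same metrics to real-map model tables:
group centroids are planar means of member coordinates (the spherical
mean would differ only for groups spanning huge areas), distances are
haversine great circles (R = 6371 km), angles are differences of initial
bearings at the target folded into [0, 180], and ST distances at or below
50 km count as zero with the model's angle undefined.

## Problem sizes and what the tests show

The test suite and the acceptance script use deliberately scaled-down
problems chosen to keep every quantity inside its stochastic tolerance:
25-Mb landscapes (FST expectations are genome-length-free), 8-Mb
replicates for cross-regime FST ordering, 20-Mb two-chromosome graphs for
the 30/70 pulse-recovery study (20 replicates), 20 unlinked 1-Mb
chromosomes per replicate for the null-calibration study (100
replicates), and 300-500 randomized experiments per protocol x density
cell for the geometry odds. Passing these checks demonstrates the
correctness and calibration of the machinery on data that satisfy its
assumptions exactly; it does not certify behaviour under ascertainment
bias, contamination, reference bias or other artefacts of real
archaeogenetic data, which the simulators deliberately omit (no
long-range migration, no Ne change, no extinction/recolonisation on
landscapes; no continuous migration on graphs).

Known limitations: the measured randomized-screen prestudy odds for 3-
and 4-way models sit ~20% above and ~20% below their reference values
respectively under every layout and distance convention we
examined (2-way agrees within ~5%); the exact published deme layout and
experiment-drawing details are not recoverable from text, and the odds
reported here are computed, not fitted. qpAdm P-values are only
asymptotically chi-square in the number of blocks; scaled-down analyses
with few blocks inherit conservative-to-liberal distortions discussed
above.
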