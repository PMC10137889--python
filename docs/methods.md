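# Methods

This note records the statistical models implemented, the numerical and
design choices made where conventions differ between packages, and what the
synthetic-data generator does and does not emulate.

## Data model and missing data

All statistics operate on aligned haploid sequences over {A, C, G, T, N, −}
with a per-sample population label. The default missing-data policy is
**complete deletion**: any alignment column containing a gap or N in any
sample is removed before computing segregating sites, pairwise differences,
or per-site diversity, and the surviving column count (`sites_used`) is the
denominator of every per-site quantity. This mirrors the convention of the
classical sequence-statistics programs and keeps the pairwise difference
matrix exact (every pair is compared over the same columns). A permissive
`gap_policy="none"` retains all columns and ignores missing states
site-wise; it changes `sites_used` and therefore per-site values.
Haplotypes are called over segregating sites and named H1, H2, … in
descending total count with lexicographic tie-breaking, so "the most
frequent haplotype" is reproducible across runs and input orderings.
Positions are reported 1-based.

## Diversity

* k̂ = Σ_{i<j} d_ij / C(n,2); π = k̂ / sites_used. An algebraic identity
  (π equals the average per-column unbiased mismatch probability) is used as
  an independent oracle in the tests.
* θ_W = S / (a₁ · sites_used), a₁ = Σ_{i=1}^{n−1} 1/i.
* h = n(1 − Σ p_i²)/(n − 1). The n/(n−1) correction is required to
  reproduce h = 0.5 exactly for two haplotypes at counts {k, k} − type
  configurations at small n.
* Across-population summaries weight populations **equally** (not by sample
  size) and use the sample SD (n−1). This is the convention that reproduces
  published mean ± SD summaries computed over per-population tables.

## AMOVA and φ_ST

One level (among/within populations). For haploid sequences the number of
pairwise differences is itself the squared Euclidean distance between
sequences, so difference counts enter the sums of squares unsquared:

    SS_total  = Σ_{i<j} δ²_ij / N
    SS_within = Σ_k Σ_{i<j∈k} δ²_ij / n_k
    σ²_w = SS_within/(N−P),   σ²_a = (SS_among/(P−1) − σ²_w)/n_c,
    n_c = (N − Σ n_k²/N)/(P−1),   φ_ST = σ²_a/(σ²_a+σ²_w)

Degenerate inputs (zero total variance, e.g. monomorphic organelle data)
return φ_ST = 0 with a warning rather than NaN so pipelines keep running.
Negative variance components are retained by default (as in distance-based
F-statistics software); `clamp_negative=True` truncates at zero. The
permutation test shuffles sample labels, keeps the observed configuration
in the numerator and denominator ((r+1)/(n+1)), and defaults to 9999
permutations. Pairwise φ_ST runs the two-population AMOVA for every pair
without clamping.

## G_ST / N_ST

Equal-population-weight unbiased estimators: per population,
h_k = n_k/(n_k−1)(1 − Σ p²) and the ordered analogue
v_k = n_k/(n_k−1) Σ_ij p_i p_j π_ij with π_ij the inter-haplotype distance
(Hamming over segregating sites by default); h_S, v_S are unweighted means;
totals use the mean haplotype frequencies with the small-sample correction
h_T = 1 − Σ p̄² + h_S/(ñP) (ñ the harmonic-mean sample size), and likewise
for v_T. G_ST = 1 − h_S/h_T, N_ST = 1 − v_S/v_T. When all inter-haplotype
distances are equal, N_ST = G_ST exactly — the identity the permutation
test exploits: haplotype identities are permuted in the distance matrix
(leaving G_ST fixed) and the one-tailed p-value is the fraction of permuted
N_ST values at least as large as the observed one. Populations with fewer
than two usable samples are dropped from the contrast (logged).

## Isolation by distance and Mantel tests

Geographic distances are great circles on a sphere of radius 6371.0 km.
The linearized IBD regression fits F_ST/(1−F_ST) on ln(distance in km) by
OLS over off-diagonal pairs; **km and natural log** are a package
convention — the slope's interpretation depends on it and the intercept
absorbs unit changes, so the scale is documented rather than inferable.
Pairs with F_ST = 1 have an undefined linearized response and are excluded
from the fit (and counted), which is exactly why a Pearson correlation on
raw F_ST versus distance is reported alongside: it tolerates complete
differentiation. Significance of both the slope (two-sided) and the
Pearson r (upper-tailed, the IBD direction) comes from Mantel permutations:
one matrix's population labels are permuted jointly over rows and columns,
9999 permutations by default. `mantel_test` itself reports upper- and
lower-tail p-values.

## Gene flow (Ennos contrast)

The ratio is implemented exactly in its classical zero-inbreeding form

    m_p/m_s = [(1−F_STn)/F_STn]·[F_STm/(1−F_STm)] − 2 ,

which is the form that reproduces published worked examples. Note that
eliminating N_e from the two island-model relations as printed gives a
formula twice as large (the contrast then estimates (m_p/m_s)/2 − 1); the
discrepancy is inherent to how the estimator is conventionally written and
used, and the full-chain simulation test treats recovery as ordinal
(ratio ≫ 1 when pollen flow dominates; the estimator centres at its
algebraic limit −1 when m_p = 0) rather than exact. Valid inputs are the
open interval (0, 1); boundary estimates raise a domain error naming the
offending quantity.

Uncertainty: maternal F_ST dispersion is taken from per-locus φ_ST
estimates (sample SD over loci) when several polymorphic sites exist;
biparental F_ST uses the delete-one-population jackknife,
Var = (P−1)/P · Σ(θ_(i) − θ̄)². The ratio SD is a first-order delta method
treating the two inputs as independent:
∂R/∂F_STn = −F_STm/[(1−F_STm)F_STn²],
∂R/∂F_STm = (1−F_STn)/[F_STn(1−F_STm)²]. With a maternal SD of the size
per-locus dispersion typically produces, this delta-method SD is large
(tens of units) — a faithful statement of how poorly two loci constrain the
ratio, and deliberately not tuned to match any smaller published figure.

## Neutrality tests

Tajima's D uses the standard constants chain (a₁, a₂, b₁, b₂, c₁, c₂, e₁,
e₂) and is undefined (flagged, not zero) when S = 0. Its p-value uses the
bounded-beta approximation of the null distribution (rescaling D onto its
attainable range with mean 0, variance 1); a simulation-based calibration
of both tests is part of the acceptance suite instead of an analytic p for
F_S. "Fu's F" is implemented as Fu's F_S: S′ = Pr(K ≥ k_obs | θ = k̂)
under the Ewens sampling formula, with unsigned Stirling numbers of the
first kind computed by exact integer recurrence and converted to logs
(safe far beyond the sample sizes involved), and F_S = ln(S′/(1−S′)).
k_obs = 1 gives S′ = 1 and F_S = +∞, returned as a flagged boundary value.

## Mismatch distribution

The sudden-expansion expectation is derived directly from the two-epoch
coalescent for a pair of lineages. In mutational time s = 2ut, the pair
coalesces with hazard 1/θ₁ for s < τ and 1/θ₀ beyond, and carries
Poisson(s) differences, giving

    F_i = F̂_i(θ₁)·P[Γ(i+1, 1+1/θ₁) ≤ τ]
        + e^{−τ/θ₁} Σ_{j≤i} Pois(j; τ) F̂_{i−j}(θ₀),

with F̂_i(θ) = θ^i/(1+θ)^{i+1} the stationary spectrum (computed in log
space to avoid overflow at large class counts). τ = 0, θ₀ = θ₁ reduces to
F̂; the closed form is validated in the tests against an independent
pairwise Monte-Carlo simulation at three parameter points.

Fitting minimizes SSD = Σ(x_i − F_i)² over (θ₀, θ₁, τ) with a coarse grid
(τ ∈ [0, 2d]; θ₁, θ₀ on log grids) followed by Nelder–Mead in log space;
on curves inside the model class this recovers the generating parameters to
SSD < 1e−8. By default the expected spectrum is renormalized over the
observed classes (tail mass folded back) so that two unit-sum vectors are
compared; `renormalize=False` disables this. Raggedness is
r = Σ(x_i − x_{i−1})² with the trailing convention x_{d+1} = 0. SSD and
raggedness p-values come from a parametric bootstrap: samples of the
original size n are drawn from the two-epoch coalescent at the fitted
parameters, refit, and compared ((r+1)/(n+1)); plain SSD is used as the
bootstrap discrepancy.

## Haplotype network

Kruskal's algorithm over all haplotype pairs sorted by (steps, name, name)
gives a deterministic MST; with `keep_alternate_minimal_edges` every
rejected edge whose weight ties the heaviest edge on its tree cycle is
restored, yielding a minimum spanning network. At the shallow divergences
this package targets (a few mutational steps) the statistical-parsimony
connection limit of TCS-style software would never disconnect anything, so
it is deliberately not implemented; no unsampled intermediate haplotypes
are inferred. Edges carry the differing 1-based alignment positions.

## Simulators

**Island model.** Continuous-time structured coalescent: within-deme pair
coalescence at rate 1/N per generation; migration with Wright's pool
convention — each lineage migrates at rate m into the metapopulation pool
and lands uniformly on one of the d demes, so the effective deme-changing
rate is m(d−1)/d. Under this convention the expected
between-vs-within coalescence-time contrast gives F_ST = 1/(1 + 2Nm) for
**any** number of demes, which is what makes the simulator a clean test bed
for the island-model estimators (measured calibration: mean AMOVA φ_ST
0.668 ± 0.006 at 2Nm = 0.478 against an expectation of 0.677, and
0.027 ± 0.002 at 2Nm = 33 against 0.029 — the residual being
finite-sample estimator bias, not simulator error). m = 0 with several
demes is rejected (the genealogy has no common root); the no-migration
limit is approached with small m. Mutations are Poisson on branches under
infinite sites, each mapped to a distinct alignment column; genealogies
carrying more mutations than columns are redrawn (logged), which very
slightly truncates the upper diversity tail — negligible at the mutation
rates used, and preferable to violating the one-mutation-per-column
contract. The two-marker-system simulator runs the maternal genealogy at
migration m_s and the biparental one at m_s + m_p/2 (a pollen migrant
carries half the ancestry of a biparental genome per generation under
haploid bookkeeping), with shared deme structure and sample labels but
independent genealogies.

**Two-epoch model.** Pair hazard 1/N₁ until t generations back, then 1/N₀,
with piecewise-exponential waiting times (memoryless restart at the epoch
boundary). The same machinery, reparameterized in mutational units
(hazards 1/θ₁, 1/θ₀ and mutation rate 1/2 per lineage), drives the mismatch
bootstrap and the closed-form oracle tests.

**Study-like fixture.** `make_paper_fixture` emits: a metadata table of ten
South-China populations (coordinates, elevation, precipitation,
temperature); a 1050 bp maternal alignment of 161 samples with exactly two
biallelic segregating sites at positions 318 and 647 defining four
haplotypes (A-A, C-A, A-C, C-C), six populations fixed and four polymorphic
with h between 0.42 and 0.52 — haplotype counts are constructed
deterministically to hit that regime, since two SNPs carry far too little
information for a coalescent simulation to reproduce such a specific
configuration at a usable rate; and a 619 bp biparental alignment of 239
samples simulated under the island model at 2Nm = 33 (expected
φ_ST ≈ 0.029) with per-site 2Nμ chosen so expected within-population
diversity is π ≈ 0.12 (deme size 1000 is an arbitrary scale; only the
scaled products matter). What the fixture does **not** emulate: sequencing
error, alignment ambiguity, indel polymorphism, recombination within the
nuclear marker, selection, and any real geographic correlation between the
metadata and the genetic data (the simulated demes exchange migrants
symmetrically, so IBD tests on the fixture are true nulls). Passing tests
on the fixture therefore demonstrate correctness of the estimator chain
under the island-model assumptions, not robustness to those violations.

## Problem sizes in the test suite

Simulation-based checks use sizes chosen to give stable Monte-Carlo
averages at interactive runtimes: 400 replicates per migration regime for
the island-model calibration (10 demes × 8 samples, 1200 sites), 200
replicates per arm for the full-chain gene-flow recovery, 4000 + 2000
replicates for the neutrality type-I-error calibration (n = 20, θ = 5),
and 2 × 10⁵ pairwise draws per parameter point for the mismatch oracle.
Tolerances were fixed from the expected Monte-Carlo error plus known
finite-sample estimator bias before the suites were finalized.

## Known limitations

* Only one grouping level in AMOVA (no region/population hierarchy).
* Tajima's D significance uses the beta approximation, not per-dataset
  coalescent simulation (the calibration test shows the statistic itself is
  well behaved; the approximation is adequate away from tiny S).
* The delta-method ratio SD assumes independent, approximately normal
  inputs; with two maternal loci the maternal SD is itself poorly
  estimated.
* The island-model simulator has no spatial arrangement of demes, so it
  cannot generate true isolation by distance.
* No recombination, selection, diploid genotypes, or median-joining
  network inference.
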