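# Methods

This note documents the models, estimators, numerical choices, and
known limitations of `canrec`. Units follow field convention: physical
coordinates in base pairs (0-based half-open internally, 1-based
inclusive in map/call TSVs, 0-based half-open in BED), genetic
distances in centimorgans for maps and Morgans inside the interference
likelihoods.

## Crossover-interference model

Chiasmata along a tetrad are modelled as a stationary renewal process
on the genetic scale whose inter-arrival distances are
gamma(shape ν, rate 2ν) in Morgans. Each chiasma resolves into a
crossover on a given chromatid with probability ½ (chromatid
thinning), which makes the observed inter-crossover distance a
geometric mixture over skipped chiasmata:

f*(x) = Σ_{j≥1} (½)^j · Gamma(x; jν, 2ν),

with mean 1 Morgan, so the expected crossover count on a chromosome of
genetic length L is L for any ν. ν = 1 collapses to a homogeneous
Poisson process (no interference); ν > 1 regularises spacing.

The two-pathway (gamma-escape) extension superposes an independent
Poisson "escape" pathway at rate p per Morgan on an interfering
pathway whose chiasma inter-arrivals are gamma(ν, 2ν(1−p)), keeping
the total rate at 1 crossover per Morgan.

### Likelihood

The likelihood of an ordered sequence x₁ < … < x_k on [0, L] is the
full stationary-renewal density with end effects:

* first event via the equilibrium first-arrival density
  g(x) = c·S(x), where S is the survival of f* and c the pathway rate;
* interior gaps via f*;
* the censored tail via S(L − x_k);
* k = 0 via P₀(L) = 1 − c·∫₀^L S, with the integral in closed form per
  mixture component (∫₀^L S_j = L·S_j(L) + (j/2c)·F_{jν+1}(L)).

Zero-crossover chromosomes therefore contribute information and are
included. A naive i.i.d.-gamma fit to observed gaps
(`naive_gamma_loglik`) is provided for sensitivity analysis only: it
ignores censoring, end effects and chromatid thinning, and is pulled
toward weaker interference because observed gaps are geometric
mixtures over skipped chiasmata.

The escape likelihood sums over all 2^k assignments of events to the
two pathways (escape subsets contribute p^{|S|}e^{−pL}, the complement
the thinned renewal density at rate c = 1−p). Enumeration is exact and
vectorised via a pre-built assignment design; sequences with k > 20
raise rather than silently truncate. At p = 0 the escape likelihood
equals the gamma likelihood to machine precision; at p = 1 it is the
Poisson likelihood — both are regression-tested, as is normalisation
(P₀ + quadrature of the k = 1, 2 densities = 1 within 1e−4 on short
intervals).

Numerical choices: the geometric weights are truncated at j = 39
(weights below 1e−12); probabilities are floored at 1e−300 before
logs; mixture sums use logsumexp where magnitudes vary.

### Fitting, CIs, model choice

Maximum likelihood is bounded: ν ∈ [0.1, 200] optimised on the log
scale (Brent for the gamma model; Nelder–Mead from three starts for
(log ν, p), with p clipped to [0, 1]). Confidence intervals are
percentile bootstrap over *meioses* (not chromosomes), preserving
within-meiosis dependence; 1000 resamples by default. Model choice
uses BIC = −2 ln L + k ln n with k the number of free parameters and
n the number of meiosis × chromosome sequences — "observations" is
ambiguous in common usage, and sequences are the independent units the
likelihood multiplies. Age-stratified fits bin meioses into
equal-frequency bins (default 7) and fit each independently.

Events enter the likelihood at the genetic-map image of the physical
midpoint of their bounding interval; the observable length L is the
chromosome's genetic length under the same sex's map (or the
informative span's genetic length when supplied). Whether to measure
spacing on the genetic or physical scale is a genuine choice; the
genetic scale via the sample's own sex-specific map is the one under
which the stationary-rate-1 model is coherent.

## Genetic maps

A crossover call contributes unit mass spread over the marker
intervals its bounding interval overlaps, proportionally to physical
overlap (the call gives no information about position within the
interval; a midpoint-assignment mode is available as a sensitivity
switch). Interval recombination fraction = mass / N_eff, where N_eff
counts duos whose informative span fully contains the interval — full
containment, because a partially covering span cannot certify
observability of the whole interval. Fractions may be non-integer
numerators; Haldane's function is applied per interval and distances
accumulate to cumulative cM. Since N_eff ≤ N and Haldane is
increasing, the correction can only lengthen the map — this
monotonicity is property-tested, and an uncensored 400-meiosis
simulation recovers a known uniform map's total length within 5%.

The sex-averaged map is the unweighted per-interval mean of the two
sex-specific genetic distances, matching the (female+male)/2
convention for reported totals. Chromosomes 27 and 32 of canFam3.1 are
likely assembled in reverse orientation; `reverse_chromosomes` mirrors
coordinates (an involution) so the telomeric end sits at the distal
coordinate before landscape analyses.

## Landscape statistics

*Telomere share*: dog autosomes are acrocentric and treated as
single-arm with the telomeric end distal (configurable); the share is
pooled genome-wide (sum of in-window cM over total cM) rather than
averaged per chromosome, weighting chromosomes by their genetic
length. *Concentration*: intervals longer than a gap threshold
(default 1 Mb — assembly gaps and marker deserts, unquantified in
common practice) are removed, remaining intervals sorted by rate
descending, and cumulative genetic vs. physical proportions traced;
the curve majorizes the diagonal by construction. Bootstrap bands
resample chromosomes with replacement (1000 draws by default) and are
reported as pointwise 2.5/97.5 percentiles on a fixed physical grid.
*Feature profiles*: physical-length-weighted mean rates in
non-overlapping 10-kb offset bins around anchor points, strand-aware
for TSS anchors. Gene preprocessing keeps protein-coding genes and the
longest isoform per gene. CpG thinning retains at most 5 islands per
non-overlapping 500-kb window, seeded.

*Marker-framework thinning* matches a dense marker set's spacing to a
coarser reference before cross-dataset comparison: markers inside
clusters (gaps below the reference's 5th percentile or half its
median) are removed first, one flank per tight gap and never two
adjacent markers per sweep; then markers are removed uniformly at
random until the median gaps agree (uniform thinning of near-Poisson
marker placement stretches scale without distorting shape).
Convergence requires median agreement within tolerance (default 5%)
and a quantile-based distributional distance below 20% over the
10th–90th percentiles — a quantile distance, unlike an empirical-CDF
supremum, is robust to lattice-valued gaps. Crossover intervals are
then expanded outward to the nearest framework markers (never
narrowed); calls without flanking markers are dropped with a warning.

## QC filters

Call probability: strictly greater than 0.5 retained. Blacklist:
any interval overlap removes the record. Clustered double crossovers:
successive calls in one meiosis whose inner gap (next left boundary −
previous right boundary) is ≤ 1 Mb are flagged; flagged pairs are
removed only when ≥ 2 meioses of the same parent carry flagged pairs
on the same chromosome sharing an identical boundary coordinate — the
conjunctive reading, since an isolated tight pair can be genuine gene
conversion or a real double crossover. Outlier meioses: per sex,
counts outside median ± 4 · 1.4826 · MAD are removed wholly; when
MAD = 0 the non-robust SD is the fallback, and when that is also 0
nothing is removed (a homogeneous dataset has no outliers). Marker QC
excludes on missingness > 5%, duo-level opposite-homozygote Mendelian
conflicts, and flagged genotyping-error probability > 0.9; iterative
pedigree-wide error modelling is out of scope and represented by the
generic error-probability filter.

All filters are idempotent, and the probability and blacklist filters
commute (both are row-local predicates).

## Synthetic data

The simulator is the model restated as a generator, which makes it the
natural oracle for the likelihood: stationarity is achieved by burn-in
(the renewal process starts 20 mean chiasma inter-arrivals before the
chromosome origin) rather than by sampling the equilibrium
first-arrival density, so the generator shares no code path with the
likelihood's closed forms. Defaults mirror the canine study design:
204 meioses per sex, the 38 canFam3.1 autosomes, sex totals of
2162/1816 cM allocated per chromosome proportionally to physical
length (genetic length tracks physical length approximately linearly
in dog pedigree data), gamma shapes 5.22 (female) and 3.73 (male), no
escape pathway.

Physical placement uses a two-segment generating map per chromosome:
interior at relative rate 1 and the distal 5-Mb window multiplied by a
sex-specific telomere bias — default 6.5 for males and 1.15 for
females, chosen so the male distal-5-Mb share is near 38% and the
female share near 10%, the broad-scale sex difference characteristic
of dog pedigree maps. Informative spans cut a uniform random fraction
from each chromosome end (expected total = `censor_fraction`, default
0.1). Retained events are reported as their containing cell of a
uniform 100-kb marker grid, the approximate median resolution of
array-based duo calls; call probabilities are drawn near 1
(1 − 0.5·Beta(1, 15)). Artifacts are labelled at injection: clustered
double-crossover groups (two meioses of one parent, two calls each,
sharing a boundary marker) and outlier meioses (count inflated to a
multiple of the sex's expectation), enabling exact
sensitivity/specificity measurement of the filters.

What the simulator does *not* emulate: genotype-level error processes
(the artifact model is the phenomenological signature, not its cause),
gene conversion, X chromosomes, non-uniform marker spacing, and
fine-scale rate heterogeneity (hotspots) beyond the telomeric bias.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to every failure
mode of real array data.

## Problem sizes in tests

The test suite and the acceptance script scale simulations to what the
checks need: goodness-of-fit uses 10⁴ single-chromosome replicates;
map-length recovery uses 400 meioses on one 100-Mb chromosome;
interference recovery uses 5–20 replicates of the 204 × 38 design
(a single replicate's gamma fit takes a few seconds); bootstrap
confidence intervals in tests use tens of resamples rather than the
default 1000.

## Known limitations

* The escape likelihood's exact enumeration is exponential in the
  per-chromosome event count (capped at 20); adequate for mammalian
  chromosomes (k rarely exceeds 8) but not for aggregated super-scaffolds.
* Burn-in stationarity is approximate to ~e^{−burn-in} effects; with
  20 mean inter-arrivals this is far below sampling noise.
* The effective-meioses profile assumes spans are correct as given; it
  does not model within-span marker sparsity.
* `bp_at` (Morgan → bp inversion) requires a strictly positive rate
  everywhere; zero-rate plateaus make the map non-invertible and raise.
* Bootstrap CIs are percentile-based; no BCa correction.
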