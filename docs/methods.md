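# Methods

This note documents the models behind `polytag`, the defaults and why,
what the simulator does and does not emulate, and the numerical choices a
maintainer would want written down.

## Read-count model

All genotype inference treats the Ref/Alt read counts of a target SNP as
the only observation; "Other" microhaplotypes (off-target variants within
the amplicon) are tallied during parsing but excluded from depth and from
every downstream statistic, so per-cell depth always means Ref+Alt. A
cell is missing below 10 reads (`min_reads`, the platform's confident
calling floor given typical depth > 30); the boundary is inclusive on the
keep side (exactly 10 reads is observed). Sample- and marker-level
filters remove missing rates ≥ 95%, samples first, marker rates then
recomputed on the survivors — the order changes the outcome and is fixed
and logged.

The emission model shared by the simulator and the dosage caller is a
beta-binomial: given dosage *d* at ploidy *m*,

    ξ0(d) = (d/m)(1−ε) + (1−d/m)ε
    ξ(d)  = ξ0 / (h(1−ξ0) + ξ0)
    alt | depth ~ BetaBinomial(depth, ξ(d), ρ)

with allele bias h > 0 (h = 1 unbiased; the map is strictly increasing in
d for any h > 0, ε < 0.5), sequencing error ε ∈ [0, 0.5) and
overdispersion ρ ∈ [0, 1) (binomial limit used below ρ = 1e−8, where the
beta parametrization degenerates). ξ is clipped to [1e−9, 1−1e−9].

## Dosage calling

Marker-wise EM over latent dosages maximizes the marginal likelihood.
The "norm" prior is a normal density evaluated at integer dosages 0..m
and renormalized (floor 1e−10); the "f1" prior is the Mendelian
gamete-combination distribution given the two parents' dosages, which are
estimated first from the parents' own reads (ML under nominal emission
parameters h = 1, ρ = 0.01, ε = 0.005) and then held fixed — joint
updating of parents and offspring was considered and rejected as needless
for diploid families with well-observed parents; a marker whose parent is
unobserved falls back to the "norm" prior with a warning.

Numerics: initialization h = 1, ε = 0.005, ρ = 0.01, μ = m·(pooled alt
ratio), σ = m/4; convergence at |Δ log L| < 1e−6 or 200 iterations, with
up to 3 jittered restarts on non-convergence (the marker is retained and
flagged either way). The (μ, σ) moment update is exact for a continuous
normal but only approximate after integer renormalization, and the
(h, ρ, ε) step is a bounded quasi-Newton move on the expected
complete-data log-likelihood, so *both* are accepted only when the
marginal log-likelihood does not decrease; the EM trace is therefore
non-decreasing by construction (and asserted in tests). `prop_mis` is
mean(1 − max posterior) — a filter of that name is standard but its
estimator is rarely stated; this is ours. Post-dosage filters:
0.05 < h < 2, prop_mis < 0.1, ρ < 0.05, all strict. A marker is
*informative* with ≥ 2 distinct called dosages.

## Ploidy inference

Allele-count ratios (alt/total at observed cells) carry ploidy in their
heterozygous modes: one interior peak (0.5) for diploids, three (0.25,
0.5, 0.75) for tetrasomic tetraploids. Standardization maps per-marker
reference-cluster means onto the expected grid d/m by a piecewise-linear
transform (anchors pinned at (0,0) and (1,1); a marker needs ≥ 2 dosage
clusters with ≥ 3 reference samples each, else it is skipped and logged).

Candidate scoring had to be chosen here (the decision surface — number of
heterozygous classes — is standard; scoring internals are not): each
candidate m is scored by a Gaussian mixture with means fixed at its
interior peaks inside the het band (0.1, 0.9) plus a uniform background
component, weights and a common σ fitted by EM (σ floor 0.01, start
0.05), compared across candidates by per-marker BIC (k free weights + σ).
A plain nearest-peak distance score was tried first and discarded: at the
platform's ~60× depth the het-cluster spread (~0.065) lets a tetraploid
peak set absorb diploid tails, and diploid cohorts score *better* under
m = 4. BIC's parsimony term is what correctly rejects the nested larger
peak set — and is also exactly why first-generation colchicine-doubled
tetraploids (ratios only at 0/0.5/1) are called diploid, reproducing the
method's documented blind spot; second-generation material (one round of
tetrasomic meiosis) recovers odd dosages and is called tetraploid.

The two-pass workflow: pass 1 scores *raw* ratios (the fitted σ absorbs
moderate allele bias), pass 2 genotypes the pass-1-confirmed diploids at
m = 2, standardizes everyone against those reference clusters, and
re-calls. Standardizing pass 1 against all samples under a provisional
diploid assumption was tried and rejected: with non-diploid cohorts the
diploid-referenced anchors warp the interior peaks and destroy the
signal. With fewer than 10 confirmed diploids, pass-1 calls stand (with
a warning). A sample needs ≥ 50 het-band ratios for a call, else it is
undetermined. Candidates default to (2, 4); 3 and 6 are accepted for
generality but off by default for this crop.

## Hybrid sub-genome classification

With B = Σ(Ref+Alt) over the blue-parent samples and C over the
cran-parent samples: a locus is cran-specific if B ≤ 10 < C,
blue-specific if C ≤ 10 < B, shared if both exceed 10, failed (and
excluded) if neither does. "Across the group" is read as the group *sum*
(the stricter reading for absence); a per-sample-all rule is available as
`rule="each"`. Genome-specific loci are dosage-called in hybrids at
ploidy 1 — presence/absence of the amplifying sub-genome's alt allele —
and shared loci at ploidy 4. Ploidy 1 for specific loci follows platform
practice even though two copies of the amplifying sub-genome are present;
ploidy 2 is a parameter away (`specific_ploidy`).

## Two-point linkage

Screening removes, in a fixed logged order: offspring-monomorphic
markers; markers uninformative or impossible given the parents (both
parents homozygous, aa×bb patterns, or observed offspring classes of zero
Mendelian probability); redundant markers (identical offspring vectors,
first kept as representative); markers > 10% missing in offspring; and
segregation-distorted markers (chi-square against the Mendelian ratio,
Bonferroni-corrected with the count of markers reaching this stage as
divisor, removing adjusted p ≤ 0.05).

RF estimation reduces each offspring genotype by the homozygous parents'
fixed contributions, after which a pair's joint genotype table depends
only on which parents are doubly heterozygous and their phases.
Likelihood maximization is a vectorized grid search (251 points in
[0, 0.5], 0.002 resolution — below the sampling noise at any n this
package targets) over all admissible phase configurations per pair class;
phase ties break toward smaller r̂. This replaces a per-pair EM over the
ab×ab ambiguity classes: it maximizes the same phase-enumerated
likelihood and is orders of magnitude faster across the ~10⁵ pairs of a
mid-density panel. A genotyping-error mass of 1e−3 is mixed into the
table so isolated miscalls cannot zero a likelihood. Pairs informative
through different parents only (ab×aa × aa×ab) have no two-point
information in a diploid F1 and are reported unavailable (r = NaN,
LOD = 0), as are pairs with < 10 jointly observed offspring.

Cleaning heuristics: `rf_filter` removes markers with < 2 partners at
r ≤ 0.3 and LOD ≥ 3 (defaults of this package; such filters rarely print
their parameters) or with linked partners on > 3 chromosomes.
`reposition_markers` detaches a marker whose RF to *any* of its ±5
physical neighbors exceeds 0.4 (the any-of reading; all-of is available
via `rule="all"`) and reassigns it when it shows r < 0.1 to markers on
exactly one other chromosome — placement is then linkage-only, with no
physical position; strong links to several chromosomes leave it
unplaced. Reassignment strictly requires prior detachment.

Linkage groups are connected components of the graph with edges at
r ≤ 0.25 and LOD ≥ 5. Among ~10⁵ null pairs a single spurious high-LOD
edge occasionally bridges two chromosomes; when the chromosome number is
known it can be passed as `n_groups`, and the LOD threshold is tightened
in 0.25 steps until that many multi-marker components exist — the same
expected-group-count input that interactive mapping tools take.

The map summary is deliberately two-point, not multipoint: markers are
ordered by physical position (reassigned markers appended, ordered by
their strongest-linked partner), adjacent distances use Haldane's
d = −50 ln(1−2r), an adjacent r ≥ 0.5 caps the gap at 50 cM and is
flagged, and an adjacent pair with no two-point information adds no
length (the chain anchor stays at the last measurable marker, so skipped
markers share its position and the next measurable jump spans the true
distance). Two-point lengths inflate with genotyping error and lose the
unanchored chromosome ends; on simulated 100 cM chromosomes they land
within ~±15%.

## Panel design

Hard filters, all strict: quality > 20, MAF > 0.05, missing rate < 0.75
("missing rate" read literally), exact-test HWE p > 0.01. The HWE test
is the exact conditional test (probabilities of all heterozygote counts
with the observed allele totals, summing the tail no more probable than
observed) — chosen over the chi-square for small-count robustness, and
hand-written since none of the installed statistics packages provides it;
tests cross-check it against independent enumeration.

Selection: per-chromosome quotas proportional to length (largest
remainder), quota-many equal bins per chromosome, the best variant per
bin by priority (QTL flag, then genic flag, then highest MAF), empty bins
backfilled by repeatedly adding the candidate that most reduces the
chromosome's largest gap, and a mandatory list always included and
counted against quotas. Deterministic for fixed input, with per-variant
selection reasons recorded.

## Simulator scope

`SimConfig` defaults are the study conditions of a mid-density cranberry
panel: 12 chromosomes of 41 Mbp (~492 Mbp genome) and 100 cM each, 3059
target loci, founder alt-allele frequencies uniform on (0.05, 0.5),
negative-binomial depth with mean 60 and size 3 (the "depth > 30"
regime; published low/failed-locus depth distributions do not exist, so
non-amplifying cells draw uniform counts between 0 and half the
classification threshold, split across the group), lognormal allele bias
(log-sd 0.2), ρ = 0.01, ε = 0.001. Crossovers follow Haldane's model
(Poisson, no interference), implemented as a per-chromosome Markov chain
over marker intervals — exactly the model the two-point math assumes.
Colchicine generation 1 doubles a diploid draw (even dosages only);
generation 2 crosses two independent gen-1 parents through tetrasomic
(hypergeometric) gametes. F1 contaminants are unrelated founders, the
pollen-contamination analogue. Hybrids are tetraploid (one 2-allele
gamete per parental sub-genome); only amplifying sub-genomes produce
reads. All randomness descends from one seed through named, spawned
streams per operation, so different operations on one config are
independent but reproducible.

What the simulator does not emulate — and hence what passing tests do not
show about real data: linkage disequilibrium and population structure
among founders, locus-specific dropout correlated with sequence
divergence (real cross-species missingness is structured, not i.i.d.),
paralog collapse, segmental allopolyploidy and preferential pairing,
crossover interference, and batch/plate depth effects.

## Test and acceptance problem sizes

Simulation-backed checks run at sizes chosen to make their statistical
assertions sharp but cheap: cohorts of 50 samples × 80–300 loci for
dosage/ploidy recovery, 150–200 offspring × 840 loci (70 per chromosome,
so ~35 informative markers per chromosome survive screening in any one
cross) for linkage, 200 replicates for selection/RF frequency claims.
One acceptance check reproduces the published panel-validation counts
and requires the released 372-sample MADC table; it is not
redistributable here, the check states how to fetch it and fails until
the file is supplied.

## Known limitations

Two-point maps are summaries, not multipoint maps: no marker-order
optimization, no phasing output, no consensus maps across families.
Ploidy calls assume tetrasomic ratio structure (no aneuploidy or
segmental calls). The f1 dosage prior covers diploid families only.
Bit-level parity with any external dosage/ploidy/PCA implementation is
not claimed anywhere; the contract is the model family and the decision
rules.
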