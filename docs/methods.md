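# Methods

This note records the models, estimators, numerical conventions and
design choices behind `clinescan`, in the order the pipeline runs them.

## Data model

A `GenotypeDataset` holds individuals grouped into named colonies, each
colony with a scalar position in km along a one-dimensional transect.
Loci are diploid (microsatellites; calls are unordered allele pairs) or
haploid (mtDNA; one haplotype call).  Allele identity is the literal
label — no size binning is applied, since no binning rule is defensible
in general.  A diploid call is missing iff either allele carries the
zero code (Genepop semantics: no partial calls).  All statistics use
per-locus available-case analysis: an individual missing at locus ℓ
contributes nothing at ℓ but normally elsewhere.  Transect positions
are supplied (colony table or simulator); the package performs no
geographic computation, so "distance" means whatever the supplied
coordinates encode (here: alongshore km).

Genepop I/O accepts both 2- and 3-digit per-allele encodings, detected
per locus from the first non-missing call; mixing widths within a locus
is an error, as are ragged genotype rows and empty POP blocks.

## Synthetic transects

The generator produces the statistical structure the analysis assumes,
not a demographic history.  Two ancestral pools are drawn per locus by
the Balding–Nichols construction: a common ancestral frequency vector
from a flat Dirichlet, then each pool from Dirichlet(ancestral ·
(1−F_pool)/F_pool).  This makes F_pool interpretable on the θ scale
(mean between-pool θ ≈ F_pool, asserted by test within sampling error).
Each individual at position x carries true eastern-ancestry
q(x) = 1/(1+exp(−4(x−c)/w)); a colony's expected allele frequencies are
the q-weighted pool mixture, drifted by a second Balding–Nichols draw
with parameter `drift_fst`.  Genotypes are two independent draws
(Hardy–Weinberg within colonies); mtDNA is one haploid locus whose
haplotype pools diverge by the same F mechanism.

Defaults are the study conditions the pipeline targets: 17 colonies ×
40 individuals over 3000 km, 12 microsatellite loci with 2–8 alleles
(drawn per locus from the seed; truly monomorphic loci are excluded by
default because they carry no information for any estimator here), 14
mtDNA haplotypes, F_pool = 0.25, drift_fst = 0.02, c = 1500 km,
w = 600 km.  Colony positions default to equal spacing and are
user-settable.  What the generator deliberately omits: mutation models
(SMM/IAM), migration matrices, within-colony spatial spread, linkage,
null alleles and scoring error.  Passing recovery tests on this
generator therefore shows the estimators work when their assumptions
hold; it says nothing about robustness to scoring artefacts or
non-equilibrium demography beyond the cline itself.

`simulate_null_shared_center` produces Gaussian quantitative traits
whose means follow sigmoids sharing one center (widths and tails may
differ), used to calibrate the coincidence test's type-I error and
power.

## Diversity and per-colony tests

Gene diversity is the unbiased estimator H̃ = n(1−Σp²)/(n−1) on gene
copies n; for haploid data the same formula is the haplotype diversity
h.  F_IS per colony–locus is 1 − H_o/H̃ (undefined when H̃ = 0); the
across-locus colony value is 1 − ΣH_o/ΣH̃, i.e. per-locus ratios
weighted by their gene-diversity denominators.  The tool the original
analyses used for F_IS does not document its estimator; this simple
form is the default, and per-locus values are exposed so any other
weighting can be recomputed.

**Hardy–Weinberg exact test.**  The null is Levene's conditional
distribution of genotype arrays given allele counts,
P(G) = n!·Πm_a!·2^h / ((2n)!·ΠG_ij!), and the p-value is the total
probability of arrays no more probable than the observed one (the
probability ordering, not the heterozygote-excess U score).  With fewer
than 5 observed alleles the arrays are enumerated and the p-value is an
exact rational sum.  Otherwise a Markov chain runs on explicit
matchings of the 2n gene copies: each step picks two genotype pairs and
re-matches their four copies uniformly over the three perfect
matchings.  The stationary law is uniform over matchings, which
projects exactly onto Levene's distribution — the same family as the
classical switch chain, without hand-derived acceptance ratios.
Defaults: 1000 batches × 1000 steps after 10⁴ burn-in; the batch
standard error of the p estimate is always reported, and tests compare
chain p-values to enumeration within 3 such errors.

**Genotypic equilibrium and genic homogeneity.**  Both are conditional
tests on contingency tables with fixed margins (genotype class ×
genotype class, or allele count × colony), using the log-likelihood
ratio statistic G = 2ΣO·ln(O/E).  The chain permutes explicit item
labels by random transpositions, whose induced table law is the
multiple hypergeometric; p = Pr(G ≥ G_obs).  Monomorphic inputs raise a
distinct "test not defined" error (never silently p = 1); a pooled-pair
table with no variation yields a "no information" marker that is
excluded from across-locus combination.  These exact tests are
conservative on sparse tables (the discrete null support makes p
stochastically larger than uniform); the calibration tests assert
type-I control rather than exact uniformity.

**r̄_d.**  Per locus, the pairwise-individual distance d_ℓ counts
allele differences (0/1/2 for diploids, equal to half the L1 distance
between allele-count vectors); r̄_d = Σ_{j<k} cov(d_j,d_k) /
Σ_{j<k} √(var d_j · var d_k).  Significance comes from permuting
genotypes among individuals independently per locus (999 by default).

**Ewens–Watterson–Slatkin.**  Conditional on (n, k) the probability of
an allele configuration under the Ewens sampling formula is
∝ 1/(Πn_i · Πa_j!) with a_j the multiplicity of count j (θ cancels).
F_obs = Σ(n_i/n)²; the exact p sums the conditional probabilities of
configurations no more probable than the observed one, over all
partitions of n into k parts (enumerated exactly whenever their number
is ≤ 10⁶, which covers all realistic colony sizes; beyond that, a
Chinese-restaurant rejection sampler conditioned on K = k provides
Monte Carlo draws from the exact conditional law).

## Differentiation

θ follows the variance-component formulation: per allele, components a
(among populations), b (among individuals within populations) and c
(within individuals) from sample sizes, allele frequencies and
heterozygote frequencies; summed over alleles and loci before the ratio
θ = Σa/Σ(a+b+c).  A mean of per-locus ratios is never taken.  Haploid
loci use the two-level analogue (MSP, MSG mean squares; no c
component).  Negative estimates are reported as computed — they are
legitimate sampling outcomes.  Colonies with zero gene copies at every
requested locus are excluded with a warning; at a single locus,
colonies without data simply drop from that locus's components.
Correctness is pinned by a test-suite oracle that transcribes the
published formulas literally, step by step, and must agree to 1e-10 on
random tiny datasets.

P[θ = 0] permutes whole individuals (multilocus genotypes, haplotypes
attached) among colonies, p = (1+#{θ* ≥ θ})/(R+1), default R = 1000.

Across-locus combination of pairwise homogeneity tests uses Fisher's
method (X = −2Σln p on 2m df); chain p-values of exactly 0 are clamped
to 1/(draws+1) with a warning, since a finite chain cannot certify
p = 0.  Benjamini–Yekutieli control under arbitrary dependence rejects
the ordered p_(1..i*) with i* the largest i such that
p_(i) ≤ iα/(m·c(m)), c(m) = Σ_{j≤m} 1/j; the realised threshold is
returned.  BY can never reject more than Benjamini–Hochberg, and the
implementation is cross-checked against an independent library
implementation in the tests.

## Isolation by distance

Genetic distance is linearised θ/(1−θ) (negative values pass through);
geographic distance is used untransformed (a log option exists but is
off by default).  The Mantel statistic reported is the Pearson r over
the n(n−1)/2 off-diagonal pairs (Z = ΣA_ij·B_ij is also reported); the
permutation distribution permutes one matrix's row/column order, and
the test is one-tailed for positive association, the IBD direction.
For n ≤ 7 all n! relabelings are enumerated and p is exact; otherwise
p = (1+#{r* ≥ r})/(R+1), default R = 10⁴.

RMA slope = sign(r)·s_y/s_x, the symmetric fit appropriate when both
distance measures carry error.  Bootstrap confidence intervals resample
**colonies** (matrix nodes), rebuild the induced pair set dropping
self-pairs, and take percentile intervals.  Pair-level resampling is
deliberately not the default: pairs sharing a colony are dependent, so
node resampling is the defensible unit even though it is known to
under-cover slightly (the coverage test asserts ≥ 85% at the 95%
level).  Regional analysis fits each named colony subset separately;
for "outside the contact zone" contrasts, the pooled same-side pair set
(west-tail pairs plus east-tail pairs, excluding zone-spanning pairs)
is used, because spanning pairs carry the full between-lineage
divergence and would measure the cline itself rather than background
IBD.

## Admixture clustering

The model: each gene copy has an origin z ∈ 1..K; individual i has
admixture q_i ~ Dirichlet(α,...,α); cluster k has allele frequencies
p_kℓ.  The default correlated-frequencies prior (F-model) draws
p_kℓ ~ Dirichlet(P_ℓ(1−F_k)/F_k) around ancestral frequencies P_ℓ with
per-cluster drift F_k ~ Uniform(0,1).  Gibbs updates for z, q and p are
conjugate; P_ℓ is Metropolis-updated with a Dirichlet proposal centred
on the current value (concentration 300), F_k on the logit scale and α
on the log scale (normal proposals, sd 0.3, α capped at 10).
Acceptance rates are recorded and asserted to land in (0.1, 0.9) on
synthetic defaults.  The uncorrelated model (p_kℓ ~ Dirichlet(λ)) is
fully conjugate and kept as a correctness baseline.  The haploid mtDNA
locus is excluded from multilocus clustering by default (it contributes
one gene copy when admitted via a flag).

Sweep counts default to desk scale (600 sweeps, 200 burn-in) and are
config knobs; model-choice runs in the tests and the acceptance script
use 250 sweeps × 100 burn-in with 3–5 replicates per K, sizes chosen so
a full K = 1..4 sweep completes in minutes while still selecting the
generating K reliably.  The per-K model score is mean(L) − var(L)/2
over the post-burn-in data log-likelihood trace, with the **sample**
variance (ddof = 1) — the convention fixed by test.  ΔK(K) =
|mean L(K+1) − 2·mean L(K) + mean L(K−1)| / sd(L(K)) for interior K;
zero replicate spread makes ΔK undefined there (flagged, excluded from
the argmax), and an all-zero or tied table is flagged rather than
silently resolved.

Label switching across replicates is resolved by exhaustive search over
the K! cluster permutations minimising the summed squared q difference
to a reference run (K ≤ 6 keeps this trivial).  Cluster polarity for
cline input is anchored to the data: the "western" cluster is the one
with the higher mean q in the colony with the smallest transect
position.  Single-locus coancestry runs the K = 2 sampler on one locus;
loci whose second-largest allele count is below 2 are flagged
unfittable rather than returning noise.

## Cline analysis

**Correspondence analysis.**  The mtDNA trait is built by CA of the
colony × haplotype contingency table: SVD of the standardised residual
matrix S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}; haplotypes take their axis-1
standard coordinates and every individual inherits its haplotype's
score, so the trait depends on the data only through haplotype
identity.  The individuals × haplotype indicator matrix was considered
and rejected: for a single categorical variable SᵀS = I − √f√fᵀ, so all
k−1 axes carry identical inertia and "axis 1" is arbitrary; the
colony-table CA is the decomposition with a well-defined first axis and
a meaningful inertia share.  The sign convention (arbitrary in any SVD)
anchors the haplotype commonest in the westernmost colony to a negative
score.

**Cline model.**  y_i ~ Normal(μ(x_i), σ²) with
μ(x) = μ_W + (μ_E−μ_W)/(1+exp(−4(x−c)/w)); the factor 4 realises the
hybrid-zone width convention w = (μ_E−μ_W)/max slope.  A single
residual variance per trait is the default (a tail-specific option
exists but is off: with colony-level positions and desk-scale n, free
tail variances cost identifiability more than they buy realism).  For
fixed (c, log w) the tail means are profiled by linear least squares on
[1−s, s] and σ² by its MLE, so optimisation runs on (c, log w) only:
a 21 × 5 grid of centers across the transect and widths over decades
(span/100 … span), then L-BFGS-B refinement from the best three grid
points, bounded to keep c within one span of the data and w in
[span/1000, 10·span].  The profiled surface is multimodal in c for weak
clines, which is what the multistart buys; everything is deterministic
given the options.  Fits are equivariant under shifting, scaling and
reversing the transect (tested).  Flat traits (zero variance) are
rejected as unfittable; near-flat fits show μ_W ≈ μ_E and are the
caller's signal that the trait is not clinal.

**Coincidence.**  Free model: independent ML fits per trait, summing
log-likelihoods.  Shared model: one common c, per-trait widths, tails
and variances, optimised jointly over (c, log w_1..log w_T) with starts
from the free fits and their mean center.  χ² = 2(Σfree − shared)
clamped at 0 (a small negative value means the shared optimiser out-ran
a free fit's local optimum; beyond 1e-6 relative it warns), df =
n_traits − 1, p from the upper χ² tail.  Unfittable traits are excluded
with a warning and df reduced.  Calibration on shared-center
simulations (2 traits, 400 individuals, 500 replicates) keeps the
empirical size within [0.02, 0.09] at nominal 0.05, and power against
centers 800 km apart (w = 400 km, 600 individuals) exceeds 0.95.

`cline_report` expresses each converged center relative to the nearest
landmark colony (signed km, west negative) and reports the max − min
spread of centers across converged fits.

## Pipeline and reproducibility

The CLI pipeline runs simulate → diversity → fst → ibd → admixture →
cline from one strict-schema YAML config.  Every stochastic stage draws
its seed deterministically from the master seed and the stage name
(seed·1000003 + CRC32(stage) mod 2³¹), so stages are independently
rerunnable; a JSON manifest records per-stage output checksums and wall
time, and a stage whose outputs match its manifest entry is skipped
unless forced.  Stages communicate only through their declared files.

`scripts/acceptance.py --seed S --out f.json` executes the full
analysis on a freshly simulated default transect (680 individuals) and
writes every quantity it computes — overall θ for microsatellites and
mtDNA, the θ permutation p, Mantel r/p, the inside/outside RMA slope
contrast, the ΔK-selected K, cline centers for coancestry and mtDNA
traits, the CA axis-1 inertia share, and the coincidence LRT — as
`{"name": {"value": v, "n": size}}`.

## Known limitations

* The Gaussian cline likelihood is a stand-in for trait models with
  bounded support; coancestry values near 0/1 have compressed noise
  that a beta model would capture.  At the simulated noise scales this
  does not move center estimates materially (recovery tests pass with
  ±75 km), but σ̂² is not interpretable near the tails.
* Exact conditional tests are conservative on sparse tables; combined
  (Fisher) p-values inherit that conservatism.
* The admixture sampler targets desk-scale data (hundreds of
  individuals, tens of loci).  It implements no linkage or
  location-prior extensions, and ΔK — like any second-difference
  criterion — cannot select K = 1; inspect the lnP(D) table when a
  single cluster is plausible.
* Node-resampling bootstrap intervals under-cover slightly by
  construction; treat the reported 95% intervals as approximate.
* The generator draws colony drift independently per colony, so
  background IBD outside the cline is weak (sigmoid-tail gradient
  only); real stepping-stone migration would produce stronger
  distance-decay everywhere.
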