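# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limits of what the test suite demonstrates.

## Study design modeled

Eighteen female pigs in two cohorts (6 and 12 animals) are sampled at nine
ages — 3, 6, 10, 12, 22, 32, 49, 50 and 53 weeks — spanning nursery entry,
growing, estrus/artificial insemination (32 wk), pre-parturition (49 wk),
parturition (50 wk) and weaning of the first litter (53 wk). All 162
samples enter the AMR plate-count panel; a balanced 8-pig subset (4 per
cohort, 72 samples) is sequenced (16S and ITS) and assayed by qPCR. The
stage label is a fixed function of age; one sample per pig-age, no
technical replicates.

## Dirichlet-multinomial mixture enterotyping

A sample's genus count vector x (total n) under component k has

log f_k(x) = log Γ(A_k) − log Γ(n + A_k) + log Γ(n + 1)
           + Σ_j [log Γ(x_j + α_kj) − log Γ(α_kj) − log Γ(x_j + 1)],

with A_k = Σ_j α_kj. The mixture is fitted to **raw counts** (the
likelihood models the library size through the multinomial total), never
to normalized values.

**Estimation.** Generalized EM: exact responsibility and weight updates;
each M-step improves the responsibility-weighted objective over log α_k by
a warm-started bounded L-BFGS step (15 inner iterations, bounds
|log α| ≤ 12). Warm starts make the ascent monotone, which is asserted on
the recorded objective trace in the tests. Initialization is seeded
k-means++ on proportion profiles; five restarts by default; convergence at
relative objective change ≤ 1e-6, cap 200 sweeps. Components with weight
below 1e-6 are pruned with a warning.

**Prior.** The fit is a MAP estimate under an independent Gamma(0.1, 0.1)
prior on every concentration parameter (log-density 0.1·λ − 0.1·e^λ in the
log-parameterization). With ~100 genera and a few dozen samples, many
concentrations are weakly identified; the prior regularizes them and makes
the model-evidence integral proper. This follows standard practice for DMM
community typing. A consequence worth knowing: exact sufficiency under
dataset duplication holds only approximately (the prior does not scale
with n).

**Model selection.** K minimizes the Laplace approximation to the
negative log evidence,
−[log L(θ̂) + log p(θ̂) + (d/2)·log 2π − ½·log det H], d = K·S + (K−1),
where H stacks the responsibility-weighted per-component Hessians of the
penalized objective in log α (verified against central finite differences
in the tests) and the weight-logit block. Ties go to the smaller K. We
deliberately do **not** use the observed-data Hessian of the unpenalized
likelihood: in the n ≪ d regime of this design, each weakly identified
parameter has curvature below 2π and would contribute *positive* spurious
evidence, making the score improve monotonically with K. The per-component
penalized Hessian, which is what established DMM implementations use, has
no such pathology and yields a clean interior minimum at the true K on
synthetic data.

Assignment is by maximum posterior probability (log-sum-exp throughout);
trajectory summaries report per-pig age-ordered label sequences, per-age
enterotype proportions and consecutive-age transition counts.

## Maturation score

Per pig, each genus is assigned the earliest sampled age at which its
relative abundance exceeds 0.5% (per-sample threshold); those onset ages
are ranked within the pig with midranks for ties. Kendall's W on the
complete-case genus submatrix (re-ranked after subsetting, so rows remain
proper rankings) measures cross-pig concordance; its permutation null
permutes each pig's ranks independently, exactly (full enumeration) when
(n!)^m fits within the permutation budget, otherwise by Monte Carlo with
the +1 correction. The consensus order is the per-genus median rank across
pigs (pairwise-complete), ties broken alphabetically. A sample's score is
the unweighted mean consensus rank of the genera present (above the same
threshold) in that sample; presence weighting is binary by design, with an
abundance-weighted variant intentionally not offered as a default. The
grammatically ambiguous "final order per pig vs across pigs" in the
method's verbal description is resolved as a single cross-pig consensus
order, consistent with reporting one score axis.

## Diversity and community structure

- **CSS**: a sample's scaling factor is the sum of its counts that are ≤
  its own q-th count quantile (q = 0.5, linear interpolation, zeros
  included), scale constant 1000. Invariant to per-sample count scaling.
- **Alpha diversity**: richness (features with count > 0) and Shannon
  entropy with natural log; all-zero samples score 0/0 by convention.
- **Bray–Curtis** on CSS-normalized values; undefined between two
  all-zero samples (error).
- **Beta-dispersion**: principal-coordinates embedding of the
  Gower-centered squared-distance matrix; negative-eigenvalue axes
  subtract from squared distances, floored at zero before the square root;
  group centroids (not spatial medians); singleton groups score 0.
- **PERMANOVA**: sequential (Type-I) sums of squares via hat matrices on
  the Gower-centered matrix, term order (age, cohort); permutations
  shuffle samples only within strata (pig) when requested; exact
  enumeration when the permutation group is small enough, else Monte
  Carlo with the +1 correction; a degenerate all-equal distance matrix
  returns R² = 0, p = 1. Pairwise comparisons subset the matrix per group
  pair and BH-adjust across pairs.
- **Shared features**: presence = nonzero count in ≥ min_samples (default
  1) samples of a group; exclusive (UpSet-style) combination counts plus
  per-group totals, the all-group intersection and the union.

NMDS is not implemented: it is a visualization; the inferential content is
covered by the dissimilarity tests and dispersion.

## Mixed models and differential abundance

The random-intercept LMM profiles γ = σ²_group/σ²_resid out of the REML
criterion (block-wise Woodbury identities; one bounded 1-D search over
log(1+γ), snapped to γ = 0 when the boundary does as well within
tolerance). Fixed effects are GLS estimates at γ̂ with Wald tests against
the normal reference — a deliberate choice over likelihood-ratio tests at
these sample sizes. The implementation agrees with statsmodels MixedLM to
~1e-6 on fixed effects in the tests, and with OLS exactly when every group
is a singleton. Post-hoc age contrasts are Wald contrasts with BH
adjustment (a documented stand-in for Tukey-adjusted comparisons, whose
studentized-range reference for mixed models is out of scope).

The differential-abundance scan filters genera below 0.01% mean relative
abundance, transforms y = log(CSS value + pseudo) with a per-genus pseudo
count of half the smallest nonzero value, fits age (continuous weeks) +
cohort with a pig random intercept, BH-adjusts across genera, and calls a
trend by the age-coefficient sign when p < 0.05 and q < 0.25. The
log-of-CSS choice (rather than total-sum scaling) is the single largest
interpretive choice in this module, made because CSS-normalized tables are
the scan's declared input.

## AMR trends and qPCR

log10 CFU/g is modeled as a cubic B-spline in age (knots at age quantiles;
default basis dimension 11 from 9 knots — with only nine distinct ages the
effective degrees of freedom are bounded by the data) plus a linear cohort
term, with an integrated-squared-second-derivative (O'Sullivan) penalty.
The penalty's null space is exactly the straight lines for any knot
layout; a coefficient-difference penalty does not have this property on
non-uniform knots, which is why it is not used. λ is chosen by GCV on the
whitened problem over a log grid (1e-4…1e6, 41 points), with near-ties
resolved toward the smoothest λ so that noiseless polynomial data shrink
to their exact fit. Residual correlation within a pig is continuous-time
AR(1), corr = φ^Δweeks with φ ∈ [0, 1) — the only range for which this is
a valid correlation function in continuous time (nlme's corCAR1 makes the
same restriction). φ is estimated by profile maximum likelihood on the
residual series and the spline refitted on Cholesky-whitened data,
iterating to |Δφ| < 1e-4 (max 20). Coefficient covariance is the
penalized-GLS sandwich; σ² uses n − edf.

Derivative bands are analytic (B-spline derivative basis × coefficients)
with **pointwise** normal quantiles — deliberately not simultaneous, and
the null-coverage consequence (≈5% of grid-pointwise excursions under a
flat truth) is the documented behavior. Change windows are the maximal
grid intervals where the lower bound is positive (increasing) or the upper
bound negative (decreasing), endpoints linearly interpolated at the bound's
zero crossing. No extrapolation outside the fitted age range.

Zero-growth plates are left-censored at the detection limit (default
log10 = 1.7) and excluded from fitting by default; substituting half the
detection limit is available via `censor_substitute`. Drug/bacterium
combinations with no resistant growth anywhere (fluoroquinolones for both
indicators; quinolones for coliforms) are excluded from trend fitting.
Classes with several drugs contribute one AR(1) series per pig × drug.

qPCR copies are standardized by the sample's 16S copies (difference of
log10 values); samples lacking a positive 16S record are flagged and
excluded from standardized models. qPCR outcomes use the random-intercept
LMM with age as categorical contrasts — the spline machinery is reserved
for the plate-count outcomes.

## Synthetic cohort generator

The generator inverts the DMM: each sequenced sample draws a library size
from a per-age log10-normal (week 3 centered near 50K reads, later ages
near 160K, cohort average ≈ 150K), then Dirichlet-multinomial counts from
its age's enterotype profile. The four profiles are built from named
anchor genera (E1: Rikenellaceae RC9/Prevotella/UCG-002; E2:
Megasphaera/Streptococcus/Prevotella_9; E3: Streptococcus/Clostridium
s.s. 1/Treponema; E4: Treponema/Clostridium s.s. 1) plus ten
component-specific companion genera at ~2% relative abundance; all other
genera share a ~0.07% baseline, low enough that overdispersion rarely
pushes them over the 0.5% first-appearance threshold. The trajectory maps
weeks 3–10 to E1, 12 to E2, 22 to E3 and 32–53 to E4, with the last two
subset pigs reverting to E3 from week 49 (the 6-of-8 / 2-of-8 split).

Community evenness is controlled by a single multiplicative concentration
scale per age, monotone from 0.32 (week 3) to 1.23 (week 53) with only a
mild gradient within one enterotype's age span. Both choices are
deliberate calibration: Shannon diversity must rise with age, the
maturation score must rise within pigs, and the mixture must remain
exactly four components — a strong within-enterotype concentration
gradient is hidden substructure that a one-α-per-component mixture cannot
absorb and inflates the selected K, while a high baseline injects rank
noise into the maturation score. Reverting pigs genuinely lower their own
late-age scores; that is designed-in biology.

Fungal counts reuse the DM machinery with a single component, 291 taxa in
two phyla (Ascomycota dominant), a small concentration total (8) for high
inter-pig variance, and a 6× weight bump on four Candida-like taxa at
parturition. AMR observations are class-specific mean curves (high at
week 3, trough near week 10, class-dependent rise over weeks 12–32) plus
a stationary continuous-time AR(1) error per pig × drug (φ = 0.8/week,
marginal sd 0.5); values under the detection limit and the no-growth
combinations are emitted as blanks. qPCR log10 copies follow fixed age
curves anchored at week-3 means of 7.10 (tet(A)) and 5.35 (bla_CTX-M),
with the 16S curve anchored at 10.70 so the standardized tet(A) value
opens at −3.6; pig-level random intercepts (sd 0.3) and noise (sd 0.2)
are added on the log scale. With all noise terms zeroed the generators
reproduce their curves exactly.

Every generator draws from a stream derived from (seed, stage-tag), so a
fixed seed reproduces all tables byte for byte regardless of call order.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: taxonomic assignment error, compositional biases
of extraction/PCR, within-age library-size/batch confounding beyond the
week-3 depth drop, zero inflation beyond what the DM induces, covariation
between the microbiome and AMR outcomes, and drug-level heterogeneity
within a class (one mean curve per class). Parameter-recovery results
certify the estimators, not the biology.

## Problem sizes in the test suite

The acceptance-style checks run the full 72-sample × 100-genus cohort:
model selection over K = 1…7 with 5 restarts across 10 replicate cohorts,
maturation monotonicity across 10 cohorts, 500-dataset null simulations
for the PERMANOVA and LMM type-I error rates (12 samples / 12 pigs each),
and 100-pig panels for spline/AR(1) recovery. These sizes were chosen so
the whole suite certifies every claim in minutes on a single core while
keeping each check at the scale its statistic needs (e.g. ±0.02 on a 5%
rejection rate requires ~500 replicates).

## Known limitations

- The Laplace evidence is an approximation; its absolute value depends on
  the prior and parameterization, so only differences across K are
  meaningful.
- Wald inference in the LMM and the pointwise derivative bands are
  asymptotic; at 8–18 pigs their small-sample calibration is approximate
  (the type-I checks bound the error at the simulated sizes only).
- CSS with a fixed median quantile is a simplification of adaptive-quantile
  implementations; the quantile is exposed as a parameter.
- PERMANOVA's sequential decomposition makes term R² order-dependent, as
  in any Type-I ANOVA; the term order (age, cohort) is fixed and
  documented.
- The DA scan's log-CSS outcome is not compositional; strong trends in
  dominant taxa can induce apparent opposite trends in others (a known
  property of scaling normalizations, visible in the test suite's own
  fixtures).
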