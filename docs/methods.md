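# Methods

## Design and model

An augmented RCBD observes, in each of *b* blocks, every one of *c* check
varieties plus a disjoint share of *n* unreplicated test entries; with the
default conditions (b = 4, c = 3, n = 100) that is 112 plots. The working
model for a plot value is additive,

    y = mu + g (genotype) + beta (block) + eps,

with independent errors of variance sigma2_e. Checks are treated as fixed
(their deviations are design constants, not draws from the genotype
population), which is the classical assumption that lets the replicated
checks estimate block effects and error for everyone else.

## Block adjustment and ANOVA

Block effects are estimated from checks only: effect_j = (mean of check
plots in block j) − (grand check mean), re-centred to sum exactly to zero.
A test entry's adjusted mean is its single observation minus its block's
effect; a check's adjusted mean is the mean of its b plots. These adjusted
means coincide (to 1e-8, tested) with the least-squares estimates of the
genotype means from a full genotype + block fit — the adjustment is just
the closed form of that fit under this layout.

The ANOVA partitions the treatment sum of squares *eliminating blocks* into
Check (df c−1), Accession (df n−1) and Accession-vs-Check (df 1). Every
component is computed as an exact least-squares hypothesis sum of squares:
RSS(model with the component's levels collapsed) − RSS(full model), with
orthonormal-basis projectors cached per layout so Monte-Carlo loops are
cheap. Two consequences, both covered by tests:

- the residual (df (b−1)(c−1)) is identical to the check × block
  interaction and to the full-model OLS residual;
- the Check component coincides exactly with the classical
  b·Σ(check mean − grand check mean)², because checks are balanced across
  blocks; the Accession-vs-Check component is the remainder of the
  partition (equal to the sequential role contrast), so the three parts add
  to the treatment sum of squares exactly.

We deliberately do **not** use the textbook shortcut that sums squared
deviations of the adjusted test values about their mean. Adjusted values
sharing a block are positively correlated (they share the block-effect
estimate, whose variance is sigma2_e(1 − 1/b)/c), which inflates that
shortcut's expectation by sigma2_e·(n/b)(b−1)/(c(n−1)) — about 25 % of
sigma2_e at the default design — and pushes the accession F-test's type-I
error from 0.05 to ≈ 0.09. The exact partition has no such inflation; the
suite verifies a 0.05 ± 0.02 rejection rate under the null over 1000
simulated trials.

The Block row is the checks-based sum of squares c·Σ(block check mean −
grand check mean)² on b−1 df, reported descriptively (its F-test is not the
focus of the analysis and block effects are nuisance here).

Significance codes: `**` p ≤ 0.01, `*` p ≤ 0.05, `ns` otherwise; no
multiplicity correction is applied across traits. A trait whose total sum
of squares is numerically zero returns a structured degenerate table (NaN
F, flagged) rather than propagating NaNs.

## Variance components and derived parameters

Method-of-moments from the ANOVA: sigma2_e = residual MS; sigma2_g =
max(0, accession MS − residual MS), floored at zero with a flag when the
difference is negative; sigma2_p = sigma2_g + sigma2_e. Derived per trait
(x̄ = mean of the adjusted genotype means over all checks and tests):

- GCV = 100·sigma_g/x̄, PCV = 100·sigma_p/x̄ (so GCV ≤ PCV always, with
  equality iff sigma2_e = 0, and h² = (GCV/PCV)²·100 — identities under
  test);
- broad-sense h² = 100·sigma2_g/sigma2_p;
- genetic advance GA = k·h²·sigma_p with h² as a fraction, and
  GAM = 100·GA/x̄. The selection constant k defaults to 2.063, the
  standardised selection differential at a 5 % selected fraction carried at
  three decimals rather than the commonly rounded 2.06; it is configurable.

Category bands: GCV/PCV/GAM are L < 10 ≤ M ≤ 20 < H (the
Sivasubramanian–Madhavamenon convention); heritability is L ≤ 30 < M ≤ 60 <
H.

**Known property, not a bug:** with only (b−1)(c−1) = 6 residual df, the
*per-trial* floored heritability estimate is biased upward at low true h²
(the floor clips the negative half of a very noisy MSG − MSE). The recovery
test therefore aggregates variance components over 500 simulated trials
before forming the ratio — the aggregate is unbiased, and recovers h² ∈
{0.2, 0.5, 0.8} within 4 points. Users analysing a single real trial should
treat low heritability estimates from this design as upper bounds.

## Shannon–Weaver diversity

For each descriptor, proportions come from integer counts (never from
pre-rounded percentages): H_raw = −Σ p ln p in nats, H_norm = H_raw/ln k
with k the number of states **defined in the descriptor dictionary**, not
the number observed — a collection can simply lack states the crop
possesses, and that absence is itself a loss of diversity. k = 1 defines
H_norm = 0. Higher H_norm means more diversity; H_norm is invariant to
state relabelling, never increased by merging states, and maximised by the
uniform distribution (checked by brute-force grid over the 2- and 3-state
simplices).

## Multivariate analysis

All multivariate stages consume the genotype × trait matrix of adjusted
means with complete cases only; traits are standardised to zero mean and
unit sample variance (n−1) before distances or components are formed,
because trait scales differ by orders of magnitude (grams of fruit weight
vs centimetres of fruit width). Correlation p-values use the exact t
reference with n−2 df. PCA is the eigendecomposition of the correlation
matrix; eigenvector signs are fixed by making each component's
largest-magnitude loading positive; components with eigenvalue ≥ 1 are
flagged retained. Biplot trait arrows are loadings scaled by sqrt(lambda).
Clustering sorts genotypes lexicographically first (order invariance, tested),
uses scipy's agglomerative linkage on the standardised Euclidean distance
matrix (complete linkage by default; average and Ward selectable), cuts to
exactly K groups, and reports cluster means in original units. Genotype-level
adjusted means are clustered — not plot-level rows — since the genotype is
the unit of selection. A trait dendrogram is available by clustering the
transposed standardised matrix.

## MGIDI

Rescaling maps each trait linearly to [0, 100] so that 100 is the *desired*
end (max for increase-goal traits, min for decrease-goal ones); constant
traits are dropped with a warning. Default goals are increase for all
traits except the phenology traits (days to male/female flower, days to
first/mature harvest), which default to decrease; goals are fully
user-overridable. The factor model retains the Kaiser set (eigenvalue ≥ 1)
of the rescaled traits' correlation matrix; initial loadings are
eigenvectors scaled by sqrt(lambda); varimax runs without row
normalisation, tolerance 1e-6, at most 1000 iterations, starting
deterministically from the unrotated loadings (no random restarts), and
preserves communalities to 1e-8 (tested). Factor scores are ordinary least
squares, F = Z·A·(AᵀA)⁻¹, with the ideotype row standardised by the
genotypes' means and SDs. MGIDIᵢ is the Euclidean distance of genotype i's
scores to the ideotype's; ranking is ascending with ties broken by genotype
id; factor contributions omega_ij = (gamma_ij − gamma_j)²/MGIDIᵢ² sum to 1
per genotype (a genotype at distance exactly 0 gets a flat 1/f profile by
convention). Selection keeps round(intensity·t) genotypes with round-half-up
(0.20 × 103 → 21). Selection differentials are mean(selected) − mean(all)
per trait, also as a percent of the mean; an expected-gain column SD% × h²
can be attached when heritabilities are supplied.

## Synthetic data

The generator draws test-entry genotypic effects from MVN(0, Σg), block
effects iid N(0, sigma_b²) per trait, and plot errors from MVN(0, Σe);
checks receive fixed deviations (default 0). One value per plot is
simulated — no within-plot plant-level noise — and the qualitative and
quantitative simulators are linked only through shared genotype identities.
Identical config and seed give bitwise-identical tables.

The default configuration is the reference study's conditions: b = 4,
c = 3, n = 100, 17 traits with means set to the published trial means,
sigma2_e to the published residual mean squares, sigma2_g to the published
genotypic variances (two traits whose accession MS fell below the residual
MS get sigma2_g = 0), and block variance back-solved from the published
block mean squares via E[block MS] = sigma2_e + c·sigma2_b (floored at 0).
Genetic correlations use a block structure over the four trait groups a
trait dendrogram of such trials shows (phenology; vigour/yield; fruit size;
leaf architecture) with 0.6 within and 0.1 between groups — chosen once as
a realistic magnitude; the exact correlation pattern of the real collection
is not recoverable from published summaries. Qualitative descriptors are
multinomial at the published state frequencies (counts/103).

What the generator does **not** emulate — and what passing tests therefore
do not certify about real data: spatial field trend within blocks,
genotype × environment interaction, non-normal or heteroscedastic errors,
missing-data mechanisms, and within-plot sampling of individual plants.

## Problem sizes and numerics

Simulation-based tests use: 1000 single-trait trials for the null
rejection rate, 500 per heritability level for recovery, 100 random layouts
for the least-squares equivalence oracle — sizes at which Monte-Carlo error
is comfortably inside the asserted bands while the whole suite stays fast.
Tolerances: exact identities are asserted at 1e-8..1e-12; published worked
examples at their printed precision (2 decimals). Degenerate inputs
(constant traits, zero variance, k = 1 descriptors) return flagged results
rather than NaNs wherever a downstream table would otherwise silently
corrupt.

## Known limitations

- RCBD-augmented layouts only (no row–column or lattice augmentations).
- No REML/mixed-model alternative to the moment estimators; no
  narrow-sense heritability.
- The published tables this package's worked examples reproduce print MS at
  2 decimals; traits with tiny mean squares are therefore not exactly
  recomputable from print, and the examples use the two rows that are.
- Clustering and MGIDI results on real data depend on choices (linkage,
  goal vector) the user must set; defaults are documented above, not
  universal truths.
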