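# Methods

`demap` analyses differential epistatic miniarray profile (dE-MAP) screens:
quantitative genetic-interaction screens of query gene deletions crossed
against an array of deletions, scored per growth condition with an S-score
(positive = alleviating, negative = aggravating double-mutant fitness), with
one unstressed control condition and one or more stress conditions.  The
package covers the statistical chain from per-condition S-score matrices to
differential interaction networks, enrichment and gene–complex association
statistics, genetic-profile correlation analysis, and integration with
external conditional regulatory gene sets, plus a synthetic screen generator
that provides planted ground truth for every stage.

## The differential z-score

S-score measurement noise is not homoscedastic: its standard deviation grows
with the magnitude of the underlying interaction.  A stress score is
therefore judged against a local null learned from the control condition.
Gene pairs are ranked by their control score `S_control`; inside a sliding
window of fixed size over that ranking, the mean and sample standard
deviation of the paired *stress* scores estimate the conditional moments
`mu(S_control) = E[S_stress | S_control]` and `sigma(S_control) =
sd[S_stress | S_control]` as piecewise-constant non-parametric functions.
The differential z-score of a pair is

    z = (S_stress − mu(S_control)) / sigma(S_control),

approximately standard normal for pairs whose interaction does not change
with the stress.  Note that `sigma` is a *conditional* scale: it absorbs
both the measurement noise of the stress score and the dispersion of latent
interaction strengths among pairs with the same control score, so it is
generally somewhat larger than the raw per-measurement noise sd.

Numerical details:

* **Window definition.** The window for a value `s` is the `window_size`
  pairs nearest to `s` in control-score rank, clamped at the ends of the
  ranking so every window has exactly `window_size` members.  Evaluation at
  an arbitrary `s` uses binary search (left insertion point); the fitted
  moments are piecewise constant between observed control values.
* **Window size.** The default is `max(50, 2.5%)` of the non-missing pair
  count: large enough for a stable sd estimate, small enough to track the
  magnitude dependence.  It is a configuration knob everywhere.
* **Sigma floor.** `sigma` is floored at 10% of the global sd of the
  windowed variable (configurable), so that degenerate flat windows cannot
  produce unbounded z-scores.  All-identical inputs yield `sigma = floor`
  rather than an error.
* **Per-screen fitting.** Moments are fitted per (stress condition, screen)
  from that screen's own control table; replicate screens had separate
  control platings and are never pooled implicitly.
* **Missing data.** A pair missing in either condition is excluded from
  differential testing; no imputation.
* **Thresholds.** Calls are boundary-inclusive: static interactions at
  |S| ≥ 3, differential interactions at |z| ≥ 2, and a relaxed |z| ≥ 1.7 used
  only inside the gene–complex association test, where per-complex counting
  recovers specificity.  Network overlap fractions compare sign-agnostic
  (query, array) pair identity by default; a sign-matched mode exists.

## Enrichment and gene–complex association

All enrichment tests condition on testability: the sampling universe is the
set of (query, array) pairs — or array genes — actually measured in the
relevant condition, never the whole genome.  Pair-level enrichments (pairs of
stress-sensitive genes; kinase–substrate and phospho-regulated pair classes)
use the hypergeometric upper tail; "sensitive pair" means both endpoints in
the sensitivity list by default.

Gene–complex association asks, for each query gene q, each complex C with at
least 4 members on the array, and each condition: do q's differential
partners (|z| ≥ 1.7) overlap C more than expected given q's differential
degree, |C|, and q's testable array universe (hypergeometric upper tail)?
False-discovery rates are estimated per (query, condition) family by
permuting complex-membership labels across the array genes (1,000
permutations by default, seeded), which preserves complex sizes and the
query's degree: `FDR(p0)` = mean permuted count of tests with p ≤ p0 divided
by the observed count, clipped to [0, 1] and made monotone non-decreasing in
p by a reverse cumulative minimum.  Associations with FDR < 15% are
reported, and the per-complex total of significant (query, condition)
associations gives the stress-responsiveness ranking of complexes.

Gene-level integration with regulatory evidence builds a 2×2 table of
{array genes with ≥ 2 differential interactions} × {regulated genes} over the
testable array universe and applies Fisher's exact test (two-sided by the
sum-of-smaller-probabilities convention, with one-sided tails also
reported); fold is the regulated fraction among differential genes over the
universe-wide regulated fraction.

## Profile correlations and rewiring tests

Each query's vector of S-scores across the array is its genetic
"finger print".  Per condition, pairwise-complete Pearson correlations are
computed over array genes scored for both queries; cells with fewer than 30
shared genes (configurable) or zero-variance profiles are masked.
Hierarchical clustering uses average linkage on distance 1 − r (the E-MAP
literature convention), with rows pre-sorted by label so ties and hence leaf
order are deterministic; masked cells are imputed as 0 with a warning.

Condition-induced correlation shifts between two query groups are tested by
comparing Δr = r_stress − r_control over cross-group pairs against the Δr of
all other query pairs with a two-sided Wilcoxon rank-sum test.  The test is
exact by enumeration up to a combined sample of 12 (ties handled on the
value multiset), exact via the tie-free rank-sum distribution up to 50, and
a tie-corrected normal approximation with continuity correction beyond that.
The normal tail is only accurate to a few percent at small sample sizes,
which is why exactness is preferred wherever feasible.

## The synthetic screen generator

The generator emulates the study conditions end to end: 49 query × 1,200
array genes, a control plus five stress conditions (high-osmotic sorbitol,
oxidative H2O2, the cell-wall stresses zymolyase and Congo red, and
caffeine), optional replicate screens with independent noise, and 2% missing
cells.  Its components:

* **Interaction backbone.** 5% of pairs carry a latent static interaction of
  magnitude ±U(3, 8) — the scale at which |S| ≥ 3 calls operate.
* **Noise.** Each measurement adds Gaussian noise with
  sd = min(sd0 + slope·|S|^γ, sd_max), defaults sd0 = 1, slope = 0.25,
  γ = 1 (a configurable non-linear exponent), sd_max = 3 — the curve's value
  at the top of the interaction range, so the cap only prevents unbounded
  growth for very large planted shifts.  For stress measurements |S|
  includes the planted shift: a strongly shifted pair is measured with the
  noise of a strong interaction.
* **Planted differential pairs.** 200 scattered pairs per stress receive a
  shift of ±U(4, 10) × the pair's own (capped) noise sd, solved by fixed
  point so the multiple refers to the noise of the *shifted* measurement.
  The range straddles the |z| = 2 threshold from both sides by design.
* **Complexes.** 15 array-side complexes (sizes 4–20, the ten used for
  association planting at 25–30).  Members share a few (default 3) strong
  query interactions with per-member jitter, which is what correlates
  complex-member profiles in real screens (mean member-profile r ≈ 0.3).
  Associations are planted into the larger complexes deliberately: with a
  per-pair null call rate of ~9% at |z| ≥ 1.7, a 4-member complex can never
  reach permutation FDR < 15%, while a 25–30-member complex gives per-
  association recovery near 1 at 5× concentration — mirroring the fact that
  large complexes (ribosome, nuclear pore) dominate real association
  rankings.
* **Query–complex associations.** For each planted (query, complex,
  condition) triple, each member receives a differential shift with
  probability 5 × the background differential-call rate at the association
  threshold (the Gaussian null tail at 1.7 plus the scattered-pair rate),
  i.e. the query's partners concentrate in the complex at 5× background.
* **Query modules and rewiring.** Four 4-query modules share dense array
  signatures (weight 0.6); under zymolyase two of them additionally gain a
  common signature (weight 1.2), raising their cross-group correlations by
  ~0.1–0.2, while the other two form a matched null pair.  The module
  signature weight is kept deliberately moderate: cross-group correlations
  share the signature realizations, and strong shared signatures make the
  cross-group Δr values co-move, which would inflate the null-module flag
  rate of the rank-sum test above its nominal level.
* **Determinism.** All randomness flows from one integer seed through
  numpy's SeedSequence; identical seeds give bit-identical screens.

An optional helper collapses simulated replicate colony sizes into a score
via a simple variance-floored modified t-statistic; it is a deliberately
minimal toy scorer, not a colony-image pipeline.

### What the generator does not emulate

Plate-position and batch effects, the correlation structure of real colony
measurements, linkage between neighbouring genes, non-Gaussian noise tails,
and realistic gene-name structure.  Passing recovery tests on this generator
therefore demonstrates the statistical machinery under the stated noise
model, not robustness to every artefact of real plates.

### Known limitation: spurious associations at strong static interactions

On the structured default screen, the association test reports more
significant (query, complex, condition) triples than were planted.  The
mechanism is inherent to the method, not a defect of the FDR estimator
(which reports ~1% under shuffled membership labels): pairs with strong
static interactions carry ~3× the measurement noise of null pairs, and when
the control draw of such a pair lands in the null-dominated mid-range, the
stress draw re-expresses the latent interaction and |z| is large.  These
spurious differential calls concentrate in exactly the complexes that share
strong interactions with a query, and membership permutation cannot
distinguish them from planted signal.  Interpreting associations for
complexes that already interact strongly with the query in the control
condition therefore warrants caution — in real screens as much as here.

## Problem sizes used in validation

The validation suite runs the generator at the study scale (49 × 1,200, five
stresses) for recovery and calibration checks, at 85 × 1,200 (~100,000
pairs) for null calibration, and across 20–40 seeds for the profile-rewiring
detection rates; brute-force oracles (window re-sorting, exhaustive
hypergeometric/Fisher/rank-sum enumeration) run on small instances where
enumeration is exact.  These sizes give Monte-Carlo margins of about one
percentage point on tail rates while keeping the whole suite fast.
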