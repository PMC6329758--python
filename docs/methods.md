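# Methods

## Problem setting

Case–control connectome studies compare two groups of subjects, each
described by an R×R weighted connectivity matrix (streamline counts from
tractography, or functional correlation indices).  The question is *which
edges*, taken together, distinguish the groups.  The regime is always
n ≪ p: tens of subjects against thousands of edges, with heavily correlated
edge weights.  Mass-univariate testing (one t-test per edge with family-wise
correction) has low power here and is blind to effects that only exist
jointly across several edges.

## The model

Connectivity matrices are vectorized into a design matrix **X** (n subjects ×
p edges; strict upper triangle for symmetric matrices, all off-diagonal
entries for directed ones; the diagonal is always dropped) and group
membership into an n×K indicator matrix **Y** (K = 2 throughout).  Sparse
discriminant analysis is solved in the optimal-scoring form: find a score
vector θ ∈ R^K and a discriminant vector β ∈ R^p minimizing

    ‖Yθ − Xβ‖² + η‖β‖₁ + γ‖β‖₂²
    s.t.  (1/n)·θᵀYᵀYθ = 1,   θᵀYᵀYθ_l = 0 for earlier directions l,

an elastic-net regression of the scored labels on the edges.  The ℓ1 weight
η is re-parameterized as **α, the number of edges retained**: the lasso path
of the ridge-augmented problem ([X; √γ·I], [y; 0]) is followed with LARS
until α variables are active, and the η at that knot is recorded, making the
α ↔ η duality explicit.  At the returned point the KKT conditions hold in
the ½-gradient convention: |x_jᵀ(y − Xβ) − γβ_j| = η/2 on the active set and
≤ η/2 off it (verified against an independent coordinate-descent solver to
10⁻⁶).

For two classes the constraint set contains a single score vector up to
sign, so the alternating β/θ optimization converges in one or two sweeps;
θ's sign is fixed (first nonzero entry positive) to remove run-to-run
flips.  Classification assigns a subject to the class with the nearest
centroid in discriminant-score space, ties to the lower class code — the
standard optimal-scoring LDA rule.  β is not re-estimated on the active set
after selection.

## Two-stage edge selection

A single sparse fit is unstable: small data perturbations change the active
set.  The pipeline therefore

1. fits one SDA model per resample of the cohort (an ensemble),
2. counts per-edge occurrences across members, and
3. keeps edges occurring at least ⌈n/2⌉ times ("half the subjects"),
   a trade-off between keeping everything ever selected and keeping only
   unanimous edges.

Resampling schemes:

* `leave_one_out` (default) — one member per subject, trained on n−1; the
  held-out predictions give an ensemble accuracy estimate.
* `bootstrap` — B stratified resamples with replacement.  With **B = n**
  members the half-the-subjects threshold is exactly a 50% selection-
  frequency cutoff.

**A limitation worth knowing:** leave-one-out perturbs each member by one
subject only.  At simulation scale (n ≈ 30, p ≈ 500) the maximal spurious
noise correlations survive every fold, so under a pure-noise cohort the top
noise edges are selected by *all* members and the occurrence threshold
prunes nothing.  The bootstrap mode, whose members each omit ~37% of
subjects, restores the intended behavior (median null selection ≤ 2 edges in
our studies).  All simulation studies in the test-suite and the acceptance
script therefore resample by stratified bootstrap with B = n; leave-one-out
remains the default for data analysis because it is the scheme the original
procedure prescribes, and its accuracy estimate is the familiar jackknife.

Occurrences are counted over this single (outer) ensemble; the nested inner
resamples used for tuning do not contribute counts.

## Hyperparameters

* **α** (positive integer ≤ p): the number of edges each ensemble member
  retains.  The single knob a user should expect to adjust; larger α only
  adds selected edges (empirically, the stability-selected sets are nested
  along an α grid in ≈100% of our runs).
* **γ** (≥ 0): ridge weight, dimensionless on z-scored edges (per-column
  Gram mass is ≈ n−1, so γ of order n is "strong").  Two regimes matter:
  - γ ≳ n (grouping regime): path entry order approaches marginal
    class-alignment ranking; correlated edges carrying a shared univariate
    effect are recovered stably.  The reference univariate-recovery studies
    use α = 13, γ = 30.
  - γ small (multivariate regime): entry order is driven by partial
    correlations, preserving jointly-discriminative sets whose members are
    marginally weak.  The multivariate-contrast study uses α = 13, γ = 0.1.
  This mirrors per-dataset tuning of (α, γ) in practice; the nested tuner
  below automates it.
* `tol = 1e-6` on the score-vector change and `max_iter = 100` alternating
  sweeps — conventional optimal-scoring settings, exposed in config.

### Nested tuning

`tune_parameters` draws ordered (validation, test) subject pairs without
replacement — capped at min(1000, n(n−1)) iterations — fits every grid pair
on the remaining n−2 subjects, scores the grid on the inner (test) subject
and estimates the error of the winner on the outer (validation) subject,
which was removed before the optimization.  On an error plateau the pair
yielding the fewest stability-selected connections wins; remaining ties go
to the smaller α, then the smaller γ, making the choice deterministic.

## Baselines

**Network-based statistic (NBS).**  Per-edge two-sample t-tests
(pooled-variance two-sided by default, Welch by flag; the primary p-value
threshold is converted to the equivalent |t| cutoff); suprathreshold edges
form a graph whose connected components are candidate subnetworks.
Family-wise control comes from the permutation distribution of the maximal
component statistic under wholesale group-label shuffles, with the +1
correction (p-values never exactly zero).  Component statistic: `extent`
(edge count, the classic choice, default) or `intensity` (summed |t|).
Extent is integer-valued; the heavy ties in its permutation null make the
test conservative on small graphs (empirical family-wise rejection ≈
0.00–0.03 at nominal 0.05), which is why the calibration and power studies
use the continuous intensity statistic.  Zero-variance edges get t = 0,
p = 1 with a warning rather than an error.

**SVM weights.**  One linear SVM (C = 1 by default, features standardized —
primal weights are only comparable across edges on a common scale) on the
true labels; per-edge null bands from the 5th/95th percentiles of weights
over label-permutation refits; edges outside their band are selected.
Under the null this selects ≈10% of edges by construction.

## Synthetic cohorts

The generator emulates the statistical shape of the motivating studies —
two groups, n ≪ p, correlated edges — not their anatomy.

* **Background**: equicorrelated standard normal edge weights (a shared
  per-subject factor gives a single correlation ρ, default 0.2), mapped
  through a Gaussian copula onto Poisson margins when integer fiber-count
  weights are requested.
* **Univariate planted edges**: group 1 shifted by d·σ (d a standardized
  mean difference; the reference recovery study plants five scattered edges
  at d = 2 in a 32-node network, p = 496 — the closest symmetric network to
  500 edges).
* **Multivariate-only pairs**: two edges with within-pair correlation c
  (default 0.9, ≥ ρ) whose sum is identically distributed in both groups
  while their difference shifts by d standard deviations of the difference,
  i.e. by d·σ·√(2(1−c)), split antisymmetrically.  Each edge's marginal
  standardized difference is d·√((1−c)/2) — 0.45 at d = 2, c = 0.9, weak
  enough that per-edge t-tests miss it in the majority of cohorts — while
  the pair jointly separates the groups sharply.  At c = 0 this reduces to
  the textbook independent-pair construction, whose marginal effect
  (0.707·d) would be individually detectable and defeat the purpose.
  The contrast study uses a 12-node network with 50+50 subjects so that the
  pair competes realistically with background noise.

What the simulations do **not** model: network topology (small-world or
modular structure), heteroscedastic or heavy-tailed tractography noise,
site effects, and spatially structured correlation.  Passing these studies
shows the machinery behaves as designed under its own assumptions, not that
any particular real dataset will yield stable edges.

## Reference study results

Computed from scratch by `scripts/acceptance.py` (sizes in parentheses):
elastic-net solver vs coordinate-descent oracle agreement (25 instances);
score-constraint residuals (8 fits); planted-edge recovery, null selection
size and ensemble held-out accuracy (20 cohorts each, 15+15 subjects,
p = 496); multivariate-pair detection vs NBS silence (20 cohorts, 50+50
subjects, p = 66); α-nesting over {5, 9, 13, 17, 21} (40 cohorts); NBS
family-wise null calibration (200 cohorts × 500 permutations) and SVM null
selection fraction (20 cohorts × 500 permutations); byte-identical reruns.

On the recovery study, expect all five planted edges with ≤1 false positive
in roughly 16–17 of 20 cohorts.  The misses are not a solver property: at
n = 15+15 the *realized* standardized difference of a nominal d = 2 edge has
standard error ≈ 0.37, and with probability ≈ 0.3 at least one of the five
planted edges realizes d ≲ 1.4 — inside the bulk of the 491 noise edges'
label correlations, where no selector that also controls false positives
can find it.

## Numerical notes and degenerate inputs

* All randomness flows through `numpy.random.default_rng` seeds recorded in
  the run log; identical config + seed gives byte-identical outputs.
* If the LARS path skips the requested active-set size (simultaneous entry
  under exact ties) the last knot not exceeding α is returned; if the path
  saturates below α, the least-squares end of the path is returned.
* β = 0 (fully shrunk model) yields an all-lower-class prediction with a
  warning, never a crash; a fold whose removal empties a group is an error
  under leave-one-out (groups of two or more are required).
* Zero-variance columns are centered, flagged, and never scaled.
* Stability thresholds above the member count warn and return an empty
  selection — a legitimate exploratory setting, not an error.
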