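# Methods

## The model and its conditioning

`divclock` fits the constant-rate reconstructed birth–death process to
the branching times of an ultrametric tree. Each lineage speciates at
rate λ and goes extinct at rate μ (events/lineage/My); each extant
species is sampled independently with probability f (ρ-sampling). The
likelihood is conditioned on the crown age and on both crown lineages
leaving sampled descendants — the natural conditioning for a tree dated
at its crown, and the one our simulator reproduces (it starts from two
crown lineages and discards replicates in which either crown lineage
leaves no sampled tip). Conditioning only on survival of the process,
or not at all, would bias λ̂ upward or downward on crown-dated trees;
no alternative conditioning is currently exposed because the generator
and estimator are intentionally matched.

The survival function E(t) and single-lineage density p₁(t) given in
the README are evaluated in log space. Two numerical regimes need
care:

* **λ ≈ μ** (critical process): the generic expressions degenerate to
  0/0. When |λ − μ| ≤ 10⁻¹² · max(λ, μ, 1) the closed forms
  1 − E(t) = f/(1 + fλt) and p₁(t) = (1 − E(t))²/f are used instead;
  a unit test checks continuity across the switch.
* **λ < μ**: the numerator and denominator of E(t) are both negative
  and the same expressions remain valid probabilities; parameter
  combinations that push E outside [0, 1] or p₁ below 0 (possible only
  for degenerate input) return −∞.

## Estimation

`fit_bd` maximizes the log-likelihood over λ > 0, μ ≥ 0 with L-BFGS-B
from five starts: a method-of-moments λ guess (the crown-conditioned
Yule MLE, inflated by 1/f under incomplete sampling) crossed with
relative-extinction starting values {0, 0.25, 0.5, 0.75, 0.9}.
Convergence tolerance is ~1e-12 in the scaled objective; the best
start wins. A μ̂ below 10⁻⁶·λ̂ is snapped to the μ = 0 boundary after a
one-dimensional re-polish, so pure-birth fits report μ̂ = 0 — and hence
ε = 0 — exactly, matching the boundary rows of the published table.

95% intervals are profile-likelihood intervals: the profiled parameter
is fixed on a grid walked outward from the MLE, the nuisance parameter
re-optimized (bounded Brent), and the boundary located by root-finding
where the profile drops 1.92 units (χ²₁ 0.95/2) below the maximum. The
lower μ bound is truncated at 0. Wald intervals would misbehave
exactly where the published data live (μ̂ on the boundary), which is
why the profile construction is used throughout.

Relative extinction is ε = μ/λ — the standard definition, and the one
the published per-clade values arithmetically satisfy. For cross-clade
regression λ is log-transformed in **base 10** and ε squared; base 10
is fixed by recomputing the published non-phylogenetic slope (91.18 per
unit rate), which a natural log would multiply by ln 10.

## Clock summaries

The mean rate is the branch-duration-weighted average of per-branch
substitution rates; the CV is the weighted population standard
deviation over the weighted mean (the convention of relaxed-clock
dating software for its coefficient-of-variation statistic). Both are
invariant to subdividing a branch into collinear halves and to branch
reordering; an unweighted CV is available behind a flag for
sensitivity analysis. A strict clock returns CV = 0 exactly (equal
rates short-circuit the variance computation). Node density counts
internal nodes *including the root* over the crown age; the inclusion
of the root is a convention — it shifts the covariate by 1/crown-age
and is harmless to the correlation screen it feeds.

Branch rates are conveyed either as BEAST-style `[&rate=…]` branch
annotations or as a chronogram/phylogram pair with identical topology
(rate = substitutions-length / time-length per branch). Trees are
written with 12 significant digits so rates and ages round-trip.

## Contrasts and regressions

Felsenstein's recursion produces k − 1 standardized contrasts on a
binary k-tip backbone; the ancestral value at each node is the
1/variance-weighted daughter average (arranged so equal daughters give
exactly-zero contrasts) and the parent branch is augmented by
v_l·v_r/(v_l+v_r). Punctuational mode sets every starting branch
length to 1. Polytomies error under the default "strict" policy or are
resolved arbitrarily with zero-length branches under "zero_length"
(flagged), since a published megatree's resolution generally cannot be
reconstructed.

The through-origin regression uses slope Σcₓc_y/Σcₓ², the uncentered
r² = (Σcₓc_y)²/(Σcₓ²Σc_y²), and F = r²/(1−r²)·(k−2) on (1, k−2)
degrees of freedom, two-sided p from the exact F distribution; this
keeps the F/r² identity and matches the behaviour of the standard PDAP
implementation. Contrast pairs are positivized (sign flipped so the
x-contrast is ≥ 0) — a plotting convention that provably changes no
statistic, which a test asserts. The slope is identical to the GLS
slope under the Brownian covariance of the same backbone; an
independently coded GLS oracle checks this to 1e-8 on random trees.
No multiple-testing correction is applied anywhere in the battery,
deliberately mirroring the analysis design this package reimplements.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *assumed* data-generating process of the
analysis, so that every estimator can be tested against known truth:

* Chronograms: forward Gillespie simulation from two crown lineages.
  Conditioning on a tip count uses first passage at n with a stop time
  drawn uniformly inside the first holding interval at n lineages,
  avoiding the branching-time bias of stopping exactly at the n-th
  birth. Conditioning on time requires both crown lineages to survive
  (retried up to 1000 replicates; the retry draws flow from the same
  generator, preserving determinism).
* Incomplete sampling: each tip kept independently with probability f,
  conditional on ≥ 2 survivors.
* Relaxed clock: i.i.d. lognormal branch rates parameterized by their
  *expectation* (log-mean = ln m − s²/2), so the generating mean is
  directly comparable to the weighted mean rate; the generating CV is
  √(e^{s²} − 1).
* Study mimic (`simulate_study`): a Yule backbone; clade-level clock
  means evolved by Brownian motion from 4·10⁻³ subst/site/My
  (σ² = 10⁻⁷ /My, reflected above a 2·10⁻⁴ floor to keep rates
  positive); true log₁₀λ = a + effect·clock_mean + Brownian noise
  (σ² = 2·10⁻³ /My); per-clade ε uniform on [0, 0.9]; tip counts
  uniform on [47, 304]. These defaults are the study conditions this
  package models: 13 clades of those sizes, rates spanning ~1–8·10⁻³,
  CVs ~0.4–1.1, ε up to ~0.9, and an effect size of 91 on the
  log₁₀λ-per-rate-unit scale.

What the simulator does **not** emulate: sequence-level noise and
alignment error, dating/calibration uncertainty (node ages are exact),
autocorrelated clocks, diversification rate variation through time or
among lineages, and non-uniform taxon sampling. Passing recovery tests
therefore demonstrate correctness of the estimators *under the model's
own assumptions*, not robustness of the scientific conclusion to
violations of them.

## Problem sizes and numerical choices

Ultrametricity is enforced within a relative tolerance of 10⁻⁶ of the
crown age (calibrated trees carry float noise). Simulation-based
checks use sizes at which the statistical targets are comfortably
testable: 200 replicates of 200-tip trees for λ recovery and CI
coverage (median λ̂ within 15%, coverage ≥ 88%), 60 replicates for the
f = 0.5 sampling-correction contrast, 2000 replicates for the 5%
type-I calibration of the contrast regression, and a single 500-tip
tree for the lognormal clock closed forms. `scripts/acceptance.py`
uses 100/40 replicates for the recovery block; all sizes are the
package's own choice of a precision/effort trade-off and are recorded
in the scripts themselves.

## Known limitations

* The likelihood assumes rate constancy in time and across lineages;
  clades violating this will push μ̂ to the boundary or inflate ε.
* Profile CIs are reported unconditionally, but on the μ = 0 boundary
  the χ²₁ calibration is conservative (the drop statistic there is a
  50:50 mixture of χ²₀ and χ²₁).
* Published per-clade λ/μ/mean-rate values cannot be recomputed from
  first principles without the original sequence data, MCMC runs and
  per-clade sampling fractions; only the ε column and the
  non-phylogenetic regressions are desk-reproducible, and the ε
  comparison is limited by the 3-d.p. rounding of its printed inputs.
* The published contrast statistics depend on an unpublished backbone
  topology; the contrast machinery is therefore validated against GLS
  and simulation oracles rather than against those printed values.
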