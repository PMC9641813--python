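# Methods

This note documents the models behind `scaleshort`, the defaults it ships
with, what the synthetic-data generator does and does not emulate, and the
numerical and design choices that were genuinely open.

## Response model and scoring

The unit of analysis is a persons × items matrix of ordinal responses
coded 1..5 ("extraordinary" to "none at all"). All items share one
direction — higher codes mean milder symptoms — so no reverse coding is
applied. Missing values are rejected at input; the pipeline assumes
complete questionnaires.

Totals over a k-item scale are standardized linearly to 0–100:

    score = 100 · (raw − k·min_cat) / (k · (max_cat − min_cat)),

so the all-minimum pattern maps to 0 and the all-maximum pattern to 100
(for k = 7 the attainable floor above zero is 100·3/28 = 10.71 at raw 10).
Quartiles of score distributions use linear interpolation between closest
ranks; the convention is configurable via numpy's quantile methods because
statistical packages differ here.

## Synthetic data

The generator draws a latent quality-of-life trait θ ~ N(0, 1) per person
and a response per person-item from a generalized partial credit model
(GPCM),

    P(X = c | θ) = exp( Σ_{v≤c} α(θ − β_v) ) / Σ_{c'} exp( Σ_{v≤c'} α(θ − β_v) ),

with categories 0..4 internally and codes 1..5 in all I/O. The packaged
default bank is the published GPCM calibration of the ten SPD-10 items
(discriminations 0.194–0.987, thresholds −2.97..3.23); the default sample
size is the instrument's original n = 164. The standard-normal trait is the
conventional identification of the GPCM scale and is assumed throughout.

What the generator emulates: a unidimensional ordinal instrument with
locally independent items of realistically heterogeneous quality, including
one nearly uninformative item (CRF7) and non-monotone threshold orderings.
What it does not emulate: local dependence between symptom items, minor
secondary dimensions, response styles, or missingness — all present in real
questionnaire data. Consequences that matter for interpreting tests: the
synthetic population is slightly *more* reliable than the real one
(population Cronbach alpha ≈ 0.81 versus the published 0.795), and its
D-study dependability at six items sits marginally above the 0.70 cutoff,
so the GT stage frequently concludes six items suffice where the original
data required seven. Passing tests therefore demonstrate correctness of the
procedures under the model's assumptions, not that real data would
reproduce every published number.

## Generalizability theory

Single-facet persons × items random design. Variance components come from
equating ANOVA mean squares to expectations (σ²pi = MS_pi,
σ²p = (MS_p − MS_pi)/n_i, σ²i = (MS_i − MS_pi)/n_p), truncating negative
estimates at zero, the standard GT practice. The D-study projects indices
on the per-item mean-score metric (components of 1–5 category scores,
divided by the hypothetical form length n′); the 0.20 error-variance
cutoffs are interpreted on that metric, which matters because they are not
metric-invariant. Thresholds are applied strictly (> 0.70, < 0.20). At n′
equal to the observed length, G reproduces Cronbach alpha exactly (Hoyt's
identity), which the tests assert to 1e-9. The phrase "test score as a
fixed facet" in some descriptions of this design is nonstandard; the
formulas implemented are those of the single-facet p×i random design they
imply.

## GPCM estimation and information

Marginal maximum likelihood by Bock–Aitkin EM: 61 equally spaced quadrature
nodes on [−6, 6] with standard-normal weights; E-step posterior node
weights per person; M-step per-item quasi-Newton (L-BFGS-B) maximization of
the expected complete-data log-likelihood with analytic gradients. The
slope is bounded to [0.01, 8] and thresholds to [−10, 10] for numerical
stability. Convergence is declared when the largest absolute parameter
change falls below 1e-3 (default, configurable); the marginal log-likelihood
history is retained and is nondecreasing up to 1e-8, which the tests check.
Item categories never observed in the data are collapsed onto the nearest
lower observed category before estimation — their adjacent threshold is
unidentified otherwise — and the collapse is reported on the results object.

Item information is the GPCM Fisher information I(θ) = α²·Var(C | θ);
test information is the sum over items (local independence). Average item
information is the standard-normal-weighted integral of I(θ), computed by
trapezoidal quadrature on a 1201-point grid over [−6, 6] (converged well
below 1e-6). The weighting convention is a choice — sample-based or
uniform-interval averages are also defensible — and the normal weight is
used because ten items of average information 0.5 imply an average test
information of 5 and hence a marginal reliability of 1 − 1/(1+5) = 0.8,
matching the classical-reliability reading of that cutoff. Factor scores
are EAP (posterior mean) estimates under the N(0, 1) prior on the same
quadrature grid.

## One-factor CFA

Items are treated as continuous: the congeneric model Σ = λλ′ + Ψ is
fitted to the sample covariance matrix by normal-theory ML (minimizing
log|Σ| + tr(SΣ⁻¹) − log|S| − p), with the factor variance fixed at 1 and
uniquenesses floored at 1e-4 of the item variance (hitting the floor flags
a Heywood case). χ² = (n−1)·F against the independence baseline
Σ = diag(S) yields CFI, TLI, and RMSEA by their usual formulas; a
saturated model (3 items, df = 0) reports RMSEA 0 and TLI as missing.
A polychoric/WLSMV treatment of the ordinal items is deliberately out of
scope; on 5-category Likert data the continuous-ML indices can differ from
categorical-estimator output, so acceptability is judged against thresholds
(CFI, TLI ≥ 0.90; RMSEA ≤ 0.10) rather than by matching specific index
values. The 0.10 RMSEA default reflects the threshold actually applied in
the motivating analysis (reported fits of 0.07–0.09 were accepted); it is
configurable.

## Item screen and selection

The seven criteria and their cutoffs are listed in the README. Two
interpretations are pinned down here: criterion 2 ("deleting the item
reduces alpha") is alpha_if_deleted strictly below the full-scale alpha,
and criterion 6's interval (−4, 4) is open, so a threshold exactly at ±4
fails. Selection keeps the k items with the highest criteria counts, ties
broken by higher average item information, then by instrument position —
the final tie-break exists only to make the procedure deterministic.

## Optimal test assembly

Stage one maximizes the TIF anchored at (−3, −1, 0, 1, 3). The default
objective is the *sum* of the TIF over the anchors; a maximin alternative
(maximize the minimum anchored TIF) is available via `ota_objective`.
The search is an exact depth-first branch-and-bound with an additive upper
bound; under the sum objective with a single cardinality constraint the
optimum provably equals the top-k items ranked by anchor-summed
information, and the tests verify both this reduction and agreement with
exhaustive enumeration over all C(10, k) subsets. Ties between subsets
resolve to the lexicographically smallest index set. Candidate forms are
not forced to be nested, and under the maximin objective they genuinely
need not be. Stage two keeps the shortest candidate with alpha ≥ 95% of
the full form's and total-score and EAP-score correlations ≥ 0.95
(inclusive comparisons); if none passes, the candidate with the highest
total-score correlation is returned flagged as non-passing.

## Pipeline behaviour

Stages run in order: CFA unidimensionality check → G-study/D-study →
GPCM fit → CTT statistics → seven-criterion screen and tandem selection →
OTA per length and criteria-based choice → reliability comparison. A
failed unidimensionality check is a recorded warning, not a gate. If no
length meets the GT thresholds the tandem route is skipped and the OTA
choice stands alone; both routes and their agreement are always reported
explicitly. Reports carry the seed, a config hash, and the package version,
and contain no timestamps, so a (config, seed) pair reproduces a run
byte-for-byte.

## Problem sizes used in the tests

Exact identities are checked at the instrument's own size (164 × 10).
Monte-Carlo checks use the smallest sizes at which their bounds are sharp:
independence limits at n = 20 000, marginal-frequency and closed-form
reliability checks at n = 50 000, GPCM recovery at n = 2000 over 20 seeds,
and the pipeline properties at the study's n = 164 (100 seeds) and at
n = 5000 (25 seeds).

## Known limitations

- Continuous-ML CFA on ordinal items (no polychoric/WLSMV path).
- Single-facet GT only; no multivariate or nested designs.
- The GPCM is the only response model (no graded-response or 2PL path).
- OTA supports a cardinality constraint only — no content or enemy-item
  constraints.
- The tandem and OTA routes can legitimately disagree on form length when
  the D-study indices sit close to their cutoffs; the report surfaces the
  disagreement rather than resolving it.
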