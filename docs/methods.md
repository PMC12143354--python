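# Methods

## Dose-response model

Monotherapy efficacy (%αSMA reduction) and cytotoxicity are modeled with a
constrained four-parameter logistic,

    y(x) = Top / (1 + (EC50 / x)^h),      y(0) = 0,

with Bottom fixed at 0 (the vehicle control is thresholded to zero by the
normalization `100·(control − drug)/control`, so a zero dose produces a
zero response by construction), Top constrained to (0, 100] (a drug cannot
reduce activation by more than all of it), and Hill slope h constrained to
(0, 5]. Data steeper than the bound fit at h = 5. The zero dose is handled
by the x → 0 limit rather than a log-dose transform, so dose-0 wells need
no special casing.

Fitting is bounded trust-region least squares started from a fixed 5 × 4
grid over (EC50, Hill) — EC50 log-spaced across the tested dose range,
Hill in {0.5, 1, 2, 4} — taking the lowest-SSE solution. The grid is
deterministic, so fits are reproducible without a seed. When every
response is within 1 unit of zero the fit returns a flat-curve sentinel
instead of meaningless parameters; no EC is defined for it.

**Absolute EC.** EC_f is the concentration producing an *absolute*
response of f units (not a fraction of the fitted Top), obtained
analytically: `EC_f = EC50 / (Top/f − 1)^(1/h)`, defined for 0 < f < Top
and exact to floating precision under the round trip y(EC_f) = f. Effects
at or above Top raise an unreachable-effect error rather than
extrapolating.

**Dead/alive threshold.** Percent cytotoxicity classifies cells against
the midpoint of the positive- and negative-control mean marker
intensities. The midpoint is the simplest symmetric rule consistent with
control-based thresholding; it is isolated in one function so a different
rule can be swapped in.

**Level selection.** L1 = min(EC1, CC1, 0.05·Cmax) and
L2 = min(EC2, CC2, 0.10·Cmax) per drug and sex, where Cmax is the maximum
clinical serum concentration; provenance records which bound was binding.
This keeps every screened dose low, noncytotoxic, and clinically
achievable.

**Replicate power.** `power_n` evaluates two-sided t-test power exactly
through the noncentral t distribution and returns the smallest per-group
n ≥ 2. The default is the two-sample formulation (treatment vs control);
at the screen's planning point (Δ = 35, SD = 10, α = 0.05, power = 0.8)
it gives n = 3, the replicate count used throughout. A one-sample variant
(against the thresholded zero control) is provided but non-default.

## Screening design

The combination screen uses a 59-run orthogonal array composite design
over 8 drugs at levels L0/L1/L2:

- a 32-run 2^(8−3) fractional factorial at the extreme levels {L0, L2},
  generators F = ABC, G = ABD, H = BCDE, giving resolution IV (no main
  effect aliased with any two-factor interaction);
- a 27-run strength-2 three-level orthogonal array built from GF(3)^3:
  rows are the 27 points, columns are dot products with 8 fixed pairwise
  non-proportional direction vectors, so every column pair contains each
  of the 9 ordered level pairs exactly 3 times.

The specific published 59-run matrix is not reproduced; the construction
is from documented generator sets, and `verify_design` re-checks by brute
force the properties that matter for the statistics — per-column balance,
pairwise orthogonality counts, and (for two-level blocks) column-product
aliasing. Those properties, not the particular matrix, determine the
estimability of the quadratic model: the OACD plus the 16 L1/L2
monotherapy runs span the full 45-term second-order basis with full
column rank, which the test suite asserts numerically.

Checkerboard ladders for two-drug follow-up are six doses
{0, L2/4, L2/2, L2, 2·L2, 4·L2} — twofold steps topping at four times the
screening dose — giving 25 nonzero dose pairs per 6×6 grid.

## Response-surface fit

Responses are modeled by the full second-order series in coded levels
{L0, L1, L2} → {0, 0.5, 1}: intercept, 8 linear, 8 quadratic and 28
bilinear terms. Ordinal coding is used because the physical concentration
spacing between L1 and L2 is drug- and sex-specific, which would make
coefficients incomparable across drugs; a concentration-valued coding can
be passed explicitly but is not the default.

**Transform selection.** Before term selection, a power transform of the
response is chosen from the candidate grid {−1, −0.5, 0, 0.5, 1, 2} (0 =
log) by Box-Cox profile log-likelihood of the full-basis least-squares
fit, including the Jacobian term so likelihoods are comparable across
exponents. Responses are shifted by (1 − min) when any response is
nonpositive, and the shift is recorded in the model. Identity wins ties.
Square-law data therefore selects exponent 2 exactly, mirroring the
square transformation such screens report when it improves fit.

**Stepwise selection.** Bidirectional F-test stepwise from an
intercept-only start: repeatedly add the excluded term with the smallest
partial-F p-value below p_enter = 0.05, then drop any included term whose
p-value exceeds p_remove = 0.10. The thresholds are classical defaults
and are exposed in configuration. No effect hierarchy is enforced — an
interaction may enter without its main effects, matching unconstrained
stepwise behavior. SSE decreases strictly at every addition, so the
procedure terminates; when the fit becomes numerically exact (relative
SSE below 1e-10) selection stops, since no remaining term can demonstrate
improvement against a zero residual. Replicates enter as individual rows
rather than per-run means, keeping the residual degrees of freedom that
the F tests and power analysis assume.

**Back-transform.** Predictions are inverted through the selected
exponent; transformed predictions with no real preimage under an
even-power transform (negative values whose square root would be
imaginary) are assigned a response of 0, and final predictions are
clamped at 0 before ranking. The clamp is monotone, so rankings agree
with the transformed scale wherever predictions are positive.

**Outliers.** Externally studentized residuals (leave-one-out error
scaling) with a default flag threshold of |t| > 3. The scan is
report-only; refitting after removing zero flagged runs is a no-op.

## Ranking, candidates, and sex bias

All 6561 level combinations are predicted, sorted descending, ties broken
lexicographically by level vector so the ranking is a deterministic
permutation. Candidate selection mirrors screen practice: the top three
combinations from each of the two-, three- and four-drug strata (nine
candidates), plus the two lowest-ranked multi-drug combinations as
predicted-ineffective negative controls. Validation correlates predicted
with (simulated) measured responses via Pearson r with a t-distribution
p-value.

Sex-bias analysis aligns the male and female rankings on level vectors
and differences the predictions (male − female). The sign rule alone is
unstable under noise for near-zero differences, so a deadband of 5
%reduction units classifies combinations as neutral; beyond it they are
male- or female-biased by sign.

## Bliss synergy

Checkerboard responses are converted to effect fractions f = pct/100
clamped to [0, 1] (Bliss independence is defined on probabilities;
negative %reduction is treated as no effect). For each nonzero dose pair,
the expectation is f_A + f_B − f_A·f_B with monotherapy effects taken
from the checkerboard's own zero row/column — not from refit curves — so
the map is self-contained. The score is 100·(observed − expected),
computed from replicate-mean effects; significance is a per-cell
one-sample t-test of replicate-matched scores against zero at α = 0.05
with no multiplicity correction. Classification: score > +10 synergistic,
< −10 antagonistic, additive between.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not the biology that produced it:

- **Monotherapy curves**: per-drug/sex 4PL truths with partial tops
  (60–95%), EC50 log-uniform over ~0.05–5 µM, Hill near 1; cytotoxicity
  curves 1–2 decades to the right, so selected levels usually bind on the
  EC or Cmax rule.
- **Combination surface**: a per-sex ground-truth quadratic series with
  weak monotherapy effects (every single-drug L2 response ≤ 15 units,
  matching the observation that monotherapies are broadly ineffective at
  screening doses) and sparse planted bilinear interactions — one strong
  (+40 units) sex-specific pair per sex (losartan×SD-208 male,
  LY294002×H1152 female), weak cross-sex coefficients (+5), and two mild
  shared pairs — so each planted pair is sex-biased by ≥ 29 units at its
  both-L2 combination.
- **Noise**: additive Gaussian at the well level, default SD 10
  %αSMA-reduction units and 3 replicates — the values the screen's power
  analysis assumed; responses are clipped below at −50 (drug-worsened
  activation is possible but bounded). Whether real well-to-well
  variability is additive Gaussian is not established from reported
  residuals; it is the assumption under which the power analysis was
  framed, and it is what the generator reproduces.
- **Warp**: a surface can carry a monotone power warp
  (observed = max(series, 0)^(1/t)) linking the quadratic scale to the
  observed scale, exercising the transform-selection path; the default
  sex pair uses t = 1 (identity), since the square transform such screens
  report is an empirical property of particular datasets rather than of
  the underlying model.
- **Checkerboards**: combination cells follow the Bliss expectation of
  the two monotherapy curves plus a planted excess (default 20 score
  units), so scoring with zero noise recovers the excess exactly wherever
  the expectation plus excess stays below saturation.

All randomness flows through explicit integer seeds (per-stage seeds are
derived from the run seed by hashing and stay below 2^31); identical
seeds reproduce identical CSV bytes.

What passing tests on these data do **not** show: robustness to per-cell
image segmentation artifacts, non-Gaussian or dose-dependent error,
plate/batch effects, drug degradation over culture, or model
misspecification beyond the planted warp — none of which the generator
emulates.

## Problem sizes and numerical choices

The recovery studies run at the screen's own scale: 59 OACD + 16
monotherapy runs × 3 replicates (225 wells) per fit, 100 seeded screens
for interaction-sign recovery, 50 for full-space ranking recovery, 200
for EC20 recovery and null-selection calibration. Stepwise fits use plain
least squares with rank guards; candidate terms that would make the
selected basis rank-deficient are skipped, and a rank-deficient final
basis raises an error naming the collinear terms. The 4PL optimizer runs
all multi-starts to tolerance 1e-14 so noiseless recovery is exact to
well below 1e-6. CSV reading uses round-trip float parsing so write→read
is the identity.

## Known limitations

- The OACD is *a* resolution-IV composite design with the stated
  properties, not the specific curated matrix used in any published
  screen; analyses that depend on the exact run list will differ run for
  run while sharing the estimability properties.
- Stepwise F-test selection inherits the usual caveats (greedy path
  dependence, post-selection p-values are nominal, no hierarchy); it is
  implemented as screens of this family describe it, not as a recommended
  modern selector.
- The Bliss analysis applies no baseline correction or surface smoothing
  before scoring, and no multiplicity correction across the 25 cells.
- Cytotoxicity is simulated with the same 4PL machinery as efficacy; no
  mechanistic toxicity model is included.
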