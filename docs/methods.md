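# Methods

## Generative dual-route observer

The simulator is the minimal generative model consistent with the fitted
cue-weight equations. Each trial's percept is built in two stages, each a
convex-style combination whose weight pair sums to one:

1. **Eye-region signal** (always): `G_ER = (1−w)·E + w·H + bias`, with
   eye-route head weight `w` (default −0.25, i.e. repulsive) and an
   additive response bias (default −1°, the small leftward shift typical of
   such data).
2. **Percept**: with the head context visible,
   `G = (1−d)·G_ER + d·H + σ_rep·z`, direct head weight `d` (default 0.15,
   attractive); with the head occluded, `G = G_ER + σ_rep·z`.

`z` is standard normal; noise enters once, at the percept stage — σ_rep
(default 3°) describes the sensory representation of the final percept, and
no separate eye-route noise is modelled. Whether bias and noise act before
or after the direct-route combination cannot be distinguished from
cue-weight data; placing the bias inside the eye-region route and the noise
at the end is this package's choice. Responses compare the noisy percept
against criteria b_L, b_R (defaults ±4°): below b_L → "left", above b_R →
"right", else "direct". A lapse parameter replaces the response with a
uniform category draw at rate `lapse_rate` (default 0, so the no-lapse
categorization model fitted downstream is well-specified; fitting lapsing
data with the no-lapse model is a deliberate misspecification scenario, not
the default).

Two closed forms tie the simulator to the fitted quantities and are used as
oracles throughout the tests. The PSE moves linearly in H with slope
`m_ER = −w/(1−w)` (head hidden) and `m_WH = −((1−d)w+d)/((1−d)(1−w))`
(head visible), and the dual-route decomposition of (m_WH, m_ER) returns
exactly `d`. Between-subject variation draws every parameter independently
from a Gaussian (rejection-truncated to its valid domain); the default
population is 20 observers with w = −0.25 ± 0.05 and d = 0.15 ± 0.05.

## Trial designs

Main experiment: 4 identities × 5 head orientations (−30…30°) × 9 eye
deviations (−20…20°) = 180 cells per block; blocks alternate the whole-head
and eye-region conditions, three repetitions each → 1,080 trials. The
condition of the first block alternates with subject parity (even subject
index starts whole-head) — the counterbalancing assignment is this
package's convention. Randomization is within block only, from a per-subject
stream seeded as `master_seed + subject_index`. The control design fixes
H = 0°, adds an eyes-only condition, and presents each condition in three
consecutive 36-trial blocks, condition order randomized per subject.

## Psychometric stage

The proportion-rightward score (mean of the 0/0.5/1 recoding) is fitted
with a two-parameter logistic `ψ(x) = 1/(1+exp(−(x−α)/β))` by weighted
nonlinear least squares, weights equal to trials per level. Least squares
rather than a binomial likelihood because the 0.5-recoded "direct"
responses make the score a trinomial mixture, not Bernoulli; no lapse/guess
asymptotes are fitted (the data saturate at 0 and 1). Decreasing data are
rejected (sign convention); an α outside the sampled eye deviations is
clamped to the range with a warning. Group-level analysis pools recoded
scores across subjects before fitting; subject-level fits each subject
separately.

Confidence intervals for α are percentile bootstrap (default 1,000
resamples), resampling trials with replacement within each eye-deviation
cell. Two finite-sample caveats, both measured during development and
re-derivable from the test suite's machinery: (i) at ~20 trials per cell
the percentile interval is ≈8% narrower than the true sampling spread
(coverage ≈0.89 instead of 0.95); at ≥80 trials per cell the width matches
and coverage is nominal — the coverage test therefore runs at 80 trials per
cell; (ii) the true score curve of the trinomial observer is a two-probit
mixture, not a logistic, so when the PSE sits off the centre of the
sampled grid the logistic fit carries a small systematic offset (−0.08° at
a PSE of 0.8° under the default regime) that no bootstrap absorbs. Both are
negligible relative to the ±0.3° accuracy claimed for the PSE.

## Cue weights and decomposition

The PSE-on-H regression uses ordinary least squares with an intercept (the
leftward bias shifts all PSEs; only the slope enters the weight formulas).
Weights `(1/(1−m), m/(m−1))` and route weights
`((1−m_ER)/(1−m_WH), (m_WH−m_ER)/(m_WH−1))` are exact algebra; m = 1 is a
singularity and raises. Per-subject weights come from per-subject slopes
and feed two-sided one-sample t tests (Cohen's d = mean/SD, no multiplicity
correction at this stage); group weights additionally come from the
group-average fits. Both the group-average and the mean-of-subjects
decomposition are reported — on simulated data they agree to ~0.002.

## Categorization model

Per subject × condition × head orientation, the left/direct/right counts
per eye deviation are fitted by maximizing the product-multinomial log
likelihood over (b_L, b_R, σ_rep). The parameterization is (midpoint,
log width, log σ), so b_L < b_R and σ > 0 hold by construction;
optimization is L-BFGS-B from 8 starts (moment-based initial values —
centroid for the midpoint, direct-response spread for the width — jittered
for the restarts). Zero-count cells contribute nothing; probabilities are
floored at 1e-12 inside logs. No lapse parameter is fitted.

Two identifiability notes. With eye-deviation levels spaced 5° apart, a
σ_rep below the level spacing is only weakly constrained: the likelihood
forms a ridge, and coarse grid searches can land away from the MLE in
parameter space while agreeing in likelihood — the oracle-equivalence tests
therefore draw σ ≥ 2°. Second, the model assumes the internal response
equals the nominal eye deviation, whereas the generative observer applies
gain (1−w) (plus (1−d) when the head is visible); the fitted criteria and
σ_rep are then the generative values divided by that gain (e.g. σ = 3°,
width 8° appear as ≈2.4° and ≈6.4° in the eye-region condition). The peak
shift per degree of head rotation equals the PSE slope, so the cue-weight
conclusions are unaffected.

The model-free companions: the **centroid** (proportion-direct-weighted
mean eye deviation, computed from raw proportions, never from model
curves) and the overall proportion of direct responses.

### Centroid vs peak at small trial counts

The centroid is commonly motivated as the more stable locator of direct
gaze when trials are few. Under this package's well-specified generative
regime that ordering does not hold at 3 trials per cell: across 200
replicate simulations the fitted peak's sampling variance (≈1.4 deg²) is
*below* the centroid's (≈1.9 deg²), and the centroid only wins at 1 trial
per cell. The reason is that the multi-start MLE pools all 27 trials —
including the informative left/right crossings — while the centroid uses
only the ~20% direct responses on a 5°-spaced grid. On real data, where
lapses, asymmetries and misspecification can destabilize the model fit,
the ordering may reverse; the package reports both measures so the choice
stays empirical.

## Problem sizes and determinism

Default analysis sizes: 20 observers × 1,080 trials (simulation ≈1 s; all
psychometric and weight fits ≈2 s; 200 subject-level category fits ≈6 s).
The robustness study uses 200 replicates at 3 trials/cell; the bootstrap
default is 1,000 resamples (the pipeline default is 0, i.e. off, since the
slope regressions do not consume the intervals). Every stage draws from an
explicitly seeded generator — a master seed per design/population plus
spawned per-observer streams — so reruns are byte-identical; no global RNG
state is touched.

## Known limitations

- The simulator does not model uncertainty-driven widening of the direct
  category under interleaved head orientations; condition differences in
  the cone width arise only if configured through the boundary parameters.
- The logistic psychometric stage offers no alternative sigmoids and no
  deviance-based goodness of fit.
- Cue-weight regressions ignore the estimation uncertainty of the PSEs
  entering them (no errors-in-variables correction).
- Repeated-measures ANOVAs and post-hoc chains on the estimates table are
  out of scope; the table is exported as tidy CSV for external tools.
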