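# Methods

## The model

The package implements a Rescorla–Wagner account of natural forgetting in
the novel-object-recognition task. A single latent state, the **engram
relevancy** `e_t ∈ [0, 1]`, represents the strength of the object–context
association for the familiar object on day `t`. It is updated once per day
by the delta rule

    e_{t+1} = e_t + α_t · δ_t,        δ_t = o_t − e_t,

where `o_t ∈ {0, 1}` indicates whether the familiar object is presented
that day and `δ_t` is the prediction error. The learning rate is
asymmetric:

    α_t = 1        if δ_t ≥ 0   (presence: one exposure fully restores e)
    α_t = α⁻       if δ_t < 0   (absence: slow decay — the forgetting rate)

The boundary case `δ = 0` takes the non-negative branch. With acquisition
on day 0 and a test on day `d` with no intervening presentations, the
relevancy entering the test day has the closed form `(1 − α⁻)^(d−1)` (one
full positive update to 1, then `d − 1` absence updates). This closed form
is used throughout the tests as an independent oracle for the iterative
trajectory; the implementation itself always iterates the delta rule.

### From relevancy to behavior

Mean exploration of the familiar object is a two-option softmax over the
relevancies of the familiar object (`e`, dynamic) and the novel object
(fixed at 0, never experienced):

    μ = exp(β·e) / (exp(β·e) + exp(β·0)).

The inverse temperature `β ≤ 0` encodes novelty preference: the more
relevant (better remembered) the familiar object, the less it is explored.
Equal relevancies give `μ = 0.5` exactly for every `β`. The softmax is
computed with max-subtraction; on a two-option problem this is a routine
guard rather than a necessity.

Across-mouse variability is modeled with a Beta distribution
parameterized by mean and concentration:

    μ̂ ~ Beta(a, b),    a = μ·κ,    b = (1 − μ)·κ.

Larger `κ` (= a + b) means less variability between mice.

### Timing conventions

* The day grid is whole days, `t = 0..21`; 24 hr = day 1, 1 week = day 7,
  2 weeks = day 14, 3 weeks = day 21.
* Test-day behavior is read from the relevancy **entering** the test day,
  before the test exposure itself updates the engram; exploration should
  reflect the memory state prior to re-exposure. The alternative
  (post-update) convention would make every test trivially perfect, since
  `α_pos = 1`.
* The experimental reminder session happens 1 hr before the test; on the
  day grid it is snapped to the day before the test (`test_day − 1`,
  configurable through the schedule builder). Reminders are full presence
  observations (`o = 1`) by default.
* Context-only exposures are **not** schedule events. That condition is
  modeled purely as a larger forgetting rate (absence updates already
  happen daily); adding explicit context events would double-count them.

## Parameters

| parameter | meaning | default | fit bounds |
|---|---|---|---|
| `alpha_neg` (α⁻) | learning rate for negative prediction errors — the forgetting speed | per condition | [0, 0.25] |
| `alpha_pos` | rate for non-negative errors | fixed 1 | — |
| `beta` (β) | softmax inverse temperature (negative = novelty preference) | −5 | [−10, 0] |
| `kappa` (κ) | Beta concentration (across-mouse consistency) | 10 | [1, 100] |
| `e_init` | relevancy before acquisition | fixed 0 | — |

Condition presets for α⁻: standard housing 0.07, enrichment 0 (empirical
fit; 0.01 as the simulation variant), Rac1 inhibition 0.01, Rac1
activation and context-only 0.5, reminder 0.07 plus a reminder event.
Values of 0.5 exceed the fitting bound deliberately; the bound constrains
estimation only, not simulation.

`β = −5` and `κ = 10` are configuration defaults for the generative
presets, not empirical estimates (the per-condition estimates of these two
parameters are not part of the preset table). At `β = −5` a fully
remembered object draws μ ≈ 0.007 of exploration and a forgotten one
μ = 0.5, spanning the behaviorally relevant range.

## Estimation

Three free parameters (`alpha_neg`, `beta`, `kappa`) are fitted jointly
per experimental group by maximizing the summed Beta log-likelihood of the
observed exploration probabilities,

    l = Σ_s log Beta(μ̂_s ; a_s, b_s),

with bound-constrained L-BFGS-B. Because the likelihood can be flat in `κ`
at small group sizes, the optimizer runs from 10 uniform random starts
inside the bounds (seeded); the best converged start wins, with exact
likelihood ties (within 1e−9) broken toward smaller `alpha_neg`, then
smaller `|beta|`, so a fit is fully determined by data + seed + number of
starts. The objective tolerance is `ftol = gtol = 1e−8`. Observed and
model probabilities are clipped to `[1e−4, 1 − 1e−4]` before likelihood
evaluation: the Beta log-density is degenerate at the boundaries for
shapes above 1, and finite `β ∈ [−10, 0]` can produce μ just outside the
clip range.

Model comparison uses `BIC = l − (k/2)·ln(S)` with `k` free parameters and
`S` subjects — note the sign convention: **higher is better**. The chance
baseline explores both objects equally (μ = 0.5) with the uniform
observation density Beta(1, 1), so its log-likelihood and BIC are
identically 0 on any dataset; a positive fitted BIC means the learning
model beats chance after the complexity penalty.

## Synthetic data

The generator emulates the structure of the study's behavioral data:
independent (between-subjects) groups of mice, one group per retention
interval at test days {1, 7, 14, 21}, each mouse contributing a single
familiar-object exploration probability drawn from the model's Beta
observation distribution at its test day. Defaults: 12 mice per group
(figure legends report 4–12) and 30 s of total exploration when raw
per-object times are attached. Draws are clipped to `[1e−4, 1 − 1e−4]`
before storage for the same boundary-density reason as above.

What it deliberately does not emulate: habituation sessions, within-test
minute-by-minute dynamics, side/object counterbalancing, repeated-measures
designs, individual differences in β or κ, and any histological
quantities. Passing recovery tests therefore show that the estimation
machinery is correct and well-calibrated *under the model's own
assumptions*; they cannot show that real mice satisfy those assumptions.

## Validation results the code computes

* **Parameter recovery** (`analysis/03_parameter_recovery.py`,
  `scripts/acceptance.py`): 20 replicates of simulate-and-refit at each
  condition rate, 4 groups × 12 mice. The mean recovered α⁻ is slightly
  conservative (biased toward 0 by roughly 0.01 at α⁻ = 0.07), a known
  consequence of boundary clipping and the small-sample likelihood; it
  stays well inside the ±0.03 band used by the tests.
* **Model comparison** (`analysis/04_model_comparison.py`): on data the
  learning model generated, its BIC exceeds the baseline's 0 in ≈100% of
  50 replicates.
* **Forgetting curves** (`analysis/05_forgetting_curves.py`): α⁻ = 0.07
  yields graded monotone forgetting over three weeks; α⁻ = 0 a flat curve;
  α⁻ = 0.5 collapse to chance within two weeks; a reminder the day before
  the test restores relevancy to 1 and with it novelty-driven exploration.

Problem sizes (group counts, replicate counts, optimizer starts) are the
package defaults chosen to match the study's design scale; larger runs
only narrow the Monte-Carlo error.

## Known limitations

* One engram only; no competing or interfering memories, no extinction
  ensemble, and no mechanistic (dopamine/Rac1) layer — interventions enter
  solely through α⁻ or reminder events.
* `β` and `κ` are estimated per group but weakly identified at `S ≈ 48`;
  their recovery is much noisier than α⁻'s (see
  `results/recovery_summary.json`).
* Sub-day timing is not representable; reminder sessions are snapped to
  whole days.
* The behavioral statistics assume a single test session; records with
  under 1 s of total exploration are flagged, not dropped, and the choice
  of exclusion rule is left to the analyst.
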