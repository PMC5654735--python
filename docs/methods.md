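# Methods

`adaptive_coach` implements a daily closed loop for encouraging walking in
sedentary type 2 diabetes patients: a server observes each patient's
accelerometer-derived walking minutes, selects one of four SMS feedback
messages each morning, and learns from the next day's behavior which message
works for whom.  Because no patient-level data from such trials are publicly
deposited, the package pairs the decision system with a synthetic cohort
simulator rich enough to exercise every part of the loop, and with the
evaluation analyses used to study such a trial.

## The decision problem

Each patient `i` has a prescribed weekly walking plan (e.g. 120 min in 3
sessions).  Each morning the system chooses an action
`a ∈ {negative, positive-self, positive-social, none}` — a
performance-avoidance framing, a mastery framing, a performance-approach
framing, or silence.  The reward for the action taken after observing day `t`
is the day-over-day activity ratio

    y = (minutes(t+1) + ε) / (minutes(t) + ε),

with ε = 1 minute so zero-activity days stay defined (ε = 0 recovers the raw
ratio; a configuration choice).  Only contiguous walking bouts of ≥ 10
minutes count toward `minutes`, matching the measurement app's contract.
Rewards above a cap (default 10) are winsorized before fitting, because ratio
rewards are heavy-tailed when the denominator day had near-zero activity.

This is a contextual bandit, not a full reinforcement-learning problem: the
model predicts the immediate effect of each action in the current context and
does not attempt multi-step credit assignment.

### Timing convention

The index form `y_t = m_{t+1}/m_t` with context built from data through day
`t` is implemented as: the decision made on the morning after day `t` uses
features through day `t`, the message influences day `t+1`, and the reward is
finalized the following morning, provided that morning's staleness check on
the response day's data passes.  `build_features(date=...)` therefore takes
the most recent fully observed day.

## The two policies

**Initial policy** (first 90 days): no message on 20% of days (i.i.d.
Bernoulli); otherwise a uniform draw `u` is compared with the fraction of the
weekly target expected to be complete that day (uniform accrual, `k/7` by the
end of weekday `k`); `u > f` sends the negative message, else one of the two
positive messages with equal probability.  The tie `u == f` goes positive
("larger than" read strictly).

**Learned policy** (after the burn-in, once ≥ 200 examples exist): a single
linear regression with all pairwise interactions predicts `y` from a
14-column base row — 10 context features (last-day minutes, week-to-date
minutes, fraction of goal, fraction vs expected, age, a female indicator, and
four days-since-each-message counters capped at 30) plus a one-hot action
block (the Kesler construction).  Interactions exclude action×action products
(structurally zero), giving 14 + C(14,2) − C(4,2) = 99 design columns.  The
model is refit every morning on all finalized examples; the next action is
drawn by Boltzmann sampling over the four predicted ratios at `T = 5`, never
adapted.  Over predicted ratios in a realistic [0, 2] range this keeps every
message's probability above 10% (measured minimum ≈ 18–19%), the design
bound for the temperature.

The one-hot block plus the intercept is exactly collinear, so the normal
equations carry a ridge penalty λ = 1e-6 (intercept unpenalized).  Predicted
*differences* between actions are identified; individual action main effects
are only identified as contrasts, which is how the parameter-recovery test
phrases them.  The fit reports adjusted R² and, in memory, the coefficient
covariance for contrast inference.  Features are left unscaled so
coefficients stay interpretable; standardization is a configuration option.

## Engine rules

* **Staleness guard** — no SMS when the most recent upload is 12 h or more
  before the decision time (inclusive boundary), or when no data ever
  arrived.  Suppressed days produce no training example.
* **Phases** — learned phase requires both the 90-day burn-in elapsed and the
  minimum example count; otherwise the engine stays on the initial policy.
* **Control arm** — never receives daily messages and never enters the
  training data; its weekly message is always the fixed reminder.
* **Weekly summaries** — sent Mondays.  "Increase" is the just-completed
  week's minutes minus the previous week's.  Achievements require at least
  one *previous* weekly increase to compare against (with none, the
  "strictly exceeds every previous increase" condition would fire vacuously
  on week two), precedence maximal-increase > maximal-social >
  significant-increase > significant-social, the "significant" variants
  thresholded at the median of the comparison set, and at most one
  achievement per 21 days.

## The synthetic cohort

Defaults emulate the study conditions the system was designed for: 20
treatment and 7 control patients, weekly plans truncated-normal with mean 139
and SD 62 min/week (floor 30; the location parameter is solved so the
*truncated* mean equals 139), three latent response clusters mixed 4:9:5, and
a gender-by-cluster table (50%, 67%, 20% female) so that a single shared
model can partially personalize through the gender feature.

Behavior is multiplicative-lognormal, chosen because the reward is a ratio:

    minutes(t) = baseline × drift(t) × cluster_mult(action)
                 × seq_mult(prev action, action) × (1 − shock) × exp(σZ)

quantized to whole minutes, with totals under 10 recorded as 0.  Default
cluster multipliers over (negative, self, social, none) are
(0.5, 0.6, 0.6, 1.0) for cluster 1 (adverse reactors), (0.9, 1.0, 1.1, 1.0)
for cluster 2 (weak reactors) and (1.0, 1.4, 1.8, 0.8) for cluster 3 (strong
positive reactors, social strongest) — a qualitative pattern of heterogeneous
message response; the exact values are stated configuration, not estimates.
Sequence effects default to a boost for negative→positive-self (×1.2) and a
damping for repeated positive-social (×0.8).  Day noise is lognormal with
σ = 0.3; baselines are plan/7 with patient-level lognormal dispersion 0.3;
transmission gaps occur on 5% of days (exercising the staleness guard); one
default cohort-wide shock (days 60–64, severity 0.6) emulates an adverse
weather event.  Cadence follows the same multiplicative structure with a
dampened exponent (0.3).  An additive-effects variant is available for
sensitivity checks, as is a demonstration HbA1c channel whose improvement is
linear in average weekly minutes (coefficient 0.002 %-points per weekly
minute over a 26-week course, i.e. ≈ 0.28% at the mean plan).

Per-(patient, day) noise streams are keyed only by the master seed, so two
policy arms replayed on the same seed face an identical world (common random
numbers) and comparisons between them are paired — standard simulation
variance reduction.

What the simulator does **not** model: physiological gait or glucose
kinetics, accelerometer noise, weekday/weekend structure, seasonal trends, or
behavioral memory beyond the one-day sequence effect.  Passing tests
therefore show that the loop's machinery is correct and can learn planted
structure, not that the system improves real patients.

## Evaluation analyses

* Per-message mean improvement and probability-weighted effectiveness, per
  policy phase; never-sent messages reported as missing.
* Sequential effects: mean reward by (previous-day, current) message over
  strictly consecutive patient-days; labelled descriptive, since pairs
  reflect policy choices rather than randomization.
* Response clustering: k-means (k = 3, 50 restarts, fixed seed) on
  per-patient 4-vectors of mean post-message change, restricted to patients
  with ≥ 2 distinct messages received; missing entries are filled with the
  patient's own mean; labels ascend with centroid mean so "cluster 1" is
  always the most negative responders.
* Per-patient OLS slopes of daily fraction-of-target (and weekly cadence
  means, excluding zero-walking weeks), group-averaged with R² weights
  ("fit of the linear function" read as R²; the weight is otherwise
  unnamed).
* Model traces from daily snapshots: stability(d) = Σ_j ||β_j(d)| −
  |β_j(d−1)|| (a literal reading — a pure sign flip contributes zero), and
  the adjusted-R² series.
* Relative HbA1c reduction (h0 − ht)/h0.

Cohort-level significance tests (ANOVA, chi-square, the multi-covariate
HbA1c regression) are deliberately not reimplemented; the report exposes the
summary tables so standard tools can be applied downstream.

## Numerical and design choices

* Weeks start Monday; all dates are local calendar dates.
* `percent_of_goal` rounds half up and is not clamped above 100.
* Percent-of-goal and context features at a morning decision are computed
  from data available at that time (through the previous day).
* Ridge λ = 1e-6; winsorization cap 10; days-since horizon 30; minimum
  training size 200 examples; all configurable.
* k-means label ordering and multiple restarts make clustering deterministic
  for a fixed seed; an all-identical input is flagged degenerate.
* Problem sizes in the test suite (e.g. 27 patients × 180 days × 20 paired
  seeds for the closed-loop comparison; 100,000 draws for policy
  distributions) were chosen to give the assertions comfortable statistical
  power at desk scale.

## Known limitations

* **Mean ratio rewards cannot rank stationary policies.**  The day-over-day
  ratio telescopes: over any long window the *geometric* mean reward of every
  stationary policy approaches the net drift, and the *arithmetic* mean is
  then ordered by reward variance, not by policy quality — a policy that
  oscillates a patient's activity (or drives it to the floor, triggering
  ε-regularized spikes) scores a higher arithmetic mean than one that holds
  activity steady and high.  Consequently, in the closed-loop comparison the
  learned policy reliably *targets* the planted best actions (its
  selection frequency of the social message in the positive-response cluster
  exceeds the uniform 25%) and raises activity, yet its arithmetic mean
  reward is statistically indistinguishable from the uniform arm's (paired
  across 20 seeds it wins about half).  The corresponding acceptance test is
  kept at its stated form and fails honestly; level-based outcomes (mean
  minutes, activity slopes) are the meaningful policy-comparison quantities
  in this simulator.
* One shared model across patients limits personalization to what the
  context features express; latent cluster membership is only partially
  recoverable through gender and activity level.
* The weekly-summary comparison set ("most previous weeks", "most
  participants") is a documented convention (medians), as the field has no
  canonical definition.
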