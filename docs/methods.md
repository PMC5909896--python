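# Methods

## The adaptive procedure

The engine implements a transformed up-down (2-down-1-up) staircase on the
stimulus onset asynchrony (SOA) of a paced serial-addition task. Digits are
drawn from 1–5 under a block constraint (each digit exactly twice per ten
presentations; identical digits may repeat), so a session of `n` response
opportunities uses `n + 1` digits — the first digit elicits no response.
Testing starts at 3500 ms. Two successive, *independent* correct sums earn
one down step; every miss or incorrect answer earns one up step. Pairs are
independent in the staircase sense: the pair counter resets after each
reduction and after any error, so no two reductions share a hit. (Scoring
uses the *overlapping* dyad definition instead — a run of n hits contains
n − 1 dyad hits — which is why the published 13-trial example has 7 dyad
hits but only 4 reductions.)

Steps are proportional: one unit is 5% of the current SOA (175 ms at the
start, 100 ms at 2.0 s), which shortens the approach to asymptote compared
with fixed steps. All units a trial earns — including retroactive
compensation, below — are applied in a **single multiplication**,
`SOA × (1 + 0.05·units)`, rounded to the nearest millisecond with halves
away from zero, and clamped at a configurable floor (200 ms). The single
multiplication matters: −2 units is ×0.90, not ×0.95², which is what makes
1995 ms map to 1795.5 → 1796 ms in the delayed-hit worked sequence. There
is no upper SOA cap (subjects worse than the starting pace drift above
3.5 s).

### Delayed responses

A response whose latency exceeds the trial's SOA registers during the
following trial. At presentation time the trial therefore counts as
unanswered: the SOA provisionally increases one unit and the pair counter
freezes. On the next trial the response resolves: a **delayed hit** earns
retroactively whatever it should have earned at its own pair position,
minus the provisional +1 (so −1 if it began a pair, −2 if it completed
one), merged with the current trial's units into that one multiplicative
application; a **delayed incorrect** keeps the +1 and resets the pair. A
response still pending when the session ends is resolved in a final
bookkeeping step without a new trial. We assume responses are at most one
trial late; a latency of at least the trial's SOA plus the following SOA is
treated as never registered and the trial is recorded as a miss (its RT is
unobservable in a real administration, so none is stored).

Note a small intrinsic asymmetry of this compensation scheme: a delayed hit
that completes a pair leaves the SOA at ×1.05×0.90 = 0.945 of its
pre-pair value versus ×0.95 for the on-time path. The scheme therefore
slightly overshoots downward, and responders with many late responses
equilibrate with asymptotic accuracy a few tenths of a percentage point
below the delay-free value.

### Scoring dialects

Two examiner-keying conventions are supported. In the two-key dialect
incorrect sums are distinguished from misses (enabling the
incorrect-to-miss ratio); in the one-key dialect the examiner keys only
correct sums, so an incorrect answer is indistinguishable from a miss and a
late incorrect never registers at all. The two dialects produce identical
SOA trajectories once incorrects are relabeled as misses, and the suite
asserts this equivalence property.

## Scores

- **minSOA**: minimum *presented* SOA over the analysis window (first 54
  trials; sessions may run 108). Lower is better.
- **dyad ratio**: overlapping dyad hits over total hits, also per half
  (27/27 split). Delayed hits count as hits on both sides of a dyad.
  Undefined (absent, not zero) when there are no hits.
- **mean RT**: over correct responses only; incorrect-response RTs exist in
  the two-key dialect but are excluded.
- **ICC(2,1)**: two-way random-effects, absolute-agreement, single-measure
  intraclass correlation from the mean-squares decomposition, for
  subjects × sessions retest matrices. The variant is fixed and recorded;
  tests cross-check it against an independent implementation.

## Normative model

Expected minSOA is linear in age (years), education (US-equivalent years)
and daily computer-use (8-point Likert with verbatim anchors encoded 1–8):
intercept 2680.88 ms, +6.36 ms/year of age, −33.56 ms/year of education,
−53.07 ms/Likert point. z = (observed − predicted)/residual SD; higher z is
worse, and abnormality is one-sided (z > 1.645 at the default 5%). The
residual SD is not part of the published equation; we derive it from the
normative cohort SD (0.52 s) and the model R² (10.5%) as
520·√(1 − 0.105) ≈ 492 ms, record that provenance in the shipped model
JSON, and allow overrides. Sex is carried in `Demographics` but excluded
from the model. Refits use ordinary least squares (statsmodels) with the
n − 4 residual denominator; non-completers — who are assigned the initial
SOA (3500 ms) as minSOA, flagged assigned-not-measured — are included when
refitting.

## Training and the validity index

Training runs 15-trial blocks at the fixed initial SOA; accuracy below 50%
triggers another block, at most three, and the final block's accuracy is
the training score. The validity index flags a subject whose test z-score
is abnormal while training accuracy is *strictly above* the empirical 20th
percentile (linear interpolation between order statistics) of a normative
training sample — the dissociation expected from feigned impairment, since
genuine impairment degrades the easy fixed-pace training too.
Sensitivity/specificity are computed among abnormal scorers only, matching
the index's intended use. The published human-cohort figures (87%/69%, ICCs
of 0.87/0.87/0.76, R² = 10.5%) depend on those datasets and are not
recomputable here; the suite instead verifies the structural properties
that produce them: the ICC reaches 1 when within-subject noise vanishes and
drops to ~0 for homogeneous cohorts, the suspect flag is monotone in the
cutoff, and regression parameter recovery succeeds at the normative sample
size.

## Subject simulator

Each simulated subject has a logistic psychometric function in log-SOA:
P(correct) = (1 − λ)·σ(β·(ln SOA − ln θ)), with threshold θ (SOA at 50%
lapse-free accuracy), slope β (default 8) and lapse λ (default 0.02). The
form is scale-invariant, which fits a proportional-step staircase; the task
itself constrains only monotonicity and the ~70% equilibrium. Response
times are lognormal (median 1800 ms, log-SD 0.20 — constants in
`src/dapasat/data/calibration.json`), giving a mean RT near 1.8 s and
~10% of responses later than the SOA at equilibrium SOAs around 2.3 s.
Errors are misses with probability 0.87 (the printed incorrect:miss ratio
of 0.13), otherwise a uniformly drawn wrong sum. Strategies:
`alternate_answer` sums only non-overlapping digit pairs (hit pattern
h,m,h,m,…, capped at 50% accuracy, SOA never decreases — the design's
defense against the strategy); `malingerer` inflates the test-phase
threshold ×1.5 while training uses the intact threshold; `quitter` carries
a per-trial quit hazard.

Cohorts draw demographics from truncated normals matched to the normative
population (age 46.2 ± 11.8 in 18–65, education 12.4 ± 3.4, computer-use
4.77 ± 2.25 on 1–8). Ability links to demographics through the norm model:
a subject's staircase-*equilibrium* SOA is `a + b·predicted_minSOA + ε`,
with defaults a = 0, b = 1 and ε ~ N(0, 480 ms) carrying unexplained
ability variance. The link targets the equilibrium point (where P(correct)
= √0.5) rather than the 50% threshold because the norm model predicts
minSOA and a subject's minSOA hovers at their equilibrium; the closed-form
conversion to θ divides by exp(logit(√0.5/(1 − λ))/β). Because minSOA is a
*minimum* over a fluctuating 54-trial trajectory it sits systematically
below the equilibrium; the normative cohort preset therefore carries a
+130 ms link intercept, calibrated once against the normative cohort mean
minSOA of 2.17 s and stored with the other calibration constants. With
that calibration the simulated population reproduces the normative
anchors within tolerance: mean minSOA ≈ 2.15 s (SD ≈ 0.43), dyad ratio
≈ 0.78, mean RT ≈ 1.83 s, accuracy ≈ 78%, administration time ≈ 2.4 min,
late-response rate ≈ 10%.

What the simulator does **not** emulate: arithmetic-strategy or
working-memory process structure, serial correlation of lapses (fatigue),
speech articulation and examiner keying delays beyond the lognormal RT,
learning within a session, and any real covariance between RT and
correctness. Passing cohort-level tests therefore shows that the *pipeline*
is faithful and well-calibrated at the population level, not that the
response model is a validated model of human behavior.

## Numerical and design choices

- Rounding: nearest millisecond, halves away from zero, once per trial
  after the single multiplicative step application (reproduces both the
  1795.5 → 1796 worked value and 2.10 s after ten reductions).
- Long-run staircase accuracy for a steep, lapse-free, on-time responder
  measures ≈ 69–70% rather than the ideal 70.7%: the SOA wanders around the
  equilibrium and the logistic is concave there, a small Jensen bias that
  an independent reference staircase reproduces exactly. The equilibrium
  check uses an effectively on-time responder to isolate the staircase
  property from the delayed-response overshoot described above.
- The early-termination rule that stopped some human administrations at
  trial 54 is not specified; sessions simply run `n_trials` (54, or 108
  opt-in), and a responder's quit signal is recorded and scored by the
  non-completer rule.
- Problem sizes in the test suite and acceptance script (cohorts of
  250–500, 4000–5000-trial equilibrium runs, three seeds averaged where a
  long-run mean is asserted) were chosen as the smallest sizes at which the
  asserted population quantities are stable to well within their
  tolerances.
- Determinism: one seeded generator per session/simulation, spawned via
  `numpy` SeedSequence; every output records its seed, and equal seeds give
  byte-identical outputs.

## Known limitations

- The abnormality cutoffs for dyad ratio and RT are exposed as empirical
  percentiles of a supplied normative cohort; no normative tables for them
  ship with the package.
- The simulator's demographic ability link is linear with Gaussian noise;
  real minSOA distributions are right-skewed at the population ceiling
  (subjects worse than the starting pace), which the engine reproduces only
  through the assigned non-completer mechanism.
- ICC variant choice (2,1) is fixed; if a retest design calls for
  consistency rather than absolute agreement the scoring module would need
  the (3,1) form.
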