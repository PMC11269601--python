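# Methods

## Design frame

All model equations are index-based: the physical durations of sequences
and breaks never enter the likelihood, only the counting structure of the
2×2 design. `trial_design.build_schedule` emits one row per modeled
(non-warm-up) correct sequence with six indices: the within-trial
sequence number ST (1…4 spaced, 1…14 massed), the cumulative modeled
sequence number S (1…Stot), the within-phase trial numbers T and T_test,
the cumulative trial number across phases, and the test indicator X.
Totals follow from the trial structure: `Stot = 210 −
(n_train_trials + n_test_trials)` (196 massed, 168 spaced) and
`Btot = n_train_trials + n_test_trials − 1` (13 massed, 41 spaced), the
rest period counting as exactly one break.

Two conventions deserve note because the equations do not force them
uniquely:

- **Break-based skill accrues on the cumulative trial counter.** The
  offline and hybrid skill curves consume `T_cum − 1`, which keeps
  counting through the rest period and the test phase, while the RI term
  consumes the *restarting* test-trial counter. Only the cumulative
  reading makes the hybridJ conservation property hold (S′ = Stot on the
  last test sequence) — with a restarting skill counter the allocated
  units would not add up.
- **Warm-up sequences consume no learning unit.** S counts modeled
  sequences only. The first trial's warm-up is absorbed into the curve's
  parameterization (modeled sequence one is experimental sequence two);
  later warm-ups are treated the same way.

## Model evaluation

All skill curves share the APEX form `a + b·exp(−c·u)·u^(−k)` with the
practice argument u per model. Wherever `u` would be zero at the first
trial — the offline curves, the trial factor of hybridE/hybridP, and the
break term of S′ — the implementation substitutes `T − 0.9999999999`,
exposed as the single constant `EPSILON_BASE`. The substitution keeps the
first-trial value finite while perturbing later trials by 1e-10, which is
numerically negligible. (One fewer nine changes nothing measurable; the
ten-nine form is used throughout.) A consequence worth knowing: with a
sizeable power rate k, the epsilon-shifted first-trial skill value is
enormous (`(1e-10)^(−k)` ≈ 10^(10k)); this is a property of the model
family itself, and fitted k values stay small enough for it not to
matter in practice.

The RI mixture `(1−X)·{(ST−1)y + (T−1)z} + X·{(ST−1)y + (T_test−1)z}` is
shared by every RI model, making within-trial RI zero on each trial's
first modeled sequence and residual RI zero on the first trial of each
phase.

## Preprocessing

A correct sequence is a greedy left-to-right match of 4-1-3-2-4; an
incorrect press resets the match (the stricter of the possible readings),
with the mismatched press retried as a new start. Because the target has
no proper border, completions cannot overlap, and incorrect presses are
attributed to the next completed sequence of the same trial (presses
after the last completion land in a trailing bucket excluded from
per-sequence means). Sequence RT is five times the geometric mean of the
five inter-press latencies — log-transform, average, anti-log, ×5; the
log base is immaterial. Warm-ups (first completed sequence per trial) are
removed for training *and* test trials, after which each participant's
stream aligns 1:1 with the schedule; misalignment raises rather than
silently reindexing. Averaging across participants is an arithmetic mean
per schedule row with its standard error.

## Fitting

`scipy.optimize.least_squares` (trust-region reflective, bounds, numeric
Jacobian, `x_scale='jac'`, ftol = xtol = gtol = 1e-12, max 10⁴
evaluations) minimizes the residual sum of squares against the averaged
series. Starting values come from a grid screen: RSS is evaluated at the
full Cartesian grid (defaults: a ∈ {500, 1000, 2000, 3000}, b ∈ {500,
1000, 2000}, c ∈ {1e-4…1e-1}, k ∈ {1e-3…0.5}, y ∈ {1, 10, 30}, z ∈
{0.5, 5, 20}, g ∈ {10, 100}, j at {0, ¼, ½, ¾}·Stot/Btot), and descent
runs from the eight best grid points; callers may inject extra starts
(e.g. a nested model's solution with the additional parameters at their
bound, which guarantees the nested-RSS dominance property). Ties break by
lowest RSS, then fewest function evaluations, then grid order; the whole
procedure is deterministic. Strict positivity is implemented as a lower
bound of 1e-12; j is bounded in [0, Stot/Btot]. BIC uses n = Stot of the
group, since fits are to participant-averaged points. On noise-free
self-generated data the identifiable models recover their parameters to
better than 1e-3 relative error with RSS below 1e-6 ms².

## Synthetic data

The generator emulates the study conditions, not any particular dataset:
four groups, 180 + 30 correct sequences per participant in the correct
trial structure, a model-generated mean RT per scheduled sequence.
Specifics:

- **Noise** is lognormal on keypress latencies (σ = `noise_cv` on the
  log-latency, default 0.10), because sequence RT is defined through log
  latencies; sequence-level log-RT residuals are then normal with
  σ/√5. Latencies within a sequence are equal shares (rt/5) perturbed
  independently — the models constrain only the sequence level.
- **Warm-ups**: the first sequence of each trial is the trial's first
  modeled prediction times `warmup_inflation` (default 1.5), mimicking
  the inflated first-sequence RTs in real data.
- **Errors**: before each sequence, Binomial(5, p) error presses with
  p = `error_prob` + `error_slope`·(position−1); the default 0.04 yields
  ≈ 0.2 error presses per sequence, the observed order of magnitude.
  Error keys are drawn from {1, 2, 3} — never the sequence-initial 4 —
  so an error run cannot blend into the following correct sequence and
  the 210-sequence structure is conserved by construction.
- **Defaults** for the online generator (a = 1800 ms, b = 2500 ms,
  c = 0.004, k = 0.12, y = 20, z = 8) produce curves in the visual range
  of real group averages; they are package defaults, not estimates.

What the generator deliberately does *not* emulate: between-participant
parameter variability, time-continuous RI dissipation during breaks, the
distractor task, post-rest extended warm-up. Passing closed-loop and
recovery tests therefore demonstrates correctness of the pipeline and
identifiability under idealized conditions, not goodness of fit to any
real dataset.

## Recovery studies

Parameter recovery draws ground truth per replicate, simulates one group
(default M10), runs the full preprocessing pipeline, and refits the
generating model; it reports per-parameter true-vs-recovered Pearson
correlations (raw scales), bias, and RMSE, with non-converged replicates
counted, never dropped. Default sampling ranges cover the empirically
plausible regime: a ∈ [1200, 2600], b ∈ [1500, 3500], c log-uniform in
[0.005, 0.02], k log-uniform in [0.05, 0.3], y ∈ [5, 30], z ∈ [1, 20],
j ∈ [0, 0.9·Stot/Btot]. The lower bound on c is an identifiability
choice: below c·Stot ≈ 1 the exponential component does not complete its
decay within the session and a/b become structurally confounded — the
least-squares optimum then genuinely beats the ground truth in RSS — so
sampling that regime would measure design identifiability rather than
estimator fidelity. The documentation-scale study uses 50 replicates;
the test suite runs 20 replicates × 20 participants at 10% noise, where
the online model's a and b recover with correlations above 0.99 while
the hybridJ allocation j recovers less faithfully than a at matched
settings — the nested online/hybridJ pair is where the identifiability
weakness of j lives, and reports surface it per-parameter rather than
averaging over it.

Model recovery fits every candidate to data simulated from each
candidate in turn and tabulates the BIC winner as a confusion matrix. At
low noise the with-RI and no-RI families separate essentially perfectly:
no-RI data is flat within trials (a step function over trials), which RI
models can only match by driving y, z to their bounds and paying the
BIC penalty, while RI data defeats the no-RI models' mean structure.

## Problem sizes

Test-suite studies use 20 replicates × 20 participants (parameter
recovery) and 20 replicates × 10 participants at 5% noise (model
recovery over three candidates), sizes at which the qualitative
conclusions above are stable across seeds.

## Known limitations

- Participant-level fits are not offered; fitting is to averaged series.
- The within-trial RI effect is linear by assumption; very long trials
  likely violate it.
- The epsilon substitution makes first-trial offline predictions
  sensitive to k in a way that is inherent to the published functional
  form; comparisons at k ≳ 0.3 should treat the first trial's predicted
  magnitude as a formal device, not a behavioral prediction.
- The offline proportion `100·Btot·j/Stot` inherits j's weak
  identifiability; it should be read with the recovery report alongside.
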