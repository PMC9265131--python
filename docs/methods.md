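# Methods

## The prediction problem

In a conventional milking parlour, the machine's pulsation ratio and
detachment threshold are herd-wide settings. Making them cow-specific
requires predicting, early in the session, (a) whether the cow is a slow
milker (average milking time, AMT ≥ 8 min) and (b) whether her removal
flow — the average flow over the seconds just before cluster detachment —
will reach 600 g/min. Both are binary classification tasks on five
features known two minutes into milking: mean flow in the 0–15, 15–30,
30–60 and 60–120 s windows, plus the 10-day average milk yield. "Value ≥
threshold" is fixed as the positive class for both tasks, with ties at
the threshold positive.

## LSSVM

The least-squares SVM replaces the SVM's hinge loss and inequality
constraints with a squared error and equality constraints. Its dual is
the bordered linear system

    [0  1ᵀ      ] [b]   [0]
    [1  Ω + I/C ] [α] = [y],    Ω_ij = exp(−‖x_i − x_j‖² / 2σ²),

solved once by dense LU with partial pivoting. The stationarity
conditions imply Σα_i = 0 and α_i = C·e_i (e_i the training residual);
both are verified to 1e-8/1e-7 in the test suite, and the solver is
cross-checked against an independent Gaussian-elimination oracle and the
Schur-complement (ridge) closed form. The solution is accepted only if
the KKT residual ∞-norm is ≤ 1e-8; the reciprocal condition number is
estimated from the LU factors (LAPACK `gecon`) and a `RuntimeWarning` is
emitted above 1e10. A decision value of exactly 0 predicts +1 (the sign
convention must be fixed somewhere; we state it).

Numerical notes: the weight on the margin term is fixed at 1, the
canonical Suykens–Vandewalle form — it is the only choice consistent
with the `Ω + I/C` system actually solved. The kernel distance is the
squared Euclidean distance in mean-normalized feature space with
denominator 2σ² exactly.

## Sparrow search algorithm (SSA)

A population metaheuristic: each iteration the flock is sorted by
fitness; the best `producer_frac` (producers) contract multiplicatively
toward the origin of their coordinates while the alarm value is below
the safety threshold ST, else take a common Gaussian step; the remaining
scroungers either re-disperse around the worst position (worse half) or
move to the best producer with a random ±1 projection step; finally a
random `scout_frac` of danger-aware birds jump relative to the global
best/worst. Positions are clipped into the search box after every
update; the recorded best is elitist, so the fitness trace is
non-increasing by construction. One seeded `numpy` generator drives
everything: a fixed seed reproduces the trajectory bitwise. Ties on
fitness resolve to the lowest index (stable argsort/argmin).

Defaults: population 20, 50 iterations, producer fraction 0.2, scout
fraction 0.1, ST 0.8, denominator guard ε = 1e-50. For (C, σ) the search
runs in log₁₀ space over C ∈ [10⁻², 10⁴], σ ∈ [10⁻², 10²] — log-space
boxes are the standard choice for scale parameters. The swarm fitness is
the mean misclassification rate of an inner stratified k-fold (fold
assignment fixed before the search, so the fitness is deterministic and
the whole tuning run is reproducible). Candidates whose KKT system is
singular receive fitness +∞.

## Cross-validation and metrics

Repeated stratified k-fold, default 5 folds × 10 repetitions, each
repetition reshuffled with a seed derived from the root seed via
`SeedSequence`. Mean normalization is fitted on each training fold and
applied to its test fold; a `normalize_on_all` switch reproduces the
variant where the means come from all rows. Metrics per confusion
matrix: accuracy (TP+TN)/(TP+TN+FP+FN), precision TP/(TP+FP), recall
TP/(TP+FN), F = 2PR/(P+R), with zero-denominator cases defined as 0 so
CV loops never raise. Aggregation is macro (per-fold metrics averaged)
with the pooled variant (one confusion matrix over all test predictions)
reported alongside, since either convention is defensible.

Baselines (KNN, Gaussian naive Bayes, decision tree, LDA) are stock
scikit-learn estimators evaluated on *identical* fold assignments as the
LSSVM variants; the fold digest is logged so the pairing is auditable.

**Tuning protocol.** In `compare_baselines` and
`feature_subset_experiment`, (C, σ) are tuned once per feature view by
inner-CV SSA on the full data and then evaluated by repeated k-fold at
the fixed pair. The alternative — re-tuning inside every outer fold —
multiplies the SSA cost by the fold count for a hyperparameter choice
that is stable across folds at these sample sizes; the residual optimism
from tuning-on-all affects all compared configurations equally, and the
paired contrasts (tuned vs untuned, full vs reduced features) are what
the experiments report.

## Synthetic herd generator

Per-session farm records are available only on request from the original
farm, so the package simulates a herd with the statistical structure the
tasks assume. Each cow's flow curve is

    f(t) = P(1 − e^{−t/τ_r})                 t ≤ t_s
    f(t) = f(t_s)·e^{−(t−t_s)/τ_d}           t > t_s

(P plateau flow g/min, τ_r rise time constant, t_s decline onset, τ_d
decline time constant, all log-normal across cows). Every recorded
quantity has a closed form: window means and session yield by piecewise
integration, peak flow f(t_s), AMT as the threshold-crossing time plus a
machine reaction delay plus attachment overhead, and removal flow as the
mean flow over the final `removal_window_s` seconds before the cluster
comes off. Because the machine reacts a few seconds late and its
effective threshold jitters (log-sd `threshold_cv`), recorded removal
flows straddle the 600 g/min set point — that is what creates the
negative class of the removal-flow task. Multiplicative log-normal
measurement noise (CV `noise_cv`) applies to all reported flows.

Two latent links carry the signal:

* `yield_link_strength` — correlation between the cow's productivity
  latent (which sets `avg_yield_10d`) and the decline onset t_s. Since
  t_s mostly exceeds 120 s, the early windows barely see it: prior yield
  carries *unique* AMT information, and severing the link (strength 0)
  removes it.
* `flow_decline_corr` — correlation between plateau P and decline rate
  τ_d. The early windows observe P and τ_r well, so they predict τ_d and
  hence both the AMT tail and the removal flow. Prior yield is *not*
  linked to τ_d, so it carries nothing about removal flow.

Calibration targets the published parlour scales, back-calculated from
the curve's closed forms and confirmed by Monte-Carlo: the default
(slow-herd) configuration — P median 3700 g/min, t_s median 170 s,
τ_d median 150 s — gives mean AMT ≈ 8.8 min, peak time ≈ 2.9 min, mean
session yield ≈ 19 kg, AMT ≥ 8 min for ≈ 57 % of cows, and removal flow
≥ 600 g/min for ≈ 75 % of sessions (a positive-dominant regime in which
the removal-flow task is recall-heavy). `general_config` (P median 6400,
t_s 130 s, τ_d 55 s) gives mean AMT ≈ 5.3 min. `high_signal_config`
saturates both latent links and shrinks the jitter, making AMT a nearly
deterministic function of the features — the configuration used to
verify that the full pipeline can recover a strong signal (repeated-CV
accuracy ≈ 0.92–0.94 at n = 300 with 5 % measurement noise).

What the simulator does **not** emulate: bimodal milk-ejection curves,
quarter-level variation, day-to-day autocorrelation within cow, lactation
-stage drift, and any dependence of the curve on the machine settings
themselves (pulsation ratio effects are outside the generative model).
Passing tests therefore show that the pipeline recovers the designed
statistical structure at realistic scales and noise levels — not that
the published farm-data performance is reproduced.

## Experiment and script problem sizes

The package's experiments run at desk scale, chosen as the smallest
sizes at which the designed effects are stable across seeds: herds of
300 single-session cows for the learning experiments (1000 for the
cross-validated headline metrics and calibration checks), SSA with
population 10–20 and 12–100 iterations depending on the role
(hyperparameter tuning vs the sphere benchmark), inner 3-fold tuning,
and medians over 10 seeds for the stochastic contrasts. Reported
quantities in `scripts/acceptance.py` use 5-seed medians for the
reduced-feature deltas and 5×5-fold CV for the headline metrics.

## Known limitations

* The dense LU solve is O(N³); fine for parlour-scale N (hundreds to a
  few thousand), not for large datasets — no low-rank or iterative
  variant is provided.
* The tune-once protocol (above) slightly optimistically biases absolute
  CV metrics; paired contrasts are unaffected.
* SSA's producer step contracts toward the coordinate origin, so its
  exploration is not translation-invariant; for the bounded log-space
  hyperparameter box this is immaterial, and the benchmark contract
  (beats equal-budget random search on the sphere in median) is tested,
  not assumed.
* The removal-flow task is intentionally weak-signal (the recorded value
  is dominated by threshold jitter): models hover near the positive-class
  prevalence with near-1 recall. That regime is a design choice of the
  generator, not an estimate of any real herd's predictability.
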