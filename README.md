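# milkpredict

Cow-specific milking prediction for conventional (non-automatic) milking
parlours. Within the first two minutes of a milking session, the pipeline
predicts two per-cow decisions a milking machine could act on:

* **AMT** — will this cow's average milking time be **≥ 8 min**? (Slow
  milkers benefit from a higher pulsation ratio, e.g. 65:35 instead of
  60:40.)
* **Removal flow** — will her detachment-time flow be **≥ 600 g/min**?
  (Cows with low removal flow risk overmilking; the detachment threshold
  can be raised for them.)

The inputs are five features available two minutes into milking: the mean
flow rates over the 0–15 s, 15–30 s, 30–60 s and 60–120 s windows, and
the cow's average milk yield over the previous 10 days.

## Model

The classifier is a **least-squares support vector machine** (LSSVM) with
an RBF kernel. With training pairs (xᵢ, yᵢ), yᵢ ∈ {+1, −1}, the LSSVM
minimizes ½‖w‖² + (C/2)Σeᵢ² subject to yᵢ = wᵀφ(xᵢ) + b + eᵢ, so the dual
problem is a single linear system rather than a quadratic program:

```
[ 0   1ᵀ        ] [ b ]   [ 0 ]
[ 1   Ω + I/C   ] [ α ] = [ y ],      Ωᵢⱼ = K(xᵢ, xⱼ) = exp(−‖xᵢ−xⱼ‖² / 2σ²)
```

with decision function sgn(Σᵢ αᵢ K(xᵢ, x) + b). The two hyperparameters
(C, σ) are tuned by the **sparrow search algorithm** (SSA), a swarm
metaheuristic with producer / scrounger / danger-aware roles, minimizing
the inner cross-validation misclassification rate over a log₁₀ box
C ∈ [10⁻², 10⁴], σ ∈ [10⁻², 10²]. Features are mean-normalized
(xₙ = x / x̄, fitted per training fold) and performance is reported as
accuracy, precision, recall and F-measure under repeated stratified
5-fold cross-validation, against stock baselines (KNN, naive Bayes,
decision tree, LDA) on identical folds.

Because per-session farm records are not publicly deposited, the package
ships a **synthetic herd simulator**: each cow gets a saturating-rise /
exponential-decline flow curve whose latents carry the task structure
(prior yield is linked to the decline onset and hence to AMT; the decline
rate is linked to the plateau flow and hence visible in the early
windows). All recorded quantities derive from the curve in closed form.

## Worked example

```python
import milkpredict as mp
from milkpredict.selection import (
    CVConfig, default_ssa_config, fit_ssa_lssvm, lssvm_factory, repeated_kfold,
)

records = mp.simulate_herd(mp.slow_cow_config(n_cows=300, sessions_per_cow=1, seed=0))
X = mp.extract_features(records)
y = mp.make_labels(records, mp.AMT)          # +1: AMT >= 8 min

model, trace = fit_ssa_lssvm(
    X, y,
    ssa=default_ssa_config(seed=0, pop_size=10, max_iter=15),
    inner_cv=CVConfig(k=3, repetitions=1, seed=0),
)
print(f"selected C={model.C:.3g}, sigma={model.sigma:.3g}, "
      f"inner-CV error={trace.best_fitness:.3f}")

report = repeated_kfold(
    X, y, lssvm_factory(model.C, model.sigma),
    cv=CVConfig(k=5, repetitions=10, seed=0),
)
print(f"repeated 5x10 CV: accuracy={report.accuracy:.3f} "
      f"precision={report.precision:.3f} recall={report.recall:.3f} "
      f"F={report.f_measure:.3f}")
```

Output:

```
selected C=1.51e+03, sigma=1.47, inner-CV error=0.093
repeated 5x10 CV: accuracy=0.905 precision=0.914 recall=0.908 F=0.910
```

The swarm picks a large C and σ ≈ 1.5 on the mean-normalized features;
the tuned model then classifies about 90 % of held-out sessions of this
300-cow herd correctly at the 8-min cut. The same workflow is available
from the shell:

```sh
milkpredict simulate --seed 1 --n-cows 300 --out herd.csv
milkpredict train    --input herd.csv --task AMT --seed 1 --out run/
milkpredict evaluate --input herd.csv --model run/model.json --task AMT --out run/
milkpredict compare  --input herd.csv --task AMT --seed 1 --out run/
```

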