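"""Sparrow search algorithm: a bounded-box swarm minimizer.

The population splits into three behavioural roles each iteration:

* **Producers** (the best ``producer_frac`` of the flock) search widely.
  While the alarm value R2 (a fresh uniform draw) stays below the safety
  threshold ST, producer ``rank`` contracts multiplicatively by
  ``exp(-rank / (a * max_iter))`` with ``a ~ U(0, 1]``; once R2 >= ST the
  flock is alarmed and producers take a common Gaussian step.
* **Scroungers** (the rest) follow. The worse half re-disperses around
  the worst position; the better half moves to the best producer with a
  random per-dimension +/-1 projection step.
* **Scouts** (a random ``scout_frac`` of the flock, the danger-aware
  birds) either jump toward the global best scaled by a Gaussian factor
  (if they are not at the best) or, if already at the best fitness, step
  away relative to their distance from the worst.

Every proposed position is clipped into the search box, and the recorded
best is elitist: the reported history is non-increasing by construction.
All randomness flows from one seeded generator, so a fixed seed gives a
bitwise-identical trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["SSAConfig", "OptimizationResult", "ssa_minimize"]

_EPS = 1e-50  # guards the scout denominator, per the canonical formulation


@dataclass
class SSAConfig:
    """Swarm settings and the per-dimension search box."""

    bounds: Sequence[tuple[float, float]]
    pop_size: int = 20
    max_iter: int = 50
    producer_frac: float = 0.2
    scout_frac: float = 0.1
    safety_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        if not self.bounds:
            raise ValueError("at least one dimension required")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bound ({lo}, {hi})")
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.producer_frac < 1 or not 0 < self.scout_frac < 1:
            raise ValueError("producer_frac and scout_frac must be in (0, 1)")
        if int(self.pop_size * self.producer_frac) < 1:
            raise ValueError("pop_size * producer_frac must be >= 1")
        if not 0.5 <= self.safety_threshold <= 1.0:
            raise ValueError("safety_threshold must be in [0.5, 1]")

    @property
    def n_dim(self) -> int:
        return len(self.bounds)


@dataclass
class OptimizationResult:
    """Best-found position and the elitist fitness trace."""

    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray = field(repr=False)
    evaluations: int = 0


def ssa_minimize(
    fitness: Callable[[np.ndarray], float], config: SSAConfig
) -> OptimizationResult:
    """Minimize ``fitness`` over the box; deterministic given the seed.

    Non-finite fitness values are treated as +inf (the sparrow simply
    never becomes the best); if every initial sparrow is non-finite the
    run aborts with :class:`ValueError`.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    n, d = config.pop_size, config.n_dim
    evaluations = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal evaluations
        evaluations += 1
        v = float(fitness(x))
        return v if np.isfinite(v) else np.inf

    pos = lo + rng.uniform(size=(n, d)) * (hi - lo)
    fit = np.array([evaluate(pos[i]) for i in range(n)])
    if not np.isfinite(fit).any():
        raise ValueError("fitness is non-finite at every initial position")

    best_idx = int(np.argmin(fit))  # argmin takes the lowest index on ties
    best_pos = pos[best_idx].copy()
    best_fit = fit[best_idx]
    history = [best_fit]

    n_prod = max(1, int(round(n * config.producer_frac)))
    n_scout = max(1, int(round(n * config.scout_frac)))

    for it in range(1, config.max_iter + 1):
        order = np.argsort(fit, kind="stable")
        pos = pos[order]
        fit = fit[order]
        worst_pos = pos[-1].copy()

        # -- producers -------------------------------------------------
        r2 = rng.uniform()
        for rank in range(n_prod):
            if r2 < config.safety_threshold:
                a = rng.uniform(np.finfo(float).tiny, 1.0)
                pos[rank] = pos[rank] * np.exp(-(rank + 1) / (a * config.max_iter))
            else:
                pos[rank] = pos[rank] + rng.normal() * np.ones(d)
        np.clip(pos[:n_prod], lo, hi, out=pos[:n_prod])
        best_producer = pos[int(np.argmin(fit[:n_prod]))].copy()

        # -- scroungers ------------------------------------------------
        for rank in range(n_prod, n):
            if rank > n / 2:
                q = rng.normal()
                pos[rank] = q * np.exp((worst_pos - pos[rank]) / (rank + 1) ** 2)
            else:
                sign = rng.integers(0, 2, size=d) * 2 - 1
                step = float(np.abs(pos[rank] - best_producer) @ sign) / d
                pos[rank] = best_producer + step
        np.clip(pos[n_prod:], lo, hi, out=pos[n_prod:])

        fit = np.array([evaluate(pos[i]) for i in range(n)])

        # -- scouts (danger-aware sparrows) ----------------------------
        f_best_now = fit.min()
        f_worst_now = fit.max()
        worst_now = pos[int(np.argmax(fit))].copy()
        scouts = rng.permutation(n)[:n_scout]
        for i in scouts:
            if fit[i] > f_best_now:
                beta = rng.normal()
                pos[i] = best_pos + beta * np.abs(pos[i] - best_pos)
            else:
                k = rng.uniform(-1.0, 1.0)
                denom = (fit[i] - f_worst_now) + _EPS
                pos[i] = pos[i] + k * np.abs(pos[i] - worst_now) / denom
            pos[i] = np.clip(pos[i], lo, hi)
            fit[i] = evaluate(pos[i])

        it_best = int(np.argmin(fit))
        if fit[it_best] < best_fit:
            best_fit = fit[it_best]
            best_pos = pos[it_best].copy()
        history.append(best_fit)

    return OptimizationResult(
        best_position=best_pos,
        best_fitness=float(best_fit),
        history=np.asarray(history),
        evaluations=evaluations,
    )
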