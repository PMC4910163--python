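"""Particle swarm optimization with an aging leader and challengers (ALC-PSO).

Plain PSO can converge prematurely: a leader sitting on a local optimum drags
the whole swarm there. ALC-PSO gives the leader a finite lifespan that is
lengthened while it shows "leading power" (it keeps improving the swarm) and
shortened when it does not. When the leader outlives its lifespan, a
challenger — the leader with a fraction of dimensions re-drawn uniformly
within bounds — takes over on trial; it is kept only if it improves the swarm
within a small number of trial iterations.

The optimizer maximizes a (optionally vectorized) objective on a bounded box
and is fully deterministic given a seed. The best-ever evaluated position is
always returned, so the per-iteration trace of best fitness is monotone
non-decreasing by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

Objective = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class PsoConfig:
    """ALC-PSO parameters.

    Defaults follow the original aging-leader formulation: swarm of 20,
    inertia 0.4, acceleration coefficients 2.0, initial lifespan 60,
    challenger trial budget 2. ``stagnation_limit`` stops a run early after
    that many iterations without any best-ever improvement (None disables).
    """

    swarm_size: int = 20
    inertia: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    initial_lifespan: int = 60
    challenger_trials: int = 2
    max_iterations: int = 500
    seed: int = 0
    stagnation_limit: int | None = 50
    vmax_fraction: float = 0.5
    aging: bool = True  # False degrades to plain gbest PSO

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if not 0 < self.inertia < 1:
            raise ValueError("inertia must lie in (0, 1)")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.initial_lifespan < 1:
            raise ValueError("initial_lifespan must be >= 1")


@dataclass
class OptimizeResult:
    """Best-ever position/fitness and the per-iteration best-fitness trace."""

    position: np.ndarray
    fitness: float
    trace: np.ndarray
    n_evaluations: int


def _as_bounds(bounds: Sequence[tuple[float, float]], d: int) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if lo.size != d or hi.size != d:
        raise ValueError(f"expected {d} bound pairs, got {lo.size}")
    if np.any(lo >= hi):
        raise ValueError("invalid bounds: lo must be < hi in every dimension")
    return lo, hi


def optimize(
    objective: Objective,
    d: int,
    bounds: Sequence[tuple[float, float]],
    config: PsoConfig,
    init: np.ndarray | None = None,
) -> OptimizeResult:
    """Maximize ``objective`` on the box ``bounds`` (list of (lo, hi)).

    ``objective`` receives an (n, d) array of positions and must return a
    length-n fitness array (higher is better). ``init``, if given, seeds
    particle 0 — the pipeline passes the zero-delta point so the optimised
    result can never fall below the untrained baseline.

    With ``max_iterations = 0`` the swarm is not built at all and ``init``
    (or the box centre) is returned after a single evaluation: a true no-op
    baseline.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    lo, hi = _as_bounds(bounds, d)
    rng = np.random.default_rng(config.seed)

    if config.max_iterations == 0:
        x0 = np.asarray(init, dtype=float) if init is not None else (lo + hi) / 2
        f0 = float(np.asarray(objective(x0[None, :]))[0])
        return OptimizeResult(position=x0.copy(), fitness=f0,
                              trace=np.array([f0]), n_evaluations=1)

    n = config.swarm_size
    vmax = config.vmax_fraction * (hi - lo)

    X = lo + rng.random((n, d)) * (hi - lo)
    if init is not None:
        X[0] = np.clip(np.asarray(init, dtype=float), lo, hi)
    V = np.zeros((n, d))

    fit = np.asarray(objective(X), dtype=float)
    n_eval = n
    pbest = X.copy()
    pfit = fit.copy()

    i_best = int(np.argmax(pfit))
    leader = pbest[i_best].copy()
    leader_age = 0
    lifespan = config.initial_lifespan

    best_pos = pbest[i_best].copy()
    best_fit = float(pfit[i_best])
    trace = [best_fit]

    # challenger trial state
    trial_left = 0
    trial_improved = False
    prev_leader: np.ndarray | None = None
    prev_iter_max = float(np.max(fit))
    stagnant = 0

    for _ in range(config.max_iterations):
        r1 = rng.random((n, d))
        r2 = rng.random((n, d))
        V = (
            config.inertia * V
            + config.c1 * r1 * (pbest - X)
            + config.c2 * r2 * (leader[None, :] - X)
        )
        np.clip(V, -vmax, vmax, out=V)
        X = np.clip(X + V, lo, hi)
        fit = np.asarray(objective(X), dtype=float)
        n_eval += n

        improved_pb = fit > pfit
        pbest[improved_pb] = X[improved_pb]
        pfit[improved_pb] = fit[improved_pb]

        iter_max = float(np.max(fit))
        improved_global = iter_max > best_fit
        if improved_global:
            i = int(np.argmax(fit))
            best_fit = float(fit[i])
            best_pos = X[i].copy()
            stagnant = 0
        else:
            stagnant += 1
        trace.append(best_fit)

        if not config.aging:
            leader = best_pos.copy()
        elif trial_left > 0:
            # a challenger is on trial: it leads unmodified while its
            # leading power is assessed
            if improved_global or bool(np.any(improved_pb)):
                trial_improved = True
            trial_left -= 1
            if trial_left == 0:
                if trial_improved:
                    leader_age = 0
                    lifespan = config.initial_lifespan
                else:
                    # challenger failed: fall back to the best-known solution
                    leader = best_pos.copy()
                    leader_age = 0
        else:
            # the leader is improved by any better solution the swarm finds;
            # its age is retained
            if improved_global:
                leader = best_pos.copy()
            # lifespan control by leading power (+2 / +1 / 0 / -1)
            if improved_global:
                lifespan += 2
            elif bool(np.any(improved_pb)):
                lifespan += 1
            elif iter_max > prev_iter_max:
                pass
            else:
                lifespan = max(1, lifespan - 1)
            leader_age += 1
            if leader_age > lifespan:
                challenger = leader.copy()
                mutate = rng.random(d) < 1.0 / d
                if not np.any(mutate):
                    mutate[int(rng.integers(d))] = True
                fresh = lo + rng.random(d) * (hi - lo)
                challenger[mutate] = fresh[mutate]
                leader = challenger
                trial_left = config.challenger_trials
                trial_improved = False

        prev_iter_max = iter_max
        if config.stagnation_limit is not None and stagnant >= config.stagnation_limit:
            break

    return OptimizeResult(
        position=best_pos, fitness=best_fit,
        trace=np.asarray(trace), n_evaluations=n_eval,
    )


def optimize_plain(
    objective: Objective,
    d: int,
    bounds: Sequence[tuple[float, float]],
    config: PsoConfig,
    init: np.ndarray | None = None,
) -> OptimizeResult:
    """Plain gbest PSO baseline (aging disabled), same contract as
    :func:`optimize`. Used to benchmark the aging mechanism."""
    return optimize(objective, d, bounds, replace(config, aging=False), init=init)


def trace_to_csv(result: OptimizeResult, path: str) -> None:
    """Export the best-fitness trace as (iteration, best_fitness) CSV."""
    with open(path, "w") as fh:
        fh.write("iteration,best_fitness\n")
        for i, v in enumerate(result.trace):
            fh.write(f"{i},{v!r}\n")
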