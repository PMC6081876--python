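"""Global-best particle swarm optimisation.

A plain gbest PSO over a bounded box: each particle's velocity is a blend of
inertia, attraction to its personal best and attraction to the swarm best,

    v <- w*v + c1*r1*(p_best - x) + c2*r2*(g_best - x),   x <- x + v,

with r1, r2 drawn uniformly per dimension.  Positions are clamped to the
bounds and the offending velocity component zeroed.  Coefficients default to
the Clerc constriction values (w = 0.72, c1 = c2 = 1.49).  Because the
physiological parameters optimised here span many orders of magnitude,
particles are initialised log-uniformly over each interval by default.

All randomness flows through a single seeded generator; the same seed gives
bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import InvalidInputError, ZebraTKError

__all__ = ["PSOConfig", "OptimizationResult", "pso_maximize", "r2_vs_identity"]


@dataclass(frozen=True)
class PSOConfig:
    """Swarm size, coefficients, bounds and termination rules.

    ``score_cutoff``: stop as soon as the swarm best reaches this score
    (``None`` disables early stopping).  ``init`` is ``"log-uniform"`` (the
    default, requires strictly positive lower bounds) or ``"uniform"``.
    """

    bounds: Sequence[tuple[float, float]]
    n_particles: int = 1000
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    max_iterations: int = 500
    score_cutoff: float | None = None
    seed: int | None = None
    init: str = "log-uniform"

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise InvalidInputError("n_particles must be >= 1")
        if self.max_iterations < 0:
            raise InvalidInputError("max_iterations must be >= 0")
        for c in (self.inertia, self.cognitive, self.social):
            if not np.isfinite(c):
                raise InvalidInputError("PSO coefficients must be finite")
        if self.init not in ("log-uniform", "uniform"):
            raise InvalidInputError("init must be 'log-uniform' or 'uniform'")
        bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        object.__setattr__(self, "bounds", bounds)
        for lo, hi in bounds:
            if not lo < hi:
                if lo == hi:
                    continue  # degenerate interval pins the parameter
                raise InvalidInputError(f"bound ({lo}, {hi}) has lower > upper")
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise InvalidInputError("bounds must be finite")
            if self.init == "log-uniform" and lo <= 0:
                raise InvalidInputError(
                    "log-uniform initialisation requires strictly positive "
                    "lower bounds (physiological parameters are positive); "
                    "use init='uniform' for transformed coordinates"
                )

    def replace(self, **kwargs) -> "PSOConfig":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass(frozen=True)
class OptimizationResult:
    """Best position/score found by the swarm and run provenance."""

    best_position: np.ndarray
    best_score: float
    iterations_run: int
    seed: int | None
    converged: bool
    n_nonfinite: int = 0


def _evaluate(objective, x: np.ndarray, vectorized: bool) -> tuple[np.ndarray, int]:
    if vectorized:
        scores = np.asarray(objective(x), dtype=float)
    else:
        scores = np.array([objective(p) for p in x], dtype=float)
    bad = ~np.isfinite(scores)
    scores[bad] = -np.inf
    return scores, int(bad.sum())


def pso_maximize(
    objective: Callable,
    config: PSOConfig,
    vectorized: bool = False,
) -> OptimizationResult:
    """Maximise ``objective`` over the configured box.

    ``objective`` takes one position vector (or, with ``vectorized=True``,
    an ``(n_particles, d)`` array returning ``(n_particles,)`` scores).
    Non-finite scores are treated as ``-inf`` and counted; a swarm whose
    scores are all non-finite at initialisation is an error.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    n, d = config.n_particles, len(config.bounds)

    span = hi > lo
    x = np.broadcast_to(lo, (n, d)).copy()
    if config.init == "log-uniform":
        u = rng.uniform(size=(n, d))
        with np.errstate(divide="ignore"):
            x[:, span] = np.exp(
                np.log(lo[span]) + u[:, span] * (np.log(hi[span]) - np.log(lo[span]))
            )
    else:
        u = rng.uniform(size=(n, d))
        x[:, span] = lo[span] + u[:, span] * (hi[span] - lo[span])
    v = np.zeros((n, d))

    scores, n_nonfinite = _evaluate(objective, x, vectorized)
    if not np.any(np.isfinite(scores)):
        raise ZebraTKError(
            "objective returned non-finite scores for the entire initial swarm"
        )
    pbest_x = x.copy()
    pbest_s = scores.copy()
    g = int(np.argmax(pbest_s))
    gbest_x, gbest_s = pbest_x[g].copy(), float(pbest_s[g])

    converged = (
        config.score_cutoff is not None and gbest_s >= config.score_cutoff
    )
    it = 0
    while not converged and it < config.max_iterations:
        it += 1
        r1 = rng.uniform(size=(n, d))
        r2 = rng.uniform(size=(n, d))
        v = (
            config.inertia * v
            + config.cognitive * r1 * (pbest_x - x)
            + config.social * r2 * (gbest_x - x)
        )
        x = x + v
        out = (x < lo) | (x > hi)
        x = np.clip(x, lo, hi)
        v[out] = 0.0

        scores, bad = _evaluate(objective, x, vectorized)
        n_nonfinite += bad
        improved = scores > pbest_s
        pbest_x[improved] = x[improved]
        pbest_s[improved] = scores[improved]
        g = int(np.argmax(pbest_s))
        if pbest_s[g] > gbest_s:
            gbest_s = float(pbest_s[g])
            gbest_x = pbest_x[g].copy()
        if config.score_cutoff is not None and gbest_s >= config.score_cutoff:
            converged = True

    return OptimizationResult(
        best_position=gbest_x,
        best_score=gbest_s,
        iterations_run=it,
        seed=config.seed,
        converged=converged,
        n_nonfinite=n_nonfinite,
    )


def r2_vs_identity(predicted, observed) -> float:
    """Coefficient of determination of predictions against the line y = x.

    ``1 - sum((pred - obs)^2) / sum((obs - mean(obs))^2)``; residuals are
    taken against the identity line, not a fitted one, so the score may be
    negative.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise InvalidInputError("predicted and observed must be equal-length 1-D")
    if pred.size < 2:
        raise InvalidInputError("need at least 2 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise InvalidInputError("observed values have zero variance; R^2 undefined")
    ss_res = float(np.sum((pred - obs) ** 2))
    return 1.0 - ss_res / ss_tot
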