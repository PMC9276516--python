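"""Particle swarm optimization (PSO) of initial FCM cluster centers.

FCM's alternate optimization converges to a local minimum of its
objective, so the starting centers matter.  A small global-best particle
swarm searches center space first: each particle is a candidate vector
of c scalar centers, its fitness is the FCM objective itself (with
memberships filled in optimally for those centers), and particles move
under inertia plus attraction to their personal best and the swarm's
global best.  The returned global-best position, sorted ascending, seeds
the FCM loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidConfigError, InvalidInputError
from .fcm_core import compute_distances, objective, update_membership

__all__ = ["PSOConfig", "pso_fitness", "pso_init_centers"]


@dataclass(frozen=True)
class PSOConfig:
    """Swarm hyperparameters.

    Defaults are canonical stable settings: inertia 0.72 with cognitive
    and social coefficients 1.49 (constriction-equivalent), swarm of 20
    particles for 50 iterations, velocities clamped to 20% of the data
    range.
    """

    swarm_size: int = 20
    iterations: int = 50
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    seed: int = 0
    velocity_clamp: float = 0.2

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise InvalidConfigError(
                f"swarm_size must be >= 2, got {self.swarm_size}"
            )
        if self.iterations < 1:
            raise InvalidConfigError(
                f"iterations must be >= 1, got {self.iterations}"
            )
        if not 0.0 <= self.inertia <= 1.0:
            raise InvalidConfigError(f"inertia must be in [0, 1], got {self.inertia}")
        if not (self.cognitive > 0 and self.social > 0):
            raise InvalidConfigError("cognitive and social weights must be > 0")
        if not self.velocity_clamp > 0:
            raise InvalidConfigError(
                f"velocity_clamp must be > 0, got {self.velocity_clamp}"
            )


def pso_fitness(position: np.ndarray, features: np.ndarray, m: float = 2.0) -> float:
    """FCM objective of a candidate center vector (lower is better).

    Memberships are filled in by the closed-form optimal update for the
    given centers, so the fitness is the best objective value those
    centers can achieve.
    """
    pos = np.asarray(position, dtype=float).ravel()
    if not np.all(np.isfinite(pos)):
        raise InvalidInputError("candidate centers contain non-finite values")
    d = compute_distances(features, pos)
    u = update_membership(d, m)
    return objective(u, d, m)


def pso_init_centers(
    features: np.ndarray,
    c: int,
    pso: PSOConfig | None = None,
    m: float = 2.0,
    return_history: bool = False,
):
    """Global-best PSO over candidate center vectors.

    Velocity and position updates are the standard rule
    ``v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x); x <- x + v``
    with positions clamped to the data range and velocities clamped to
    ``velocity_clamp`` times that range.  Bit-reproducible for equal
    seeds.  Returns the global-best centers sorted ascending (and the
    per-iteration global-best fitness trace if ``return_history``).
    """
    pso = pso or PSOConfig()
    x = np.asarray(features, dtype=float).ravel()
    if x.size == 0:
        raise InvalidInputError("feature set is empty")
    if c < 1:
        raise InvalidConfigError(f"cluster count must be >= 1, got {c}")

    rng = np.random.default_rng(pso.seed)
    lo, hi = float(x.min()), float(x.max())
    span = hi - lo or 1.0
    vmax = pso.velocity_clamp * span

    pos = rng.uniform(lo, hi, size=(pso.swarm_size, c))
    vel = rng.uniform(-vmax, vmax, size=(pso.swarm_size, c))
    fit = np.array([pso_fitness(p, x, m) for p in pos])
    pbest = pos.copy()
    pbest_fit = fit.copy()
    g = int(np.argmin(fit))
    gbest = pos[g].copy()
    gbest_fit = float(fit[g])
    history = [gbest_fit]

    for _ in range(pso.iterations):
        r1 = rng.random(size=pos.shape)
        r2 = rng.random(size=pos.shape)
        vel = (
            pso.inertia * vel
            + pso.cognitive * r1 * (pbest - pos)
            + pso.social * r2 * (gbest[None, :] - pos)
        )
        np.clip(vel, -vmax, vmax, out=vel)
        pos = np.clip(pos + vel, lo, hi)
        fit = np.array([pso_fitness(p, x, m) for p in pos])
        improved = fit < pbest_fit
        pbest[improved] = pos[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest_fit = float(pbest_fit[g])
            gbest = pbest[g].copy()
        history.append(gbest_fit)

    centers = np.sort(gbest)
    if return_history:
        return centers, np.asarray(history)
    return centers
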