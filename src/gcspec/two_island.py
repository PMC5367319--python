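"""Genetic-distance dynamics between two islands.

The distance ``z`` — the fraction of incompatibility loci at which the two
populations are fixed for different alleles — evolves under two opposing
forces.  Mutation-and-fixation on either island turns shared loci into
differing ones at rate ``u`` per locus; a successful migration event
(Poisson rate ``m`` in each direction) lets the migrant allele fix at each
differing locus independently with probability ``epsilon``, pulling ``z``
back down.  In the diffusion approximation

.. math::  \\Delta z = M(z)\\,\\Delta t + \\sqrt{V(z)\\,\\Delta t}\\;\\xi,

with drift and variance rate

.. math::

    M(z) = 2u(1-z) - 2 m \\varepsilon z, \\qquad
    V(z) = \\frac{2u(1-z)}{l}
         + 2m\\Big[(\\varepsilon z)^2
         + \\frac{\\varepsilon z (1-\\varepsilon)}{l}\\Big].

The three variance sources are the Poisson timing of allelic replacements,
the Poisson timing of migration events, and the binomial sampling of which
loci fix the migrant allele.  Speciation occurs when ``z`` first exceeds the
threshold ``z_c``; because fluctuations scale like ``1/l`` and with the
migration-event size ``epsilon``, a threshold above the deterministic
equilibrium ``z* = u/(u + m*eps)`` is still reached in finite time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import ModelParams

__all__ = [
    "TwoIslandState",
    "drift_two_island",
    "diffusion_two_island",
    "step_two_island",
    "equilibrium_two_island",
    "deterministic_two_island",
    "first_passage_two_island",
    "simulate_two_island",
    "FirstPassageSample",
]


@dataclass(frozen=True)
class TwoIslandState:
    """Time (generations) and genetic distance of the two-island system."""

    t: float
    z: float

    def __post_init__(self):
        if not 0 <= self.z <= 1:
            raise ValueError(f"genetic distance must lie in [0, 1], got {self.z}")


def _symmetric_rates(params: ModelParams) -> tuple[float, float, float, float]:
    m = params.symmetric_m()
    return params.u, m, params.epsilon, params.l


def drift_two_island(z, params: ModelParams):
    """Mean rate of change of the distance, ``M(z) = 2u(1-z) - 2m*eps*z``.

    The four underlying processes — allelic replacement on each island and
    migration in each direction — contribute ``u(1-z)`` and ``-m*eps*z``
    apiece.  Accepts scalar or array ``z``.
    """
    u, m, eps, _ = _symmetric_rates(params)
    z = np.asarray(z, dtype=float)
    out = 2.0 * u * (1.0 - z) - 2.0 * m * eps * z
    return out if out.ndim else float(out)


def diffusion_two_island(z, params: ModelParams):
    """Variance-generating rate ``V(z)`` of the distance.

    ``V(z) = 2u(1-z)/l + 2m[(eps*z)^2 + eps*z*(1-eps)/l]``.  The ``1/l``
    terms (replacement timing and migrant-allele sampling) vanish in the
    infinite-locus limit, leaving only the migration-timing term.
    """
    u, m, eps, l = _symmetric_rates(params)
    z = np.asarray(z, dtype=float)
    per_locus = 0.0 if l == math.inf else 1.0 / l
    out = (
        2.0 * u * (1.0 - z) * per_locus
        + 2.0 * m * ((eps * z) ** 2 + z * eps * (1.0 - eps) * per_locus)
    )
    return out if out.ndim else float(out)


def equilibrium_two_island(params: ModelParams) -> float:
    """Deterministic equilibrium distance, the root of the drift.

    Setting ``M(z) = 0`` gives ``z* = u / (u + m*eps)``: the balance point
    between mutation-driven divergence and migration-driven homogenisation.
    With no migration the populations diverge completely (``z* = 1``).
    """
    u, m, eps, _ = _symmetric_rates(params)
    denom = u + m * eps
    if denom <= 0:
        raise ValueError("u + m*eps must be positive to define an equilibrium")
    return u / denom


def deterministic_two_island(t, params: ModelParams, z0: float = 0.0):
    """Closed-form solution of ``dz/dt = M(z)`` from ``z(0) = z0``.

    The drift is affine, so ``z(t) = z* + (z0 - z*) exp(-2(u + m*eps) t)``.
    With ``m = 0`` this reduces to ``z(t) = 1 - (1 - z0) exp(-2ut)``.
    """
    u, m, eps, _ = _symmetric_rates(params)
    rate = 2.0 * (u + m * eps)
    zstar = equilibrium_two_island(params)
    t = np.asarray(t, dtype=float)
    out = zstar + (z0 - zstar) * np.exp(-rate * t)
    return out if out.ndim else float(out)


def _check_dt(params: ModelParams, dt: float) -> None:
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    u, m = params.u, max(params.m.values(), default=0.0)
    if u * dt > 0.1 or m * dt > 0.1:
        warnings.warn(
            f"dt = {dt} is large relative to the event rates (u*dt = {u * dt:.3g}, "
            f"m*dt = {m * dt:.3g}); the Euler-Maruyama step assumes both << 1",
            stacklevel=3,
        )


def step_two_island(
    state: TwoIslandState, params: ModelParams, dt: float, rng: np.random.Generator
) -> TwoIslandState:
    """One Euler-Maruyama step of the distance SDE, clipped to [0, 1]."""
    _check_dt(params, dt)
    z = _step_batch(np.array([state.z]), params, dt, rng)[0]
    return TwoIslandState(t=state.t + dt, z=float(z))


def _step_batch(
    z: np.ndarray, params: ModelParams, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised Euler-Maruyama step for an array of independent replicates."""
    xi = rng.standard_normal(z.shape)
    z_new = z + drift_two_island(z, params) * dt + np.sqrt(
        diffusion_two_island(z, params) * dt
    ) * xi
    return np.clip(z_new, 0.0, 1.0)


def simulate_two_island(
    params: ModelParams,
    z0: float = 0.0,
    dt: float = 1.0,
    t_max: float = 1e5,
    record_stride: int = 1,
    rng: np.random.Generator | None = None,
    deterministic: bool = False,
) -> "np.recarray":
    """Simulate one trajectory; returns a structured array with fields t, z.

    With ``deterministic=True`` the noise is switched off and the recursion
    is the forward-Euler discretisation of ``dz/dt = M(z)``.
    """
    _check_dt(params, dt)
    if rng is None:
        rng = np.random.default_rng()
    n_steps = int(round(t_max / dt))
    times = [0.0]
    zs = [z0]
    z = np.array([z0], dtype=float)
    for k in range(1, n_steps + 1):
        if deterministic:
            z = np.clip(z + drift_two_island(z, params) * dt, 0.0, 1.0)
        else:
            z = _step_batch(z, params, dt, rng)
        if k % record_stride == 0:
            times.append(k * dt)
            zs.append(float(z[0]))
    out = np.rec.fromarrays(
        [np.array(times), np.array(zs)], names=["t", "z"]
    )
    return out


@dataclass
class FirstPassageSample:
    """Replicate first-passage times to ``z > z_c`` with censoring info.

    ``times`` holds the waiting time of each uncensored replicate;
    ``n_censored`` counts replicates still below threshold at ``t_max``.
    """

    times: np.ndarray
    n_censored: int
    t_max: float

    @property
    def n(self) -> int:
        return len(self.times) + self.n_censored

    @property
    def mean(self) -> float:
        if len(self.times) == 0:
            raise ValueError(
                f"all {self.n_censored} replicates were censored at t_max = {self.t_max}; "
                "no mean waiting time is defined"
            )
        return float(np.mean(self.times))

    @property
    def se(self) -> float:
        n = len(self.times)
        if n < 2:
            return float("nan")
        return float(np.std(self.times, ddof=1) / math.sqrt(n))


def first_passage_two_island(
    params: ModelParams,
    z0: float = 0.0,
    dt: float = 1.0,
    t_max: float = 1e7,
    reps: int = 100,
    rng: np.random.Generator | None = None,
) -> FirstPassageSample:
    """Waiting time until the distance first exceeds ``z_c``, per replicate.

    All replicates are stepped in lock-step as a vectorised batch; each stops
    (is frozen) once it crosses the threshold.  Replicates that never cross
    within ``t_max`` are reported as censored rather than folded into the
    mean.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    _check_dt(params, dt)
    if rng is None:
        rng = np.random.default_rng()
    z = np.full(reps, float(z0))
    hit_time = np.full(reps, np.nan)
    active = z <= params.z_c
    hit_time[~active] = 0.0  # already above threshold at t = 0
    t = 0.0
    n_steps = int(round(t_max / dt))
    for k in range(1, n_steps + 1):
        if not active.any():
            break
        t = k * dt
        z[active] = _step_batch(z[active], params, dt, rng)
        crossed = active & (z > params.z_c)
        hit_time[crossed] = t
        active &= ~crossed
    return FirstPassageSample(
        times=hit_time[~np.isnan(hit_time)],
        n_censored=int(np.isnan(hit_time).sum()),
        t_max=t_max,
    )
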