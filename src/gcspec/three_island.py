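"""Stochastic dynamics of geographical-configuration fractions on three islands.

With three islands the pairwise genetic distances are not a Markov state: a
single migration event lets many loci change configuration at once, which
correlates the changes of the three distances in a way the distances alone
cannot express.  The model therefore tracks the five configuration fractions
``z1..z5`` and derives distances from them.

Two operators act on the fractions over a short interval ``dt``:

**Mutation accumulation.**  Fixation of a novel allele on island ``alpha``
moves a locus from configuration ``i`` to a unique successor (e.g. fixation
on A sends (ABC) to (A)(BC)).  The flux of loci making each such move is

.. math:: g(\\alpha, i) = u z_i\\,dt + \\sqrt{u z_i\\,dt / l}\\;\\xi,

a Gaussian approximation to the Poisson number of fixations, and the same
realisation of ``g`` is subtracted from the source fraction and added to the
target, so the fractions always sum to one.

**Migration.**  Successful migration across the directed bond
``alpha -> beta`` occurs as a Poisson process with rate ``m_ab``; at each
event every locus whose configuration has a transition under that bond fixes
the migrant allele independently with probability ``epsilon``.  The flux of
loci making transition ``i -> j`` over ``dt`` is therefore compound Poisson
with binomial marks:

.. math::

   f(\\alpha\\beta, i \\to j) = m z_i \\varepsilon\\,dt
     + \\sqrt{m\\,dt}\\; z_i \\varepsilon\\; \\Delta W_0^{\\alpha\\beta}
     + \\sqrt{m z_i \\varepsilon (1-\\varepsilon)\\,dt / l}\\;\\Delta W_i,

whose mean, variance and covariance match the compound-Poisson moments
``E = m z_i eps dt`` and ``Var = m dt [(z_i eps)^2 + z_i eps (1-eps)/l]``.
The timing term ``dW_0`` is *shared* by the three transitions of one bond —
they are triggered by the same migration events — which produces the
within-bond covariance ``m dt z_i eps z_k eps`` that distinguishes, for
example, a genome split between (ABC) and (A)(B)(C) from one split evenly
among the three two-group configurations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (
    DIRECTED_BONDS,
    DIRECTED_TO_UNDIRECTED,
    BondGraph,
    GCFractions,
    ModelParams,
    SpeciationRecord,
    distances_from_array,
    distances_from_gc,
    normalize_gc,
    normalize_gc_array,
    speciation_state,
)

__all__ = [
    "ThreeIslandState",
    "MUTATION_FLOWS",
    "MIGRATION_TRANSITIONS",
    "mutation_transition_map",
    "migration_transition_map",
    "mutation_update",
    "migration_update",
    "increment_moments",
    "step_three_island",
    "simulate_three_island",
    "first_passage_three_island",
]

# ---------------------------------------------------------------------------
# Transition structure

#: Mutation flows (island, source config, target config): fixation of a new
#: allele on the island removes it from every sharing group it belonged to.
#: Configuration-preserving replacements (e.g. a new allele on A when A is
#: already distinct) do not move the locus and carry no flux.
MUTATION_FLOWS = (
    ("A", 1, 2),
    ("B", 1, 3),
    ("C", 1, 4),
    ("B", 2, 5),
    ("C", 2, 5),
    ("A", 3, 5),
    ("C", 3, 5),
    ("A", 4, 5),
    ("B", 4, 5),
)

#: For each directed bond alpha->beta, the three configuration transitions
#: enabled by fixation of the migrant allele on the destination island.
#: Configurations in which source and destination already share the allele
#: are fixed points of the bond.
MIGRATION_TRANSITIONS = {
    "AB": ((2, 4), (3, 1), (5, 4)),
    "BA": ((2, 1), (3, 4), (5, 4)),
    "AC": ((2, 3), (4, 1), (5, 3)),
    "CA": ((2, 1), (4, 3), (5, 3)),
    "BC": ((3, 2), (4, 1), (5, 2)),
    "CB": ((3, 1), (4, 2), (5, 2)),
}

_MUT_SRC = np.array([i - 1 for _, i, _ in MUTATION_FLOWS])
_MUT_DST = np.array([j - 1 for _, _, j in MUTATION_FLOWS])

_MIG_SRC = np.array(
    [i - 1 for b in DIRECTED_BONDS for i, _ in MIGRATION_TRANSITIONS[b]]
)
_MIG_DST = np.array(
    [j - 1 for b in DIRECTED_BONDS for _, j in MIGRATION_TRANSITIONS[b]]
)
_MIG_BOND = np.repeat(np.arange(6), 3)

_N_MUT = len(MUTATION_FLOWS)  # 9
_N_MIG = len(_MIG_SRC)  # 18


def _incidence(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-hot source / destination matrices of shape (n_flows, 5)."""
    n = len(src)
    S = np.zeros((n, 5))
    D = np.zeros((n, 5))
    S[np.arange(n), src] = 1.0
    D[np.arange(n), dst] = 1.0
    return S, D


_MUT_S, _MUT_D = _incidence(_MUT_SRC, _MUT_DST)
_MIG_S, _MIG_D = _incidence(_MIG_SRC, _MIG_DST)
#: Net effect of one unit of each flow on the five fractions.
_MUT_E = _MUT_D - _MUT_S
_MIG_E = _MIG_D - _MIG_S

#: Undirected-bond index of each directed bond, ordered like DIRECTED_BONDS.
_BOND_UND = np.array([DIRECTED_TO_UNDIRECTED[b] for b in DIRECTED_BONDS])


def mutation_transition_map(config: int, island: str) -> int:
    """Configuration reached when a novel allele fixes on ``island``.

    The island leaves whatever sharing group it belonged to; if it was
    already distinct the configuration is unchanged (a self-map).
    """
    if config not in (1, 2, 3, 4, 5):
        raise ValueError(f"invalid configuration label {config}")
    if island not in ("A", "B", "C"):
        raise ValueError(f"invalid island {island!r}")
    for isl, i, j in MUTATION_FLOWS:
        if isl == island and i == config:
            return j
    return config


def migration_transition_map(config: int, bond: str) -> int | None:
    """Configuration reached when a migrant allele fixes across ``bond``.

    ``bond`` is an ordered pair such as ``"AB"`` (migration from A into B).
    Returns ``None`` when source and destination islands already share the
    allele, in which case fixation changes nothing.
    """
    if config not in (1, 2, 3, 4, 5):
        raise ValueError(f"invalid configuration label {config}")
    if bond not in MIGRATION_TRANSITIONS:
        raise ValueError(f"invalid directed bond {bond!r}")
    for i, j in MIGRATION_TRANSITIONS[bond]:
        if i == config:
            return j
    return None


# ---------------------------------------------------------------------------
# SDE increments


@dataclass(frozen=True)
class ThreeIslandState:
    """Time, configuration fractions, and bond-graph status."""

    t: float
    gc: GCFractions
    graph: BondGraph


def _cap_flows(z: np.ndarray, f: np.ndarray, S: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Scale flows so that no configuration is drained below zero.

    ``z`` has shape (R, 5), ``f`` shape (R, n_flows).  A positive flow drains
    its source; a negative realisation drains its destination.  Whenever the
    total drain on a configuration exceeds its current mass, every flow
    draining it is scaled down proportionally.
    """
    pos = np.clip(f, 0.0, None)
    neg = np.clip(-f, 0.0, None)
    drain = pos @ S + neg @ D  # (R, 5)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(drain > z, z / np.where(drain > 0, drain, 1.0), 1.0)
    src_idx = np.argmax(S, axis=1)
    dst_idx = np.argmax(D, axis=1)
    flow_scale = np.where(f > 0, scale[:, src_idx], scale[:, dst_idx])
    return f * flow_scale


def _mutation_increments_batch(
    z: np.ndarray, params: ModelParams, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Mutation-accumulation increments for a batch of states (R, 5)."""
    u, l = params.u, params.l
    zi = z[:, _MUT_SRC]
    mean = u * zi * dt
    if l == math.inf:
        f = mean
    else:
        sd = np.sqrt(u * zi * dt / l)
        f = mean + sd * rng.standard_normal(zi.shape)
    f = _cap_flows(z, f, _MUT_S, _MUT_D)
    return f @ _MUT_E


def _migration_increments_batch(
    z: np.ndarray,
    params: ModelParams,
    open_mask: np.ndarray,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Migration increments for a batch; ``open_mask`` has shape (R, 6).

    The timing noise ``dW0`` is drawn once per bond and shared by that bond's
    three transitions, realising the within-bond covariance of the compound
    Poisson process; the fixation-sampling noise is independent per flow.
    """
    eps, l = params.epsilon, params.l
    m_eff = params.m_array() * open_mask  # (R, 6)
    m_flow = m_eff[:, _MIG_BOND]  # (R, 18)
    zi = z[:, _MIG_SRC]
    mean = m_flow * zi * eps * dt
    w0 = rng.standard_normal((z.shape[0], 6))
    timing = np.sqrt(m_flow * dt) * zi * eps * w0[:, _MIG_BOND]
    if l == math.inf:
        sampling = 0.0
    else:
        sampling = np.sqrt(
            m_flow * zi * eps * (1.0 - eps) * dt / l
        ) * rng.standard_normal(zi.shape)
    f = mean + timing + sampling
    f = _cap_flows(z, f, _MIG_S, _MIG_D)
    return f @ _MIG_E


def mutation_update(
    gc: GCFractions, params: ModelParams, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Increment of the five fractions from mutation accumulation over ``dt``.

    Each of the nine mutation flows is realised once and applied with
    opposite signs to its source and target, so the increments sum to zero
    exactly.  Configuration 5 is absorbing: no mutation flow leaves it.
    """
    z = gc.as_array()[None, :]
    return _mutation_increments_batch(z, params, dt, rng)[0]


def migration_update(
    gc: GCFractions,
    params: ModelParams,
    graph: BondGraph,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Increment of the five fractions from migration over ``dt``.

    Only open bonds contribute; a closed bond means migrants cannot mix, so
    its effective rate is zero.  Flows out of a configuration are capped at
    its current mass so no fraction can be driven negative within one step.
    """
    z = gc.as_array()[None, :]
    open_mask = graph.open_mask()[None, :]
    return _migration_increments_batch(z, params, open_mask, dt, rng)[0]


def increment_moments(
    gc: GCFractions,
    params: ModelParams,
    dt: float,
    graph: BondGraph | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic mean and covariance of the one-step increment ``dz``.

    Returns the mean five-vector and the 5x5 covariance matrix implied by
    the flow construction: independent Gaussian mutation fluxes with
    ``Var = u z_i dt / l``, and migration fluxes with compound-Poisson
    moments — ``Var = m dt [(z_i eps)^2 + z_i eps (1-eps)/l]`` and, between
    two transitions of the same bond, ``Cov = m dt z_i eps z_k eps``.

    These are the diffusion coefficients the jump-process oracle must
    reproduce empirically; boundary capping is ignored (it only binds when a
    fraction is within one step of zero).
    """
    z = gc.as_array()
    u, eps, l = params.u, params.epsilon, params.l
    per_locus = 0.0 if l == math.inf else 1.0 / l
    open_mask = np.ones(6) if graph is None else graph.open_mask().astype(float)
    m_eff = params.m_array() * open_mask

    mean = np.zeros(5)
    cov = np.zeros((5, 5))

    # mutation fluxes: independent
    g_mean = u * z[_MUT_SRC] * dt
    g_var = u * z[_MUT_SRC] * dt * per_locus
    mean += g_mean @ _MUT_E
    cov += (_MUT_E.T * g_var) @ _MUT_E

    # migration fluxes: shared timing noise within a bond
    m_flow = m_eff[_MIG_BOND]
    zi = z[_MIG_SRC]
    f_mean = m_flow * zi * eps * dt
    mean += f_mean @ _MIG_E
    same_bond = _MIG_BOND[:, None] == _MIG_BOND[None, :]
    timing_cov = (
        same_bond
        * np.sqrt(m_flow[:, None] * m_flow[None, :])
        * (zi[:, None] * eps)
        * (zi[None, :] * eps)
        * dt
    )
    sampling_var = np.diag(m_flow * zi * eps * (1.0 - eps) * dt * per_locus)
    cov += _MIG_E.T @ (timing_cov + sampling_var) @ _MIG_E
    return mean, cov


# ---------------------------------------------------------------------------
# Stepping and simulation


def _check_dt(params: ModelParams, dt: float) -> None:
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    total_rate = 3 * params.u + sum(params.m.values()) * params.epsilon
    if total_rate * dt > 0.1:
        warnings.warn(
            f"dt = {dt} is large relative to the total event rate "
            f"({total_rate:.3g} per generation); increments may not be small",
            stacklevel=3,
        )


def step_three_island(
    state: ThreeIslandState,
    params: ModelParams,
    dt: float,
    rng: np.random.Generator,
) -> tuple[ThreeIslandState, str]:
    """One Euler-Maruyama step of the configuration SDE.

    Applies the mutation and migration increments, projects back onto the
    simplex, advances time, and refreshes the bond graph and speciation
    state.  Returns the new state and the species count label.
    """
    _check_dt(params, dt)
    z = state.gc.as_array()
    dz = mutation_update(state.gc, params, dt, rng) + migration_update(
        state.gc, params, state.graph, dt, rng
    )
    gc_new = normalize_gc(z + dz)
    t_new = state.t + dt
    label, graph_new = speciation_state(
        distances_from_gc(gc_new), params, state.graph, t=t_new
    )
    return ThreeIslandState(t=t_new, gc=gc_new, graph=graph_new), label


class _BatchEngine:
    """Lock-step Euler-Maruyama integrator for many independent replicates.

    Maintains per-replicate configuration fractions, bond status, and the
    speciation record; replicates freeze once all three bonds are severed.
    """

    def __init__(
        self,
        params: ModelParams,
        gc0: GCFractions,
        reps: int,
        dt: float,
        rng: np.random.Generator,
    ):
        _check_dt(params, dt)
        self.params = params
        self.dt = dt
        self.rng = rng
        self.t = 0.0
        self.z = np.tile(gc0.as_array(), (reps, 1))
        self.closed = np.zeros((reps, 3), dtype=bool)
        self.severed = np.zeros((reps, 3), dtype=bool)
        self.tau2 = np.full(reps, np.nan)
        self.tau3 = np.full(reps, np.nan)
        self._refresh_graph(np.arange(reps))

    def _refresh_graph(self, idx: np.ndarray) -> None:
        """Re-evaluate bond status and speciation for replicates ``idx``."""
        d = distances_from_array(self.z[idx])
        exceeded = d > self.params.z_c
        if self.params.irreversible_bonds:
            closed = self.closed[idx] | exceeded | self.severed[idx]
        else:
            closed = exceeded | self.severed[idx]
        n_closed = closed.sum(axis=1)
        split = n_closed >= 2
        # permanent severing of closed bonds at the moment of disconnection
        self.severed[idx] |= closed & split[:, None]
        newly2 = split & np.isnan(self.tau2[idx])
        self.tau2[idx[newly2]] = self.t
        newly3 = (n_closed == 3) & np.isnan(self.tau3[idx])
        self.tau3[idx[newly3]] = self.t
        self.closed[idx] = closed

    @property
    def active(self) -> np.ndarray:
        return np.flatnonzero(np.isnan(self.tau3))

    def step(self, idx: np.ndarray | None = None) -> None:
        if idx is None:
            idx = self.active
        if len(idx) == 0:
            self.t += self.dt
            return
        z = self.z[idx]
        open_mask = ~self.closed[idx][:, _BOND_UND]
        dz = _mutation_increments_batch(z, self.params, self.dt, self.rng)
        dz += _migration_increments_batch(z, self.params, open_mask, self.dt, self.rng)
        self.z[idx] = normalize_gc_array(z + dz)
        self.t += self.dt
        self._refresh_graph(idx)


def simulate_three_island(
    params: ModelParams,
    gc0: GCFractions | None = None,
    dt: float = 1.0,
    t_max: float = 1e5,
    record_stride: int = 1,
    rng: np.random.Generator | None = None,
    stop_at_tau3: bool = False,
) -> tuple[pd.DataFrame, SpeciationRecord]:
    """Simulate one trajectory of the three-island configuration SDE.

    Starts by default from a genetically uniform species (``z1 = 1``) and
    runs to ``t_max`` (or until three species have formed when
    ``stop_at_tau3``).  Returns the recorded trajectory — columns ``t``,
    ``z1..z5``, ``zAB``, ``zBC``, ``zCA``, ``bonds_open`` — and the
    speciation record with the waiting times tau2 (first disconnection of
    the migration graph) and tau3 (all bonds closed), ``None`` if censored.
    """
    if gc0 is None:
        gc0 = GCFractions(1.0, 0.0, 0.0, 0.0, 0.0)
    if rng is None:
        rng = np.random.default_rng()
    eng = _BatchEngine(params, gc0, reps=1, dt=dt, rng=rng)
    rows = []

    def record():
        d = distances_from_array(eng.z[0])
        rows.append(
            (eng.t, *eng.z[0], *d, int(3 - eng.closed[0].sum()))
        )

    record()
    n_steps = int(round(t_max / dt))
    for k in range(1, n_steps + 1):
        eng.step(np.array([0]) if np.isnan(eng.tau3[0]) else np.array([], dtype=int))
        if k % record_stride == 0:
            record()
        if stop_at_tau3 and not np.isnan(eng.tau3[0]):
            if k % record_stride != 0:
                record()
            break
    traj = pd.DataFrame(
        rows,
        columns=["t", "z1", "z2", "z3", "z4", "z5", "zAB", "zBC", "zCA", "bonds_open"],
    )
    rec = SpeciationRecord(
        tau2=None if np.isnan(eng.tau2[0]) else float(eng.tau2[0]),
        tau3=None if np.isnan(eng.tau3[0]) else float(eng.tau3[0]),
    )
    return traj, rec


def first_passage_three_island(
    params: ModelParams,
    gc0: GCFractions | None = None,
    dt: float = 1.0,
    t_max: float = 1e6,
    reps: int = 50,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Waiting times to two and three species for ``reps`` replicates.

    Returns ``(tau2, tau3)`` arrays of length ``reps``; NaN marks a
    replicate censored at ``t_max``.  Replicates are advanced in lock-step
    and dropped from the batch once three species have formed.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if gc0 is None:
        gc0 = GCFractions(1.0, 0.0, 0.0, 0.0, 0.0)
    if rng is None:
        rng = np.random.default_rng()
    eng = _BatchEngine(params, gc0, reps=reps, dt=dt, rng=rng)
    n_steps = int(round(t_max / dt))
    for _ in range(n_steps):
        idx = eng.active
        if len(idx) == 0:
            break
        eng.step(idx)
    return eng.tau2.copy(), eng.tau3.copy()
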