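"""Exact per-locus jump-process simulator (Gillespie-style).

The diffusion model of :mod:`gcspec.three_island` approximates an underlying
discrete process: each of ``l`` loci carries a geographical-configuration
label, novel alleles fix on each island as independent Poisson streams of
rate ``u`` per locus, and successful migration events arrive on each open
directed bond as a Poisson process of rate ``m_ab``.  At a migration event
every locus whose configuration has a transition under that bond fixes the
migrant allele independently with probability ``epsilon`` — so one event can
move many loci at once, which is precisely the correlation the shared noise
term of the SDE mimics.

This module simulates that process exactly (event-driven, continuous event
times, no time discretisation) and serves as the ground truth against which
the SDE drift, variance and covariance formulas are checked, both for three
islands and for the degenerate two-island case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DIRECTED_BONDS,
    BondGraph,
    GCFractions,
    ModelParams,
    SpeciationRecord,
    distances_from_gc,
    speciation_state,
)
from .three_island import (
    MIGRATION_TRANSITIONS,
    migration_transition_map,
    mutation_transition_map,
)

__all__ = [
    "LocusStateVector",
    "event_rates",
    "apply_mutation",
    "apply_migration",
    "gillespie_run",
    "moment_probe",
    "gillespie_two_island",
]

_ISLANDS = ("A", "B", "C")


@dataclass
class LocusStateVector:
    """Per-locus configuration labels (1..5) at a moment in time."""

    labels: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or len(self.labels) < 1:
            raise ValueError("labels must be a non-empty 1-D array")
        if not np.all((self.labels >= 1) & (self.labels <= 5)):
            raise ValueError("labels must be configuration indices in 1..5")

    @property
    def l(self) -> int:
        return len(self.labels)

    def counts(self) -> np.ndarray:
        """Number of loci in each configuration, length-5."""
        return np.bincount(self.labels, minlength=6)[1:]

    def gc_fractions(self) -> GCFractions:
        return GCFractions.from_array(self.counts() / self.l)

    @classmethod
    def from_gc(cls, gc: GCFractions, l: int) -> "LocusStateVector":
        """Build a state with exactly ``l * z_i`` loci per configuration.

        Raises if any ``l * z_i`` is not an integer: the oracle needs whole
        locus counts.
        """
        counts = np.asarray(gc.as_array()) * l
        rounded = np.rint(counts)
        if not np.allclose(counts, rounded, atol=1e-9):
            raise ValueError(
                f"l * z_i must be integral for every configuration; got {counts}"
            )
        labels = np.repeat(np.arange(1, 6), rounded.astype(int))
        return cls(labels=labels)


def event_rates(state: LocusStateVector, params: ModelParams, graph: BondGraph | None = None) -> dict:
    """Total rate of each event class in the current state.

    Mutation-and-fixation strikes each locus on each island at rate ``u``
    (total ``3 u l``); each open directed bond fires successful migration
    events at its rate ``m_ab``.  Closed bonds contribute nothing.
    """
    rates = {"mutation": 3.0 * params.u * state.l}
    for b in DIRECTED_BONDS:
        open_ = True if graph is None else graph.is_open(b)
        rates[f"migration_{b}"] = params.m[b] if open_ else 0.0
    return rates


def apply_mutation(state: LocusStateVector, island: str, locus: int) -> LocusStateVector:
    """Fix a novel allele on ``island`` at ``locus``; relabels that locus."""
    labels = state.labels.copy()
    labels[locus] = mutation_transition_map(int(labels[locus]), island)
    return LocusStateVector(labels=labels, t=state.t)


def apply_migration(
    state: LocusStateVector, bond: str, rng: np.random.Generator, epsilon: float
) -> LocusStateVector:
    """One successful migration event across a directed bond.

    Every locus whose configuration has a transition under this bond fixes
    the migrant allele independently with probability ``epsilon``; loci at
    which the two islands already share the allele are untouched.  A single
    event can therefore relabel many loci simultaneously.
    """
    labels = state.labels.copy()
    targets = {i: j for i, j in ((c, migration_transition_map(c, bond)) for c in range(1, 6)) if j}
    for i, j in targets.items():
        mask = labels == i
        if mask.any():
            flip = rng.random(mask.sum()) < epsilon
            idx = np.flatnonzero(mask)[flip]
            labels[idx] = j
    return LocusStateVector(labels=labels, t=state.t)


def gillespie_run(
    params: ModelParams,
    state0: LocusStateVector,
    t_max: float,
    rng: np.random.Generator,
    record_stride: float = 1.0,
    event_log: bool = False,
) -> tuple[pd.DataFrame, SpeciationRecord, pd.DataFrame | None]:
    """Exact event-driven simulation of the per-locus process.

    Exponential waiting times between events; the event class is chosen
    proportionally to its rate.  Configuration fractions and distances are
    recorded on a regular grid of spacing ``record_stride`` so the output
    schema matches the SDE trajectories.  Bond closure and speciation use
    the same policy as the SDE (closed bonds stop firing; disconnection
    permanently severs its bonds).

    Returns (trajectory, speciation record, event log or None).
    """
    state = LocusStateVector(labels=state0.labels.copy(), t=state0.t)
    graph = BondGraph()
    rec = SpeciationRecord()
    rows = []
    events = [] if event_log else None

    def refresh_graph(t):
        nonlocal graph
        label, graph = speciation_state(
            distances_from_gc(state.gc_fractions()), params, graph, t=t
        )
        if rec.tau2 is None and label in ("two_species", "three_species"):
            rec.tau2 = t
        if rec.tau3 is None and label == "three_species":
            rec.tau3 = t

    refresh_graph(state.t)
    next_record = state.t

    def record(t):
        gc = state.counts() / state.l
        d = distances_from_gc(GCFractions.from_array(gc))
        rows.append((t, *gc, d.z_AB, d.z_BC, d.z_CA, int(3 - graph.n_closed)))

    t = state.t
    while True:
        rates = event_rates(state, params, graph)
        classes = list(rates)
        rate_vals = np.array([rates[c] for c in classes])
        total = rate_vals.sum()
        dt_next = rng.exponential(1.0 / total) if total > 0 else math.inf
        t_event = t + dt_next
        while next_record <= min(t_event, t_max):
            record(next_record)
            next_record += record_stride
        if t_event > t_max or total == 0:
            state.t = t_max
            break
        t = t_event
        cls = classes[rng.choice(len(classes), p=rate_vals / total)]
        if cls == "mutation":
            island = _ISLANDS[rng.integers(3)]
            locus = int(rng.integers(state.l))
            before = int(state.labels[locus])
            state = apply_mutation(state, island, locus)
            n_changed = int(before != state.labels[locus])
        else:
            bond = cls.removeprefix("migration_")
            before = state.labels.copy()
            state = apply_migration(state, bond, rng, params.epsilon)
            n_changed = int((before != state.labels).sum())
        state.t = t
        refresh_graph(t)
        if events is not None:
            events.append((t, cls, n_changed))
        if rec.tau3 is not None:
            break
    traj = pd.DataFrame(
        rows,
        columns=["t", "z1", "z2", "z3", "z4", "z5", "zAB", "zBC", "zCA", "bonds_open"],
    )
    log = (
        pd.DataFrame(events, columns=["t", "event_class", "n_loci_changed"])
        if events is not None
        else None
    )
    return traj, rec, log


def moment_probe(
    gc0: GCFractions,
    params: ModelParams,
    dt: float,
    n_reps: int,
    rng: np.random.Generator,
    open_bonds: tuple | None = None,
    return_samples: bool = False,
):
    """Empirical moments of the one-interval increment of the fractions.

    Replays ``n_reps`` independent exact simulations of length ``dt`` from
    the same initial state (which must have integer locus counts) and
    returns the sample mean five-vector and the 5x5 sample covariance of the
    increments ``dz`` — directly comparable to
    :func:`gcspec.three_island.increment_moments`.

    ``open_bonds`` optionally restricts which directed bonds fire (all open
    by default); bond status is frozen during the interval, matching the
    one-step SDE coefficients.

    The simulation works on configuration counts: loci in the same
    configuration are exchangeable, so mutation hits a configuration with
    probability proportional to its count and a migration event moves a
    binomial number of loci per eligible configuration.
    """
    if params.l == math.inf:
        raise ValueError("the jump oracle requires a finite number of loci")
    l = int(params.l)
    counts0 = LocusStateVector.from_gc(gc0, l).counts()
    if open_bonds is None:
        open_bonds = DIRECTED_BONDS
    bond_rates = np.array(
        [params.m[b] if b in open_bonds else 0.0 for b in DIRECTED_BONDS]
    )
    bond_transitions = [
        [(i - 1, j - 1) for i, j in MIGRATION_TRANSITIONS[b]] for b in DIRECTED_BONDS
    ]
    mut_rate = 3.0 * params.u * l
    total_rate = mut_rate + bond_rates.sum()
    eps = params.epsilon
    # per-(island, config) relabel targets, 0-based; -1 marks a self-map
    mut_target = np.full((3, 5), -1, dtype=int)
    for a, isl in enumerate(_ISLANDS):
        for c in range(1, 6):
            j = mutation_transition_map(c, isl)
            if j != c:
                mut_target[a, c - 1] = j - 1

    z0 = counts0 / l
    increments = np.empty((n_reps, 5))
    n_classes = 7
    class_p = np.concatenate(([mut_rate], bond_rates)) / total_rate if total_rate > 0 else None
    for r in range(n_reps):
        counts = counts0.copy()
        t = 0.0
        while total_rate > 0:
            t += rng.exponential(1.0 / total_rate)
            if t >= dt:
                break
            k = rng.choice(n_classes, p=class_p)
            if k == 0:
                island = rng.integers(3)
                # locus uniform over l => configuration proportional to count
                c = rng.choice(5, p=counts / l)
                j = mut_target[island, c]
                if j >= 0:
                    counts[c] -= 1
                    counts[j] += 1
            else:
                for i, j in bond_transitions[k - 1]:
                    n_flip = rng.binomial(counts[i], eps)
                    counts[i] -= n_flip
                    counts[j] += n_flip
        increments[r] = counts / l - z0
    mean = increments.mean(axis=0)
    cov = np.cov(increments, rowvar=False)
    if return_samples:
        return mean, cov, increments
    return mean, cov


def gillespie_two_island(
    params: ModelParams,
    k0: int = 0,
    t_max: float = 1e5,
    rng: np.random.Generator | None = None,
    record_stride: float = 1.0,
) -> pd.DataFrame:
    """Exact two-island per-locus process; returns a t, z trajectory.

    The sufficient statistic is the number ``k`` of differing loci: novel
    alleles fix at total rate ``2 u l`` (on either island) and increase ``k``
    only when they strike one of the ``l - k`` shared loci; migration in each
    direction (rate ``m``) reduces ``k`` by a Binomial(k, epsilon) draw.
    Migration stops once the distance exceeds ``z_c``.
    """
    if params.l == math.inf:
        raise ValueError("the jump oracle requires a finite number of loci")
    if rng is None:
        rng = np.random.default_rng()
    l = int(params.l)
    m = params.symmetric_m()
    u, eps = params.u, params.epsilon
    k = int(k0)
    t = 0.0
    rows = []
    next_record = 0.0
    while True:
        open_bond = (k / l) <= params.z_c
        mut_rate = 2.0 * u * l
        mig_rate = 2.0 * m if open_bond else 0.0
        total = mut_rate + mig_rate
        t_event = t + (rng.exponential(1.0 / total) if total > 0 else math.inf)
        while next_record <= min(t_event, t_max):
            rows.append((next_record, k / l))
            next_record += record_stride
        if t_event > t_max or total == 0:
            break
        t = t_event
        if rng.random() < mut_rate / total:
            # a shared locus diverges; hits on already-differing loci change nothing
            if rng.integers(l) >= k:
                k += 1
        else:
            k -= rng.binomial(k, eps)
    return pd.DataFrame(rows, columns=["t", "z"])
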