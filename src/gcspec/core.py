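"""Geographical-configuration (GC) algebra and the speciation predicate.

A species lives on three islands A, B, C.  At each incompatibility locus the
pattern of allele sharing between islands is one of five *geographical
configurations*:

====  =========  ===========================================
label partition  meaning
====  =========  ===========================================
1     (ABC)      all three islands share one fixed allele
2     (A)(BC)    A differs; B and C share
3     (B)(CA)    B differs; C and A share
4     (C)(AB)    C differs; A and B share
5     (A)(B)(C)  all three islands carry distinct alleles
====  =========  ===========================================

The state of the whole genome is summarised by the fractions ``z1..z5`` of
loci in each configuration (summing to one).  Pairwise genetic distances —
the fraction of loci at which two islands are fixed for different alleles —
are linear functions of these fractions.  A pair of islands stops exchanging
genes when their distance exceeds the incompatibility threshold ``z_c``;
speciation is the event that the migration graph on the three islands
becomes disconnected.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CONFIG_LABELS",
    "DIRECTED_BONDS",
    "UNDIRECTED_BONDS",
    "ModelParams",
    "GCFractions",
    "PairwiseDistances",
    "BondGraph",
    "SpeciationRecord",
    "distances_from_gc",
    "normalize_gc",
    "speciation_state",
]

#: Human-readable names of the five configurations, indexed by label 1..5.
CONFIG_LABELS = {1: "(ABC)", 2: "(A)(BC)", 3: "(B)(CA)", 4: "(C)(AB)", 5: "(A)(B)(C)"}

#: The six ordered island pairs, in canonical order.
DIRECTED_BONDS = ("AB", "BA", "AC", "CA", "BC", "CB")

#: The three unordered migration bonds, in canonical order.
UNDIRECTED_BONDS = ("AB", "BC", "CA")

#: Map from a directed bond to the index of its undirected bond in
#: :data:`UNDIRECTED_BONDS`.
DIRECTED_TO_UNDIRECTED = {"AB": 0, "BA": 0, "BC": 1, "CB": 1, "CA": 2, "AC": 2}

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the island speciation model.

    Parameters
    ----------
    l : int or math.inf
        Number of incompatibility-controlling loci.  ``math.inf`` selects the
        diffusion limit in which per-locus sampling noise vanishes.
    u : float
        Per-locus rate of mutation *and* fixation per generation (each island
        replaces the resident allele at a given locus at this rate).
    epsilon : float
        Migration impact: the expected fraction of loci at which the migrant
        allele reaches fixation after one successful migration event.  In the
        underlying population model ``epsilon = N'/(N + N')`` where ``N'`` is
        the migrant group size, so the model assumes ``epsilon << 1``.
    z_c : float
        Incompatibility threshold: two populations whose genetic distance
        exceeds ``z_c`` can no longer produce viable, fecund offspring.
    m : dict
        Rate per generation of successful migration events for each ordered
        island pair, keyed by the strings in :data:`DIRECTED_BONDS`.  A scalar
        may be passed for fully symmetric migration.
    irreversible_bonds : bool
        If True, a migration bond that once closes (distance exceeded
        ``z_c``) never reopens even while the species is still a single
        connected cluster.  The default (False) lets distances fluctuate back
        below threshold and gene flow resume, until the island graph actually
        disconnects — disconnection is always permanent.
    """

    l: float = 100
    u: float = 1e-4
    epsilon: float = 0.01
    z_c: float = 0.5
    m: dict = field(default_factory=dict)
    irreversible_bonds: bool = False

    def __post_init__(self):
        m = self.m
        if np.isscalar(m):
            m = {b: float(m) for b in DIRECTED_BONDS}
        else:
            m = {b: float(m.get(b, 0.0)) for b in DIRECTED_BONDS}
            unknown = set(self.m) - set(DIRECTED_BONDS)
            if unknown:
                raise ValueError(f"unknown migration bond keys: {sorted(unknown)}")
        object.__setattr__(self, "m", m)
        if not (self.l == math.inf or (self.l == int(self.l) and self.l >= 1)):
            raise ValueError(f"l must be a positive integer or infinite, got {self.l}")
        if self.u < 0:
            raise ValueError(f"u must be nonnegative, got {self.u}")
        if not 0 <= self.epsilon <= 1:
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if self.epsilon > 0.25:
            warnings.warn(
                f"epsilon = {self.epsilon} is large; the diffusion model assumes the "
                "migrant group is a small fraction of the resident population",
                stacklevel=2,
            )
        if not 0 <= self.z_c <= 1:
            raise ValueError(f"z_c must lie in [0, 1], got {self.z_c}")
        for b, rate in m.items():
            if rate < 0:
                raise ValueError(f"migration rate m[{b}] must be nonnegative, got {rate}")

    @property
    def finite_l(self) -> bool:
        return self.l != math.inf

    def m_array(self) -> np.ndarray:
        """Directed migration rates as an array ordered like DIRECTED_BONDS."""
        return np.array([self.m[b] for b in DIRECTED_BONDS], dtype=float)

    def symmetric_m(self) -> float:
        """The common migration rate, for fully symmetric parameter sets."""
        rates = set(self.m.values())
        if len(rates) != 1:
            raise ValueError("migration rates are not symmetric")
        return rates.pop()

    def to_dict(self) -> dict:
        return {
            "l": "infinite" if not self.finite_l else int(self.l),
            "u": self.u,
            "epsilon": self.epsilon,
            "z_c": self.z_c,
            "m": dict(self.m),
            "irreversible_bonds": self.irreversible_bonds,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        if str(d.get("l", "")).lower() in {"infinite", "inf"}:
            d["l"] = math.inf
        return cls(**d)


@dataclass(frozen=True)
class GCFractions:
    """Fractions of loci in each of the five geographical configurations."""

    z1: float
    z2: float
    z3: float
    z4: float
    z5: float

    def __post_init__(self):
        v = self.as_array()
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError(f"GC fractions must lie in [0, 1], got {tuple(v)}")
        if abs(v.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"GC fractions must sum to 1, got sum {v.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.z1, self.z2, self.z3, self.z4, self.z5], dtype=float)

    @classmethod
    def from_array(cls, v) -> "GCFractions":
        v = np.asarray(v, dtype=float)
        if v.shape != (5,):
            raise ValueError(f"expected a five-vector, got shape {v.shape}")
        return cls(*v)

    def to_json(self) -> str:
        return json.dumps({f"z{i+1}": x for i, x in enumerate(self.as_array())})


@dataclass(frozen=True)
class PairwiseDistances:
    """Genetic distances between the three island pairs.

    ``z_AB`` is the fraction of incompatibility loci at which islands A and B
    are fixed for different alleles (and likewise for the other pairs).  The
    degenerate two-island case is the single distance ``z = z_AB``.
    """

    z_AB: float
    z_BC: float
    z_CA: float

    def __post_init__(self):
        for name in ("z_AB", "z_BC", "z_CA"):
            x = getattr(self, name)
            if not 0 <= x <= 1 + _SUM_TOL:
                raise ValueError(f"{name} must lie in [0, 1], got {x}")

    def as_array(self) -> np.ndarray:
        return np.array([self.z_AB, self.z_BC, self.z_CA], dtype=float)

    def to_json(self) -> str:
        return json.dumps({"zAB": self.z_AB, "zBC": self.z_BC, "zCA": self.z_CA})


@dataclass(frozen=True)
class BondGraph:
    """Status of the three migration bonds between islands.

    ``closed`` marks bonds whose current genetic distance exceeds the
    incompatibility threshold; ``severed`` marks bonds across which migration
    has been permanently shut down because the island graph disconnected
    while they were closed.  ``closure_time`` records when each bond was
    (most recently) closed, ``None`` while open.
    """

    closed: tuple = (False, False, False)  # order: AB, BC, CA
    severed: tuple = (False, False, False)
    closure_time: tuple = (None, None, None)

    @property
    def n_closed(self) -> int:
        return sum(self.closed)

    def is_open(self, directed_bond: str) -> bool:
        return not self.closed[DIRECTED_TO_UNDIRECTED[directed_bond]]

    def open_mask(self) -> np.ndarray:
        """Boolean mask over DIRECTED_BONDS: True where migration can occur."""
        return np.array(
            [not self.closed[DIRECTED_TO_UNDIRECTED[b]] for b in DIRECTED_BONDS]
        )


@dataclass
class SpeciationRecord:
    """Bond-closure bookkeeping for one simulated history.

    ``tau2`` is the first time the open-bond graph disconnects (two species);
    ``tau3`` the first time all three bonds are closed (three species).
    Either is ``None`` while the event has not yet occurred.
    """

    tau2: float | None = None
    tau3: float | None = None
    bond_closure_times: dict = field(default_factory=dict)


def distances_from_gc(gc: GCFractions) -> PairwiseDistances:
    """Map configuration fractions to the three pairwise genetic distances.

    Two islands differ at a locus exactly when the locus's configuration
    separates them, so each distance is a sum of three of the five fractions:

    .. math::

        z_{AB} = z_2 + z_3 + z_5,\\quad
        z_{BC} = z_3 + z_4 + z_5,\\quad
        z_{CA} = z_2 + z_4 + z_5.

    The map is linear and many distinct configuration vectors share the same
    distance triplet, which is why the model tracks configurations rather
    than distances.
    """
    return PairwiseDistances(
        z_AB=gc.z2 + gc.z3 + gc.z5,
        z_BC=gc.z3 + gc.z4 + gc.z5,
        z_CA=gc.z2 + gc.z4 + gc.z5,
    )


def distances_from_array(z: np.ndarray) -> np.ndarray:
    """Vectorised distance map: ``z`` has shape (..., 5), result (..., 3).

    Column order matches :data:`UNDIRECTED_BONDS`: (z_AB, z_BC, z_CA).
    """
    z = np.asarray(z, dtype=float)
    return np.stack(
        [
            z[..., 1] + z[..., 2] + z[..., 4],
            z[..., 2] + z[..., 3] + z[..., 4],
            z[..., 1] + z[..., 3] + z[..., 4],
        ],
        axis=-1,
    )


def normalize_gc(raw) -> GCFractions:
    """Project a raw five-vector back onto the simplex of GC fractions.

    Gaussian increments from the SDE can push components slightly outside
    [0, 1]; this clips each to [0, 1] and rescales so the sum is one.  A
    vector that is already valid is returned unchanged.
    """
    v = np.asarray(raw, dtype=float)
    if v.shape != (5,):
        raise ValueError(f"expected a five-vector, got shape {v.shape}")
    clipped = np.clip(v, 0.0, 1.0)
    total = clipped.sum()
    if total <= 0:
        raise ValueError("degenerate GC state: all components are zero after clipping")
    return GCFractions.from_array(clipped / total)


def normalize_gc_array(v: np.ndarray) -> np.ndarray:
    """Vectorised simplex projection for arrays of shape (..., 5)."""
    clipped = np.clip(v, 0.0, 1.0)
    total = clipped.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("degenerate GC state: all components are zero after clipping")
    return clipped / total


def speciation_state(
    d: PairwiseDistances,
    params: ModelParams,
    graph: BondGraph,
    t: float = 0.0,
) -> tuple[str, BondGraph]:
    """Classify the current state as one, two or three species.

    A bond is *closed* while its genetic distance strictly exceeds ``z_c``
    (a distance exactly at threshold leaves the bond open).  Populations on
    islands joined by a chain of open bonds still belong to one species, so
    the species count is read off the connectivity of the triangle graph:

    - 0 or 1 closed bond: all three islands remain connected — one species;
    - 2 closed bonds: one island is isolated — two species;
    - 3 closed bonds: all pairs isolated — three species.

    While the species is a single cluster, closure is reversible by default
    (set ``params.irreversible_bonds`` for sticky closure).  The moment the
    graph disconnects, the bonds that are closed are permanently severed:
    migration across them is zero from then on.
    """
    dist = d.as_array()
    closed = list(graph.closed)
    times = list(graph.closure_time)
    for i in range(3):
        if graph.severed[i]:
            closed[i] = True
            continue
        exceeded = dist[i] > params.z_c
        if exceeded and not closed[i]:
            closed[i] = True
            times[i] = t
        elif not exceeded and closed[i] and not params.irreversible_bonds:
            closed[i] = False
            times[i] = None
    n_closed = sum(closed)
    severed = list(graph.severed)
    if n_closed >= 2:
        # graph disconnected: permanently sever every currently closed bond
        for i in range(3):
            if closed[i]:
                severed[i] = True
    state = ("one_species", "one_species", "two_species", "three_species")[n_closed]
    new_graph = BondGraph(
        closed=tuple(closed), severed=tuple(severed), closure_time=tuple(times)
    )
    return state, new_graph


def zero_severed_rates(params: ModelParams, graph: BondGraph) -> ModelParams:
    """Return params with migration rates across severed bonds set to zero."""
    if not any(graph.severed):
        return params
    m = dict(params.m)
    for b in DIRECTED_BONDS:
        if graph.severed[DIRECTED_TO_UNDIRECTED[b]]:
            m[b] = 0.0
    return replace(params, m=m)
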