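"""Batch waiting-time experiments for the three-island speciation model.

Three standard designs are provided:

- :func:`sweep_threshold` — mean waiting time to speciation (tau2, first
  disconnection of the migration graph) as a function of the incompatibility
  threshold ``z_c`` and the number of loci ``l``.  A finite number of loci
  adds per-locus sampling noise, so speciation at thresholds above the
  deterministic equilibrium is reached much sooner than with ``l`` infinite.
- :func:`sweep_epsilon_fixed_product` — mean waiting time along a curve of
  ``(m, epsilon)`` pairs with the product ``m * epsilon`` (the deterministic
  migration rate) held fixed.  Fewer, larger migration events generate more
  variance, so the waiting time falls as ``epsilon`` grows.
- :func:`ratio_vs_migration_sd` — the ratio of the waiting times to three
  and to two species, ``tau3 / tau2 >= 1``, against the standard deviation
  of the three bond migration rates, with an ordinary least-squares trend.

All replicate streams are derived from one master seed through a
counter-based scheme (see :func:`replicate_rng`), so any replicate can be
reproduced in isolation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import GCFractions, ModelParams, UNDIRECTED_BONDS
from .three_island import first_passage_three_island

__all__ = [
    "WaitingTimeSummary",
    "replicate_rng",
    "summarize",
    "sweep_threshold",
    "sweep_epsilon_fixed_product",
    "ratio_vs_migration_sd",
]

#: Default parameters for the threshold sweep.
THRESHOLD_SWEEP_DEFAULTS = dict(u=0.000075, m=0.01, epsilon=0.025)
#: Default (m, epsilon) pairs of the fixed-product sweep, m * eps = 0.00025.
FIXED_PRODUCT_PAIRS = ((0.1, 0.0025), (0.005, 0.05), (0.001, 0.25))
#: Default parameters for the tau3/tau2 ratio experiment.
RATIO_DEFAULTS = dict(l=20, u=0.000075, epsilon=0.01, z_c=0.3)


def replicate_rng(master_seed: int, index: int) -> np.random.Generator:
    """Independent generator for one unit of work under a master seed.

    Uses ``SeedSequence(master_seed, spawn_key=(index,))``: replicate ``k``
    is reproducible without generating streams ``0..k-1``.
    """
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


@dataclass
class WaitingTimeSummary:
    """Waiting-time samples and summary statistics for one parameter set."""

    params: ModelParams
    tau2: np.ndarray
    tau3: np.ndarray
    t_max: float

    def __post_init__(self):
        ok = ~(np.isnan(self.tau2) | np.isnan(self.tau3))
        if np.any(self.tau3[ok] < self.tau2[ok]):
            raise ValueError("tau3 < tau2 in a replicate; inconsistent record")

    @property
    def n(self) -> int:
        return len(self.tau2)

    def summary_row(self) -> dict:
        """Per-cell summary; fully censored times appear as NaN means."""
        row = {
            "n": self.n,
            "tau2_censored": int(np.isnan(self.tau2).sum()),
            "tau3_censored": int(np.isnan(self.tau3).sum()),
        }
        for name, arr in (("tau2", self.tau2), ("tau3", self.tau3)):
            obs = arr[~np.isnan(arr)]
            if len(obs):
                s = summarize(obs.tolist())
                row[f"{name}_mean"] = s["mean"]
                row[f"{name}_se"] = s["se"]
            else:
                row[f"{name}_mean"] = math.nan
                row[f"{name}_se"] = math.nan
        return row


def summarize(samples) -> dict:
    """Arithmetic mean and standard error of a waiting-time sample.

    ``samples`` may contain NaN for censored replicates; those are counted
    separately and excluded from the mean.  An empty (or fully censored)
    sample raises.
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    censored = int(np.isnan(arr).sum())
    obs = arr[~np.isnan(arr)]
    if obs.size == 0:
        raise ValueError(f"all {censored} replicates censored; no mean is defined")
    se = float(np.std(obs, ddof=1) / math.sqrt(obs.size)) if obs.size > 1 else 0.0
    return {"mean": float(np.mean(obs)), "se": se, "n": int(obs.size), "censored": censored}


def _run_cell(
    params: ModelParams,
    reps: int,
    master_seed: int,
    cell_index: int,
    dt: float,
    t_max: float,
) -> WaitingTimeSummary:
    rng = replicate_rng(master_seed, cell_index)
    tau2, tau3 = first_passage_three_island(
        params, dt=dt, t_max=t_max, reps=reps, rng=rng
    )
    return WaitingTimeSummary(params=params, tau2=tau2, tau3=tau3, t_max=t_max)


def sweep_threshold(
    params_base: ModelParams | None = None,
    zc_list=(0.15, 0.20, 0.25),
    l_list=(10, math.inf),
    reps: int = 200,
    master_seed: int = 0,
    dt: float = 1.0,
    t_max: float = 2e5,
) -> pd.DataFrame:
    """Mean waiting time to speciation versus threshold ``z_c`` and loci ``l``.

    One row per (z_c, l) cell with the mean and standard error of tau2 over
    ``reps`` replicates; censored replicates (no speciation by ``t_max``)
    are flagged per cell rather than averaged in.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2 to estimate a standard error")
    if params_base is None:
        params_base = ModelParams(
            l=100, z_c=0.3, m=THRESHOLD_SWEEP_DEFAULTS["m"],
            u=THRESHOLD_SWEEP_DEFAULTS["u"], epsilon=THRESHOLD_SWEEP_DEFAULTS["epsilon"],
        )
    rows = []
    for k, (zc, l) in enumerate(itertools.product(zc_list, l_list)):
        params = replace(params_base, z_c=zc, l=l)
        cell = _run_cell(params, reps, master_seed, k, dt, t_max)
        row = {"z_c": zc, "l": l, **cell.summary_row()}
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_epsilon_fixed_product(
    product: float = 0.00025,
    pairs=FIXED_PRODUCT_PAIRS,
    params_base: ModelParams | None = None,
    reps: int = 200,
    master_seed: int = 0,
    dt: float = 1.0,
    t_max: float = 2e5,
) -> pd.DataFrame:
    """Mean waiting time along (m, epsilon) pairs with ``m * eps`` fixed.

    Every pair must satisfy ``m * eps == product`` (to 1e-12): the pairs all
    share the same deterministic drift, so any difference in waiting time is
    purely an effect of the fluctuation magnitude, which grows with eps.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2 to estimate a standard error")
    for m, eps in pairs:
        if abs(m * eps - product) > 1e-12:
            raise ValueError(
                f"pair (m={m}, eps={eps}) violates m*eps = {product}: got {m * eps}"
            )
    if params_base is None:
        params_base = ModelParams(l=100, u=0.000075, z_c=0.3, epsilon=0.01, m=0.0)
    rows = []
    for k, (m, eps) in enumerate(pairs):
        params = replace(params_base, m=m, epsilon=eps)
        cell = _run_cell(params, reps, master_seed, k, dt, t_max)
        rows.append({"m": m, "epsilon": eps, **cell.summary_row()})
    return pd.DataFrame(rows)


def migration_rate_sd(combo) -> float:
    """Standard deviation (population form) of the three bond rates."""
    return float(np.std(np.asarray(combo, dtype=float)))


def ratio_vs_migration_sd(
    m_combos,
    params_base: ModelParams | None = None,
    reps: int = 50,
    master_seed: int = 0,
    dt: float = 1.0,
    t_max: float = 5e5,
    gc0: GCFractions | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Ratio of waiting times tau3/tau2 against migration-rate heterogeneity.

    ``m_combos`` is an iterable of triples giving the (symmetric) rate on
    each of the three undirected bonds (AB, BC, CA).  For each combination
    the mean over replicates of tau2 and tau3 yields the ratio
    ``mean(tau3) / mean(tau2)``; the mean of per-replicate ratios is also
    reported.  The second return value holds the unweighted ordinary
    least-squares fit (with intercept) of the ratio against the standard
    deviation of the three rates.

    Combinations in which tau3 is censored in every replicate appear with a
    NaN ratio and are excluded from the regression.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if params_base is None:
        params_base = ModelParams(m=0.0, **RATIO_DEFAULTS)
    rows = []
    for k, combo in enumerate(m_combos):
        m_ab, m_bc, m_ca = (float(x) for x in combo)
        m = {"AB": m_ab, "BA": m_ab, "BC": m_bc, "CB": m_bc, "CA": m_ca, "AC": m_ca}
        params = replace(params_base, m=m)
        cell = _run_cell(params, reps, master_seed, k, dt, t_max)
        ok = ~(np.isnan(cell.tau2) | np.isnan(cell.tau3))
        row = {
            "m_AB": m_ab,
            "m_BC": m_bc,
            "m_CA": m_ca,
            "sigma_m": migration_rate_sd(combo),
            **cell.summary_row(),
        }
        row["ratio"] = (
            row["tau3_mean"] / row["tau2_mean"]
            if not math.isnan(row["tau3_mean"])
            else math.nan
        )
        row["ratio_per_replicate"] = (
            float(np.mean(cell.tau3[ok] / cell.tau2[ok])) if ok.any() else math.nan
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    fit_rows = table.dropna(subset=["ratio"])
    if len(fit_rows) >= 2 and fit_rows["sigma_m"].nunique() > 1:
        res = stats.linregress(fit_rows["sigma_m"], fit_rows["ratio"])
        fit = {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "rvalue": float(res.rvalue),
            "n": int(len(fit_rows)),
        }
    else:
        fit = {"slope": math.nan, "intercept": math.nan, "rvalue": math.nan, "n": int(len(fit_rows))}
    return table, fit


def default_m_combos(rates=(0.0, 0.005, 0.01, 0.02, 0.04), require_connected=False):
    """All combinations of bond rates from a grid, as sorted unique triples.

    Combinations are taken over unordered triples (the three bonds play
    symmetric roles).  With ``require_connected``, combinations in which two
    or more bonds have zero rate are dropped (one island then receives no
    gene flow at all and divergence is purely allopatric).
    """
    combos = sorted(set(itertools.combinations_with_replacement(sorted(rates), 3)))
    if require_connected:
        combos = [c for c in combos if sum(r == 0 for r in c) <= 1]
    return combos
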