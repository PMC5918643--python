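"""Interval binning of agents by Low membership and the feedback signal.

After each stage, every (agent, variable) pair is placed in one of eleven
bins by its shadow Low membership: bin 0 holds exactly-zero memberships
(no resources needed) and bins 1..10 hold the intervals (0, 0.1],
(0.1, 0.2], ..., (0.9, 1.0].  The clustering is virtual — an agent lives
in one subspace per linguistic variable simultaneously.

The per-variable *need* is the mean Low membership over agents outside
bin 0; the two needs are normalised into the allocation fraction ``p``
fed back to the institutional model for the next stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import Population

__all__ = ["DiscrepancySignal", "assign_bin", "assign_bins", "cluster_subspaces", "discrepancy"]

#: memberships within this absolute tolerance of 0 land in bin 0, so
#: floating-point dust does not register as resource demand
ZERO_TOL = 1e-12


@dataclass(frozen=True)
class DiscrepancySignal:
    """Per-variable unmet need and the derived allocation fraction p."""

    needs: tuple[float, ...]
    p: float


def assign_bin(mu: float) -> int:
    """Map one Low membership in [0, 1] to its bin index 0..10."""
    if not -ZERO_TOL <= mu <= 1.0 + ZERO_TOL:
        raise ValueError(f"membership must be in [0, 1], got {mu}")
    if abs(mu) <= ZERO_TOL:
        return 0
    # half-open lower / closed upper endpoints: 0.1 -> bin 1, 0.1+eps -> bin 2
    return min(10, math.ceil(mu * 10 - 1e-9))


def assign_bins(mu: np.ndarray) -> np.ndarray:
    """Vectorised :func:`assign_bin` over an array of memberships."""
    mu = np.asarray(mu, dtype=float)
    if ((mu < -ZERO_TOL) | (mu > 1.0 + ZERO_TOL)).any():
        raise ValueError("memberships must be in [0, 1]")
    bins = np.minimum(10, np.ceil(mu * 10 - 1e-9).astype(int))
    bins[np.abs(mu) <= ZERO_TOL] = 0
    return bins


def cluster_subspaces(pop: Population) -> pd.DataFrame:
    """One row per (agent, variable) with the bin of its shadow Low value."""
    bins = assign_bins(pop.mu_low_social)
    n, q = bins.shape
    return pd.DataFrame(
        {
            "agent_id": np.repeat(np.arange(n), q),
            "variable": np.tile(np.arange(q), n),
            "bin": bins.ravel(),
        }
    )


def discrepancy(
    assignments: pd.DataFrame, pop: Population, default_p: float = 0.5
) -> DiscrepancySignal:
    """Aggregate unmet need per variable and derive the allocation split.

    need_j is the mean shadow-Low membership over agents in bin >= 1 for
    variable j (0 if every agent sits in bin 0).  For the two-variable
    case p = need_1/(need_1 + need_2) when the sum is positive, otherwise
    the configured default.
    """
    bins = (
        assignments.set_index(["agent_id", "variable"])["bin"]
        .unstack()
        .to_numpy()
    )
    mu = pop.mu_low_social
    needs = []
    for j in range(pop.n_variables):
        active = bins[:, j] >= 1
        needs.append(float(mu[active, j].mean()) if active.any() else 0.0)
    if pop.n_variables == 2 and (needs[0] + needs[1]) > 0:
        p = needs[0] / (needs[0] + needs[1])
    else:
        p = default_p
    return DiscrepancySignal(needs=tuple(needs), p=p)
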