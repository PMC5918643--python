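"""Institutional stock-flow model with a Mamdani fuzzy investment controller.

Two capacity stocks are maintained by the institution: COASF (capacity of
safe outdoor activity space and facilities, s1) and CSSHF (capacity of
stores serving healthy food, s2).  Each stock is built by an inflow
phi_k and decays with lifetime d_k (outflow lambda_k = s_k/d_k):

    ds1/dt = phi1 - s1/d1,     ds2/dt = phi2 - s2/d2

Investment is drawn from a fixed initial fund C.  The spend rate omega is
set by a Mamdani controller: the institution fuzzifies its perceived
stock values through triangular linguistic variables, fires the nine
(COASF term x CSSHF term) rules of the rule base by min-conjunction,
clips each fired consequent at its strength, aggregates by pointwise max,
and defuzzifies by centre of gravity to an impact z_COG in [0, 1].  Then

    omega = z_COG * rho / d3,  phi1 = omega * p,  phi2 = omega * (1 - p)
    drho/dt = -omega

with d3 the investment delay and p the allocation fraction, so the fund
satisfies rho(t) = C - integral of omega.  For a frozen z_COG the fund
decays exactly as C * exp(-z t / d3); the explicit-Euler integrator used
here converges to that closed form at first order in dt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .membership import MembershipVector, TermParams, membership

__all__ = [
    "TERMS",
    "SDParams",
    "SDState",
    "RuleBase",
    "ImpactAggregate",
    "default_rule_base",
    "rule_strengths",
    "aggregate_consequent",
    "cog_defuzzify",
    "mamdani_impact",
    "sd_step",
    "perceived_memberships",
]

logger = logging.getLogger(__name__)

TERMS = ("low", "medium", "high")

#: consequent term shapes on the impact universe z in [0, 1]: a symmetric
#: partition-of-unity cover by three triangles
_CONSEQUENT_VERTICES = {
    "low": (0.0, 0.0, 0.5),
    "medium": (0.0, 0.5, 1.0),
    "high": (0.5, 1.0, 1.0),
}

#: analytic centroids of the full consequent triangles (used by tests)
CONSEQUENT_CENTROIDS = {"low": 1.0 / 6.0, "medium": 0.5, "high": 5.0 / 6.0}


@dataclass(frozen=True)
class SDParams:
    """Parameters of the institutional model.

    C: initial investment fund (currency units); d1, d2: capacity
    lifetimes (time units); d3: investment delay (time units); p: default
    allocation fraction to COASF; dt: Euler step, guarded at
    min(d1, d2, d3)/4 so the decay terms cannot overshoot;
    coasf_terms / csshf_terms: the institution's own triangular
    linguistic-variable constants for perceiving each stock.
    """

    C: float
    d1: float
    d2: float
    d3: float
    p: float
    dt: float
    coasf_terms: TermParams
    csshf_terms: TermParams

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError("C must be >= 0")
        if min(self.d1, self.d2, self.d3) <= 0:
            raise ValueError("d1, d2, d3 must be > 0")
        if not 0 < self.p < 1:
            raise ValueError(f"p must be in (0, 1), got {self.p}")
        guard = min(self.d1, self.d2, self.d3) / 4.0
        if not 0 < self.dt <= guard:
            raise ValueError(
                f"dt must satisfy 0 < dt <= min(d1,d2,d3)/4 = {guard}, got {self.dt}"
            )


@dataclass(frozen=True)
class SDState:
    """Stocks, remaining fund, and the last flows for tracing."""

    t: float
    s1: float
    s2: float
    rho: float
    omega: float = 0.0
    z_cog: float = 0.0
    phi1: float = 0.0
    phi2: float = 0.0
    lambda1: float = 0.0
    lambda2: float = 0.0


@dataclass(frozen=True)
class RuleBase:
    """9 rules mapping (COASF term, CSSHF term) -> impact term."""

    rules: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        expected = {(a, b) for a in TERMS for b in TERMS}
        if set(self.rules) != expected:
            raise ValueError(
                f"rule base must cover all {len(expected)} antecedent pairs exactly once"
            )
        bad = [v for v in self.rules.values() if v not in TERMS]
        if bad:
            raise ValueError(f"unknown consequent terms: {bad}")

    def __len__(self) -> int:
        return len(self.rules)


def default_rule_base() -> RuleBase:
    """The institution's nine-rule investment policy.

    Investment impact is driven mostly by the perceived COASF level, with
    CSSHF nudging the middle rows: low capacities call for low spend
    caution early on, high perceived capacity licenses high spend.
    """
    return RuleBase(
        rules={
            ("low", "low"): "low",
            ("low", "medium"): "low",
            ("low", "high"): "medium",
            ("medium", "low"): "low",
            ("medium", "medium"): "medium",
            ("medium", "high"): "medium",
            ("high", "low"): "high",
            ("high", "medium"): "high",
            ("high", "high"): "high",
        }
    )


@dataclass(frozen=True)
class ImpactAggregate:
    """Aggregated consequent membership mu(z) on a grid over [0, 1]."""

    z: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        if self.z.shape != self.mu.shape:
            raise ValueError("z and mu grids must align")


def _triangle(z: np.ndarray, verts: tuple[float, float, float]) -> np.ndarray:
    left, peak, right = verts
    mu = np.zeros_like(z)
    if peak > left:
        m = (z >= left) & (z < peak)
        mu[m] = (z[m] - left) / (peak - left)
    if right > peak:
        m = (z > peak) & (z <= right)
        mu[m] = (right - z[m]) / (right - peak)
    mu[z == peak] = 1.0
    if peak == left:  # edge triangle: vertical left side collapses at the peak
        mu[z <= peak] = 1.0
    if peak == right:
        mu[z >= peak] = 1.0
    return mu


def rule_strengths(
    m1: MembershipVector, m2: MembershipVector, rules: RuleBase
) -> dict[tuple[str, str], float]:
    """Firing strength of each rule: min of its two antecedent degrees."""
    return {
        (a1, a2): min(m1[a1], m2[a2])
        for (a1, a2) in rules.rules
    }


def aggregate_consequent(
    strengths: dict[tuple[str, str], float],
    rules: RuleBase,
    grid_size: int = 1001,
) -> ImpactAggregate:
    """Clip each fired consequent at its strength; aggregate by max."""
    z = np.linspace(0.0, 1.0, grid_size)
    mu = np.zeros_like(z)
    for antecedents, strength in strengths.items():
        if strength <= 0:
            continue
        term = rules.rules[antecedents]
        clipped = np.minimum(_triangle(z, _CONSEQUENT_VERTICES[term]), strength)
        np.maximum(mu, clipped, out=mu)
    return ImpactAggregate(z=z, mu=mu)


def cog_defuzzify(agg: ImpactAggregate, fallback: float | None = None) -> float:
    """Centre-of-gravity defuzzification by trapezoidal quadrature.

    If no rule fired (identically zero aggregate) the centroid is
    undefined; returns ``fallback`` (typically the previous impact, or 0
    at the start) with a warning, or raises if no fallback is given.
    """
    denom = float(np.trapezoid(agg.mu, agg.z))
    if denom <= 1e-300:
        if fallback is None:
            raise ZeroDivisionError("zero aggregate: COG undefined and no fallback")
        logger.warning("zero aggregate: falling back to z_COG=%.4f", fallback)
        return fallback
    num = float(np.trapezoid(agg.z * agg.mu, agg.z))
    return num / denom


def mamdani_impact(
    m1: MembershipVector,
    m2: MembershipVector,
    rules: RuleBase,
    grid_size: int = 1001,
    fallback: float | None = None,
) -> float:
    """Full Mamdani pipeline: strengths -> clipped max aggregate -> COG."""
    strengths = rule_strengths(m1, m2, rules)
    agg = aggregate_consequent(strengths, rules, grid_size)
    return cog_defuzzify(agg, fallback=fallback)


def perceived_memberships(
    state: SDState, params: SDParams
) -> tuple[MembershipVector, MembershipVector]:
    """Fuzzify the current stocks through the institutional constants."""
    return (
        membership(state.s1, params.coasf_terms),
        membership(state.s2, params.csshf_terms),
    )


def sd_step(state: SDState, params: SDParams, p: float, z_cog: float) -> SDState:
    """One explicit-Euler step of the stock-flow equations.

    omega = z_COG * rho / d3 (truncated so the fund never goes negative);
    phi1 = omega*p, phi2 = omega*(1-p); lambda_k = s_k/d_k;
    s_k += (phi_k - lambda_k) dt; rho -= omega dt.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if not 0 <= z_cog <= 1:
        raise ValueError(f"z_cog must be in [0, 1], got {z_cog}")
    dt = params.dt
    omega = z_cog * state.rho / params.d3
    omega = min(omega, state.rho / dt)  # cannot spend more than remains
    phi1 = omega * p
    phi2 = omega * (1.0 - p)
    lam1 = state.s1 / params.d1
    lam2 = state.s2 / params.d2
    s1 = state.s1 + (phi1 - lam1) * dt
    s2 = state.s2 + (phi2 - lam2) * dt
    rho = max(0.0, state.rho - omega * dt)
    return SDState(
        t=state.t + dt,
        s1=s1,
        s2=s2,
        rho=rho,
        omega=omega,
        z_cog=z_cog,
        phi1=phi1,
        phi2=phi2,
        lambda1=lam1,
        lambda2=lam2,
    )
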