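"""Closed-form membership trajectories for two canonical base-variable paths.

When the base variable declines linearly, ``f(t) = -a*t + beta``, or
exponentially, ``g(t) = exp(beta - a*t)``, the term memberships trace
piecewise closed forms in time.  The path crosses the constants ``d``,
``c`` and ``b`` at breakpoints ``t1 < t2 < t3`` that divide the horizon
into regimes: High holds its shoulder on [t0, t1], hands over to Medium on
[t1, t2], Medium hands over to Low on [t2, t3], and Low saturates at 1 on
[t3, t4].  A declining base value therefore makes the Low and High terms
exchange their relative position over time.

These closed forms are independent re-derivations of the composition
``membership(base_value(t))`` and double as the oracle for the
simulation's membership dynamics.  The analytic first/second derivative
signs (linear: Low rises affinely on (t2,t3); exponential: Low rises
concave-down, High falls concave-up) are exposed via
:func:`derivative_report`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .membership import MembershipVector, TermParams

__all__ = [
    "BaseTrajectorySpec",
    "RegimeBreakpoints",
    "base_value",
    "breakpoints",
    "membership_trajectory",
    "derivative_report",
]

_KINDS = ("linear", "exponential")


@dataclass(frozen=True)
class BaseTrajectorySpec:
    """A decreasing base-variable path over the horizon [0, t4].

    ``kind='linear'`` gives f(t) = -alpha*t + beta;
    ``kind='exponential'`` gives g(t) = exp(beta - alpha*t).
    Both require alpha, beta > 0, so the path is strictly decreasing.
    """

    kind: str
    alpha: float
    beta: float
    t4: float

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0 (increasing paths not supported)")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.t4 <= 0:
            raise ValueError("t4 must be > 0")


@dataclass(frozen=True)
class RegimeBreakpoints:
    """Times at which the path crosses d, c and b (t1 < t2 < t3).

    A threshold not crossed within [0, t4] is still reported (as the raw
    solution of the crossing equation, possibly outside the horizon) and
    flagged in ``uncrossed``.
    """

    t1: float
    t2: float
    t3: float
    uncrossed: tuple[str, ...] = field(default=())


def base_value(t: float, spec: BaseTrajectorySpec) -> float:
    """Evaluate the base path at time ``t`` in [0, t4]."""
    if not 0 <= t <= spec.t4:
        raise ValueError(f"t={t} outside the horizon [0, {spec.t4}]")
    if spec.kind == "linear":
        x = -spec.alpha * t + spec.beta
        if x < 0:
            raise ValueError(
                f"linear path negative at t={t} (x={x}); membership undefined for x<0"
            )
        return x
    return math.exp(spec.beta - spec.alpha * t)


def breakpoints(spec: BaseTrajectorySpec, params: TermParams) -> RegimeBreakpoints:
    """Solve for the crossing times of d, c and b.

    Linear: t_k = (beta - v)/alpha; exponential: t_k = (beta - ln v)/alpha,
    for thresholds v in {d, c, b}.  Crossings outside [0, t4] are flagged.
    """
    names = ("t1", "t2", "t3")
    thresholds = (params.d, params.c, params.b)
    times = []
    uncrossed = []
    for name, v in zip(names, thresholds):
        if spec.kind == "linear":
            tk = (spec.beta - v) / spec.alpha
        else:
            tk = (spec.beta - math.log(v)) / spec.alpha
        times.append(tk)
        if not 0 <= tk <= spec.t4:
            uncrossed.append(name)
    return RegimeBreakpoints(*times, uncrossed=tuple(uncrossed))


def membership_trajectory(
    t: float, spec: BaseTrajectorySpec, params: TermParams
) -> MembershipVector:
    """Closed-form term memberships at time ``t``.

    Written directly from the per-regime closed forms (not by composing
    :func:`~fuzzyhybrid.membership.membership` with :func:`base_value`),
    so equality of the two routes is a meaningful oracle check.
    """
    if not 0 <= t <= spec.t4:
        raise ValueError(f"t={t} outside the horizon [0, {spec.t4}]")
    b, c, d = params.b, params.c, params.d
    bp = breakpoints(spec, params)
    if spec.kind == "linear":
        x = -spec.alpha * t + spec.beta
        if x < 0:
            raise ValueError(f"linear path negative at t={t}")
    else:
        x = math.exp(spec.beta - spec.alpha * t)

    if t <= bp.t1:  # x >= d: High shoulder
        return MembershipVector(0.0, 0.0, 1.0)
    if t <= bp.t2:  # x in [c, d]
        high = (x - c) / (d - c)
        med = (d - x) / (d - c)
        return MembershipVector(0.0, med, high)
    if t <= bp.t3:  # x in [b, c]
        low = (c - x) / (c - b)
        med = (x - b) / (c - b)
        return MembershipVector(low, med, 0.0)
    return MembershipVector(1.0, 0.0, 0.0)  # x <= b: Low shoulder


_SIGNS_LINEAR = {
    # (term, regime) -> (first-derivative sign, second-derivative sign)
    ("high", 0): (0, 0),   # shoulder at 1
    ("high", 1): (-1, 0),
    ("high", 2): (0, 0),
    ("high", 3): (0, 0),
    ("medium", 0): (0, 0),
    ("medium", 1): (1, 0),
    ("medium", 2): (-1, 0),
    ("medium", 3): (0, 0),
    ("low", 0): (0, 0),
    ("low", 1): (0, 0),
    ("low", 2): (1, 0),
    ("low", 3): (0, 0),    # shoulder at 1
}

_SIGNS_EXP = {
    ("high", 0): (0, 0),
    ("high", 1): (-1, 1),   # falls, concave up
    ("high", 2): (0, 0),
    ("high", 3): (0, 0),
    ("medium", 0): (0, 0),
    ("medium", 1): (1, -1),  # rises, concave down
    ("medium", 2): (-1, 1),  # falls, concave up
    ("medium", 3): (0, 0),
    ("low", 0): (0, 0),
    ("low", 1): (0, 0),
    ("low", 2): (1, -1),     # rises, concave down
    ("low", 3): (0, 0),
}


@dataclass(frozen=True)
class DerivativeSigns:
    """Signs (+1, 0, -1) of d(mu)/dt and d2(mu)/dt2 on one open regime."""

    first: int
    second: int


def derivative_report(
    spec: BaseTrajectorySpec,
    params: TermParams,
    term: str,
    interval: tuple[float, float],
) -> DerivativeSigns:
    """Analytic derivative signs of one term's membership on an interval.

    The interval must lie strictly inside one regime of the breakpoints
    (signs are undefined at the kinks).  Linear paths give affine
    memberships (second derivative 0); exponential paths give the
    curvature signs stated in the module docstring.
    """
    if term not in ("low", "medium", "high"):
        raise ValueError(f"unknown term {term!r}")
    lo, hi = interval
    if not (0 <= lo < hi <= spec.t4):
        raise ValueError(f"invalid interval {interval}")
    bp = breakpoints(spec, params)
    edges = [0.0, bp.t1, bp.t2, bp.t3, spec.t4]
    regime = None
    for r in range(4):
        if edges[r] <= lo and hi <= edges[r + 1]:
            regime = r
            break
    if regime is None:
        raise ValueError(
            f"interval {interval} straddles a regime breakpoint {bp}"
        )
    table = _SIGNS_LINEAR if spec.kind == "linear" else _SIGNS_EXP
    first, second = table[(term, regime)]
    return DerivativeSigns(first, second)
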