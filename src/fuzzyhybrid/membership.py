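"""Triangular linguistic-variable machinery.

Each linguistic variable carries three terms (Low, Medium, High) whose
membership functions are triangles sharing the breakpoints ``b < c < d``:
Low has a shoulder plateau at 1 on ``[0, b]`` and falls linearly to 0 at
``c``; Medium rises from 0 at ``b`` to a peak of 1 at ``c`` and falls back
to 0 at ``d``; High rises from 0 at ``c`` and plateaus at 1 from ``d``
onward.  Because all three share the same breakpoints, the degrees of
membership sum to exactly 1 for every base value ``x >= 0`` (a partition
of unity), which the binning and inference layers rely on.

Agent heterogeneity enters through the constants: each agent draws its own
``(b, c, d)`` triple from per-variable normal distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TermParams",
    "MembershipVector",
    "ConstantDistributionSpec",
    "make_term_params",
    "membership",
    "membership_arrays",
    "sample_population_params",
]


class ValidationError(ValueError):
    """Raised when membership-function constants violate their ordering."""


class SamplingError(RuntimeError):
    """Raised when rejection sampling cannot produce a valid ordered triple."""


@dataclass(frozen=True)
class TermParams:
    """Constants ``0 < b < c < d`` of one triangular linguistic variable.

    ``b`` is the end of the Low shoulder, ``c`` the Medium peak and ``d``
    the start of the High shoulder, all in the base variable's units.
    """

    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValidationError(f"b > 0 violated: b={self.b}")
        if not self.b < self.c:
            raise ValidationError(f"b < c violated: b={self.b}, c={self.c}")
        if not self.c < self.d:
            raise ValidationError(f"c < d violated: c={self.c}, d={self.d}")


@dataclass(frozen=True)
class MembershipVector:
    """Degrees of membership of one base value in the three terms."""

    low: float
    medium: float
    high: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.low, self.medium, self.high)

    def __getitem__(self, term: str) -> float:
        return {"low": self.low, "medium": self.medium, "high": self.high}[term]


@dataclass(frozen=True)
class ConstantDistributionSpec:
    """Normal distributions for the constants of one linguistic variable.

    ``B ~ N(b_mean, b_sd^2)`` and likewise for C and D; the means must be
    strictly ordered so that valid triples exist.
    """

    b_mean: float
    c_mean: float
    d_mean: float
    b_sd: float = 0.0
    c_sd: float = 0.0
    d_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.b_mean < self.c_mean < self.d_mean):
            raise ValidationError(
                "means must satisfy 0 < b_mean < c_mean < d_mean, got "
                f"({self.b_mean}, {self.c_mean}, {self.d_mean})"
            )
        for name in ("b_sd", "c_sd", "d_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def make_term_params(b: float, c: float, d: float) -> TermParams:
    """Validate and build a :class:`TermParams` triple."""
    return TermParams(float(b), float(c), float(d))


def membership(x: float, params: TermParams) -> MembershipVector:
    """Evaluate the three term memberships of base value ``x``.

    Piecewise-linear: Low is 1 on [0, b] and (c-x)/(c-b) on [b, c];
    Medium is (x-b)/(c-b) on [b, c] and (d-x)/(d-c) on [c, d];
    High is (x-c)/(d-c) on [c, d] and 1 on [d, inf).
    The components always sum to 1.
    """
    if x < 0:
        raise ValueError(f"base value must be >= 0, got {x}")
    low, med, high = membership_arrays(
        np.asarray(x, dtype=float),
        np.asarray(params.b),
        np.asarray(params.c),
        np.asarray(params.d),
    )
    return MembershipVector(float(low), float(med), float(high))


def membership_arrays(
    x: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised membership evaluation (broadcasting over agents/variables).

    Returns ``(low, medium, high)`` arrays.  Caller guarantees x >= 0 and
    b < c < d elementwise.
    """
    x = np.asarray(x, dtype=float)
    low = np.where(x <= b, 1.0, np.where(x < c, (c - x) / (c - b), 0.0))
    med = np.where(
        (x >= b) & (x <= c),
        (x - b) / (c - b),
        np.where((x > c) & (x <= d), (d - x) / (d - c), 0.0),
    )
    high = np.where(x >= d, 1.0, np.where((x > c) & (x < d), (x - c) / (d - c), 0.0))
    return low, med, high


def sample_population_params(
    spec: ConstantDistributionSpec,
    n: int,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> list[TermParams]:
    """Draw ``n`` ordered triples from the constant distributions.

    B, C and D are drawn independently; triples violating ``0 < b < c < d``
    are rejected and redrawn in full (up to ``max_attempts`` rounds), so each
    accepted marginal stays normal conditional on acceptance rather than
    being distorted by sorting.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    b = rng.normal(spec.b_mean, spec.b_sd, size=n)
    c = rng.normal(spec.c_mean, spec.c_sd, size=n)
    d = rng.normal(spec.d_mean, spec.d_sd, size=n)
    bad = ~((b > 0) & (b < c) & (c < d))
    attempts = 1
    while bad.any():
        if attempts >= max_attempts:
            raise SamplingError(
                f"could not sample valid ordered triples within {max_attempts} "
                f"attempts for spec {spec}"
            )
        m = int(bad.sum())
        b[bad] = rng.normal(spec.b_mean, spec.b_sd, size=m)
        c[bad] = rng.normal(spec.c_mean, spec.c_sd, size=m)
        d[bad] = rng.normal(spec.d_mean, spec.d_sd, size=m)
        bad = ~((b > 0) & (b < c) & (c < d))
        attempts += 1
    return [TermParams(float(bi), float(ci), float(di)) for bi, ci, di in zip(b, c, d)]
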