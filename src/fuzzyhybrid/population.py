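"""Fuzzy agents, contact structure, and the peer-influence update rules.

A population of ``n`` agents each carries ``q`` linguistic variables with
agent-specific triangular membership constants.  Two dynamics act on the
agents each time unit, in order:

1. *Perception* — the institutional intervention re-determines every
   agent's base value (a shared signal per variable, e.g. the current
   capacity stock) and the memberships are recomputed from each agent's
   own constants.
2. *Peer interaction* — agents contact ``k`` peers per time unit (either
   uniformly at random or along a fixed scale-free network) and exchange
   information about the Low term only: resource targeting prioritises
   the worst-off, so only the Low membership is socially negotiated.
   Three inference rules are available: pessimistic (both take the min),
   optimistic (both take the max), and realistic (each takes a weighted
   mean; an agent with smaller constants — i.e. more sensitive to the
   intervention — defers more to a peer with larger constants).

The socially updated Low value is kept as a *shadow* value alongside the
geometry-derived one; the next perception step overwrites it, since the
intervention re-determines memberships each period.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .membership import ConstantDistributionSpec, membership_arrays, sample_population_params

__all__ = [
    "ContactModelSpec",
    "InteractionRuleSpec",
    "Population",
    "ContactModel",
    "init_agents",
    "contact_pairs",
    "pessimistic_update",
    "optimistic_update",
    "realistic_update",
    "interaction_round",
    "perceive",
]

_RULES = ("pessimistic", "optimistic", "realistic")


@dataclass(frozen=True)
class ContactModelSpec:
    """How agents meet: uniformly random or along a scale-free network.

    ``k`` is the number of contacts an agent initiates per time unit
    (default 3, capped at 5).  ``q_exponent`` is the power-law degree
    exponent for the scale-free mode, restricted to (2, 3).
    """

    mode: str
    n_agents: int
    k: int = 3
    q_exponent: float = 2.5

    def __post_init__(self) -> None:
        if self.mode not in ("random", "scale_free"):
            raise ValueError(f"mode must be 'random' or 'scale_free', got {self.mode!r}")
        if not 1 <= self.k <= 5:
            raise ValueError(f"k must be in [1, 5], got {self.k}")
        if self.mode == "scale_free" and not 2 < self.q_exponent < 3:
            raise ValueError(f"q_exponent must be in (2, 3), got {self.q_exponent}")
        if self.n_agents < 2:
            raise ValueError("need at least 2 agents")
        if self.k >= self.n_agents:
            raise ValueError(f"k={self.k} must be < n_agents={self.n_agents}")


@dataclass(frozen=True)
class InteractionRuleSpec:
    """Which of the three peer-inference rules a run uses."""

    rule: str

    def __post_init__(self) -> None:
        if self.rule not in _RULES:
            raise ValueError(f"rule must be one of {_RULES}, got {self.rule!r}")


class Population:
    """Array-backed state of n agents x q linguistic variables.

    Attributes
    ----------
    b, c, d : (n, q) arrays of per-agent membership constants.
    x : (n, q) current base values.
    mu_low_geo, mu_medium, mu_high : (n, q) memberships derived from x.
    mu_low_social : (n, q) shadow Low membership carrying peer influence.
    """

    def __init__(self, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> None:
        self.b = np.asarray(b, dtype=float)
        self.c = np.asarray(c, dtype=float)
        self.d = np.asarray(d, dtype=float)
        if not (self.b.shape == self.c.shape == self.d.shape) or self.b.ndim != 2:
            raise ValueError("b, c, d must be equal-shape (n, q) arrays")
        n, q = self.b.shape
        self.x = np.zeros((n, q))
        self.mu_low_geo = np.ones((n, q))
        self.mu_medium = np.zeros((n, q))
        self.mu_high = np.zeros((n, q))
        self.mu_low_social = np.ones((n, q))

    @property
    def n_agents(self) -> int:
        return self.b.shape[0]

    @property
    def n_variables(self) -> int:
        return self.b.shape[1]

    def copy(self) -> "Population":
        out = Population(self.b.copy(), self.c.copy(), self.d.copy())
        out.x = self.x.copy()
        out.mu_low_geo = self.mu_low_geo.copy()
        out.mu_medium = self.mu_medium.copy()
        out.mu_high = self.mu_high.copy()
        out.mu_low_social = self.mu_low_social.copy()
        return out


def init_agents(
    n: int,
    specs: list[ConstantDistributionSpec],
    initial_base_values: list[float],
    rng: np.random.Generator,
) -> Population:
    """Sample n agents' constants per variable and set initial memberships."""
    if n < 2:
        raise ValueError("need at least 2 agents")
    if len(specs) != len(initial_base_values):
        raise ValueError("one initial base value per variable required")
    q = len(specs)
    b = np.empty((n, q))
    c = np.empty((n, q))
    d = np.empty((n, q))
    for j, spec in enumerate(specs):
        triples = sample_population_params(spec, n, rng)
        b[:, j] = [p.b for p in triples]
        c[:, j] = [p.c for p in triples]
        d[:, j] = [p.d for p in triples]
    pop = Population(b, c, d)
    perceive(pop, list(initial_base_values))
    return pop


class ContactModel:
    """Draws the contact pairs for one time unit.

    Random mode: each agent initiates ``k`` contacts drawn uniformly
    without replacement (no self-pairs).  Scale-free mode: a graph with
    power-law degree distribution P(deg) ~ deg^(-q) is generated once via
    the configuration model (minimum degree 1, self-loops and parallel
    edges dropped); each time unit every agent activates at most ``k`` of
    its incident edges.
    """

    def __init__(self, spec: ContactModelSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        self.graph: nx.Graph | None = None
        if spec.mode == "scale_free":
            self.graph = _scale_free_graph(spec.n_agents, spec.q_exponent, rng)

    def draw_pairs(self, rng: np.random.Generator) -> list[tuple[int, int]]:
        spec = self.spec
        n, k = spec.n_agents, spec.k
        if spec.mode == "random":
            # a contact is symmetric: if both parties happen to choose each
            # other within the round it is still one meeting
            chosen_r: set[tuple[int, int]] = set()
            for i in range(n):
                partners = rng.choice(n - 1, size=k, replace=False)
                # shift indices >= i by one to skip self
                for r0 in partners:
                    r = int(r0) + (1 if r0 >= i else 0)
                    chosen_r.add((min(i, r), max(i, r)))
            pairs = sorted(chosen_r)
        else:
            chosen: set[tuple[int, int]] = set()
            for i in self.graph.nodes:
                nbrs = list(self.graph.neighbors(i))
                if len(nbrs) > k:
                    idx = rng.choice(len(nbrs), size=k, replace=False)
                    nbrs = [nbrs[t] for t in idx]
                for r in nbrs:
                    chosen.add((min(i, r), max(i, r)))
            pairs = sorted(chosen)
        order = rng.permutation(len(pairs))
        return [pairs[t] for t in order]


def _scale_free_graph(n: int, q: float, rng: np.random.Generator) -> nx.Graph:
    """Configuration-model graph with P(deg) ~ deg^(-q), min degree 1."""
    kmax = max(2, n - 1)
    ks = np.arange(1, kmax + 1)
    pmf = ks ** (-q)
    pmf /= pmf.sum()
    degrees = rng.choice(ks, size=n, p=pmf)
    if degrees.sum() % 2:
        degrees[int(rng.integers(n))] += 1
    g = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(g)  # collapse parallel edges
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def contact_pairs(
    model: ContactModel | ContactModelSpec, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Contact pairs for one time unit (builds a model from a bare spec)."""
    if isinstance(model, ContactModelSpec):
        model = ContactModel(model, rng)
    return model.draw_pairs(rng)


def pessimistic_update(mu_i: float, mu_r: float) -> tuple[float, float]:
    """Both parties adopt the smaller Low membership."""
    m = min(mu_i, mu_r)
    return m, m


def optimistic_update(mu_i: float, mu_r: float) -> tuple[float, float]:
    """Both parties adopt the larger Low membership."""
    m = max(mu_i, mu_r)
    return m, m


def realistic_update(
    mu_i: float, mu_r: float, b_i: float, b_r: float
) -> tuple[float, float]:
    """Each party takes a convex combination weighted by the b constants.

    Agent i keeps weight phi_i = b_i/(b_i+b_r) on its own value and puts
    omega_i = b_r/(b_i+b_r) on the peer's, so phi_i < omega_i exactly when
    the peer's constant is larger (the more sensitive agent defers more);
    equal constants give a plain average.  The peer's weights are derived
    the same way from its own perspective.
    """
    tot = b_i + b_r
    omega_i = b_r / tot
    omega_r = b_i / tot
    new_i = (1.0 - omega_i) * mu_i + omega_i * mu_r
    new_r = (1.0 - omega_r) * mu_r + omega_r * mu_i
    return new_i, new_r


def interaction_round(
    pop: Population,
    pairs: list[tuple[int, int]],
    rule: InteractionRuleSpec,
) -> Population:
    """Apply one round of peer updates to the shadow Low memberships.

    Pairs are processed sequentially in the given order (each update sees
    the values left by earlier pairs in the round), for every linguistic
    variable; Medium/High stay as derived from the base values.  Mutates
    and returns ``pop``.
    """
    mu = pop.mu_low_social
    if rule.rule == "pessimistic":
        for i, r in pairs:
            m = np.minimum(mu[i], mu[r])
            mu[i] = m
            mu[r] = m
    elif rule.rule == "optimistic":
        for i, r in pairs:
            m = np.maximum(mu[i], mu[r])
            mu[i] = m
            mu[r] = m
    elif rule.rule == "realistic":
        for i, r in pairs:
            tot = pop.b[i] + pop.b[r]
            omega_i = pop.b[r] / tot
            omega_r = pop.b[i] / tot
            new_i = (1.0 - omega_i) * mu[i] + omega_i * mu[r]
            new_r = (1.0 - omega_r) * mu[r] + omega_r * mu[i]
            mu[i] = new_i
            mu[r] = new_r
    else:  # pragma: no cover - spec guarantees validation
        raise ValueError(f"unknown rule {rule.rule!r}")
    return pop


def perceive(pop: Population, base_signals: list[float]) -> Population:
    """First dynamic: the intervention re-determines every membership.

    Sets x_ij := signal_j (shared across agents; heterogeneity enters only
    through each agent's constants), recomputes the geometric memberships,
    and resets the shadow Low value to the freshly perceived one.
    Mutates and returns ``pop``.
    """
    signals = np.asarray(base_signals, dtype=float)
    if signals.shape != (pop.n_variables,):
        raise ValueError(f"expected {pop.n_variables} base signals, got {signals.shape}")
    if (signals < 0).any():
        raise ValueError(f"base signals must be >= 0, got {signals}")
    pop.x[:] = signals[None, :]
    low, med, high = membership_arrays(pop.x, pop.b, pop.c, pop.d)
    pop.mu_low_geo = low
    pop.mu_medium = med
    pop.mu_high = high
    pop.mu_low_social = low.copy()
    return pop
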