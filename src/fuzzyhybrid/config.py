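"""Scenario configuration: schema, validation, YAML round-trip, presets.

A scenario file has five sections:

``population``
    agent count and, per linguistic variable, the normal distributions of
    the membership constants plus the initial base value.
``contact``
    contact model (``random`` or ``scale_free``), contacts per time unit
    ``k`` and the scale-free degree exponent.
``interaction``
    which peer-inference rule to use.
``sd``
    institutional fund, lifetimes, delay, default allocation fraction,
    Euler step, the institution's own membership constants per stock, and
    whether the allocation fraction adapts to the clustering feedback.
``engine``
    time units per stage, maximum stages, homogenisation threshold, seed
    and output thinning.

Exactly two linguistic variables are supported — they map one-to-one onto
the two capacity stocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .membership import ConstantDistributionSpec, TermParams, ValidationError
from .institution import SDParams
from .population import ContactModelSpec, InteractionRuleSpec

__all__ = [
    "VariableSpec",
    "EngineConfig",
    "load_config",
    "save_config",
    "validate_config",
    "generate_demo_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """A scenario file failed validation; ``errors`` lists every problem."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass(frozen=True)
class VariableSpec:
    """One linguistic variable: constant distributions + initial base value."""

    name: str
    distribution: ConstantDistributionSpec
    initial: float

    def __post_init__(self) -> None:
        if self.initial < 0:
            raise ValidationError(f"initial base value must be >= 0, got {self.initial}")


@dataclass(frozen=True)
class EngineConfig:
    n_agents: int
    variables: tuple[VariableSpec, VariableSpec]
    contact: ContactModelSpec
    interaction: InteractionRuleSpec
    sd: SDParams
    adaptive_p: bool
    tau_len: int
    max_stages: int
    homogenization_threshold: float
    seed: int
    thinning: int = 1

    def __post_init__(self) -> None:
        if len(self.variables) != 2:
            raise ValidationError(
                "exactly 2 linguistic variables are supported (one per capacity stock)"
            )
        if self.n_agents < 2:
            raise ValidationError("population.n must be >= 2")
        if self.contact.n_agents != self.n_agents:
            raise ValidationError(
                f"contact.n_agents ({self.contact.n_agents}) must equal "
                f"population.n ({self.n_agents})"
            )
        if self.tau_len < 1:
            raise ValidationError("engine.tau_len must be >= 1")
        if self.max_stages < 1:
            raise ValidationError("engine.max_stages must be >= 1")
        if not 0 <= self.homogenization_threshold <= 1:
            raise ValidationError("engine.homogenization_threshold must be in [0, 1]")
        if self.seed < 0:
            raise ValidationError("engine.seed must be a nonnegative integer")
        if self.thinning < 1:
            raise ValidationError("output.thinning must be >= 1")


def _to_dict(cfg: EngineConfig) -> dict:
    return {
        "population": {
            "n": cfg.n_agents,
            "variables": [
                {
                    "name": v.name,
                    "b_mean": v.distribution.b_mean,
                    "c_mean": v.distribution.c_mean,
                    "d_mean": v.distribution.d_mean,
                    "b_sd": v.distribution.b_sd,
                    "c_sd": v.distribution.c_sd,
                    "d_sd": v.distribution.d_sd,
                    "initial": v.initial,
                }
                for v in cfg.variables
            ],
        },
        "contact": {
            "mode": cfg.contact.mode,
            "k": cfg.contact.k,
            "q_exponent": cfg.contact.q_exponent,
        },
        "interaction": {"rule": cfg.interaction.rule},
        "sd": {
            "C": cfg.sd.C,
            "d1": cfg.sd.d1,
            "d2": cfg.sd.d2,
            "d3": cfg.sd.d3,
            "p": cfg.sd.p,
            "dt": cfg.sd.dt,
            "adaptive_p": cfg.adaptive_p,
            "coasf_terms": {
                "b": cfg.sd.coasf_terms.b,
                "c": cfg.sd.coasf_terms.c,
                "d": cfg.sd.coasf_terms.d,
            },
            "csshf_terms": {
                "b": cfg.sd.csshf_terms.b,
                "c": cfg.sd.csshf_terms.c,
                "d": cfg.sd.csshf_terms.d,
            },
        },
        "engine": {
            "tau_len": cfg.tau_len,
            "max_stages": cfg.max_stages,
            "homogenization_threshold": cfg.homogenization_threshold,
            "seed": cfg.seed,
        },
        "output": {"thinning": cfg.thinning},
    }


def _from_dict(raw: dict) -> EngineConfig:
    errors: list[str] = []

    def need(section: str, key: str, default=None):
        sec = raw.get(section)
        if not isinstance(sec, dict):
            errors.append(f"missing section '{section}'")
            return default
        if key not in sec:
            if default is None:
                errors.append(f"missing key '{section}.{key}'")
            return default
        return sec[key]

    n = need("population", "n")
    var_rows = need("population", "variables") or []
    contact_mode = need("contact", "mode", "random")
    k = need("contact", "k", 3)
    q_exp = need("contact", "q_exponent", 2.5)
    rule = need("interaction", "rule")
    sd_keys = {key: need("sd", key) for key in ("C", "d1", "d2", "d3", "p", "dt")}
    adaptive_p = bool(need("sd", "adaptive_p", False))
    coasf = need("sd", "coasf_terms")
    csshf = need("sd", "csshf_terms")
    tau_len = need("engine", "tau_len")
    max_stages = need("engine", "max_stages")
    threshold = need("engine", "homogenization_threshold")
    seed = need("engine", "seed", 0)
    thinning = need("output", "thinning", 1)
    if errors:
        raise ConfigError(errors)

    variables = []
    for idx, row in enumerate(var_rows):
        try:
            dist = ConstantDistributionSpec(
                b_mean=float(row["b_mean"]),
                c_mean=float(row["c_mean"]),
                d_mean=float(row["d_mean"]),
                b_sd=float(row.get("b_sd", 0.0)),
                c_sd=float(row.get("c_sd", 0.0)),
                d_sd=float(row.get("d_sd", 0.0)),
            )
            variables.append(
                VariableSpec(
                    name=str(row.get("name", f"var{idx}")),
                    distribution=dist,
                    initial=float(row.get("initial", 0.0)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            errors.append(f"population.variables[{idx}]: {exc}")
    if errors:
        raise ConfigError(errors)

    def build(label, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (TypeError, ValueError) as exc:
            errors.append(f"{label}: {exc}")
            return None

    contact = build(
        "contact",
        ContactModelSpec,
        mode=str(contact_mode),
        n_agents=int(n),
        k=int(k),
        q_exponent=float(q_exp),
    )
    interaction = build("interaction.rule", InteractionRuleSpec, rule=str(rule))
    coasf_terms = build(
        "sd.coasf_terms", TermParams, float(coasf["b"]), float(coasf["c"]), float(coasf["d"])
    ) if isinstance(coasf, dict) else errors.append("sd.coasf_terms must be a mapping")
    csshf_terms = build(
        "sd.csshf_terms", TermParams, float(csshf["b"]), float(csshf["c"]), float(csshf["d"])
    ) if isinstance(csshf, dict) else errors.append("sd.csshf_terms must be a mapping")
    sd = None
    if coasf_terms and csshf_terms and all(v is not None for v in sd_keys.values()):
        sd = build(
            "sd",
            SDParams,
            C=float(sd_keys["C"]),
            d1=float(sd_keys["d1"]),
            d2=float(sd_keys["d2"]),
            d3=float(sd_keys["d3"]),
            p=float(sd_keys["p"]),
            dt=float(sd_keys["dt"]),
            coasf_terms=coasf_terms,
            csshf_terms=csshf_terms,
        )
    if errors or sd is None or contact is None or interaction is None:
        raise ConfigError(errors or ["incomplete sd section"])

    try:
        return EngineConfig(
            n_agents=int(n),
            variables=tuple(variables),
            contact=contact,
            interaction=interaction,
            sd=sd,
            adaptive_p=adaptive_p,
            tau_len=int(tau_len),
            max_stages=int(max_stages),
            homogenization_threshold=float(threshold),
            seed=int(seed),
            thinning=int(thinning),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError([str(exc)]) from exc


def load_config(path: str) -> EngineConfig:
    """Read and validate a YAML scenario file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(["scenario file must be a YAML mapping"])
    return _from_dict(raw)


def save_config(cfg: EngineConfig, path: str) -> None:
    """Write a scenario to YAML; round-trips all validated fields exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=False)


def validate_config(path: str) -> list[str]:
    """Return the itemised error list for a scenario file (empty if valid)."""
    try:
        load_config(path)
    except ConfigError as exc:
        return exc.errors
    except (OSError, yaml.YAMLError) as exc:
        return [str(exc)]
    return []


def generate_demo_config(preset: str = "small", seed: int = 0) -> EngineConfig:
    """Built-in scenarios.

    ``small``: 50 agents, 5 time units per stage, up to 10 stages, a fund
    sized so sustained investment drives both stocks well past the upper
    perception threshold (adequate resourcing).  ``paper_like``: 1,000
    agents with wider constant spread and longer stages, producing the
    characteristic growth-then-saturation capacity curves with
    heterogeneous membership fans.
    """
    if preset not in ("small", "paper_like"):
        raise ValueError(f"unknown preset {preset!r}")
    base_var = dict(b_mean=2.0, c_mean=5.0, d_mean=8.0)
    if preset == "small":
        n, sd_sigma, tau_len, max_stages, rule = 50, 0.3, 5, 10, "realistic"
        fund = 300.0
    else:
        n, sd_sigma, tau_len, max_stages, rule = 1000, 0.5, 10, 10, "realistic"
        fund = 400.0
    dists = [
        ConstantDistributionSpec(
            **base_var, b_sd=sd_sigma, c_sd=sd_sigma, d_sd=sd_sigma
        )
        for _ in range(2)
    ]
    variables = (
        VariableSpec(name="coasf", distribution=dists[0], initial=0.5),
        VariableSpec(name="csshf", distribution=dists[1], initial=0.5),
    )
    sd = SDParams(
        C=fund,
        d1=10.0,
        d2=10.0,
        d3=2.0,
        p=0.5,
        dt=1.0 / 16.0,
        coasf_terms=TermParams(2.0, 5.0, 8.0),
        csshf_terms=TermParams(2.0, 5.0, 8.0),
    )
    return EngineConfig(
        n_agents=n,
        variables=variables,
        contact=ContactModelSpec(mode="random", n_agents=n, k=3),
        interaction=InteractionRuleSpec(rule=rule),
        sd=sd,
        adaptive_p=True,
        tau_len=tau_len,
        max_stages=max_stages,
        homogenization_threshold=0.9,
        seed=int(seed),
        thinning=1,
    )
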