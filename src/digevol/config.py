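"""Simulation configuration: every run parameter in one flat namespace.

A configuration file is plain text, one ``key = value`` pair per line
(``#`` comments allowed), with snake_case names matching the model's
standard parameter table 1:1.  Unknown keys are rejected.  The same flat
dictionary form is embedded in backups so that a run directory is
self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

from .decoding import DecodingRules
from .mutation import MutationRates
from .phenotype import EnvironmentSpec

__all__ = [
    "SimulationConfig",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "apply_overrides",
    "EVOLUTIONARY_KEYS",
    "UnknownConfigKeyError",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of an evolutionary run.

    Defaults reproduce the reference parameter set: N = 1,000 individuals,
    5,000-bp random founder, d_max = 4, w_max = 5e-3, tau = 2,500,
    sigma = 5e-3, k = 750, local mutation rates 5e-6/bp and rearrangement
    rates 5e-5/bp.
    """

    population_size: int = 1000
    initial_genome_length: int = 5000
    selection_k: float = 750.0
    generations: int = 0
    seed: int = 0
    rules: DecodingRules = field(default_factory=DecodingRules)
    env: EnvironmentSpec = field(default_factory=EnvironmentSpec)
    rates: MutationRates = field(default_factory=MutationRates)
    backup_period: int = 0  # 0 = no periodic backups
    stats_period: int = 1
    record_lineage: bool = False
    init_max_attempts: int = 10 ** 6


# Mapping between flat config keys and the nested dataclasses.
_RULES_KEYS = {
    "promoter_consensus": ("consensus", str),
    "max_promoter_mismatches": ("d_max", int),
    "terminator_stem": ("stem_len", int),
    "terminator_loop": ("loop_len", int),
    "shine_dalgarno": ("shine_dalgarno", str),
    "spacer_length": ("spacer_len", int),
    "start_codon": ("start_codon", str),
    "stop_codon": ("stop_codon", str),
    "w_max": ("w_max", float),
}
_ENV_KEYS = {
    "sigma": ("sigma", float),
    "tau": ("tau", float),
    "env_resolution": ("resolution", int),
}
_RATES_KEYS = {
    "u_point": ("point", float),
    "u_small_insertion": ("small_ins", float),
    "u_small_deletion": ("small_del", float),
    "u_large_deletion": ("large_del", float),
    "u_duplication": ("duplication", float),
    "u_inversion": ("inversion", float),
    "u_translocation": ("translocation", float),
    "indel_length_max": ("indel_len_max", int),
}
_TOP_KEYS = {
    "population_size": int,
    "initial_genome_length": int,
    "selection_k": float,
    "generations": int,
    "seed": int,
    "backup_period": int,
    "stats_period": int,
    "record_lineage": lambda s: str(s).lower() in ("1", "true", "yes"),
    "init_max_attempts": int,
}

#: Keys that may be overridden when replaying from a backup: evolutionary
#: parameters only.  Structural constants (signal definitions, population
#: size, genetic code) would invalidate the stored genomes' semantics.
EVOLUTIONARY_KEYS = frozenset(
    ["selection_k", "generations", "sigma", "tau", "env_resolution",
     "env_gaussians", "backup_period", "stats_period", "record_lineage"]
    + list(_RATES_KEYS)
)


class UnknownConfigKeyError(KeyError):
    pass


def _format_gaussians(env: EnvironmentSpec) -> str:
    return ";".join(f"{h!r}:{m!r}:{s!r}" for h, m, s in env.gaussians)


def _parse_gaussians(text: str):
    out = []
    for part in text.split(";"):
        h, m, s = (float(x) for x in part.split(":"))
        out.append((h, m, s))
    return tuple(out)


def _format_code(rules: DecodingRules) -> str:
    return ",".join(f"{codon}:{role}" for codon, role in rules.genetic_code)


def _parse_code(text: str):
    return tuple(tuple(pair.split(":")) for pair in text.split(","))


def config_to_dict(cfg: SimulationConfig) -> Dict[str, str]:
    """Flatten a configuration into an ordered {key: string} mapping."""
    d: Dict[str, str] = {}
    for key, conv in _TOP_KEYS.items():
        d[key] = str(getattr(cfg, key))
    for key, (attr, _) in _RULES_KEYS.items():
        d[key] = str(getattr(cfg.rules, attr))
    d["genetic_code"] = _format_code(cfg.rules)
    d["env_gaussians"] = _format_gaussians(cfg.env)
    for key, (attr, _) in _ENV_KEYS.items():
        d[key] = str(getattr(cfg.env, attr))
    for key, (attr, _) in _RATES_KEYS.items():
        d[key] = str(getattr(cfg.rates, attr))
    return d


def config_from_dict(d: Dict[str, str],
                     base: Optional[SimulationConfig] = None
                     ) -> SimulationConfig:
    """Build a configuration from a flat mapping; unknown keys are rejected."""
    cfg = base if base is not None else SimulationConfig()
    top, rules_kw, env_kw, rates_kw = {}, {}, {}, {}
    for key, raw in d.items():
        val = raw.strip() if isinstance(raw, str) else raw
        if key in _TOP_KEYS:
            top[key] = _TOP_KEYS[key](val)
        elif key in _RULES_KEYS:
            attr, conv = _RULES_KEYS[key]
            rules_kw[attr] = conv(val)
        elif key == "genetic_code":
            rules_kw["genetic_code"] = (
                _parse_code(val) if isinstance(val, str) else val)
        elif key in _ENV_KEYS:
            attr, conv = _ENV_KEYS[key]
            env_kw[attr] = conv(val)
        elif key == "env_gaussians":
            env_kw["gaussians"] = (
                _parse_gaussians(val) if isinstance(val, str) else val)
        elif key in _RATES_KEYS:
            attr, conv = _RATES_KEYS[key]
            rates_kw[attr] = conv(val)
        else:
            raise UnknownConfigKeyError(f"unknown configuration key: {key}")
    if rules_kw:
        cfg = replace(cfg, rules=replace(cfg.rules, **rules_kw))
    if env_kw:
        cfg = replace(cfg, env=replace(cfg.env, **env_kw))
    if rates_kw:
        cfg = replace(cfg, rates=replace(cfg.rates, **rates_kw))
    if top:
        cfg = replace(cfg, **top)
    return cfg


def load_config(path, base: Optional[SimulationConfig] = None
                ) -> SimulationConfig:
    """Parse a flat ``key = value`` configuration file."""
    d: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            d[key.strip()] = val.strip()
    return config_from_dict(d, base=base)


def save_config(cfg: SimulationConfig, path) -> None:
    """Write a configuration snapshot re-parseable by :func:`load_config`."""
    with open(path, "w") as fh:
        for key, val in config_to_dict(cfg).items():
            fh.write(f"{key} = {val}\n")


def apply_overrides(cfg: SimulationConfig, overrides: Dict[str, str],
                    restrict_to_evolutionary: bool = False
                    ) -> SimulationConfig:
    """Apply ``--set key=value``-style overrides to a configuration.

    With ``restrict_to_evolutionary=True`` (replay from a backup), only
    evolutionary parameters may change; structural keys are rejected.
    """
    if restrict_to_evolutionary:
        bad = set(overrides) - EVOLUTIONARY_KEYS
        if bad:
            raise ValueError(
                "replay may only override evolutionary parameters; "
                f"rejected: {sorted(bad)}")
    return config_from_dict(overrides, base=cfg)
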