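"""Structured-text (YAML) run configuration with schema validation.

A configuration names the data, the site/clock model (or a model-averaging
set), the tree prior, operator weights and chain settings.  Validation is
aggregated: all schema errors are reported at once, and unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["ConfigError", "RunConfig", "load_config", "dump_config", "DEFAULTS"]


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


DEFAULTS: dict[str, Any] = {
    "data": {
        "alignment": None,  # path; None allowed for prior-only runs
        "format": "fasta",
        "date_format": None,  # "suffix" or None
        "date_table": None,
        "starting_tree": None,  # Newick/NEXUS path; simulated if absent
    },
    "model": {
        "site": {
            "code": "111111",
            "average_over": None,  # "all_reversible" | "no_ti_tv_sharing"
            "gamma_categories": 4,
            "use_gamma": False,
            "use_invariant": False,
        },
        "clock": {
            "kind": "strict",
            "rate": 1.0,
            "sigma": 0.5,
        },
    },
    "prior": {
        "kind": "coalescent",  # coalescent | bd_serial | bdsky
        "Ne": 1.0,
        "origin": None,
        "lambda": 2.0,
        "mu": 1.0,
        "psi": 0.5,
        "r": 1.0,
        "rho": 0.0,
        "change_heights": [],
    },
    "operators": {
        "tree_weight": 60.0,
        "scalar_weight": 20.0,
        "rj_weight": 15.0,
        "sa_weight": 5.0,
    },
    "chain": {
        "length": 100000,
        "log_every": 100,
        "seed": 1,
        "burn_in": 0.1,
    },
    "output": {
        "prefix": "skytree_run",
    },
}


@dataclass
class RunConfig:
    data: dict
    model: dict
    prior: dict
    operators: dict
    chain: dict
    output: dict
    raw: dict = field(repr=False, default_factory=dict)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:12]

    def as_dict(self) -> dict:
        return {
            "data": self.data,
            "model": self.model,
            "prior": self.prior,
            "operators": self.operators,
            "chain": self.chain,
            "output": self.output,
        }


def _merge(defaults: dict, given: dict, path: str, errors: list[str]) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in given.items():
        if key not in defaults:
            errors.append(f"unknown key {path}{key!r}")
            continue
        if isinstance(defaults[key], dict) and not isinstance(value, dict):
            errors.append(f"{path}{key}: expected a mapping")
        elif isinstance(defaults[key], dict):
            out[key] = _merge(defaults[key], value, f"{path}{key}.", errors)
        else:
            out[key] = value
    return out


def _validate(cfg: dict, errors: list[str]) -> None:
    chain = cfg["chain"]
    for key in ("length", "log_every", "seed"):
        if not isinstance(chain[key], int) or chain[key] < 0:
            errors.append(f"chain.{key}: must be a non-negative integer")
    if not (0 <= chain["burn_in"] < 1):
        errors.append("chain.burn_in: must lie in [0, 1)")
    prior = cfg["prior"]
    if prior["kind"] not in ("coalescent", "bd_serial", "bdsky"):
        errors.append(f"prior.kind: unknown kind {prior['kind']!r}")
    if prior["kind"] in ("bd_serial", "bdsky") and prior["origin"] is None:
        errors.append(f"prior.origin: required for {prior['kind']}")
    site = cfg["model"]["site"]
    if site["average_over"] not in (None, "all_reversible", "no_ti_tv_sharing"):
        errors.append(f"model.site.average_over: unknown set {site['average_over']!r}")
    from .substitution import is_canonical

    if not is_canonical(str(site["code"])):
        errors.append(f"model.site.code: {site['code']!r} is not canonical")
    clock = cfg["model"]["clock"]
    if clock["kind"] not in ("strict", "relaxed_lognormal"):
        errors.append(f"model.clock.kind: unknown kind {clock['kind']!r}")


def load_config(path: str) -> RunConfig:
    """Load and validate; raises :class:`ConfigError` listing *all*
    schema violations, not just the first."""
    with open(path) as fh:
        given = yaml.safe_load(fh) or {}
    if not isinstance(given, dict):
        raise ConfigError(["top level must be a mapping"])
    errors: list[str] = []
    merged = _merge(DEFAULTS, given, "", errors)
    if not errors:
        _validate(merged, errors)
    if errors:
        raise ConfigError(errors)
    return RunConfig(
        data=merged["data"],
        model=merged["model"],
        prior=merged["prior"],
        operators=merged["operators"],
        chain=merged["chain"],
        output=merged["output"],
        raw=merged,
    )


def dump_config(cfg: RunConfig) -> str:
    """YAML echo of the fully-defaulted configuration (reloads identically)."""
    return yaml.safe_dump(cfg.as_dict(), sort_keys=True)
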