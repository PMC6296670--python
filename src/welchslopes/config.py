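"""Configuration handling for the command-line interface.

Keys mirror the variable names of the planning-program convention
(``sigsq1``, ``tausq1``, ``rn21``, ...) so a specification block can be
transferred verbatim; long-form aliases are accepted too.  Files may be
YAML or JSON; command-line flags override file values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "ConfigError"]

COMMANDS = ("test", "power", "samplesize", "simulate", "tables")

# long-form alias -> canonical short key
ALIASES = {
    "sigma2_1": "sigsq1",
    "sigma2_2": "sigsq2",
    "tau2_1": "tausq1",
    "tau2_2": "tausq2",
    "ratio": "rn21",
    "beta1_1": "beta11",
    "beta1_2": "beta12",
}


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    command: str
    alpha: float = 0.05
    power: float | None = None
    n1: int | None = None
    n2: int | None = None
    beta11: float | None = None
    beta12: float | None = None
    sigsq1: float | None = None
    sigsq2: float | None = None
    tausq1: float | None = None
    tausq2: float | None = None
    rn21: float | None = None
    reps: int = 10_000
    seed: int | None = None
    method: str = "MT"
    fixture: str | None = None
    data: str | None = None
    out: str | None = None
    fmt: str = "text"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def require(self, *keys: str) -> None:
        missing = [k for k in keys if getattr(self, k) is None]
        if missing:
            raise ConfigError(
                f"command '{self.command}' requires: {', '.join(missing)}"
            )


_PARAM_KEYS = ("beta11", "beta12", "sigsq1", "sigsq2", "tausq1", "tausq2")


def _read_file(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config file must hold a mapping")
    return data


def load_config(
    command: str,
    path: str | Path | None = None,
    flags: dict | None = None,
    log=None,
) -> RunConfig:
    """Merge config file and flags (flags win) into a validated RunConfig."""
    if command not in COMMANDS:
        raise ConfigError(f"unknown command {command!r}; choose from {COMMANDS}")
    valid = {f.name for f in fields(RunConfig)} - {"command"}
    merged: dict = {}
    for source, name in ((_read_file(path) if path else {}, "file"),
                        (dict(flags or {}), "flag")):
        for key, value in source.items():
            key = ALIASES.get(key, key)
            if key not in valid:
                raise ConfigError(f"unknown {name} key {key!r}")
            if value is None:
                continue
            if key in merged and merged[key] != value and log is not None:
                log(f"{name} overrides {key}: {merged[key]!r} -> {value!r}")
            merged[key] = value
    rc = RunConfig(command=command, **merged)
    _validate(rc)
    return rc


def _validate(rc: RunConfig) -> None:
    if not 0 < rc.alpha < 1:
        raise ConfigError(f"alpha must be in (0, 1), got {rc.alpha}")
    if rc.power is not None and not rc.alpha < rc.power < 1:
        raise ConfigError(f"power must be in (alpha, 1), got {rc.power}")
    if rc.method not in ("ST", "MT"):
        raise ConfigError(f"method must be ST or MT, got {rc.method!r}")
    if rc.fmt not in ("text", "csv", "json"):
        raise ConfigError(f"format must be text, csv or json, got {rc.fmt!r}")
    for key in ("sigsq1", "sigsq2", "tausq1", "tausq2"):
        val = getattr(rc, key)
        if val is not None and not val > 0:
            raise ConfigError(f"{key} must be strictly positive, got {val}")
    for key in ("n1", "n2"):
        val = getattr(rc, key)
        if val is not None and val < 3:
            raise ConfigError(f"{key} must be >= 3, got {val}")
    if rc.rn21 is not None and not rc.rn21 > 0:
        raise ConfigError(f"rn21 must be positive, got {rc.rn21}")
    if rc.reps is not None and rc.reps < 100:
        raise ConfigError(f"reps must be >= 100, got {rc.reps}")

    if rc.command == "test":
        if rc.fixture is None and rc.data is None:
            raise ConfigError("command 'test' needs --data CSV or --fixture")
    elif rc.command == "power":
        if rc.fixture is None:
            rc.require(*_PARAM_KEYS)
        rc.require("n1", "n2")
    elif rc.command == "samplesize":
        if rc.fixture is None:
            rc.require(*_PARAM_KEYS)
        rc.require("power", "rn21")
    elif rc.command == "simulate":
        if rc.fixture is None:
            rc.require(*_PARAM_KEYS)
        rc.require("n1", "n2")
    elif rc.command == "tables":
        rc.require("beta11", "beta12", "rn21", "power")
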