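"""Run configuration: resolved defaults, validation, YAML loading, echo."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError
from .fingerprints import FP_TYPES
from .measures import MEASURES
from .properties import DEFAULT_PH
from .transformation import DEFAULT_DEGREE

LEVELS = ("reaction", "transformation")


@dataclass
class RunConfig:
    """Resolved parameters of one scoring run.

    Defaults mirror the tool's stated behavior: reaction level, extended
    fingerprint, tanimoto, transformation degree 1, pH 7, no property
    correction, forward orientation.
    """

    levels: tuple[str, ...] = ("reaction",)
    fp_types: tuple[str, ...] = ("extended",)
    measures: tuple[str, ...] = ("tanimoto",)
    degrees: tuple[int, ...] = (DEFAULT_DEGREE,)
    ph: float = DEFAULT_PH
    properties: tuple[str, ...] = ()
    orientation: str = "forward"
    correct_transformation: bool = False
    input: Optional[str] = None
    pairs: Optional[str] = None
    output: Optional[str] = None
    dialect: str = "tsv"
    strict: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        for name in ("levels", "fp_types", "measures", "degrees", "properties"):
            setattr(self, name, tuple(getattr(self, name)))
        self.validate()

    def validate(self) -> None:
        if not self.levels:
            raise ConfigError("select at least one similarity level")
        bad = set(self.levels) - set(LEVELS)
        if bad:
            raise ConfigError(f"unknown level(s) {sorted(bad)}; valid: {LEVELS}")
        if not self.fp_types:
            raise ConfigError("select at least one fingerprint type")
        bad = set(self.fp_types) - set(FP_TYPES)
        if bad:
            raise ConfigError(
                f"unknown fingerprint type(s) {sorted(bad)}; valid: {FP_TYPES}"
            )
        if not self.measures:
            raise ConfigError("select at least one similarity measure")
        bad = set(self.measures) - set(MEASURES)
        if bad:
            raise ConfigError(
                f"unknown measure(s) {sorted(bad)}; valid: {MEASURES}"
            )
        if "transformation" in self.levels and not self.degrees:
            raise ConfigError(
                "degree list must be non-empty when transformation level is selected"
            )
        if any(d < 0 for d in self.degrees):
            raise ConfigError("transformation degrees must be >= 0")
        bad = set(self.properties) - {"mass", "volume"}
        if bad:
            raise ConfigError(
                f"unknown property/properties {sorted(bad)}; valid: ('mass', 'volume')"
            )
        if self.orientation not in ("forward", "auto"):
            raise ConfigError("orientation must be 'forward' or 'auto'")
        if not 0 <= self.ph <= 14:
            raise ConfigError(f"pH must be within [0, 14], got {self.ph}")

    def echo(self) -> dict:
        """Machine-readable echo of every resolved parameter."""
        return asdict(self)

    def write_echo(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.echo(), indent=2, sort_keys=True))

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config key(s) in {path}: {sorted(bad)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    @classmethod
    def from_echo(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
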