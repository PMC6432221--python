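"""Run configuration: YAML round-trip and validation.

A :class:`RunConfig` bundles the module name, a flat parameter map, the
RNG seed and output paths.  ``parse(serialize(cfg)) == cfg`` holds
exactly; validation is strict about the module name and the seed type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["RunConfig", "KNOWN_MODULES"]

KNOWN_MODULES = (
    "wlc",
    "squeelix",
    "arcarc",
    "adsorb",
    "bistab",
    "mt",
    "presets",
)


@dataclass
class RunConfig:
    module: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    out: str | None = None

    def __post_init__(self) -> None:
        if self.module not in KNOWN_MODULES:
            raise ValueError(
                f"unknown module {self.module!r}; expected one of {KNOWN_MODULES}"
            )
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ValueError("seed must be an integer")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not isinstance(self.params, dict):
            raise ValueError("params must be a mapping")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config must be a YAML mapping")
        unknown = set(data) - {"module", "params", "seed", "out"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
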