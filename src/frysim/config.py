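"""One-file YAML configuration for a frying run.

A config file holds up to six blocks — ``properties``, ``conditions``,
``boiling``, ``vsn``, ``enthalpy``, ``synthetic`` — each mapping onto the
corresponding dataclass with exactly its field names. Missing blocks and
missing keys fall back to the defaults; unknown keys are rejected so typos
cannot silently change a run. The effective (fully resolved) configuration
is echoed into every output for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .enthalpy import EnthalpyConfig
from .properties import BoilingModel, FryingConditions, PropertySet
from .traces import SyntheticTraceSpec
from .vsn import VSNConfig

__all__ = ["RunConfig", "load_config"]

_BLOCKS = {
    "properties": PropertySet,
    "conditions": FryingConditions,
    "boiling": BoilingModel,
    "vsn": VSNConfig,
    "enthalpy": EnthalpyConfig,
    "synthetic": SyntheticTraceSpec,
}


@dataclass
class RunConfig:
    properties: PropertySet = field(default_factory=PropertySet)
    conditions: FryingConditions = field(default_factory=FryingConditions)
    boiling: BoilingModel = field(default_factory=BoilingModel)
    vsn: VSNConfig = field(default_factory=VSNConfig)
    enthalpy: EnthalpyConfig = field(default_factory=EnthalpyConfig)
    synthetic: SyntheticTraceSpec = field(default_factory=SyntheticTraceSpec)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(_BLOCKS)
        if unknown:
            raise ValueError(f"unknown config blocks {sorted(unknown)}")
        kwargs = {}
        for name, typ in _BLOCKS.items():
            block = d.get(name, {})
            if not isinstance(block, dict):
                raise ValueError(f"config block {name!r} must be a mapping")
            kwargs[name] = typ.from_dict(block)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {name: getattr(self, name).to_dict() for name in _BLOCKS}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; absent file sections use defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
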