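"""Flat key–value configuration round-tripping (YAML / JSON / TOML).

A run configuration is a plain mapping with three groups of keys:

* ``params.*`` — every :class:`~ecovir.model.EcoParams` rate constant
  (all rates per unit time, ``q`` and ``r12``/``r21`` per unit density);
* ``specs`` — a list of ``{case, strength, preferred_host}`` mappings;
* run plumbing — ``sweep_mode``, ``seed``, ``outdir``.

YAML and JSON round-trip losslessly through :func:`save_config` /
:func:`load_config`; TOML is read-only (stdlib ``tomllib``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Union

import yaml

from .model import EcoParams, PreferredHost, SpecialismCase, SpecialismSpec

__all__ = [
    "RunConfig",
    "params_to_dict",
    "params_from_dict",
    "spec_to_dict",
    "spec_from_dict",
    "load_config",
    "save_config",
]


def params_to_dict(params: EcoParams) -> Dict[str, float]:
    return dataclasses.asdict(params)


def params_from_dict(d: Dict[str, Any]) -> EcoParams:
    return EcoParams(**{k: float(v) for k, v in d.items()})


def spec_to_dict(spec: SpecialismSpec) -> Dict[str, Any]:
    return {
        "case": spec.case_id.value,
        "strength": spec.strength,
        "preferred_host": spec.preferred_host.value,
    }


def spec_from_dict(d: Dict[str, Any]) -> SpecialismSpec:
    return SpecialismSpec(
        case_id=SpecialismCase(d.get("case", "generalist")),
        strength=float(d.get("strength", 0.0)),
        preferred_host=PreferredHost(int(d.get("preferred_host", 1))),
    )


@dataclasses.dataclass
class RunConfig:
    """Validated bundle of everything one CLI run needs."""

    params: EcoParams = dataclasses.field(default_factory=EcoParams)
    specs: List[SpecialismSpec] = dataclasses.field(
        default_factory=lambda: [SpecialismSpec()]
    )
    sweep_mode: str = "reciprocal_equal"
    seed: Optional[int] = None
    outdir: str = "ecovir-out"

    def to_dict(self) -> Dict[str, Any]:
        return {
            "params": params_to_dict(self.params),
            "specs": [spec_to_dict(s) for s in self.specs],
            "sweep_mode": self.sweep_mode,
            "seed": self.seed,
            "outdir": self.outdir,
        }

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "RunConfig":
        return cls(
            params=params_from_dict(d.get("params", {})),
            specs=[spec_from_dict(s) for s in d.get("specs", [{}])],
            sweep_mode=str(d.get("sweep_mode", "reciprocal_equal")),
            seed=d.get("seed"),
            outdir=str(d.get("outdir", "ecovir-out")),
        )


def load_config(path: Union[str, Path]) -> RunConfig:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
    elif suffix == ".json":
        data = json.loads(path.read_text())
    elif suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        raise ValueError(f"unsupported config format: {path.suffix!r}")
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    elif path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        raise ValueError(f"can only write YAML or JSON configs, not {path.suffix!r}")
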