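"""YAML preset loading for simulation parameters."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .simulate import CovariateParams, EffectParams, SimParams

__all__ = ["load_preset", "available_presets"]


def available_presets() -> list[str]:
    pkg = resources.files("ipvconsist") / "presets"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_preset(name_or_path: str | Path, **overrides) -> SimParams:
    """Load a :class:`SimParams` from a named preset or a YAML file path.

    Named presets ship with the package (``paper_like``, ``null_model``).
    Keyword overrides (e.g. ``n=20000, seed=1``) are applied on top.
    """
    path = Path(name_or_path)
    if path.suffix == ".yaml" and path.exists():
        text = path.read_text()
    else:
        res = resources.files("ipvconsist") / "presets" / f"{name_or_path}.yaml"
        if not res.is_file():
            raise FileNotFoundError(
                f"unknown preset {name_or_path!r}; available: {available_presets()}"
            )
        text = res.read_text()
    raw = yaml.safe_load(text) or {}
    cov = CovariateParams(**{k: _tup(v) for k, v in raw.pop("covariates", {}).items()})
    eff = EffectParams(**raw.pop("effects", {}))
    raw = {k: _tup(v) for k, v in raw.items()}
    params = SimParams(covariates=cov, effects=eff, **raw).replace(**overrides)
    params.validate()
    return params


def _tup(v):
    return tuple(v) if isinstance(v, list) else v
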