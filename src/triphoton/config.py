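"""Strict YAML configuration for the pipeline.

Unknown keys are rejected with an explicit error rather than ignored, so a
typo in a config file cannot silently fall back to a default.  Seeds are
mandatory for stochastic stages (scene simulation, network training).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .blindspot import N2VTrainConfig, UNet3DConfig
from .synthetic import NoiseParams, SceneParams


def _build(cls, mapping: dict, where: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ValueError(f"section {where!r} must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in section {where!r}; "
            f"known keys: {sorted(known)}")
    kw = dict(mapping)
    for f in dataclasses.fields(cls):
        if f.name in kw and isinstance(kw[f.name], list):
            kw[f.name] = tuple(kw[f.name])
    return cls(**kw)


@dataclass
class PipelineConfig:
    """All per-stage configurations plus global settings."""

    scene: SceneParams = field(default_factory=SceneParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    n2v_net: UNet3DConfig = field(default_factory=UNet3DConfig)
    n2v_train: N2VTrainConfig = field(default_factory=N2VTrainConfig)
    perstruc: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    quantify: dict = field(default_factory=dict)
    seed: int | None = None
    out_dir: str = "."
    verbosity: int = 1

    _SECTIONS = {"scene": SceneParams, "noise": NoiseParams,
                 "n2v_net": UNet3DConfig, "n2v_train": N2VTrainConfig}

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        mapping = dict(mapping or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(
                f"unknown top-level key(s) {sorted(unknown)}; "
                f"known keys: {sorted(known)}")
        kw = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in mapping:
                kw[name] = _build(section_cls, mapping.pop(name), name)
        kw.update(mapping)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        return cls.from_mapping(yaml.safe_load(text))

    def to_mapping(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                d = dataclasses.asdict(v)
                out[f.name] = {k: (list(x) if isinstance(x, tuple) else x)
                               for k, x in d.items()}
            else:
                out[f.name] = v
        return out

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_mapping(),
                                             sort_keys=False))
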