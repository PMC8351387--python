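"""Configuration loading, run manifests, and the shared CSV dialects.

One CSV dialect everywhere: comma-separated, UTF-8, '.' decimal, header
row mandatory. Config files are YAML (JSON is a YAML subset) mirroring
SimConfig field names exactly; unknown keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .abm import ConfigError, SimConfig, SpeciesParams

__all__ = ["load_config", "dump_config", "config_to_dict", "RunManifest"]

_SPECIES_FIELDS = {f.name for f in dataclasses.fields(SpeciesParams)}
_TOP_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def load_config(path) -> SimConfig:
    """Read and validate a simulation config; defaults fill absent keys.

    An empty file yields the full default configuration. Unknown keys at
    either level raise :class:`~crossfeed.abm.ConfigError` naming the key.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> SimConfig:
    unknown = set(raw) - _TOP_FIELDS
    if unknown:
        raise ConfigError(f"unknown config key {sorted(unknown)[0]!r}")
    kwargs = dict(raw)
    for sp in ("yeast", "bacteria"):
        if sp in kwargs:
            spraw = kwargs[sp]
            if not isinstance(spraw, dict):
                raise ConfigError(f"{sp} must be a mapping of species parameters")
            bad = set(spraw) - _SPECIES_FIELDS
            if bad:
                raise ConfigError(f"unknown config key {sp}.{sorted(bad)[0]}")
            defaults = dataclasses.asdict(getattr(SimConfig(), sp))
            defaults.update(spraw)
            kwargs[sp] = SpeciesParams(**defaults)
    try:
        return SimConfig(**kwargs)
    except TypeError as e:  # wrong value type
        raise ConfigError(str(e)) from e


def dump_config(config: SimConfig, path=None) -> str:
    """Canonical YAML form; ``load(dump(c))`` reproduces ``c`` exactly."""
    text = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written beside every CLI run's outputs.

    Captures the resolved configuration, all seeds, input digests and the
    produced files — enough to re-execute a deterministic stage
    bit-identically.
    """

    command: str
    config: dict
    seeds: dict
    inputs: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    tool_version: str = ""
    started: str = ""
    finished: str = ""

    def __post_init__(self):
        if not self.tool_version:
            from . import __version__

            self.tool_version = __version__
        if not self.started:
            self.started = time.strftime("%Y-%m-%dT%H:%M:%S%z")

    def add_input(self, path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _sha256(p)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, directory) -> Path:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S%z")
        out = Path(directory) / "manifest.json"
        out.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return out
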