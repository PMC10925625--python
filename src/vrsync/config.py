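"""Run configuration: one YAML/JSON file covering the whole pipeline."""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .blink_sync import BlinkSyncConfig
from .ssvep import SsvepConfig, StimulusSet


@dataclass
class RunConfig:
    """Merged configuration for offset estimation, classification and I/O.

    Sections map to the component configs; ``streams`` renames the
    expected stream labels, ``seed`` controls any simulation involved.
    Unknown keys are rejected with a warning naming them, so typos in a
    config file do not silently fall back to defaults.
    """

    blink_sync: BlinkSyncConfig = field(default_factory=BlinkSyncConfig)
    ssvep: SsvepConfig = field(default_factory=SsvepConfig)
    stimulus: StimulusSet = field(default_factory=StimulusSet)
    streams: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)
    seed: int = 0

    def resolved(self) -> dict:
        """Plain-dict view for embedding in JSON reports."""
        return {
            "blink_sync": dataclasses.asdict(self.blink_sync),
            "ssvep": dataclasses.asdict(self.ssvep),
            "stimulus": dataclasses.asdict(self.stimulus),
            "streams": dict(self.streams),
            "seed": self.seed,
        }


def _build_section(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        warnings.warn(
            f"config section {section!r}: unknown keys ignored: {unknown}",
            stacklevel=3,
        )
    kwargs = {k: v for k, v in data.items() if k in names}
    # YAML lists for tuple-typed fields
    for k, v in kwargs.items():
        if isinstance(v, list):
            kwargs[k] = tuple(v)
    return cls(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from YAML or JSON; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    data = data or {}
    known = {"blink_sync", "ssvep", "stimulus", "streams", "output", "seed"}
    unknown = sorted(set(data) - known)
    if unknown:
        warnings.warn(f"config file {path}: unknown sections ignored: {unknown}")
    return RunConfig(
        blink_sync=_build_section(BlinkSyncConfig, data.get("blink_sync", {}), "blink_sync"),
        ssvep=_build_section(SsvepConfig, data.get("ssvep", {}), "ssvep"),
        stimulus=_build_section(StimulusSet, data.get("stimulus", {}), "stimulus"),
        streams=dict(data.get("streams", {})),
        output=dict(data.get("output", {})),
        seed=int(data.get("seed", 0)),
    )
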