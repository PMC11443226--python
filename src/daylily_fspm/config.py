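"""YAML/JSON configuration files.

Two file kinds: a site/weather config (latitude, longitude, synthetic
season statistics, seed) and a leaf gas-exchange parameter file mirroring
:class:`~daylily_fspm.leaf_physiology.PhotosynthesisParams`.  Unknown keys
are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .leaf_physiology import PhotosynthesisParams
from .weather_sky import SyntheticWeatherConfig

__all__ = [
    "load_photosynthesis_params",
    "save_photosynthesis_params",
    "load_site_config",
    "save_site_config",
]


def _read(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def _write(path, payload: dict) -> None:
    path = Path(path)
    if str(path).endswith(".json"):
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def _from_mapping(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_photosynthesis_params(path) -> PhotosynthesisParams:
    return _from_mapping(PhotosynthesisParams, _read(path))


def save_photosynthesis_params(p: PhotosynthesisParams, path) -> None:
    _write(path, dataclasses.asdict(p))


def load_site_config(path) -> SyntheticWeatherConfig:
    return _from_mapping(SyntheticWeatherConfig, _read(path))


def save_site_config(cfg: SyntheticWeatherConfig, path) -> None:
    _write(path, dataclasses.asdict(cfg))
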