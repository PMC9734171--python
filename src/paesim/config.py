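"""YAML configuration: serialize and load the simulation dataclasses.

A config file is a mapping of section name to field overrides, e.g.::

    sensor:
      Sm_base: 2.0e-12
      Q_res: 8
    demod:
      f_if: 50.0e+6
    optical:
      beam_waist_fwhm: 7.4e-6
    geometry:
      mode: raster
      raster_range: [0.8e-3, 0.8e-3]
      raster_pixels: [80, 80]
    hydrophone: {}

Unknown sections or fields raise, so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields, is_dataclass
from pathlib import Path

import yaml

from .calibration import HydrophoneSpec
from .demod import DemodConfig
from .imaging import ScanGeometry
from .phantom import OpticalModel
from .sensor import SensorSpec

__all__ = ["SECTION_TYPES", "load_config", "dump_config"]

SECTION_TYPES = {
    "sensor": SensorSpec,
    "demod": DemodConfig,
    "optical": OpticalModel,
    "geometry": ScanGeometry,
    "hydrophone": HydrophoneSpec,
}


def _build(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    coerced = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path) -> dict:
    """Read a YAML config file into a dict of dataclass instances.

    Sections absent from the file are instantiated with defaults only when
    listed under an ``include`` key; otherwise only present sections are
    returned.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    include = raw.pop("include", [])
    unknown = set(raw) - set(SECTION_TYPES)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    out = {}
    for name, cls in SECTION_TYPES.items():
        if name in raw:
            out[name] = _build(cls, raw[name] or {})
        elif name in include:
            out[name] = cls()
    return out


def dump_config(path, **sections) -> None:
    """Write dataclass instances back to a YAML config file."""
    doc = {}
    for name, obj in sections.items():
        if name not in SECTION_TYPES:
            raise ValueError(f"unknown config section {name!r}")
        if not is_dataclass(obj):
            raise TypeError(f"section {name!r} is not a dataclass instance")
        doc[name] = {
            f.name: (list(v) if isinstance(v, tuple) else v)
            for f in fields(obj)
            for v in [getattr(obj, f.name)]
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
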