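"""YAML configuration loading.

A config file may contain any of the top-level sections ``material``,
``frame``, ``trend`` and ``pipeline``; unknown keys raise immediately so
typos do not silently fall back to defaults.  Example::

    material:
      D: 1.0e-5
      C10: 0.03
      mu1: 0.02
      gamma1: 40.0
      mu2: 0.008
      gamma2: 30.0
      out_of_plane_angle_deg: 15.0
    trend:
      eps_threshold: 0.01
      eps_mid: 0.05
      eps_max: 0.08
    pipeline:
      normalization_mode: total_one
      asymmetry_tol: 0.25
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .constitutive import FibrilFrame, MaterialParams


@dataclass(frozen=True)
class PipelineConfig:
    normalization_mode: str = "total_one"
    asymmetry_tol: float = 0.25


@dataclass(frozen=True)
class TrendConfig:
    eps_threshold: float = 0.01
    eps_mid: float = 0.05
    eps_max: float = 0.08


def _build(cls, section: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
    return cls(**section)


def load_config(path: str | Path) -> dict:
    """Parse a YAML config into typed sections.

    Returns a dict with keys ``material`` (:class:`MaterialParams`),
    ``frame`` (:class:`FibrilFrame`), ``trend`` (:class:`TrendConfig`)
    and ``pipeline`` (:class:`PipelineConfig`); absent sections get
    defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known_sections = {"material", "frame", "trend", "pipeline"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    material = _build(MaterialParams, raw.get("material", {}), "material")
    frame_section = raw.get("frame", {})
    angle = frame_section.get("out_of_plane_angle_deg", material.out_of_plane_angle_deg)
    extra = set(frame_section) - {"out_of_plane_angle_deg"}
    if extra:
        raise ValueError(f"unknown keys in config section 'frame': {sorted(extra)}")
    return {
        "material": material,
        "frame": FibrilFrame.standard(angle),
        "trend": _build(TrendConfig, raw.get("trend", {}), "trend"),
        "pipeline": _build(PipelineConfig, raw.get("pipeline", {}), "pipeline"),
    }
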