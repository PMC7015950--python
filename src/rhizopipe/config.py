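"""YAML configuration loading for the command-line interface.

A single config file with one section per pipeline stage; every value
is optional and falls back to the dataclass defaults.  Example::

    simulate:
      seed: 7
      reps_per_line: 8
      fractions: [rhizosphere, root]
    preprocess:
      thresholds: {prokaryote16S: 10000, eukaryote18S: 5000}
    permanova:
      formula: fraction + ploidy + ancestry + species(ancestry)
      n_perm: 9999
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import yaml

from .data_model import ValidationError
from .pipeline import PipelineConfig
from .synthetic import SimConfig

log = logging.getLogger("rhizopipe")


def load_config(path) -> dict:
    """Load the raw YAML config (empty dict when path is None)."""
    if path is None:
        return {}
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return data


def _filter_fields(cls, mapping: dict) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(mapping) - names)
    if unknown:
        raise ValidationError(
            f"unknown option(s) for {cls.__name__}: {unknown}")
    return dict(mapping)


def sim_config_from(mapping: dict, seed: int | None = None) -> SimConfig:
    opts = _filter_fields(SimConfig, mapping.get("simulate", {}))
    if seed is not None:
        opts["seed"] = seed
    if "fractions" in opts:
        opts["fractions"] = tuple(opts["fractions"])
    if "lines" in opts:
        opts["lines"] = tuple(opts["lines"])
    return SimConfig(**opts)


def pipeline_config_from(mapping: dict, out_dir, seed: int | None = None,
                         ) -> PipelineConfig:
    opts = _filter_fields(
        PipelineConfig,
        {k: v for k, v in mapping.get("pipeline", {}).items()})
    if "libraries" in opts:
        opts["libraries"] = tuple(opts["libraries"])
    if seed is not None:
        opts["seed"] = seed
    cfg = PipelineConfig(out_dir=out_dir,
                         sim=sim_config_from(mapping, seed=seed), **opts)
    for section in ("preprocess",):
        thr = mapping.get(section, {}).get("thresholds")
        if thr:
            cfg.thresholds.update(thr)
    perm = mapping.get("permanova", {})
    if "formula" in perm:
        cfg.formula = perm["formula"]
    if "n_perm" in perm:
        cfg.n_perm = int(perm["n_perm"])
    return cfg
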