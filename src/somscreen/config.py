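"""YAML configuration loading for the command-line interface.

A config file is a single declarative document, e.g.::

    input:
      path: data/cortex_nuclear.csv
      dialect: csv
    preprocess:
      outlier_threshold: 0.5
      drop_mice: []
      drop_flagged: false
    som:
      side: auto
      runs: 10
      epochs: 200
      scheme: batch
      neighborhood: gaussian
      base_seed: 1
    experiment:
      classes: [c-CS-s, c-CS-m, c-SC-s, c-SC-m]
      proteins: null
      comparisons: [NL, NLm]
    synthetic:
      n_proteins: 77
      mice_per_class: 8
      seed: 0
"""
from __future__ import annotations

from pathlib import Path

import yaml

from .pipeline import ExperimentConfig
from .som import TrainingParams
from .synthetic import SyntheticConfig


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")
    return doc


def synthetic_config(doc: dict, seed: int | None = None) -> SyntheticConfig:
    block = dict(doc.get("synthetic") or {})
    if "effect_delta" in block:  # convenience: uniform-delta default map
        from .synthetic import default_effect_map
        block["effect_map"] = default_effect_map(float(block.pop("effect_delta")))
    if seed is not None:
        block["seed"] = seed
    if "protein_scale_range" in block:
        block["protein_scale_range"] = tuple(block["protein_scale_range"])
    return SyntheticConfig(**block)


def experiment_config(doc: dict, name: str = "experiment",
                      seed: int | None = None) -> ExperimentConfig:
    inp = doc.get("input") or {}
    pre = doc.get("preprocess") or {}
    som = doc.get("som") or {}
    exp = doc.get("experiment") or {}
    params = TrainingParams(
        epochs=int(som.get("epochs", 200)),
        scheme=som.get("scheme", "batch"),
        neighborhood=som.get("neighborhood", "gaussian"),
    )
    synth = None
    if "synthetic" in doc and not inp.get("path"):
        synth = synthetic_config(doc)
    return ExperimentConfig(
        name=name,
        input_path=inp.get("path"),
        dialect=inp.get("dialect", "csv"),
        synthetic=synth,
        classes=exp.get("classes"),
        proteins=exp.get("proteins"),
        outlier_threshold=float(pre.get("outlier_threshold", 0.5)),
        drop_flagged_mice=bool(pre.get("drop_flagged", False)),
        drop_mice=tuple(pre.get("drop_mice") or ()),
        side=som.get("side", "auto"),
        n_runs=int(som.get("runs", 10)),
        params=params,
        base_seed=int(seed if seed is not None else som.get("base_seed", 1)),
        comparisons=tuple(exp.get("comparisons") or ()),
        allow_missing_comparisons=bool(exp.get("allow_missing_comparisons", False)),
        render=bool(exp.get("render", False)),
    )
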