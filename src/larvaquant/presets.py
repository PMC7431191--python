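"""Packaged per-genotype generator presets.

The YAML files under ``larvaquant/configs`` transcribe the published group
conditions: crawling parameters per genotype (kin_*), nascent-transcript
ratio conditions per genotype and lineage stage (fish_*), and phenotype
category proportions per genotype (pheno_*).  SDs are reconstructed from
printed SEMs as sem * sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import load_packaged_config, packaged_config_names
from .synthetic import FishGenParams, KinematicParams, PhenotypeProportions


@dataclass
class KinematicPreset:
    genotype: str
    n_larvae: int
    params: KinematicParams


@dataclass
class FishPreset:
    genotype: str
    stage: str
    params: FishGenParams


@dataclass
class PhenotypePreset:
    genotype: str
    n_segments: int
    proportions: PhenotypeProportions


def kinematic_preset(name: str) -> KinematicPreset:
    """Load a kin_* preset by stem name (e.g. ``'kin_control'``)."""
    cfg = _load(name, "kinematics")
    params = KinematicParams(**cfg["params"])
    params.validate()
    return KinematicPreset(genotype=cfg["genotype"],
                           n_larvae=int(cfg["n_larvae"]), params=params)


def fish_preset(name: str) -> FishPreset:
    """Load a fish_* preset by stem name (e.g. ``'fish_wt_fc'``)."""
    cfg = _load(name, "fish")
    p = dict(cfg["params"])
    if "stack_shape" in p:
        p["stack_shape"] = tuple(p["stack_shape"])
    params = FishGenParams(**p)
    params.validate()
    return FishPreset(genotype=cfg["genotype"], stage=cfg["stage"],
                      params=params)


def phenotype_preset(name: str) -> PhenotypePreset:
    """Load a pheno_* preset by stem name (e.g. ``'pheno_col_dL13'``)."""
    cfg = _load(name, "phenotype")
    props = PhenotypeProportions(**cfg["proportions"])
    props.validate()
    return PhenotypePreset(genotype=cfg["genotype"],
                           n_segments=int(cfg["n_segments"]),
                           proportions=props)


def available_presets():
    return packaged_config_names()


def _load(name: str, kind: str) -> dict:
    cfg = load_packaged_config(name)
    if cfg.get("kind") != kind:
        raise ValueError(f"preset {name!r} has kind {cfg.get('kind')!r}, "
                         f"expected {kind!r}")
    return cfg
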