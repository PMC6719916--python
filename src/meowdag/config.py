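"""YAML configuration: one file with a section per pipeline stage.

Sections mirror the corresponding dataclasses field-for-field::

    synthetic:          # CorpusSpec scalars + per-class profile overrides
      seed: 0
      pad_silence: 0.5
      alaw: true
      duration_spread_is_variance: true
      profiles:
        food: {f0_base: 600.0, am_rate: 8.5}
    vad:                # VadParams
      threshold: 1.0
      hangover: 3
      trim_mode: all
    features:
      frame_s: 0.030
      shift_s: 0.010
      literal_overlap: false        # 20 ms shift reading of "10 ms overlap"
      stream: mfcc                  # mfcc | tm | fused
      mfcc: {n_mel_filters: 23, n_kept_coeffs: 12}
      modulation: {n_subbands: 8, n_mod_bands: 6}
    hmm:                # TrainSpec + the search grids
      states_grid: [3, 4]
      gauss_grid: [2, 4, 8]
      em_max_iter: 25
      em_threshold: 0.001
    dag:
      val_fraction: 0.2
      refit: true
    esn:                # EsnConfig
      sr_grid: [0.9, 0.99]
    evaluation:
      k: 10
      stratified: true
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any

import yaml

from .audio import VadParams
from .baselines import EsnConfig
from .features import FrameGrid, MfccConfig, ModulationConfig
from .hmm import DEFAULT_GAUSS_GRID, DEFAULT_STATES_GRID, TrainSpec
from .synthetic import CorpusSpec


def _apply(obj, overrides: dict[str, Any]):
    names = {f.name for f in fields(obj)}
    unknown = set(overrides) - names
    if unknown:
        raise KeyError(f"unknown {type(obj).__name__} fields: "
                       f"{sorted(unknown)}")
    return replace(obj, **overrides)


@dataclass
class Config:
    synthetic: CorpusSpec = field(default_factory=CorpusSpec)
    vad: VadParams = field(default_factory=VadParams)
    grid: FrameGrid = field(default_factory=FrameGrid)
    mfcc: MfccConfig = field(default_factory=MfccConfig)
    modulation: ModulationConfig = field(default_factory=ModulationConfig)
    hmm: TrainSpec = field(default_factory=TrainSpec)
    esn: EsnConfig = field(default_factory=EsnConfig)
    stream: str = "mfcc"
    states_grid: tuple = DEFAULT_STATES_GRID
    gauss_grid: tuple = DEFAULT_GAUSS_GRID
    val_fraction: float = 0.2
    refit: bool = True
    cv_k: int = 10
    stratified: bool = True


def load_config(path: str | None = None) -> Config:
    """Defaults, optionally overridden section-by-section from YAML."""
    cfg = Config()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    if "synthetic" in raw:
        s = dict(raw["synthetic"])
        profiles = s.pop("profiles", {})
        cfg.synthetic = _apply(cfg.synthetic, s)
        for name, over in profiles.items():
            cfg.synthetic.profiles[name] = _apply(
                cfg.synthetic.profiles[name], over)
    if "vad" in raw:
        cfg.vad = _apply(cfg.vad, raw["vad"])
    if "features" in raw:
        f = dict(raw["features"])
        cfg.stream = f.pop("stream", cfg.stream)
        if f.pop("literal_overlap", False):
            cfg.grid = FrameGrid.literal_overlap()
        cfg.mfcc = _apply(cfg.mfcc, f.pop("mfcc", {}))
        cfg.modulation = _apply(cfg.modulation, f.pop("modulation", {}))
        cfg.grid = _apply(cfg.grid, f)
    if "hmm" in raw:
        h = dict(raw["hmm"])
        cfg.states_grid = tuple(h.pop("states_grid", cfg.states_grid))
        cfg.gauss_grid = tuple(h.pop("gauss_grid", cfg.gauss_grid))
        cfg.hmm = _apply(cfg.hmm, h)
    if "dag" in raw:
        d = raw["dag"]
        cfg.val_fraction = d.get("val_fraction", cfg.val_fraction)
        cfg.refit = d.get("refit", cfg.refit)
    if "esn" in raw:
        e = {k: tuple(v) if isinstance(v, list) else v
             for k, v in raw["esn"].items()}
        cfg.esn = _apply(cfg.esn, e)
    if "evaluation" in raw:
        cfg.cv_k = raw["evaluation"].get("k", cfg.cv_k)
        cfg.stratified = raw["evaluation"].get("stratified", cfg.stratified)
    return cfg
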