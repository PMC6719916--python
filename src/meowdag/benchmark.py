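"""End-to-end synthetic benchmark: corpus generation, silence removal,
feature extraction and ten-fold cross-validation of all five systems
(DAG-HMM, class-specific HMMs, universal HMM, SVM, ESN) on one fold plan.

Desk-scale defaults keep a full five-system run on one CPU tractable: HMM
grid S in {3,4} x g in {2,4,8}, the MFCC(52) stream, ESN reservoirs up to
500 units.  The full grids and the fused MFCC+TM stream are plain options.
"""

from __future__ import annotations

import logging

import numpy as np

from .audio import NoEventError, VadParams, trim_clip
from .baselines import (ClassHmmClassifier, EsnClassifier, EsnConfig,
                        SvmClassifier, UniversalHmmClassifier)
from .dag import DagHmmClassifier
from .evaluation import EvalReport, FoldPlan, make_folds, run_cv
from .features import (FrameGrid, MfccConfig, ModulationConfig, extract_mfcc,
                       extract_modulation, fuse_streams)
from .hmm import TrainSpec
from .synthetic import CorpusSpec, generate_corpus

logger = logging.getLogger("meowdag")

DESK_STATES_GRID = (3, 4)
DESK_GAUSS_GRID = (2, 4, 8)


def corpus_features(seed: int = 0, spec: CorpusSpec | None = None,
                    stream: str = "mfcc", vad: VadParams | None = None,
                    grid: FrameGrid | None = None,
                    mfcc_cfg: MfccConfig | None = None,
                    tm_cfg: ModulationConfig | None = None
                    ) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Generate the corpus at ``seed``, trim silence, extract one stream.

    Returns (sequences, labels) keyed by clip id.  Clips whose activity
    mask comes back empty are excluded with a log record rather than
    failing the run.
    """
    spec = spec or CorpusSpec(seed=seed)
    if spec.seed != seed:
        spec = CorpusSpec(**{**spec.__dict__, "seed": seed})
    clips, _ = generate_corpus(spec)
    grid = grid or FrameGrid()
    sequences: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for clip in clips:
        try:
            trimmed = trim_clip(clip, vad)
        except NoEventError:
            logger.warning("excluding clip %s: no event", clip.clip_id)
            continue
        if stream == "mfcc":
            feats = extract_mfcc(trimmed, grid, mfcc_cfg).data
        elif stream == "tm":
            feats = extract_modulation(trimmed, tm_cfg, grid).data
        elif stream == "fused":
            feats = fuse_streams(extract_mfcc(trimmed, grid, mfcc_cfg),
                                 extract_modulation(trimmed, tm_cfg,
                                                    grid)).data
        else:
            raise ValueError(f"unknown stream {stream!r}")
        sequences[clip.clip_id] = feats
        labels[clip.clip_id] = clip.label
    return sequences, labels


def make_classifier_factory(name: str, seed: int,
                            states_grid=DESK_STATES_GRID,
                            gauss_grid=DESK_GAUSS_GRID,
                            esn_cfg: EsnConfig | None = None,
                            spec: TrainSpec | None = None,
                            cache: dict | None = None):
    """Factory of factories: per-fold constructor for one system.

    ``cache`` memoizes HMM trainings; shared across systems it lets e.g.
    the class-specific baseline reuse models the DAG search already fit on
    identical data (training is deterministic, so results are unchanged).
    """
    spec = spec or TrainSpec(seed=seed)

    def factory(fold: int):
        fold_seed = seed * 1000 + fold
        fold_spec = TrainSpec(**{**spec.__dict__, "seed": fold_seed})
        if name == "dag":
            return DagHmmClassifier(states_grid, gauss_grid, fold_spec,
                                    seed=fold_seed, cache=cache)
        if name == "chmm":
            return ClassHmmClassifier(states_grid, gauss_grid, fold_spec,
                                      seed=fold_seed, cache=cache)
        if name == "uhmm":
            return UniversalHmmClassifier(states_grid, gauss_grid, fold_spec,
                                          seed=fold_seed, cache=cache)
        if name == "svm":
            return SvmClassifier(seed=fold_seed)
        if name == "esn":
            cfg = esn_cfg or EsnConfig()
            return EsnClassifier(EsnConfig(**{**cfg.__dict__,
                                              "seed": fold_seed}))
        raise ValueError(f"unknown classifier {name!r}")

    return factory


def run_benchmark(seed: int = 0,
                  classifiers: tuple[str, ...] = ("dag", "chmm", "uhmm",
                                                  "svm", "esn"),
                  stream: str = "mfcc", k: int = 10,
                  states_grid=DESK_STATES_GRID, gauss_grid=DESK_GAUSS_GRID,
                  corpus_spec: CorpusSpec | None = None,
                  esn_cfg: EsnConfig | None = None,
                  plan: FoldPlan | None = None,
                  sequences: dict[str, np.ndarray] | None = None,
                  labels: dict[str, str] | None = None
                  ) -> dict[str, EvalReport]:
    """Cross-validate the requested systems on one shared fold plan."""
    if sequences is None or labels is None:
        sequences, labels = corpus_features(seed, corpus_spec, stream)
    plan = plan or make_folds(sorted(sequences), labels, k=k, seed=seed)
    reports: dict[str, EvalReport] = {}
    cache: dict = {}
    for name in classifiers:
        factory = make_classifier_factory(name, seed, states_grid,
                                          gauss_grid, esn_cfg, cache=cache)
        reports[name] = run_cv(factory, sequences, labels, plan,
                               classifier_id=name, seed=seed)
        logger.info("%s: %.2f%%", name, reports[name].recognition_rate)
    return reports
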