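"""Comparison systems: class-specific HMMs, universal HMM (background model
with mean-adapted class models), RBF-SVM on pooled clip vectors, and an
echo state network with a ridge readout.

All four consume exactly the same per-fold feature sets as the DAG-HMM so
comparisons are fair.  Variable-length clips reach the SVM as fixed-length
mean++sd pooled vectors; the ESN time-averages its post-washout reservoir
states.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import random as sparse_random
from scipy.sparse.linalg import eigs
from sklearn.linear_model import Ridge
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .hmm import (DEFAULT_GAUSS_GRID, DEFAULT_STATES_GRID, HmmModel,
                  TrainSpec, _batch, _estep, cached_train,
                  viterbi_loglik, viterbi_loglik_batch)

logger = logging.getLogger("meowdag")


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _split_train_val(ids: list[str], labels: dict[str, str],
                     val_fraction: float, seed: int
                     ) -> tuple[list[str], list[str]]:
    # same label-equivariant split as the DAG's TS/VS split, so trainings
    # on identical data hit the shared model cache
    ts, vs = [], []
    by_class: dict[str, list[str]] = {}
    for cid in ids:
        by_class.setdefault(labels[cid], []).append(cid)
    for lab in sorted(by_class):
        members = sorted(by_class[lab])
        rng = np.random.default_rng(
            [seed, zlib.crc32("|".join(members).encode())])
        rng.shuffle(members)
        n_val = max(1, int(round(val_fraction * len(members))))
        vs.extend(members[:n_val])
        ts.extend(members[n_val:])
    return ts, vs


def _grid_configs(states_grid: Sequence[int], gauss_grid: Sequence[int],
                  min_frames: int, frames_min_class: int
                  ) -> list[tuple[int, int]]:
    configs = sorted((g, s) for s in states_grid for g in gauss_grid)
    ok = [(s, g) for g, s in configs if frames_min_class >= min_frames * s * g]
    return ok or [(configs[0][1], configs[0][0])]


# ---------------------------------------------------------------------------
# class-specific HMMs
# ---------------------------------------------------------------------------

def classify_class_hmm(models: dict[str, HmmModel],
                       features: np.ndarray) -> str:
    """Argmax of Viterbi log-likelihood over the per-class models."""
    if not models:
        raise ValueError("no class models provided")
    labels = sorted(models)
    scores = [viterbi_loglik(models[lab], features) for lab in labels]
    return labels[int(np.argmax(scores))]


def _argmax_predict(models: dict[str, HmmModel],
                    sequences: dict[str, np.ndarray]) -> dict[str, str]:
    """Batched argmax-Viterbi decision for a set of clips."""
    ids = sorted(sequences)
    labs = sorted(models)
    seqs = [sequences[c] for c in ids]
    scores = np.stack([viterbi_loglik_batch(models[lab], seqs)
                       for lab in labs])
    return {cid: labs[k] for cid, k in zip(ids, scores.argmax(axis=0))}


class ClassHmmClassifier:
    """One grid-searched GMM-HMM per class; argmax Viterbi decision.

    A single (S, g) architecture shared by all class models — the usual
    convention for class-specific model banks — is selected by multiclass
    recognition rate on a held-out validation part of the training data
    (ties toward the smaller architecture, the stock convention), then the
    models are refit on the full fold.  One shared architecture must
    compromise across classes of different acoustic complexity; the DAG
    relieves exactly this by optimizing each binary task separately.
    """

    def __init__(self, states_grid: Sequence[int] = DEFAULT_STATES_GRID,
                 gauss_grid: Sequence[int] = DEFAULT_GAUSS_GRID,
                 spec: TrainSpec | None = None, val_fraction: float = 0.2,
                 seed: int = 0, cache: dict | None = None):
        self.states_grid, self.gauss_grid = states_grid, gauss_grid
        self.spec = spec or TrainSpec(seed=seed)
        self.val_fraction, self.seed = val_fraction, seed
        self.cache = cache
        self.models_: dict[str, HmmModel] = {}
        self.config_: tuple[int, int] | None = None

    def fit(self, sequences: dict[str, np.ndarray],
            labels: dict[str, str]) -> "ClassHmmClassifier":
        ids = sorted(sequences)
        ts, vs = _split_train_val(ids, labels, self.val_fraction, self.seed)
        classes = sorted({labels[c] for c in ids})
        ids_of = lambda pool, lab: tuple(  # noqa: E731
            c for c in pool if labels[c] == lab)
        train_one = lambda pool, lab, s, g: cached_train(  # noqa: E731
            self.cache, (lab, ids_of(pool, lab)),
            [sequences[c] for c in pool if labels[c] == lab], s, g, self.spec)
        frames_min = min(sum(len(sequences[c]) for c in ids_of(ts, lab))
                         for lab in classes)
        configs = _grid_configs(self.states_grid, self.gauss_grid,
                                self.spec.min_frames_per_component, frames_min)
        vs_seqs = [sequences[c] for c in vs]
        truth_idx = np.array([classes.index(labels[c]) for c in vs])
        best = None
        for s, g in configs:
            models = {lab: train_one(ts, lab, s, g) for lab in classes}
            scores = np.stack([viterbi_loglik_batch(models[lab], vs_seqs)
                               for lab in classes])       # (C, n_vs)
            rate = float(np.mean(scores.argmax(axis=0) == truth_idx))
            if best is None or rate > best[0]:
                best = (rate, (s, g))
        self.config_ = best[1]
        s, g = self.config_
        self.models_ = {lab: train_one(ids, lab, s, g) for lab in classes}
        return self

    def predict(self, sequences: dict[str, np.ndarray]) -> dict[str, str]:
        return _argmax_predict(self.models_, sequences)


# ---------------------------------------------------------------------------
# universal HMM (background model + mean adaptation)
# ---------------------------------------------------------------------------

def adapt_means(ubm: HmmModel, sequences: list[np.ndarray],
                relevance: float = 2.0) -> HmmModel:
    """MAP adaptation of the emission means toward class data.

    With occupancy n_sg and class data mean ybar_sg per state/component,
    the adapted mean is (n*ybar + tau*mu_ubm) / (n + tau): relevance tau ->
    infinity leaves the background model untouched, tau -> 0 approaches a
    fully class-specific re-estimate.
    """
    X, lengths, idx, valid = _batch([np.atleast_2d(x) for x in sequences])
    stats, _ = _estep(ubm, X, lengths, idx, valid)
    comp_post = stats["comp_post"]                      # (T, S, g)
    n = comp_post.sum(axis=0)                           # (S, g)
    ysum = np.tensordot(comp_post, X, axes=([0], [0]))  # (S, g, D)
    ybar = ysum / np.maximum(n, 1e-300)[:, :, None]
    w = (n / (n + relevance))[:, :, None]
    adapted = HmmModel(ubm.startprob.copy(), ubm.transmat.copy(),
                       ubm.weights.copy(),
                       w * ybar + (1.0 - w) * ubm.means,
                       ubm.variances.copy(), topology=ubm.topology,
                       var_floor=ubm.var_floor)
    return adapted


def classify_universal_hmm(adapted: dict[str, HmmModel],
                           features: np.ndarray) -> str:
    return classify_class_hmm(adapted, features)


class UniversalHmmClassifier:
    """One background HMM trained on all classes pooled, specialised per
    class by MAP mean adaptation; argmax Viterbi over the adapted models.
    The background (S, g) is selected generatively, by held-out pooled
    log-likelihood."""

    def __init__(self, states_grid: Sequence[int] = DEFAULT_STATES_GRID,
                 gauss_grid: Sequence[int] = DEFAULT_GAUSS_GRID,
                 spec: TrainSpec | None = None, relevance: float = 2.0,
                 val_fraction: float = 0.2, seed: int = 0,
                 cache: dict | None = None):
        self.states_grid, self.gauss_grid = states_grid, gauss_grid
        self.spec = spec or TrainSpec(seed=seed)
        self.relevance, self.val_fraction, self.seed = \
            relevance, val_fraction, seed
        self.cache = cache
        self.ubm_: HmmModel | None = None
        self.models_: dict[str, HmmModel] = {}
        self.config_: tuple[int, int] | None = None

    def _fit_at(self, sequences, labels, pool, s, g):
        ubm = cached_train(self.cache, ("__pooled__", tuple(pool)),
                           [sequences[c] for c in pool], s, g, self.spec)
        classes = sorted({labels[c] for c in pool})
        adapted = {lab: adapt_means(
            ubm, [sequences[c] for c in pool if labels[c] == lab],
            self.relevance) for lab in classes}
        return ubm, adapted

    def fit(self, sequences: dict[str, np.ndarray],
            labels: dict[str, str]) -> "UniversalHmmClassifier":
        ids = sorted(sequences)
        ts, vs = _split_train_val(ids, labels, self.val_fraction, self.seed)
        frames_min = min(
            sum(len(sequences[c]) for c in ts if labels[c] == lab)
            for lab in sorted({labels[c] for c in ids}))
        configs = _grid_configs(self.states_grid, self.gauss_grid,
                                self.spec.min_frames_per_component, frames_min)
        best = None
        vs_all = [sequences[c] for c in vs]
        n_frames = sum(len(x) for x in vs_all)
        for s, g in configs:
            ubm = cached_train(self.cache, ("__pooled__", tuple(ts)),
                               [sequences[c] for c in ts], s, g, self.spec)
            ll = float(viterbi_loglik_batch(ubm, vs_all).sum()) / n_frames
            if best is None or ll > best[0]:
                best = (ll, (s, g))
        self.config_ = best[1]
        self.ubm_, self.models_ = self._fit_at(sequences, labels, ids,
                                               *self.config_)
        return self

    def predict(self, sequences: dict[str, np.ndarray]) -> dict[str, str]:
        return _argmax_predict(self.models_, sequences)


# ---------------------------------------------------------------------------
# SVM on pooled clip vectors
# ---------------------------------------------------------------------------

def pooled_vector(features: np.ndarray) -> np.ndarray:
    """Fixed-length clip representation: per-dimension mean ++ sd (2D dims)."""
    X = np.atleast_2d(features)
    return np.concatenate([X.mean(axis=0), X.std(axis=0)])


DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (1e-3, 1e-2, 1e-1, 1.0)


def classify_svm(train_vectors: np.ndarray, train_labels: Sequence[str],
                 test_vector: np.ndarray,
                 c_grid: Sequence[float] = DEFAULT_C_GRID,
                 gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
                 seed: int = 0) -> str:
    """One-shot pairwise-voting RBF-SVM decision with inner-CV grid search."""
    clf = SvmClassifier(c_grid, gamma_grid, seed=seed)
    clf._fit_arrays(np.asarray(train_vectors), list(train_labels))
    return clf._predict_arrays(np.atleast_2d(test_vector))[0]


class SvmClassifier:
    """RBF-SVM with pairwise (one-vs-one) voting on z-normalized pooled
    vectors; C and gamma from a log grid by cross-validation on the
    training data only."""

    def __init__(self, c_grid: Sequence[float] = DEFAULT_C_GRID,
                 gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
                 inner_cv: int = 3, seed: int = 0):
        self.c_grid, self.gamma_grid = c_grid, gamma_grid
        self.inner_cv, self.seed = inner_cv, seed
        self.search_: GridSearchCV | None = None

    def _fit_arrays(self, V: np.ndarray, y: list[str]) -> None:
        if len(set(y)) < 2:
            raise ValueError("training set contains a single class")
        pipe = make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", decision_function_shape="ovo",
                random_state=self.seed))
        grid = {"svc__C": list(self.c_grid),
                "svc__gamma": list(self.gamma_grid)}
        n_min = min(np.bincount(np.unique(y, return_inverse=True)[1]))
        self.search_ = GridSearchCV(pipe, grid,
                                    cv=min(self.inner_cv, max(2, n_min)))
        self.search_.fit(V, y)

    def _predict_arrays(self, V: np.ndarray) -> list[str]:
        return list(self.search_.predict(V))

    def fit(self, sequences: dict[str, np.ndarray],
            labels: dict[str, str]) -> "SvmClassifier":
        ids = sorted(sequences)
        V = np.stack([pooled_vector(sequences[c]) for c in ids])
        self._fit_arrays(V, [labels[c] for c in ids])
        return self

    def predict(self, sequences: dict[str, np.ndarray]) -> dict[str, str]:
        ids = sorted(sequences)
        V = np.stack([pooled_vector(sequences[c]) for c in ids])
        return dict(zip(ids, self._predict_arrays(V)))


# ---------------------------------------------------------------------------
# echo state network
# ---------------------------------------------------------------------------

#: full-size reference grids for the ESN search
FULL_SR_GRID = (0.8, 0.9, 0.95, 0.99)
FULL_SIZE_GRID = (100, 500, 1000, 5000, 10000, 20000)
FULL_SC_GRID = (0.1, 0.5, 0.7, 0.95, 0.99)


@dataclass
class EsnConfig:
    """Echo-state-network search space and fixed hyper-parameters.

    Desk-scale default grids keep reservoir sizes <= 500; the full printed
    grids are available as ``FULL_*_GRID`` constants.  ``selection`` picks
    the search criterion: validation classification error ("error") or
    readout target-reconstruction MSE ("mse").
    """

    sr_grid: tuple = (0.9, 0.99)
    size_grid: tuple = (100, 500)
    sc_grid: tuple = (0.5, 0.95)
    washout: int = 20
    ridge: float = 1.0
    seed: int = 0
    selection: str = "mse"    # minimum target-reconstruction error
    val_fraction: float = 0.2


class _Reservoir:
    """Sparse random recurrent matrix rescaled to unit spectral radius."""

    def __init__(self, size: int, seed: int):
        rng = np.random.RandomState(seed)
        density = min(1.0, 10.0 / size)
        W = sparse_random(size, size, density=density, random_state=rng,
                          data_rvs=rng.standard_normal).tocsr()
        if size <= 600:
            rho = np.abs(np.linalg.eigvals(W.toarray())).max()
        else:
            rho = abs(eigs(W, k=1, which="LM",
                           return_eigenvectors=False,
                           maxiter=size * 20)[0])
        self.W = W / rho                      # spectral radius exactly 1
        self.size = size
        self.rng_state = seed


def reservoir_matrix(size: int, spectral_radius: float,
                     seed: int = 0) -> np.ndarray:
    """Dense copy of the scaled reservoir; largest |eigenvalue| equals
    ``spectral_radius`` to within the eigensolver's accuracy."""
    return (_Reservoir(size, seed).W * spectral_radius).toarray()


def esn_states(features: np.ndarray, W, w_in: np.ndarray,
               washout: int) -> np.ndarray:
    """Run the reservoir over one sequence; return the time-averaged
    post-washout state."""
    T = len(features)
    if washout >= T:
        raise ValueError(f"washout ({washout}) must be smaller than the "
                         f"sequence length ({T})")
    x = np.zeros(W.shape[0])
    acc = np.zeros(W.shape[0])
    for t in range(T):
        x = np.tanh(W @ x + w_in @ features[t])
        if t >= washout:
            acc += x
    return acc / (T - washout)


def esn_states_batch(seq_list: list[np.ndarray], W, w_in: np.ndarray,
                     washout: int) -> np.ndarray:
    """Time-averaged post-washout reservoir states for many sequences at
    once (the recursion is stepped over a padded batch)."""
    N = len(seq_list)
    lengths = np.array([len(x) for x in seq_list])
    tmax = int(lengths.max())
    D = seq_list[0].shape[1]
    size = W.shape[0]
    U = np.zeros((N, tmax, D))
    for i, x in enumerate(seq_list):
        U[i, :len(x)] = x
    wo = np.minimum(washout, lengths - 1)
    X = np.zeros((N, size))
    acc = np.zeros((N, size))
    for t in range(tmax):
        X = np.tanh((W @ X.T).T + U[:, t] @ w_in.T)
        use = (t >= wo) & (t < lengths)
        acc[use] += X[use]
    return acc / (lengths - wo)[:, None]


def classify_esn(cfg: EsnConfig, train_sequences: list[np.ndarray],
                 train_labels: list[str], test_sequence: np.ndarray) -> str:
    """One-shot ESN decision (full search on the training data)."""
    clf = EsnClassifier(cfg)
    seqs = {f"c{i}": x for i, x in enumerate(train_sequences)}
    labs = {f"c{i}": y for i, y in enumerate(train_labels)}
    clf.fit(seqs, labs)
    return clf.predict({"t": test_sequence})["t"]


class EsnClassifier:
    """Fixed random reservoir + ridge readout from time-averaged states.

    The (SR, size, sc) configuration is selected on a 20% validation split
    of the training data.  Reservoir state vectors depend only on the
    configuration and the clip, so they can be cached across folds via
    ``state_cache``.
    """

    def __init__(self, cfg: EsnConfig | None = None,
                 state_cache: dict | None = None):
        self.cfg = cfg or EsnConfig()
        self.cache = state_cache if state_cache is not None else {}
        self._reservoirs: dict[int, _Reservoir] = {}
        self.best_: tuple | None = None
        self.readout_: Ridge | None = None
        self.classes_: list[str] = []

    def _states(self, key: tuple, sequences: dict[str, np.ndarray],
                ids: list[str]) -> np.ndarray:
        sr, size, sc = key
        if size not in self._reservoirs:
            self._reservoirs[size] = _Reservoir(size, self.cfg.seed)
        res = self._reservoirs[size]
        W = res.W * sr
        dim = next(iter(sequences.values())).shape[1]
        rng = np.random.RandomState(self.cfg.seed + size)
        w_in = sc * rng.uniform(-1, 1, (size, dim))
        todo = [cid for cid in ids if (key, cid) not in self.cache]
        if todo:
            states = esn_states_batch([sequences[c] for c in todo], W, w_in,
                                      self.cfg.washout)
            for cid, s in zip(todo, states):
                self.cache[(key, cid)] = s
        return np.stack([self.cache[(key, cid)] for cid in ids])

    def _one_hot(self, y: list[str]) -> np.ndarray:
        return np.stack([[float(lab == c) for c in self.classes_]
                         for lab in y])

    def fit(self, sequences: dict[str, np.ndarray],
            labels: dict[str, str]) -> "EsnClassifier":
        ids = sorted(sequences)
        self.classes_ = sorted({labels[c] for c in ids})
        ts, vs = _split_train_val(ids, labels, self.cfg.val_fraction,
                                  self.cfg.seed)
        best = None
        for size in self.cfg.size_grid:
            for sr in self.cfg.sr_grid:
                for sc in self.cfg.sc_grid:
                    key = (sr, size, sc)
                    S_ts = self._states(key, sequences, ts)
                    S_vs = self._states(key, sequences, vs)
                    ridge = Ridge(alpha=self.cfg.ridge)
                    ridge.fit(S_ts, self._one_hot([labels[c] for c in ts]))
                    Y = ridge.predict(S_vs)
                    if self.cfg.selection == "mse":
                        score = float(np.mean(
                            (Y - self._one_hot([labels[c] for c in vs])) ** 2))
                    else:
                        pred = [self.classes_[k] for k in Y.argmax(axis=1)]
                        score = float(np.mean(
                            [p != labels[c] for p, c in zip(pred, vs)]))
                    if best is None or score < best[0]:
                        best = (score, key)
        self.best_ = best[1]
        S_all = self._states(self.best_, sequences, ids)
        self.readout_ = Ridge(alpha=self.cfg.ridge)
        self.readout_.fit(S_all, self._one_hot([labels[c] for c in ids]))
        return self

    def predict(self, sequences: dict[str, np.ndarray]) -> dict[str, str]:
        ids = sorted(sequences)
        S = self._states(self.best_, sequences, ids)
        Y = self.readout_.predict(S)
        return {cid: self.classes_[k] for cid, k in zip(ids, Y.argmax(axis=1))}
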