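"""Gaussian-mixture-emission hidden Markov models.

This is the learner inside every DAG node and the HMM baselines: k-means
initialization (segmental, up to 50 iterations), Baum-Welch EM (up to 25
iterations, stopping when the relative log-likelihood improvement drops
below 0.001 — the Torch trainer convention; an absolute mode is available),
scaled forward and Viterbi log-likelihood scoring, and a model-space search
over states S in {3,4,5,6} x Gaussians g in {2..256}.

Emissions are diagonal-covariance Gaussian mixtures with a variance floor
of 1e-3 times the pooled per-dimension training variance.  Topology is
left-to-right with self-loops and single-step forward transitions by
default (standard for short vocalizations); ergodic is available.  Zeros
planted in the initial distribution and transition matrix are preserved by
EM, so the topology is enforced at initialization only.

The E-step is batched: all training sequences are padded to a common length
and the scaled forward/backward recursions run over the whole batch at
once, which keeps ten-fold benchmark runs tractable on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    """Log-sum-exp along one axis (max-shifted, keeps -inf safe)."""
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    out = m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis)

logger = logging.getLogger("meowdag")

DEFAULT_STATES_GRID = (3, 4, 5, 6)
DEFAULT_GAUSS_GRID = (2, 4, 8, 16, 32, 64, 128, 256)

_LOG0 = -1e30  # stand-in for log(0) that survives arithmetic


class EmStepError(RuntimeError):
    """Raised when an E-step produces non-finite statistics."""


@dataclass
class TrainSpec:
    kmeans_max_iter: int = 50
    em_max_iter: int = 25
    em_threshold: float = 0.001
    threshold_mode: str = "rel"        # "rel" | "abs"
    var_floor_scale: float = 1e-3
    topology: str = "left-right"       # "left-right" | "ergodic"
    kmeans_subsample: int = 1000       # frames per state used by k-means init
    min_frames_per_component: int = 5  # feasibility rule for the grid search
    seed: int = 0

    def __post_init__(self) -> None:
        if self.em_max_iter < 1 or self.kmeans_max_iter < 1:
            raise ValueError("iteration limits must be >= 1")
        if self.em_threshold <= 0:
            raise ValueError("em_threshold must be positive")


@dataclass
class HmmModel:
    """S-state HMM with g-component diagonal-Gaussian mixtures per state."""

    startprob: np.ndarray              # (S,)
    transmat: np.ndarray               # (S, S)
    weights: np.ndarray                # (S, g)
    means: np.ndarray                  # (S, g, D)
    variances: np.ndarray              # (S, g, D)
    topology: str = "left-right"
    var_floor: np.ndarray | None = None
    training_log: list = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def dim(self) -> int:
        return self.means.shape[2]

    def validate(self, atol: float = 1e-8) -> None:
        assert abs(self.startprob.sum() - 1.0) < atol
        assert np.allclose(self.transmat.sum(axis=1), 1.0, atol=atol)
        assert np.allclose(self.weights.sum(axis=1), 1.0, atol=atol)
        assert np.all(self.variances > 0)

    def to_dict(self) -> dict:
        return {
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "topology": self.topology,
            "var_floor": None if self.var_floor is None
            else self.var_floor.tolist(),
            "training_log": list(self.training_log),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmModel":
        return cls(startprob=np.array(d["startprob"]),
                   transmat=np.array(d["transmat"]),
                   weights=np.array(d["weights"]),
                   means=np.array(d["means"]),
                   variances=np.array(d["variances"]),
                   topology=d.get("topology", "left-right"),
                   var_floor=None if d.get("var_floor") is None
                   else np.array(d["var_floor"]),
                   training_log=list(d.get("training_log", [])))


# ---------------------------------------------------------------------------
# emission densities
# ---------------------------------------------------------------------------

def _log_gauss(X: np.ndarray, means: np.ndarray, variances: np.ndarray
               ) -> np.ndarray:
    """Log N(x; mu, diag sigma^2) for all frames/components: (T, g)."""
    D = X.shape[1]
    inv = 1.0 / variances
    const = -0.5 * (D * np.log(2 * np.pi) + np.sum(np.log(variances), axis=1))
    quad = ((X ** 2) @ inv.T - 2.0 * (X @ (means * inv).T)
            + np.sum(means ** 2 * inv, axis=1))
    return const - 0.5 * quad


def log_components(model: HmmModel, X: np.ndarray) -> np.ndarray:
    """Per-frame, per-state, per-component weighted log densities (T, S, g)."""
    T = X.shape[0]
    out = np.empty((T, model.n_states, model.n_components))
    logw = np.log(np.maximum(model.weights, 1e-300))
    for s in range(model.n_states):
        out[:, s, :] = logw[s] + _log_gauss(X, model.means[s],
                                            model.variances[s])
    return out


def log_emissions(model: HmmModel, X: np.ndarray) -> np.ndarray:
    return _lse(log_components(model, X), axis=2)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _init_mixture(frames: np.ndarray, g: int, spec: TrainSpec,
                  rng: np.random.Generator, floor: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """K-means mixture init for one state: weights, means, variances."""
    D = frames.shape[1]
    if len(frames) > spec.kmeans_subsample:
        sel = rng.choice(len(frames), spec.kmeans_subsample, replace=False)
        frames = frames[sel]
    if len(frames) < g:  # duplicate with jitter so k-means has g points
        reps = int(np.ceil(g / len(frames)))
        frames = np.tile(frames, (reps, 1))
        frames = frames + rng.normal(0, np.sqrt(floor), frames.shape)
    if g == 1:
        labels = np.zeros(len(frames), dtype=int)
        centers = frames.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=g, n_init=1, max_iter=spec.kmeans_max_iter,
                    random_state=int(rng.integers(2 ** 31)))
        labels = km.fit_predict(frames)
        centers = km.cluster_centers_
    weights = np.zeros(g)
    variances = np.empty((g, D))
    for k in range(g):
        members = frames[labels == k]
        weights[k] = max(len(members), 0.5)
        if len(members) > 1:
            variances[k] = members.var(axis=0)
        else:
            variances[k] = frames.var(axis=0)
    weights /= weights.sum()
    return weights, centers, np.maximum(variances, floor)


def init_hmm(sequences: Sequence[np.ndarray], n_states: int,
             n_components: int, spec: TrainSpec | None = None) -> HmmModel:
    """Segmental initialization: each sequence is split into ``n_states``
    contiguous temporal segments; the pooled frames of segment s seed state
    s's mixture by k-means.  Deterministic given ``spec.seed``."""
    spec = spec or TrainSpec()
    sequences = [np.atleast_2d(np.asarray(x, dtype=np.float64))
                 for x in sequences]
    if not sequences:
        raise ValueError("need at least one training sequence")
    pooled = np.vstack(sequences)
    need = n_states * n_components
    if len(pooled) < need:
        raise ValueError(f"insufficient data: {len(pooled)} frames pooled, "
                         f"need >= {need} (S*g)")
    rng = np.random.default_rng(spec.seed)
    floor = np.maximum(spec.var_floor_scale * pooled.var(axis=0), 1e-10)

    S, g, D = n_states, n_components, pooled.shape[1]
    weights = np.empty((S, g))
    means = np.empty((S, g, D))
    variances = np.empty((S, g, D))
    if spec.topology == "ergodic" and S > 1:
        # no temporal ordering to exploit: states start as global k-means
        # clusters of the pooled frames
        sub = pooled
        if len(sub) > S * spec.kmeans_subsample:
            sel = rng.choice(len(sub), S * spec.kmeans_subsample,
                             replace=False)
            sub = sub[sel]
        km = KMeans(n_clusters=S, n_init=1, max_iter=spec.kmeans_max_iter,
                    random_state=int(rng.integers(2 ** 31)))
        assign = km.fit_predict(sub)
        state_frames = [sub[assign == s] if (assign == s).any() else sub
                        for s in range(S)]
    else:
        state_frames = [
            np.vstack([np.array_split(x, S)[s] for x in sequences
                       if len(np.array_split(x, S)[s])])
            for s in range(S)]
    for s in range(S):
        weights[s], means[s], variances[s] = _init_mixture(
            state_frames[s], g, spec, rng, floor)

    if spec.topology == "left-right":
        A = np.zeros((S, S))
        for s in range(S - 1):
            A[s, s], A[s, s + 1] = 0.6, 0.4
        A[S - 1, S - 1] = 1.0
        pi = np.zeros(S)
        pi[0] = 1.0
    elif spec.topology == "ergodic":
        A = np.full((S, S), 0.2 / max(S - 1, 1))
        np.fill_diagonal(A, 0.8 if S > 1 else 1.0)
        A /= A.sum(axis=1, keepdims=True)
        pi = np.full(S, 1.0 / S)
    else:
        raise ValueError(f"unknown topology {spec.topology!r}")
    return HmmModel(pi, A, weights, means, variances,
                    topology=spec.topology, var_floor=floor)


# ---------------------------------------------------------------------------
# Baum-Welch (batched scaled forward-backward EM)
# ---------------------------------------------------------------------------

def _batch(sequences: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray,
                                                 np.ndarray, np.ndarray]:
    """Concatenate sequences; return X, lengths, flat-index map and validity."""
    lengths = np.array([len(x) for x in sequences])
    X = np.vstack(sequences)
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    tmax = lengths.max()
    t = np.arange(tmax)
    valid = t[None, :] < lengths[:, None]
    idx = np.minimum(offsets[:, None] + t[None, :],
                     (offsets + lengths - 1)[:, None])
    return X, lengths, idx, valid


def _estep(model: HmmModel, X: np.ndarray, lengths: np.ndarray,
           idx: np.ndarray, valid: np.ndarray) -> tuple[dict, float]:
    S = model.n_states
    logcomp = log_components(model, X)           # (Ttot, S, g)
    if not np.all(np.isfinite(logcomp)):
        bad = np.argwhere(~np.isfinite(logcomp))
        t, s, k = bad[0]
        raise EmStepError(f"non-finite emission at state {s}, component {k}")
    logB = _lse(logcomp, axis=2)                 # (Ttot, S)

    N, Tmax = idx.shape
    logBp = logB[idx]                            # (N, Tmax, S)
    m = logBp.max(axis=2)
    B = np.exp(logBp - m[:, :, None])

    A = model.transmat
    alphas = np.empty((N, Tmax, S))
    c = np.empty((N, Tmax))
    alpha = model.startprob[None, :] * B[:, 0]
    c[:, 0] = np.maximum(alpha.sum(axis=1), 1e-300)
    alpha /= c[:, 0, None]
    alphas[:, 0] = alpha
    for t in range(1, Tmax):
        alpha = (alpha @ A) * B[:, t]
        c[:, t] = np.maximum(alpha.sum(axis=1), 1e-300)
        alpha /= c[:, t, None]
        alphas[:, t] = alpha

    logliks = np.sum((np.log(c) + m) * valid, axis=1)
    total_ll = float(logliks.sum())

    # backward pass with per-step renormalization of beta: gamma and xi are
    # normalized per frame, so beta's absolute scale is irrelevant and the
    # recursion cannot overflow even for near-deterministic topologies
    gamma_flat = np.zeros((len(X), S))
    xi_acc = np.zeros((S, S))
    beta = np.zeros((N, S))
    last = lengths - 1
    for t in range(Tmax - 1, -1, -1):
        beta[last == t] = 1.0 / S
        here = valid[:, t]
        gamma = alphas[:, t] * beta
        gsum = np.maximum(gamma.sum(axis=1, keepdims=True), 1e-300)
        gamma_flat[idx[here, t]] = (gamma / gsum)[here]
        if t >= 1:
            u = B[:, t] * beta                       # (N, S)
            pred = alphas[:, t - 1] @ A
            z = np.maximum((pred * u).sum(axis=1), 1e-300)
            inner = here & valid[:, t - 1]
            w = np.where(inner, 1.0 / z, 0.0)
            xi_acc += ((alphas[:, t - 1] * w[:, None]).T @ u) * A
            beta = u @ A.T
            beta /= np.maximum(beta.sum(axis=1, keepdims=True), 1e-300)
    start_gamma = gamma_flat[idx[:, 0]]

    # component posteriors within each state
    comp = logcomp - _lse(logcomp, axis=2)[:, :, None]
    comp_post = np.exp(comp) * gamma_flat[:, :, None]   # (Ttot, S, g)

    stats = dict(gamma=gamma_flat, xi=xi_acc, start=start_gamma,
                 comp_post=comp_post)
    return stats, total_ll


def _mstep(model: HmmModel, X: np.ndarray, stats: dict) -> None:
    floor = model.var_floor if model.var_floor is not None else 1e-6
    pi = stats["start"].sum(axis=0)
    model.startprob = pi / pi.sum()

    xi = stats["xi"]
    rows = xi.sum(axis=1, keepdims=True)
    keep = rows[:, 0] <= 1e-12          # states never left: keep old row
    newA = np.where(keep[:, None], model.transmat,
                    xi / np.maximum(rows, 1e-300))
    model.transmat = newA / newA.sum(axis=1, keepdims=True)

    comp_post = stats["comp_post"]
    Nsg = comp_post.sum(axis=0)                        # (S, g)
    Ns = np.maximum(stats["gamma"].sum(axis=0), 1e-300)
    w = Nsg / Ns[:, None]
    alive = Nsg > 1e-3
    sums = np.tensordot(comp_post, X, axes=([0], [0]))        # (S, g, D)
    sq = np.tensordot(comp_post, X ** 2, axes=([0], [0]))
    denom = np.maximum(Nsg, 1e-300)[:, :, None]
    mu = sums / denom
    var = sq / denom - mu ** 2
    model.means = np.where(alive[:, :, None], mu, model.means)
    model.variances = np.where(alive[:, :, None],
                               np.maximum(var, floor), model.variances)
    w = np.maximum(w, 1e-8)
    model.weights = w / w.sum(axis=1, keepdims=True)


def baum_welch(model: HmmModel, sequences: Sequence[np.ndarray],
               spec: TrainSpec | None = None) -> HmmModel:
    """EM re-estimation in place; returns the model for chaining.

    Stops after ``em_max_iter`` iterations or when the log-likelihood
    improvement between subsequent iterations falls below ``em_threshold``
    (relative by default, absolute with ``threshold_mode="abs"``).
    ``model.training_log`` records the per-iteration total log-likelihood.
    """
    spec = spec or TrainSpec()
    seqs = [np.atleast_2d(np.asarray(x, dtype=np.float64)) for x in sequences]
    X, lengths, idx, valid = _batch(seqs)
    prev = None
    for _ in range(spec.em_max_iter):
        stats, ll = _estep(model, X, lengths, idx, valid)
        model.training_log.append(ll)
        if prev is not None:
            gain = ll - prev
            tol = (spec.em_threshold * abs(prev)
                   if spec.threshold_mode == "rel" else spec.em_threshold)
            if gain < tol:
                break
        _mstep(model, X, stats)
        prev = ll
    return model


def train_gmm_hmm(sequences: Sequence[np.ndarray], n_states: int,
                  n_components: int, spec: TrainSpec | None = None
                  ) -> HmmModel:
    """Convenience: segmental k-means init followed by Baum-Welch."""
    spec = spec or TrainSpec()
    model = init_hmm(sequences, n_states, n_components, spec)
    return baum_welch(model, sequences, spec)


def cached_train(cache: dict | None, key, sequences: Sequence[np.ndarray],
                 n_states: int, n_components: int,
                 spec: TrainSpec) -> HmmModel:
    """Memoized :func:`train_gmm_hmm`.

    Training is deterministic given (data, S, g, spec), so when the same
    class data is modelled at the same configuration by several callers —
    the two pair tasks sharing a class inside the DAG search, or the DAG
    and the class-specific baseline on one fold — the model is trained
    once.  ``key`` must identify the training data (e.g. the clip ids).
    """
    if cache is None:
        return train_gmm_hmm(sequences, n_states, n_components, spec)
    k = (key, n_states, n_components, spec.seed, spec.topology)
    if k not in cache:
        cache[k] = train_gmm_hmm(sequences, n_states, n_components, spec)
    return cache[k]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _log_model_params(model: HmmModel) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore"):
        logpi = np.log(model.startprob)
        logA = np.log(model.transmat)
    return np.maximum(logpi, _LOG0), np.maximum(logA, _LOG0)


def forward_loglik(model: HmmModel, sequence: np.ndarray) -> float:
    """log P(sequence | model): sum over all state paths (scaled forward)."""
    X = np.atleast_2d(np.asarray(sequence, dtype=np.float64))
    if X.shape[0] == 0:
        raise ValueError("empty sequence")
    if X.shape[1] != model.dim:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {model.dim}")
    logB = log_emissions(model, X)
    logpi, logA = _log_model_params(model)
    la = logpi + logB[0]
    for t in range(1, len(X)):
        la = _lse(la[:, None] + logA, axis=0) + logB[t]
    return float(_lse(la, 0))


def viterbi_loglik(model: HmmModel, sequence: np.ndarray) -> float:
    """log probability of the single best state path."""
    X = np.atleast_2d(np.asarray(sequence, dtype=np.float64))
    if X.shape[0] == 0:
        raise ValueError("empty sequence")
    if X.shape[1] != model.dim:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {model.dim}")
    logB = log_emissions(model, X)
    logpi, logA = _log_model_params(model)
    delta = logpi + logB[0]
    for t in range(1, len(X)):
        delta = np.max(delta[:, None] + logA, axis=0) + logB[t]
    return float(delta.max())


def viterbi_loglik_batch(model: HmmModel,
                         sequences: Sequence[np.ndarray]) -> np.ndarray:
    """Viterbi log-likelihood of many sequences under one model.

    Identical to mapping :func:`viterbi_loglik`, but the dynamic program
    is stepped over a padded batch, which is much faster when scoring a
    whole validation or test set.
    """
    seqs = [np.atleast_2d(np.asarray(x, dtype=np.float64)) for x in sequences]
    if not seqs:
        return np.array([])
    X, lengths, idx, valid = _batch(seqs)
    logB = log_emissions(model, X)
    logBp = logB[idx]                              # (N, Tmax, S)
    logpi, logA = _log_model_params(model)
    delta = logpi[None, :] + logBp[:, 0]
    out = np.where(lengths == 1, delta.max(axis=1), np.nan)
    for t in range(1, idx.shape[1]):
        delta = np.max(delta[:, :, None] + logA[None], axis=1) + logBp[:, t]
        done = lengths == t + 1
        if done.any():
            out[done] = delta[done].max(axis=1)
    return out


def sample_hmm(model: HmmModel, n_steps: int,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one observation sequence; returns (X, state path)."""
    S, g, D = model.n_states, model.n_components, model.dim
    states = np.empty(n_steps, dtype=int)
    X = np.empty((n_steps, D))
    s = rng.choice(S, p=model.startprob)
    for t in range(n_steps):
        states[t] = s
        k = rng.choice(g, p=model.weights[s])
        X[t] = rng.normal(model.means[s, k], np.sqrt(model.variances[s, k]))
        if t + 1 < n_steps:
            s = rng.choice(S, p=model.transmat[s])
    return X, states


# ---------------------------------------------------------------------------
# model-space search
# ---------------------------------------------------------------------------

def classify_pair(models: dict[str, HmmModel], sequence: np.ndarray) -> str:
    """Higher-Viterbi-loglik class; exact ties go to the lexicographically
    smaller label (deterministic)."""
    labels = sorted(models)
    scores = [viterbi_loglik(models[lab], sequence) for lab in labels]
    return labels[int(np.argmax(scores))]  # argmax takes first on ties


def search_model_space(train: dict[str, list[np.ndarray]],
                       validation: list[tuple[np.ndarray, str]],
                       states_grid: Sequence[int] = DEFAULT_STATES_GRID,
                       gauss_grid: Sequence[int] = DEFAULT_GAUSS_GRID,
                       spec: TrainSpec | None = None,
                       trainer=None
                       ) -> tuple[dict[str, HmmModel], tuple[int, int], float]:
    """Explore the (S, g) grid for one binary task.

    For each configuration one HMM per class is trained on ``train`` and the
    pair is scored by validation recognition rate (fraction of validation
    clips whose true-class model wins on Viterbi log-likelihood).  Returns
    (best model pair, best (S, g), best rate).  Infeasible configurations —
    fewer than 5*S*g training frames in some class — are skipped and logged.
    Rate ties (common when several configurations solve an easy task
    perfectly on a modest validation set) break toward the larger mean
    per-frame log-likelihood margin between the true and the competing
    model, then toward smaller g and S.
    """
    spec = spec or TrainSpec()
    if len(train) != 2:
        raise ValueError("search_model_space expects exactly two classes")
    if not validation:
        raise ValueError("empty validation set")
    frames = {lab: sum(len(x) for x in seqs) for lab, seqs in train.items()}

    best: tuple[dict, tuple[int, int], float] | None = None
    configs = sorted(((g, s) for s in states_grid for g in gauss_grid))
    feasible = []
    for g, s in configs:
        if min(frames.values()) < spec.min_frames_per_component * s * g:
            logger.debug("skipping (S=%d, g=%d): fewer than %d frames",
                         s, g, spec.min_frames_per_component * s * g)
            continue
        feasible.append((g, s))
    if not feasible:          # tiny data: fall back to the smallest config
        feasible = [configs[0]]
        logger.warning("no feasible (S, g); falling back to %s", configs[0])

    if trainer is None:
        trainer = lambda lab, seqs, s, g: train_gmm_hmm(seqs, s, g, spec)  # noqa: E731
    val_seqs = [x for x, _ in validation]
    val_labels = np.array([lab for _, lab in validation])
    val_frames = np.array([len(x) for x in val_seqs], dtype=float)
    pair = sorted(train)
    truth = (val_labels == pair[1]).astype(int)
    best_margin = -np.inf
    rate_seen = -np.inf
    for g, s in feasible:
        models = {lab: trainer(lab, seqs, s, g)
                  for lab, seqs in train.items()}
        scores = np.stack([viterbi_loglik_batch(models[lab], val_seqs)
                           for lab in pair])
        preds = np.array(pair)[scores.argmax(axis=0)]  # ties -> smaller label
        rate = float(np.mean(preds == val_labels))
        margin = float(np.mean((scores[truth, np.arange(len(val_seqs))]
                                - scores[1 - truth, np.arange(len(val_seqs))])
                               / val_frames))
        if best is None or rate > rate_seen or (rate == rate_seen
                                                and margin > best_margin):
            best = (models, (s, g), rate)
            best_margin = margin
        rate_seen = max(rate_seen, rate)
    assert best is not None
    return best
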