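"""GMM-HMM engine: scoring oracles, EM correctness, initialization and the
model-space search.

Viterbi and forward scores are checked against explicit enumeration of all
S^T state paths on small instances; forward is additionally cross-checked
against hmmlearn as an independent implementation.
"""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from meowdag.hmm import (HmmModel, TrainSpec, baum_welch, forward_loglik,
                         init_hmm, sample_hmm, search_model_space,
                         train_gmm_hmm, viterbi_loglik, viterbi_loglik_batch)


def random_model(rng, S, g, D, ergodic=True):
    pi = rng.dirichlet(np.ones(S))
    A = rng.dirichlet(np.ones(S), size=S)
    w = rng.dirichlet(np.ones(g), size=S)
    means = rng.normal(0, 2, (S, g, D))
    variances = rng.uniform(0.3, 2.0, (S, g, D))
    return HmmModel(pi, A, w, means, variances, topology="ergodic")


def brute_force_logliks(model, X):
    """Enumerate every state path: exact forward and Viterbi references."""
    S, T = model.n_states, len(X)
    logB = np.empty((T, S))
    for t in range(T):
        for s in range(S):
            comp = [np.log(model.weights[s, k])
                    + norm.logpdf(X[t], model.means[s, k],
                                  np.sqrt(model.variances[s, k])).sum()
                    for k in range(model.n_components)]
            logB[t, s] = np.logaddexp.reduce(comp)
    path_logps = []
    for path in itertools.product(range(S), repeat=T):
        lp = np.log(model.startprob[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(model.transmat[path[t - 1], path[t]]) + logB[t,
                                                                      path[t]]
        path_logps.append(lp)
    path_logps = np.array(path_logps)
    return np.logaddexp.reduce(path_logps), path_logps.max()


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("case", range(25))
def test_scores_match_path_enumeration(case):
    """Forward = log-sum over paths, Viterbi = max over paths, to 1e-8."""
    rng = np.random.default_rng(case)
    S = int(rng.integers(1, 5))
    g = int(rng.integers(1, 3))
    T = int(rng.integers(1, 7))
    model = random_model(rng, S, g, D=2)
    X = rng.normal(0, 1.5, (T, 2))
    fwd_ref, vit_ref = brute_force_logliks(model, X)
    assert forward_loglik(model, X) == pytest.approx(fwd_ref, rel=1e-8)
    assert viterbi_loglik(model, X) == pytest.approx(vit_ref, rel=1e-8)


def test_viterbi_below_forward():
    rng = np.random.default_rng(42)
    for _ in range(20):
        model = random_model(rng, 3, 2, 4)
        X = rng.normal(0, 1, (30, 4))
        assert viterbi_loglik(model, X) <= forward_loglik(model, X) + 1e-10


def test_single_state_scores_coincide():
    """S=1: no path choice, both scores equal the summed mixture density."""
    rng = np.random.default_rng(3)
    model = random_model(rng, 1, 3, 2)
    X = rng.normal(0, 1, (12, 2))
    direct = 0.0
    for x in X:
        comps = [np.log(model.weights[0, k])
                 + norm.logpdf(x, model.means[0, k],
                               np.sqrt(model.variances[0, k])).sum()
                 for k in range(3)]
        direct += np.logaddexp.reduce(comps)
    assert viterbi_loglik(model, X) == pytest.approx(direct, rel=1e-10)
    assert forward_loglik(model, X) == pytest.approx(direct, rel=1e-10)


def test_batch_viterbi_matches_single():
    rng = np.random.default_rng(5)
    model = random_model(rng, 3, 2, 3)
    seqs = [rng.normal(0, 1, (int(rng.integers(2, 40)), 3))
            for _ in range(15)]
    batch = viterbi_loglik_batch(model, seqs)
    single = [viterbi_loglik(model, x) for x in seqs]
    assert np.allclose(batch, single, rtol=1e-10)


def test_loglik_decreases_with_extension():
    """Appending frames strictly lowers the log-likelihood when densities
    are below one (unit variances in normalized feature space)."""
    rng = np.random.default_rng(8)
    model = HmmModel(np.array([0.5, 0.5]),
                     np.array([[0.8, 0.2], [0.3, 0.7]]),
                     np.ones((2, 1)),
                     np.array([[[0.0, 0.0]], [[1.0, 1.0]]]),
                     np.ones((2, 1, 2)), topology="ergodic")
    X = rng.normal(0, 1, (20, 2))
    lls = [forward_loglik(model, X[:t]) for t in range(1, 21)]
    assert np.all(np.diff(lls) < 0)


def test_empty_sequence_errors():
    rng = np.random.default_rng(0)
    model = random_model(rng, 2, 1, 2)
    with pytest.raises(ValueError):
        viterbi_loglik(model, np.empty((0, 2)))
    with pytest.raises(ValueError, match="dimension"):
        forward_loglik(model, np.zeros((4, 5)))


def test_forward_matches_hmmlearn():
    """Independent cross-check of the forward score against hmmlearn."""
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    rng = np.random.default_rng(17)
    model = random_model(rng, 3, 2, 4)
    ref = hmmlearn.GMMHMM(n_components=3, n_mix=2, covariance_type="diag",
                          init_params="")
    ref.startprob_ = model.startprob
    ref.transmat_ = model.transmat
    ref.weights_ = model.weights
    ref.means_ = model.means
    ref.covars_ = model.variances
    for _ in range(5):
        X = rng.normal(0, 1.5, (25, 4))
        assert forward_loglik(model, X) == pytest.approx(ref.score(X),
                                                         rel=1e-8)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def test_init_degenerate_single_gaussian():
    rng = np.random.default_rng(0)
    seqs = [rng.normal(2.0, 1.5, (30, 3)) for _ in range(5)]
    model = init_hmm(seqs, 1, 1, TrainSpec(seed=0))
    pooled = np.vstack(seqs)
    assert np.allclose(model.means[0, 0], pooled.mean(axis=0), atol=1e-8)
    assert np.allclose(model.variances[0, 0], pooled.var(axis=0), rtol=0.05)


def test_init_deterministic():
    rng = np.random.default_rng(1)
    seqs = [rng.normal(0, 1, (40, 4)) for _ in range(6)]
    a = init_hmm(seqs, 3, 2, TrainSpec(seed=9))
    b = init_hmm(seqs, 3, 2, TrainSpec(seed=9))
    assert np.array_equal(a.means, b.means)
    assert np.array_equal(a.weights, b.weights)


def test_init_recovers_planted_clusters():
    rng = np.random.default_rng(2)
    a = rng.normal(-3.0, 0.1, (200, 2))
    b = rng.normal(3.0, 0.1, (200, 2))
    frames = np.vstack([a, b])
    rng.shuffle(frames)
    model = init_hmm([frames], 1, 2, TrainSpec(seed=0))
    centers = sorted(model.means[0, :, 0])
    assert abs(centers[0] + 3.0) < 0.1
    assert abs(centers[1] - 3.0) < 0.1


def test_init_insufficient_frames():
    with pytest.raises(ValueError, match="insufficient"):
        init_hmm([np.zeros((3, 2))], 2, 4, TrainSpec())


# ---------------------------------------------------------------------------
# Baum-Welch
# ---------------------------------------------------------------------------

def test_em_loglik_monotone():
    rng = np.random.default_rng(4)
    seqs = [rng.normal(0, 1, (40, 3)) + np.linspace(0, 4, 40)[:, None]
            for _ in range(12)]
    spec = TrainSpec(seed=0, em_max_iter=25, threshold_mode="abs",
                     em_threshold=1e-9)
    model = train_gmm_hmm(seqs, 3, 2, spec)
    lls = np.array(model.training_log)
    assert len(lls) > 3
    assert np.all(np.diff(lls) >= -1e-6 * np.abs(lls[:-1]))


def test_em_preserves_stochasticity():
    rng = np.random.default_rng(6)
    seqs = [rng.normal(0, 1, (30, 2)) for _ in range(8)]
    for topology in ("left-right", "ergodic"):
        model = train_gmm_hmm(seqs, 3, 2, TrainSpec(seed=1,
                                                    topology=topology))
        model.validate()
        if topology == "left-right":
            assert np.allclose(np.tril(model.transmat, -1), 0.0)


def test_constant_sequence_means():
    const = np.full((50, 2), 3.5)
    model = train_gmm_hmm([const] * 4, 2, 1, TrainSpec(seed=0))
    assert np.allclose(model.means, 3.5, atol=1e-6)


def test_planted_hmm_recovery():
    """A 3-state HMM with distinct states is recovered from 200 simulated
    sequences: transitions within 0.1 elementwise after state matching,
    held-out log-likelihood within 2% of the generating model's."""
    truth = HmmModel(
        np.array([1.0, 0.0, 0.0]),
        np.array([[0.85, 0.15, 0.00],
                  [0.00, 0.80, 0.20],
                  [0.05, 0.00, 0.95]]),
        np.ones((3, 1)),
        np.array([[[-4.0, 0.0]], [[0.0, 3.0]], [[4.0, -2.0]]]),
        np.full((3, 1, 2), 0.5), topology="ergodic")
    rng = np.random.default_rng(123)
    train = [sample_hmm(truth, 40, rng)[0] for _ in range(200)]
    test = [sample_hmm(truth, 40, rng)[0] for _ in range(50)]

    spec = TrainSpec(seed=0, topology="ergodic")
    fitted = train_gmm_hmm(train, 3, 1, spec)

    # match states by nearest means
    perm = [int(np.argmin(np.linalg.norm(fitted.means[:, 0]
                                         - truth.means[s, 0], axis=1)))
            for s in range(3)]
    assert sorted(perm) == [0, 1, 2]
    A_matched = fitted.transmat[np.ix_(perm, perm)]
    assert np.max(np.abs(A_matched - truth.transmat)) < 0.1

    ll_true = sum(forward_loglik(truth, x) for x in test)
    ll_fit = sum(forward_loglik(fitted, x) for x in test)
    assert abs(ll_fit - ll_true) < 0.02 * abs(ll_true)


def test_serialization_roundtrip():
    rng = np.random.default_rng(9)
    seqs = [rng.normal(0, 1, (20, 2)) for _ in range(5)]
    model = train_gmm_hmm(seqs, 2, 2, TrainSpec(seed=0))
    clone = HmmModel.from_dict(model.to_dict())
    X = rng.normal(0, 1, (15, 2))
    assert viterbi_loglik(clone, X) == pytest.approx(
        viterbi_loglik(model, X), rel=1e-12)


# ---------------------------------------------------------------------------
# model-space search
# ---------------------------------------------------------------------------

def _pair_data(rng, sep=6.0):
    mk = lambda mu: [rng.normal(mu, 1.0, (25, 2)) for _ in range(8)]  # noqa: E731
    train = {"a": mk(-sep / 2), "b": mk(sep / 2)}
    val = [(rng.normal(-sep / 2, 1.0, (25, 2)), "a") for _ in range(6)] + \
          [(rng.normal(sep / 2, 1.0, (25, 2)), "b") for _ in range(6)]
    return train, val


def test_search_single_config_returned():
    rng = np.random.default_rng(11)
    train, val = _pair_data(rng)
    models, config, rate = search_model_space(train, val, (3,), (2,),
                                              TrainSpec(seed=0))
    assert config == (3, 2)
    assert set(models) == {"a", "b"}


def test_search_separable_pair_perfect():
    rng = np.random.default_rng(12)
    train, val = _pair_data(rng, sep=8.0)
    _, _, rate = search_model_space(train, val, (3, 4), (2, 4),
                                    TrainSpec(seed=0))
    assert rate == 1.0


def test_search_rate_self_consistent():
    rng = np.random.default_rng(13)
    train, val = _pair_data(rng, sep=1.0)   # imperfect task
    models, _, rate = search_model_space(train, val, (3,), (2,),
                                         TrainSpec(seed=0))
    recomputed = np.mean([
        max(models, key=lambda lab: viterbi_loglik(models[lab], x)) == lab
        for x, lab in val])
    assert 0.0 <= rate <= 1.0
    assert rate == pytest.approx(recomputed)


def test_search_empty_validation_errors():
    rng = np.random.default_rng(14)
    train, _ = _pair_data(rng)
    with pytest.raises(ValueError, match="validation"):
        search_model_space(train, [], (3,), (2,), TrainSpec())
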