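"""DAG construction, task ordering and traversal."""

import numpy as np
import pytest

import meowdag.dag as dag_mod
from meowdag.baselines import ClassHmmClassifier
from meowdag.benchmark import corpus_features
from meowdag.dag import (DagHmmClassifier, DagModel, DagTask, build_dag,
                         classify, classify_batch, order_tasks)
from meowdag.features import Normalizer
from meowdag.hmm import TrainSpec
from meowdag.synthetic import CorpusSpec, make_separable_profiles


def stub_tasks(rates):
    """DagTask list from {(a, b): rate} with placeholder models."""
    return [DagTask(pair, rate, models=None) for pair, rate in rates.items()]


def all_pairs(classes):
    return [(a, b) for i, a in enumerate(classes) for b in classes[i + 1:]]


# ---------------------------------------------------------------------------
# ordering (stubbed search)
# ---------------------------------------------------------------------------

def test_order_tasks_descending(monkeypatch):
    rates = {("A", "B"): 0.9, ("A", "C"): 0.7, ("B", "C"): 0.8}

    def stub_search(train, val, states, gauss, spec, trainer=None):
        pair = tuple(sorted(train))
        return {lab: None for lab in pair}, (3, 2), rates[pair]

    monkeypatch.setattr(dag_mod, "search_model_space", stub_search)
    rng = np.random.default_rng(0)
    seqs = {f"{lab}{i}": rng.normal(size=(10, 2))
            for lab in "ABC" for i in range(6)}
    labels = {cid: cid[0] for cid in seqs}
    tasks = order_tasks(seqs, labels, (3,), (2,), TrainSpec(seed=0), seed=0)
    assert [t.pair for t in tasks] == [("A", "B"), ("B", "C"), ("A", "C")]
    assert [t.rate for t in tasks] == [0.9, 0.8, 0.7]


def test_order_tasks_equal_rates_lexicographic(monkeypatch):
    def stub_search(train, val, states, gauss, spec, trainer=None):
        return {lab: None for lab in sorted(train)}, (3, 2), 0.5

    monkeypatch.setattr(dag_mod, "search_model_space", stub_search)
    rng = np.random.default_rng(0)
    seqs = {f"{lab}{i}": rng.normal(size=(10, 2))
            for lab in "ABC" for i in range(6)}
    labels = {cid: cid[0] for cid in seqs}
    tasks = order_tasks(seqs, labels, (3,), (2,), TrainSpec(seed=0), seed=0)
    assert [t.pair for t in tasks] == [("A", "B"), ("A", "C"), ("B", "C")]


@pytest.mark.parametrize("seed", range(5))
def test_inseparable_pair_ranks_last(seed, inseparable_corpus):
    """Two classes share one acoustic profile; across seeds their task is
    always the hardest and sorts last."""
    seqs, labels = inseparable_corpus
    tasks = order_tasks(seqs, labels, (3,), (2,), TrainSpec(seed=seed),
                        seed=seed)
    assert tasks[-1].pair == ("brushing", "isolation")
    assert tasks[-1].rate < min(t.rate for t in tasks[:-1])


@pytest.fixture(scope="module")
def inseparable_corpus():
    from dataclasses import replace
    profiles = make_separable_profiles()
    profiles["brushing"] = replace(profiles["isolation"],
                                   context_label="brushing")
    counts = {(ctx, "MC", "NF"): 20 for ctx in profiles}
    spec = CorpusSpec(cell_counts=counts, profiles=profiles, seed=21)
    seqs, labels = corpus_features(seed=21, spec=spec)
    norm = Normalizer().fit(list(seqs.values()))
    return {c: norm.transform(x) for c, x in seqs.items()}, labels


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_classes,expected_nodes",
                         [(2, 1), (3, 3), (10, 45), (20, 190)])
def test_node_count_law(n_classes, expected_nodes):
    classes = [f"c{i:02d}" for i in range(n_classes)]
    rng = np.random.default_rng(n_classes)
    tasks = stub_tasks({p: float(rng.uniform(0.5, 1.0))
                        for p in all_pairs(classes)})
    dag = build_dag(tasks, classes)
    assert dag.n_nodes == expected_nodes
    assert len(dag.nodes()) == expected_nodes


@pytest.mark.parametrize("n_classes", range(2, 9))
def test_structural_laws(n_classes):
    """Acyclicity, 0-or-2 out-degree, and Cm-1 nodes per root-leaf path."""
    classes = [f"c{i}" for i in range(n_classes)]
    rng = np.random.default_rng(n_classes + 100)
    tasks = stub_tasks({p: float(rng.uniform(0, 1))
                        for p in all_pairs(classes)})
    dag = build_dag(tasks, classes)
    for (i, j) in dag.nodes():
        children = dag.children(i, j)
        assert len(children) == 2
        for child in children:
            if isinstance(child, tuple):
                ci, cj = child
                assert cj - ci == (j - i) - 1      # one class eliminated
    # every root-to-leaf path visits exactly Cm-1 nodes
    def walk(i, j, depth):
        if i == j:
            assert depth == n_classes - 1
            return
        walk(i, j - 1, depth + 1)
        walk(i + 1, j, depth + 1)
    walk(0, n_classes - 1, 0)


def test_root_is_highest_rate_task():
    classes = ["a", "b", "c", "d"]
    rates = {p: 0.5 for p in all_pairs(classes)}
    rates[("b", "d")] = 0.99
    dag = build_dag(stub_tasks(rates), classes)
    i, j = 0, len(classes) - 1
    assert dag.node_task(i, j).pair == ("b", "d")


def test_build_dag_incomplete_tasks():
    with pytest.raises(ValueError, match="cover"):
        build_dag(stub_tasks({("a", "b"): 0.9}), ["a", "b", "c"])


def test_dag_serialization_roundtrip():
    classes = ["x", "y", "z"]
    rng = np.random.default_rng(0)
    tasks = stub_tasks({p: float(rng.uniform(0, 1))
                        for p in all_pairs(classes)})
    dag = build_dag(tasks, classes)
    clone = DagModel.from_dict(dag.to_dict())
    assert clone.class_order == dag.class_order
    assert {t.pair: t.rate for t in clone.tasks.values()} == \
           {t.pair: t.rate for t in dag.tasks.values()}
    assert "digraph" in dag.to_dot()


# ---------------------------------------------------------------------------
# traversal
# ---------------------------------------------------------------------------

def rigged_dag(classes, rates, loglik_table, monkeypatch):
    """DAG whose node models are string markers; Viterbi is stubbed to read
    the rigged table."""
    tasks = [DagTask(p, r, models={lab: f"model_{lab}" for lab in p})
             for p, r in rates.items()]
    monkeypatch.setattr(dag_mod, "viterbi_loglik",
                        lambda model, x: loglik_table[model.split("_")[1]])
    return build_dag(tasks, classes)


def test_classify_follows_max_loglik(monkeypatch):
    classes = ["a", "b", "c"]
    rates = {p: 0.9 for p in all_pairs(classes)}
    dag = rigged_dag(classes, rates, {"a": -50.0, "b": -10.0, "c": -30.0},
                     monkeypatch)
    label, trace = classify(dag, np.zeros((5, 2)))
    assert label == "b"
    assert len(trace) == len(classes) - 1
    eliminated = {step["eliminated"] for step in trace}
    assert "b" not in eliminated


def test_classify_tie_keeps_lexicographically_smaller(monkeypatch):
    classes = ["a", "b"]
    dag = rigged_dag(classes, {("a", "b"): 1.0},
                     {"a": -20.0, "b": -20.0}, monkeypatch)
    label, trace = classify(dag, np.zeros((5, 2)))
    assert label == "a"


def test_end_to_end_separable_corpus(small_separable):
    """Held-out clips from a widely separated corpus are nearly all
    correct."""
    seqs, labels = small_separable
    ids = sorted(seqs)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(ids))
    test_ids = {ids[i] for i in perm[:6]}
    train = {c: seqs[c] for c in ids if c not in test_ids}
    clf = DagHmmClassifier((3,), (2,), TrainSpec(seed=0), seed=0)
    clf.fit(train, labels)
    preds = clf.predict({c: seqs[c] for c in test_ids})
    acc = np.mean([preds[c] == labels[c] for c in test_ids])
    assert acc >= 0.95
    # batch traversal agrees with the single-clip walk
    for c in test_ids:
        assert classify(clf.dag_, seqs[c])[0] == preds[c]


def test_two_class_dag_equals_class_hmm(small_separable):
    """With two classes the DAG and the class-specific bank coincide."""
    seqs, labels = small_separable
    two = {c: x for c, x in seqs.items()
           if labels[c] in ("food", "isolation")}
    ids = sorted(two)
    train = {c: two[c] for c in ids[3:-3]}
    test = {c: two[c] for c in ids[:3] + ids[-3:]}
    dag = DagHmmClassifier((3,), (2,), TrainSpec(seed=5), seed=5)
    chmm = ClassHmmClassifier((3,), (2,), TrainSpec(seed=5), seed=5)
    dag.fit(train, labels)
    chmm.fit(train, labels)
    assert dag.predict(test) == chmm.predict(test)


def test_label_equivariance(small_separable):
    """Renaming the class labels renames the predictions, nothing else."""
    seqs, labels = small_separable
    rename = {"food": "ctx_z", "isolation": "ctx_a", "brushing": "ctx_m"}
    relabeled = {c: rename[labels[c]] for c in labels}
    ids = sorted(seqs)
    train_ids, test_ids = ids[4:], ids[:4]
    kw = dict(states_grid=(3,), gauss_grid=(2,), spec=TrainSpec(seed=2),
              seed=2)
    p1 = DagHmmClassifier(**kw).fit(
        {c: seqs[c] for c in train_ids}, labels).predict(
        {c: seqs[c] for c in test_ids})
    p2 = DagHmmClassifier(**kw).fit(
        {c: seqs[c] for c in train_ids}, relabeled).predict(
        {c: seqs[c] for c in test_ids})
    assert {c: rename[p1[c]] for c in p1} == p2


def test_classify_batch_matches_single(small_separable):
    seqs, labels = small_separable
    clf = DagHmmClassifier((3,), (2,), TrainSpec(seed=1), seed=1)
    clf.fit(seqs, labels)
    subset = {c: seqs[c] for c in sorted(seqs)[:8]}
    batch = classify_batch(clf.dag_, subset)
    for c, x in subset.items():
        assert classify(clf.dag_, x)[0] == batch[c]
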