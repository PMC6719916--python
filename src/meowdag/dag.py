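"""Directed-acyclic-graph of binary GMM-HMM classifiers (DAG-HMM).

A Cm-class problem is decomposed into Cm(Cm-1)/2 pairwise tasks, one node
per class pair.  Task difficulty is estimated up front: the training fold
is split into a training part (TS) and a validation part (VS), each pair
task runs a model-space search over (states, Gaussians), and tasks are
ranked by descending validation recognition rate — easy tasks sit nearest
the root so classes likely to cause misclassifications are eliminated
early.  Classification walks the graph from the root: each node scores the
clip under its two HMMs, follows the larger Viterbi log-likelihood and
eliminates one class; after Cm-1 nodes a single label remains.

Topologically the graph is the rooted triangular structure over an ordered
class list (each node tests the two endpoint classes of a contiguous
sublist; eliminating a class shortens the list from one end).  This is the
only layout in which every pair appears exactly once, which is what gives
the Cm(Cm-1)/2 node count; the class ordering is chosen greedily so that
the highest-rate tasks occupy the levels nearest the root.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hmm import (DEFAULT_GAUSS_GRID, DEFAULT_STATES_GRID, HmmModel,
                  TrainSpec, cached_train, search_model_space,
                  viterbi_loglik)

logger = logging.getLogger("meowdag")


@dataclass
class DagTask:
    """One pairwise classification task with its selected models and rate."""

    pair: tuple[str, str]              # sorted class pair
    rate: float
    models: dict[str, HmmModel] | None = None
    config: tuple[int, int] | None = None      # selected (S, g)

    def __post_init__(self) -> None:
        a, b = self.pair
        if a == b:
            raise ValueError("a task needs two distinct classes")
        self.pair = tuple(sorted(self.pair))
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must be in [0, 1]")


@dataclass
class DagModel:
    """Ordered class list + one task per pair; nodes are list intervals."""

    class_order: list[str]
    tasks: dict[tuple[str, str], DagTask]
    split_record: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate_structure()

    @property
    def classes(self) -> set[str]:
        return set(self.class_order)

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    @property
    def n_nodes(self) -> int:
        c = self.n_classes
        return c * (c - 1) // 2

    def nodes(self) -> list[tuple[int, int]]:
        """All internal nodes as intervals (i, j), i < j, of the class list."""
        c = self.n_classes
        return [(i, j) for i in range(c) for j in range(i + 1, c)]

    def node_task(self, i: int, j: int) -> DagTask:
        pair = tuple(sorted((self.class_order[i], self.class_order[j])))
        return self.tasks[pair]

    def children(self, i: int, j: int) -> tuple[tuple[int, int] | str,
                                                tuple[int, int] | str]:
        """The two outgoing links of node (i, j); leaves are class labels."""
        left = (i, j - 1) if j - 1 > i else self.class_order[i]
        right = (i + 1, j) if i + 1 < j else self.class_order[j]
        return left, right

    def validate_structure(self) -> None:
        c = self.n_classes
        pairs = {tuple(sorted(p)) for p in self.tasks}
        want = {tuple(sorted((a, b)))
                for k, a in enumerate(self.class_order)
                for b in self.class_order[k + 1:]}
        if pairs != want:
            raise ValueError("tasks must cover every class pair exactly once")
        assert len(self.nodes()) == c * (c - 1) // 2

    def to_dict(self) -> dict:
        return {
            "class_order": self.class_order,
            "seed": self.seed,
            "split_record": self.split_record,
            "tasks": [{"pair": list(t.pair), "rate": t.rate,
                       "config": list(t.config) if t.config else None,
                       "models": {k: m.to_dict()
                                  for k, m in (t.models or {}).items()}}
                      for t in self.tasks.values()],
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "DagModel":
        tasks = {}
        for t in d["tasks"]:
            pair = tuple(t["pair"])
            tasks[pair] = DagTask(
                pair, t["rate"],
                models={k: HmmModel.from_dict(m)
                        for k, m in t["models"].items()} or None,
                config=tuple(t["config"]) if t.get("config") else None)
        return cls(d["class_order"], tasks, d.get("split_record", {}),
                   d.get("seed", 0))

    def to_dot(self) -> str:
        """GraphViz DOT rendering of G for documentation."""
        lines = ["digraph G {", "  rankdir=TB;"]
        for (i, j) in self.nodes():
            t = self.node_task(i, j)
            lines.append(f'  "n{i}_{j}" [label="{t.pair[0]} vs {t.pair[1]}'
                         f'\\nrate={t.rate:.2f}"];')
        for (i, j) in self.nodes():
            for child in self.children(i, j):
                tgt = (f"n{child[0]}_{child[1]}" if isinstance(child, tuple)
                       else f"leaf_{child}")
                lines.append(f'  "n{i}_{j}" -> "{tgt}";')
        for lab in self.class_order:
            lines.append(f'  "leaf_{lab}" [shape=box, label="{lab}"];')
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# topological ordering of the tasks
# ---------------------------------------------------------------------------

def split_train_validation(ids: Sequence[str], labels: dict[str, str],
                           val_fraction: float = 0.2, seed: int = 0
                           ) -> tuple[list[str], list[str]]:
    """Stratified TS/VS split of the training fold (default 80/20).

    Each class is shuffled by a generator seeded from (seed, member ids),
    so the split depends only on which clips share a class — renaming the
    class labels permutes nothing (label equivariance).
    """
    ts: list[str] = []
    vs: list[str] = []
    by_class: dict[str, list[str]] = {}
    for cid in ids:
        by_class.setdefault(labels[cid], []).append(cid)
    for lab in sorted(by_class):
        members = sorted(by_class[lab])
        rng = np.random.default_rng(
            [seed, zlib.crc32("|".join(members).encode())])
        rng.shuffle(members)
        n_val = max(1, int(round(val_fraction * len(members))))
        if len(members) - n_val < 1:
            raise ValueError(f"class {lab!r} too small to split "
                             f"({len(members)} clips)")
        vs.extend(members[:n_val])
        ts.extend(members[n_val:])
    return ts, vs


def order_tasks(sequences: dict[str, np.ndarray], labels: dict[str, str],
                states_grid: Sequence[int] = DEFAULT_STATES_GRID,
                gauss_grid: Sequence[int] = DEFAULT_GAUSS_GRID,
                spec: TrainSpec | None = None, val_fraction: float = 0.2,
                seed: int = 0, cache: dict | None = None) -> list[DagTask]:
    """Rank all pairwise tasks by descending validation recognition rate.

    For every class pair the HMM model space is explored on TS and scored on
    VS; the returned list is sorted by descending rate, ties broken by
    lexicographic pair order.  Deterministic given ``seed``.  A class shared
    by two pair tasks is modelled on the same TS data, so those trainings
    are memoized (``cache`` additionally shares them with other callers).
    """
    spec = spec or TrainSpec(seed=seed)
    classes = sorted(set(labels[c] for c in sequences))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    ts, vs = split_train_validation(sorted(sequences), labels,
                                    val_fraction, seed)
    ts_lab = {labels[c] for c in ts}
    vs_lab = {labels[c] for c in vs}
    missing = (set(classes) - ts_lab) | (set(classes) - vs_lab)
    if missing:
        raise ValueError(f"classes {sorted(missing)} missing from TS or VS")

    cache = cache if cache is not None else {}
    ts_ids = {lab: tuple(c for c in ts if labels[c] == lab)
              for lab in classes}
    trainer = lambda lab, seqs, s, g: cached_train(  # noqa: E731
        cache, (lab, ts_ids[lab]), seqs, s, g, spec)
    tasks = []
    for k, a in enumerate(classes):
        for b in classes[k + 1:]:
            train = {a: [sequences[c] for c in ts if labels[c] == a],
                     b: [sequences[c] for c in ts if labels[c] == b]}
            val = [(sequences[c], labels[c]) for c in vs
                   if labels[c] in (a, b)]
            models, config, rate = search_model_space(
                train, val, states_grid, gauss_grid, spec, trainer=trainer)
            logger.info("task %s vs %s: rate %.3f at (S=%d, g=%d)",
                        a, b, rate, *config)
            tasks.append(DagTask((a, b), rate, models, config))
    tasks.sort(key=lambda t: (-t.rate, t.pair))
    return tasks


# ---------------------------------------------------------------------------
# DAG construction
# ---------------------------------------------------------------------------

def _order_classes(tasks: dict[tuple[str, str], DagTask],
                   classes: list[str]) -> list[str]:
    """Greedy class-list ordering: the highest-rate pair takes the two ends
    (the root task); successive inward positions are filled to maximize the
    rates of the tasks that enter the graph at each level."""
    c = len(classes)
    if c == 2:
        return sorted(classes)

    def rate(a: str, b: str) -> float:
        return tasks[tuple(sorted((a, b)))].rate

    root = sorted(tasks.values(), key=lambda t: (-t.rate, t.pair))[0].pair
    order: list[str | None] = [None] * c
    order[0], order[-1] = root
    remaining = [x for x in classes if x not in root]
    left, right = 1, c - 2
    while left < right:
        best = None
        for u in remaining:
            for v in remaining:
                if u == v:
                    continue
                score = rate(u, order[-1]) + rate(order[0], v)
                if best is None or score > best[0]:
                    best = (score, u, v)
        _, u, v = best
        order[left], order[right] = u, v
        remaining.remove(u)
        remaining.remove(v)
        left, right = left + 1, right - 1
    if left == right:
        order[left] = remaining.pop()
    return order  # type: ignore[return-value]


def build_dag(tasks: Sequence[DagTask], classes: Sequence[str] | None = None,
              seed: int = 0, split_record: dict | None = None) -> DagModel:
    """Assemble the DAG from an ordered task list covering all class pairs."""
    task_map = {t.pair: t for t in tasks}
    if len(task_map) != len(tasks):
        raise ValueError("duplicate task pairs")
    if classes is None:
        classes = sorted({c for t in tasks for c in t.pair})
    classes = sorted(classes)
    want = {tuple(sorted((a, b))) for k, a in enumerate(classes)
            for b in classes[k + 1:]}
    if set(task_map) != want:
        raise ValueError("tasks must cover all class pairs exactly once")
    order = _order_classes(task_map, list(classes))
    return DagModel(order, task_map, split_record or {}, seed)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify(dag: DagModel, features: np.ndarray
             ) -> tuple[str, list[dict]]:
    """Traverse the DAG for one feature sequence.

    Returns the predicted label and the per-node decision trace (both
    log-likelihoods at every visited node).  Exact ties keep the
    lexicographically smaller class, logged.
    """
    i, j = 0, dag.n_classes - 1
    trace: list[dict] = []
    while i < j:
        a, b = dag.class_order[i], dag.class_order[j]
        task = dag.node_task(i, j)
        if task.models is None:
            raise RuntimeError(f"task {task.pair} has no trained models")
        ll = {lab: viterbi_loglik(task.models[lab], features)
              for lab in (a, b)}
        if ll[a] == ll[b]:
            survivor = min(a, b)
            logger.info("loglik tie at node %s; keeping %s", task.pair,
                        survivor)
        else:
            survivor = a if ll[a] > ll[b] else b
        eliminated = b if survivor == a else a
        trace.append(dict(pair=task.pair, loglik=ll, eliminated=eliminated))
        if eliminated == b:
            j -= 1
        else:
            i += 1
    return dag.class_order[i], trace


def classify_batch(dag: DagModel,
                   sequences: dict[str, np.ndarray]) -> dict[str, str]:
    """Traverse the DAG for many clips at once.

    Equivalent to mapping :func:`classify`; every node model scores the
    whole clip set in one batched Viterbi pass before the traversals.
    """
    from .hmm import viterbi_loglik_batch

    ids = sorted(sequences)
    seqs = [sequences[c] for c in ids]
    ll: dict[tuple, np.ndarray] = {}
    for task in dag.tasks.values():
        if task.models is None:
            raise RuntimeError(f"task {task.pair} has no trained models")
        for lab, model in task.models.items():
            ll[(task.pair, lab)] = viterbi_loglik_batch(model, seqs)
    preds = {}
    for n, cid in enumerate(ids):
        i, j = 0, dag.n_classes - 1
        while i < j:
            a, b = dag.class_order[i], dag.class_order[j]
            pair = tuple(sorted((a, b)))
            la, lb = ll[(pair, a)][n], ll[(pair, b)][n]
            survivor = min(a, b) if la == lb else (a if la > lb else b)
            if survivor == a:
                j -= 1
            else:
                i += 1
        preds[cid] = dag.class_order[i]
    return preds


def fit_dag(sequences: dict[str, np.ndarray], labels: dict[str, str],
            states_grid: Sequence[int] = DEFAULT_STATES_GRID,
            gauss_grid: Sequence[int] = DEFAULT_GAUSS_GRID,
            spec: TrainSpec | None = None, val_fraction: float = 0.2,
            refit: bool = True, seed: int = 0,
            cache: dict | None = None) -> DagModel:
    """End-to-end DAG training on one training fold.

    Runs the task ordering (model search on TS, rates on VS), builds the
    graph, and by default refits every node's winning (S, g) configuration
    on TS+VS — the validation part is consumed by selection only.
    """
    spec = spec or TrainSpec(seed=seed)
    tasks = order_tasks(sequences, labels, states_grid, gauss_grid, spec,
                        val_fraction, seed, cache=cache)
    if refit:
        ids_by_class: dict[str, list[str]] = {}
        for cid in sorted(sequences):
            ids_by_class.setdefault(labels[cid], []).append(cid)
        for task in tasks:
            s, g = task.config
            task.models = {
                lab: cached_train(cache, (lab, tuple(ids_by_class[lab])),
                                  [sequences[c] for c in ids_by_class[lab]],
                                  s, g, spec)
                for lab in task.pair}
    classes = sorted({labels[c] for c in sequences})
    return build_dag(tasks, classes, seed,
                     split_record=dict(val_fraction=val_fraction, seed=seed))


class DagHmmClassifier:
    """Cross-validation wrapper around :func:`fit_dag` / :func:`classify`."""

    def __init__(self, states_grid: Sequence[int] = DEFAULT_STATES_GRID,
                 gauss_grid: Sequence[int] = DEFAULT_GAUSS_GRID,
                 spec: TrainSpec | None = None, val_fraction: float = 0.2,
                 refit: bool = True, seed: int = 0,
                 cache: dict | None = None):
        self.states_grid, self.gauss_grid = states_grid, gauss_grid
        self.spec = spec or TrainSpec(seed=seed)
        self.val_fraction, self.refit, self.seed = val_fraction, refit, seed
        self.cache = cache
        self.dag_: DagModel | None = None

    def fit(self, sequences: dict[str, np.ndarray],
            labels: dict[str, str]) -> "DagHmmClassifier":
        self.dag_ = fit_dag(sequences, labels, self.states_grid,
                            self.gauss_grid, self.spec, self.val_fraction,
                            self.refit, self.seed, cache=self.cache)
        return self

    def predict(self, sequences: dict[str, np.ndarray]) -> dict[str, str]:
        return classify_batch(self.dag_, sequences)
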