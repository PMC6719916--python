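"""Ten-fold cross-validation harness: fold plans, recognition rates,
row-normalized confusion matrices and per-class F1.

One :class:`FoldPlan` is built per experiment and passed to every
classifier, so train/test parts are identical across systems and the
comparison is fair.  All model selection and normalization statistics are
computed inside the training side of each fold.

Two aggregate conventions are reported side by side: the clip-weighted
recognition rate (correct / total) and the class-balanced rate (mean of
per-class recalls) — with imbalanced class counts the two can differ, so
both are labelled explicitly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import KFold, StratifiedKFold

from .features import Normalizer

logger = logging.getLogger("meowdag")


@dataclass
class FoldPlan:
    """A k-way partition of clip ids (the SAME plan feeds every system)."""

    folds: list[list[str]]
    stratified: bool
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    @property
    def all_ids(self) -> list[str]:
        return [cid for fold in self.folds for cid in fold]

    def plan_hash(self) -> str:
        return hashlib.sha1(json.dumps(self.folds).encode()).hexdigest()[:12]

    def train_test(self, i: int) -> tuple[list[str], list[str]]:
        test = self.folds[i]
        train = [cid for j, fold in enumerate(self.folds) if j != i
                 for cid in fold]
        return train, test


def make_folds(ids: list[str], labels: dict[str, str], k: int = 10,
               stratified: bool = True, seed: int = 0) -> FoldPlan:
    """Deterministic k-fold partition, stratified by class by default."""
    ids = sorted(ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} clips for {k} folds")
    y = [labels[c] for c in ids]
    if stratified:
        counts = pd.Series(y).value_counts()
        small = counts[counts < k]
        if len(small):
            raise ValueError(
                f"classes {list(small.index)} have fewer than {k} clips; "
                "use stratified=False")
        splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                   random_state=seed)
        folds = [[ids[i] for i in test]
                 for _, test in splitter.split(ids, y)]
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [[ids[i] for i in test] for _, test in splitter.split(ids)]
    return FoldPlan(folds, stratified, seed)


@dataclass
class EvalReport:
    """Aggregated cross-validation outcome for one classifier."""

    classifier_id: str
    predictions: dict[str, str]          # clip id -> predicted label
    truth: dict[str, str]
    fold_of: dict[str, int]
    classes: list[str]
    plan_hash: str
    seed: int = 0
    config_hash: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def recognition_rate(self) -> float:
        """Clip-weighted rate, percent."""
        hits = sum(self.predictions[c] == self.truth[c]
                   for c in self.predictions)
        return 100.0 * hits / len(self.predictions)

    @property
    def balanced_rate(self) -> float:
        """Class-balanced rate (mean per-class recall), percent."""
        return float(np.mean([row[lab] for lab, row in
                              self.confusion_matrix().iterrows()]))

    def confusion_matrix(self) -> pd.DataFrame:
        """Row-normalized (%) confusion matrix: rows are true classes."""
        mat = pd.DataFrame(0.0, index=self.classes, columns=self.classes)
        for cid, pred in self.predictions.items():
            mat.loc[self.truth[cid], pred] += 1
        sums = mat.sum(axis=1)
        return mat.div(sums.replace(0, np.nan), axis=0) * 100.0

    def per_class_scores(self) -> pd.DataFrame:
        """Precision/recall/F1 from pooled cross-fold counts."""
        ids = sorted(self.predictions)
        p, r, f, s = precision_recall_fscore_support(
            [self.truth[c] for c in ids],
            [self.predictions[c] for c in ids],
            labels=self.classes, zero_division=0)
        return pd.DataFrame({"precision": p, "recall": r, "f1": f,
                             "support": s}, index=self.classes)

    def fold_rates(self) -> list[float]:
        k = max(self.fold_of.values()) + 1
        out = []
        for i in range(k):
            members = [c for c in self.predictions if self.fold_of[c] == i]
            hits = sum(self.predictions[c] == self.truth[c] for c in members)
            out.append(100.0 * hits / len(members) if members else np.nan)
        return out

    def to_dict(self) -> dict:
        return {"classifier": self.classifier_id,
                "recognition_rate": self.recognition_rate,
                "balanced_rate": self.balanced_rate,
                "confusion": self.confusion_matrix().round(4).to_dict(),
                "per_class": self.per_class_scores().round(4).to_dict(),
                "fold_rates": self.fold_rates(),
                "plan_hash": self.plan_hash, "seed": self.seed,
                "config_hash": self.config_hash,
                "predictions": self.predictions}

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def text_table(self) -> str:
        lines = [f"classifier: {self.classifier_id}",
                 f"recognition rate (clip-weighted): "
                 f"{self.recognition_rate:.2f}%",
                 f"recognition rate (class-balanced): "
                 f"{self.balanced_rate:.2f}%",
                 "", "confusion matrix (row %):",
                 self.confusion_matrix().round(2).to_string(),
                 "", "per-class scores:",
                 self.per_class_scores().round(3).to_string()]
        return "\n".join(lines)


class OracleClassifier:
    """Returns the true labels (harness arithmetic checks)."""

    def __init__(self, labels: dict[str, str]):
        self.labels = labels

    def fit(self, sequences, labels):
        return self

    def predict(self, sequences):
        return {cid: self.labels[cid] for cid in sequences}


class ConstantClassifier:
    """Always predicts one fixed label."""

    def __init__(self, label: str):
        self.label = label

    def fit(self, sequences, labels):
        return self

    def predict(self, sequences):
        return {cid: self.label for cid in sequences}


def run_cv(classifier_factory, sequences: dict[str, np.ndarray],
           labels: dict[str, str], plan: FoldPlan,
           classifier_id: str = "", normalize: bool = True,
           seed: int = 0) -> EvalReport:
    """Run one classifier through the fold plan.

    ``classifier_factory(fold_index)`` must return an object with
    ``fit(sequences, labels)`` and ``predict(sequences) -> {id: label}``.
    Per-dimension z-normalization statistics are fit on the training side
    of each fold and applied to both sides.
    """
    predictions: dict[str, str] = {}
    fold_of: dict[str, int] = {}
    for i in range(plan.k):
        train_ids, test_ids = plan.train_test(i)
        if normalize:
            norm = Normalizer().fit([sequences[c] for c in train_ids])
            tr = {c: norm.transform(sequences[c]) for c in train_ids}
            te = {c: norm.transform(sequences[c]) for c in test_ids}
        else:
            tr = {c: sequences[c] for c in train_ids}
            te = {c: sequences[c] for c in test_ids}
        clf = classifier_factory(i)
        try:
            clf.fit(tr, labels)
            preds = clf.predict(te)
        except Exception as exc:
            raise RuntimeError(
                f"classifier {classifier_id or clf!r} failed on fold {i}: "
                f"{exc}") from exc
        predictions.update(preds)
        fold_of.update({c: i for c in test_ids})
        logger.info("%s fold %d/%d: %.1f%%", classifier_id, i + 1, plan.k,
                    100.0 * np.mean([preds[c] == labels[c] for c in test_ids]))
    classes = sorted(set(labels[c] for c in predictions))
    return EvalReport(classifier_id or type(clf).__name__, predictions,
                      {c: labels[c] for c in predictions}, fold_of, classes,
                      plan.plan_hash(), seed=seed)


def compare_systems(reports: list[EvalReport]) -> pd.DataFrame:
    """Rank systems by recognition rate over the identical fold plan.

    Also reports per-fold paired accuracy differences of each system
    against the top-ranked one.
    """
    if not reports:
        raise ValueError("no reports to compare")
    hashes = {r.plan_hash for r in reports}
    if len(hashes) > 1:
        raise ValueError("reports use different fold plans; "
                         "comparison is invalid")
    rows = sorted(reports, key=lambda r: (-r.recognition_rate,
                                          r.classifier_id))
    top = np.array(rows[0].fold_rates())
    table = pd.DataFrame({
        "classifier": [r.classifier_id for r in rows],
        "recognition_rate": [r.recognition_rate for r in rows],
        "balanced_rate": [r.balanced_rate for r in rows],
        "mean_fold_diff_vs_top": [
            float(np.nanmean(np.array(r.fold_rates()) - top)) for r in rows],
    })
    return table.set_index("classifier")
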