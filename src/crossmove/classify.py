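"""Person identification by SVM with grid search, metrics and baseline.

The protocol: an extensive 5-fold cross-validated grid search over four
kernels (linear, radial-basis, sigmoid, polynomial) and a cost grid
C = 2^-5, 2^-4.75, ..., 2^15 (81 values, 324 configurations), selecting
the configuration with the best mean fold accuracy and refitting it on
all training data.  Evaluation reports the confusion matrix, accuracy,
and macro-averaged precision / recall / F1, all in percent, alongside
the zero-rule baseline (ZRB): the accuracy of always predicting the most
frequent training class, i.e. the chance floor for unbalanced data.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .preprocess import MovementVector

__all__ = [
    "SplitPlan",
    "SvmSearchSpace",
    "ClassificationReport",
    "make_splits",
    "zero_rule_baseline",
    "confusion_metrics",
    "fit_svm",
    "evaluate",
]


@dataclass(frozen=True)
class SplitPlan:
    """90:10 partition of each domain, stratified by subject and condition."""

    fraction_gan_train: float = 0.90
    fraction_heldout: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fraction_heldout < 1:
            raise ValueError("held-out fraction must be in (0, 1)")
        if abs(self.fraction_gan_train + self.fraction_heldout - 1.0) > 1e-9:
            raise ValueError("partition fractions must sum to 1")


@dataclass(frozen=True)
class SvmSearchSpace:
    """Kernel and cost grid of the hyperparameter search."""

    kernels: tuple[str, ...] = ("linear", "rbf", "sigmoid", "poly")
    cost_exponent_start: float = -5.0
    cost_exponent_stop: float = 15.0
    cost_exponent_step: float = 0.25
    folds: int = 5

    def __post_init__(self):
        object.__setattr__(self, "kernels", tuple(self.kernels))
        if self.folds < 2:
            raise ValueError("need at least 2 cross-validation folds")

    @property
    def costs(self) -> np.ndarray:
        exponents = np.arange(self.cost_exponent_start,
                              self.cost_exponent_stop + 1e-9,
                              self.cost_exponent_step)
        return 2.0 ** exponents

    @property
    def n_configurations(self) -> int:
        return len(self.costs) * len(self.kernels)


def make_splits(trials: list, plan: SplitPlan) -> dict[str, list]:
    """Split one domain's trials into ``gan_train`` and ``heldout``.

    Stratified by subject: every subject contributes
    ``round(fraction_heldout * n)`` held-out trials (at least one),
    allocated across that subject's conditions by largest remainder so
    the condition mix of the held-out set mirrors the training set.
    """
    by_subject: dict = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)
    for sid, items in by_subject.items():
        if len(items) < 2:
            raise ValueError(
                f"subject {sid!r} has {len(items)} trial(s); need at least 2")
    rng = np.random.default_rng(plan.seed)
    gan_train, heldout = [], []
    for sid in sorted(by_subject):
        items = by_subject[sid]
        target = max(int(round(plan.fraction_heldout * len(items))), 1)
        by_cond: dict = {}
        for t in items:
            by_cond.setdefault(t.condition, []).append(t)
        conds = sorted(by_cond)
        quotas = np.array([plan.fraction_heldout * len(by_cond[c])
                           for c in conds])
        take = np.floor(quotas).astype(int)
        remainder = quotas - take
        for i in np.argsort(-remainder)[:max(target - take.sum(), 0)]:
            take[i] += 1
        # keep the per-subject total exact even after flooring artifacts
        while take.sum() > target:
            take[np.argmax(take)] -= 1
        for c, n_take in zip(conds, take):
            pool = by_cond[c]
            order = rng.permutation(len(pool))
            n_take = min(n_take, len(pool) - 1)
            heldout.extend(pool[i] for i in order[:n_take])
            gan_train.extend(pool[i] for i in order[n_take:])
    return {"gan_train": gan_train, "heldout": heldout}


def zero_rule_baseline(train_labels) -> float:
    """Accuracy (%) of always predicting the most frequent training class."""
    labels = list(train_labels)
    if not labels:
        raise ValueError("cannot compute a baseline from empty labels")
    modal = Counter(labels).most_common(1)[0][1]
    return 100.0 * modal / len(labels)


def confusion_metrics(confusion: np.ndarray) -> dict[str, float]:
    """Accuracy and macro precision/recall/F1 (%) from a K x K count matrix.

    Rows index true classes, columns predictions.  Per class, one-vs-rest
    TP/FP/FN are counted; classes with no predicted positives get
    precision 0 (and analogously recall 0 without test support); F1 is
    the harmonic mean, 0 when precision + recall = 0.
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0) or not np.issubdtype(cm.dtype, np.number):
        raise ValueError("confusion matrix must hold non-negative counts")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return {
        "accuracy": 100.0 * tp.sum() / total,
        "precision": 100.0 * precision.mean(),
        "recall": 100.0 * recall.mean(),
        "f1": 100.0 * f1.mean(),
    }


def _as_matrix(trials_or_array, labels=None):
    if labels is not None:
        return np.asarray(trials_or_array, dtype=float), list(labels)
    x = np.stack([t.values for t in trials_or_array])
    y = [t.subject_id for t in trials_or_array]
    return x, y


def fit_svm(train, space: SvmSearchSpace = SvmSearchSpace(), seed: int = 0,
            labels=None):
    """Cross-validated grid search, refit on all training data.

    ``train`` is a list of :class:`MovementVector` (labels taken from
    ``subject_id``) or an array with explicit ``labels``.  Ties are
    broken toward smaller cost and earlier kernel in the stated order.
    The training set is brought into a canonical order first, so the
    result does not depend on how trials were collected.
    """
    x, y = _as_matrix(train, labels)
    y = np.asarray(y)
    counts = Counter(y.tolist())
    thin = {c: n for c, n in counts.items() if n < space.folds}
    if thin:
        raise ValueError(
            f"classes with fewer than {space.folds} trials: {thin}")
    order = np.lexsort(np.vstack([x.T, y.reshape(1, -1)]))
    x, y = x[order], y[order]
    grid = [{"C": [c], "kernel": [k]}
            for c in space.costs for k in space.kernels]
    search = GridSearchCV(
        SVC(gamma="scale", degree=3),
        grid,
        scoring="accuracy",
        cv=StratifiedKFold(space.folds, shuffle=True, random_state=seed),
        n_jobs=1,
        refit=True,
    )
    search.fit(x, y)
    chosen = {"kernel": search.best_params_["kernel"],
              "C": float(search.best_params_["C"]),
              "cv_accuracy": 100.0 * float(search.best_score_)}
    return search.best_estimator_, chosen


@dataclass
class ClassificationReport:
    """Outcome of one identification task (percent metrics + metadata)."""

    confusion: np.ndarray
    labels: list
    accuracy: float
    precision: float
    recall: float
    f1: float
    zrb: float
    kernel: str | None = None
    C: float | None = None
    n_train: int = 0
    n_test: int = 0
    task: str = ""

    @property
    def f1_zrb_ratio(self) -> float:
        """How many times better than always guessing the modal class."""
        return self.f1 / self.zrb

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("task", "accuracy", "precision", "recall", "f1", "zrb",
              "kernel", "C", "n_train", "n_test")}
        d["f1_zrb_ratio"] = self.f1_zrb_ratio
        d["labels"] = list(self.labels)
        d["confusion"] = np.asarray(self.confusion).tolist()
        return d

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, default=str))
        return path

    @classmethod
    def load(cls, path) -> "ClassificationReport":
        d = json.loads(Path(path).read_text())
        return cls(confusion=np.asarray(d["confusion"]), labels=d["labels"],
                   accuracy=d["accuracy"], precision=d["precision"],
                   recall=d["recall"], f1=d["f1"], zrb=d["zrb"],
                   kernel=d["kernel"], C=d["C"], n_train=d["n_train"],
                   n_test=d["n_test"], task=d["task"])


def evaluate(model, test, train_labels, labels=None,
             task: str = "", chosen: dict | None = None
             ) -> ClassificationReport:
    """Score a fitted model on test trials against the zero-rule floor.

    Labels unseen in training simply count as misclassifications.
    """
    x, y = _as_matrix(test, labels)
    train_labels = list(train_labels)
    pred = model.predict(x)
    label_set = sorted(set(train_labels) | set(y))
    cm = _sk_confusion(y, pred, labels=label_set)
    metrics = confusion_metrics(cm)
    chosen = chosen or {}
    return ClassificationReport(
        confusion=cm, labels=label_set, zrb=zero_rule_baseline(train_labels),
        kernel=chosen.get("kernel"), C=chosen.get("C"),
        n_train=len(train_labels), n_test=len(y), task=task, **metrics)
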