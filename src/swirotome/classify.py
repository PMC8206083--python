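"""Classification cases and the repeated stratified hold-out harness.

Three escalating schemes, the positive class always being ``effusion``:

* Case 1 — depth-1 decision tree (a single threshold) on mean ROI intensity.
* Case 2 — decision tree on the full 11-feature set.
* Case 3 — 200-tree random forest on the full set, class-weighted and with
  its score threshold tuned on the training subset to maximize balanced
  accuracy.

Validation is 10 independent stratified random 62/38 hold-outs.  The 62/38
division is incompatible with a disjoint 10-fold partition, so "tenfold
hold-out" is read as 10 repetitions.  Splits may be grouped by ear (no ear
straddles train/test; the default) or done at frame level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES, INPUT_SETS

POSITIVE = "effusion"


@dataclass(frozen=True)
class SplitSpec:
    """Repeated stratified hold-out configuration."""

    n_iterations: int = 10
    train_fraction: float = 0.62
    stratified: bool = True
    grouping: str = "ear"  # {"ear", "frame"}
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.grouping not in ("ear", "frame"):
            raise ValueError("grouping must be 'ear' or 'frame'")


@dataclass(frozen=True)
class CaseSpec:
    """One of the three classification scenarios."""

    case_id: int
    input_set: str
    model: str  # {"decision_tree", "random_forest"}
    n_trees: int = 200
    max_depth: int | None = None
    min_samples_leaf: int = 1
    balanced_optimization: bool = False

    def __post_init__(self) -> None:
        if self.case_id not in (1, 2, 3):
            raise ValueError("case_id must be 1, 2 or 3")
        expected = {
            1: ("set1", "decision_tree"),
            2: ("set2", "decision_tree"),
            3: ("set2", "random_forest"),
        }[self.case_id]
        if (self.input_set, self.model) != expected:
            raise ValueError(
                f"case {self.case_id} requires input_set/model {expected}"
            )

    @classmethod
    def case(cls, case_id: int) -> "CaseSpec":
        """Default specification for case 1, 2 or 3."""
        if case_id == 1:
            return cls(1, "set1", "decision_tree", max_depth=1)
        if case_id == 2:
            return cls(2, "set2", "decision_tree", min_samples_leaf=5)
        if case_id == 3:
            return cls(3, "set2", "random_forest", n_trees=200,
                       balanced_optimization=True)
        raise ValueError("case_id must be 1, 2 or 3")


@dataclass
class CaseModel:
    """A fitted case: estimator + feature columns + decision threshold."""

    spec: CaseSpec
    estimator: object
    feature_columns: tuple[str, ...]
    threshold: float = 0.5
    positive_index: int = 1  # column of predict_proba holding the positive class


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _largest_remainder(counts: np.ndarray, fraction: float) -> np.ndarray:
    """Per-class train counts: round(fraction * count) reconciled by largest
    remainder so class counts sum to round(fraction * total)."""
    exact = fraction * counts
    base = np.floor(exact).astype(int)
    total = int(round(fraction * counts.sum()))
    short = total - base.sum()
    order = np.argsort(-(exact - base))
    take = base.copy()
    for i in range(short):
        take[order[i % len(counts)]] += 1
    # never allocate more than the class holds, nor empty a class side
    return np.minimum(take, counts)


def make_splits(
    table: pd.DataFrame, spec: SplitSpec
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate ``n_iterations`` stratified train/test index pairs.

    Indices are positional row indices into ``table``.  With
    ``grouping="ear"`` all frames of an ear land on the same side.
    """
    y = table["label"].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present to split")
    rng = np.random.default_rng(spec.seed)
    splits = []
    for _ in range(spec.n_iterations):
        train_idx: list[np.ndarray] = []
        test_idx: list[np.ndarray] = []
        if spec.grouping == "ear":
            ears = table["ear_id"].to_numpy()
            ear_label = {e: l for e, l in zip(ears, y)}
            uniq = np.array(sorted(ear_label))
            ear_y = np.array([ear_label[e] for e in uniq])
            counts = np.array([(ear_y == c).sum() for c in classes])
            if counts.min() < 2:
                raise ValueError("each class needs >= 2 ears under ear grouping")
            n_train = _largest_remainder(counts, spec.train_fraction)
            train_ears: list[str] = []
            for c, k in zip(classes, n_train):
                pool = uniq[ear_y == c]
                perm = rng.permutation(len(pool))
                train_ears.extend(pool[perm[:k]])
            in_train = np.isin(ears, train_ears)
            train_idx.append(np.flatnonzero(in_train))
            test_idx.append(np.flatnonzero(~in_train))
        else:
            counts = np.array([(y == c).sum() for c in classes])
            n_train = _largest_remainder(counts, spec.train_fraction)
            for c, k in zip(classes, n_train):
                pool = np.flatnonzero(y == c)
                perm = rng.permutation(len(pool))
                train_idx.append(pool[perm[:k]])
                test_idx.append(pool[perm[k:]])
        tr = np.sort(np.concatenate(train_idx))
        te = np.sort(np.concatenate(test_idx))
        splits.append((tr, te))
    return splits


# ---------------------------------------------------------------------------
# Fitting and scoring
# ---------------------------------------------------------------------------

def _class_weight(spec: CaseSpec):
    return "balanced" if spec.balanced_optimization else None


def fit_case(train: pd.DataFrame, case: CaseSpec, seed: int = 0) -> CaseModel:
    """Fit one case on a training table; errors on a single-class table."""
    cols = INPUT_SETS[case.input_set]
    missing = [c for c in cols if c not in train.columns]
    if missing:
        raise ValueError(f"training table lacks feature columns {missing}")
    if len(train) == 0:
        raise ValueError("empty training table")
    X = train[list(cols)].to_numpy(dtype=float)
    y = (train["label"].to_numpy() == POSITIVE).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")

    if case.model == "decision_tree":
        est = DecisionTreeClassifier(
            max_depth=case.max_depth,
            min_samples_leaf=case.min_samples_leaf,
            class_weight=_class_weight(case),
            random_state=seed,
        )
    elif case.model == "random_forest":
        est = RandomForestClassifier(
            n_estimators=case.n_trees,
            max_features="sqrt",
            bootstrap=True,
            oob_score=case.balanced_optimization,
            class_weight=_class_weight(case),
            random_state=seed,
            n_jobs=1,
        )
    else:
        raise ValueError(f"unknown model {case.model!r}")
    est.fit(X, y)
    pos = int(np.flatnonzero(est.classes_ == 1)[0])
    model = CaseModel(case, est, tuple(cols), threshold=0.5, positive_index=pos)
    if case.balanced_optimization:
        # tune on out-of-bag scores when available: in-bag forest scores are
        # memorized and would push the threshold toward the extremes
        oob = getattr(est, "oob_decision_function_", None)
        if oob is not None:
            scores = oob[:, pos]
            keep = ~np.isnan(scores)
            model.threshold = _tune_threshold(scores[keep], y[keep])
        else:
            model.threshold = _tune_threshold(predict_scores(model, train), y)
    return model


def _tune_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Threshold (predict positive when score >= t) maximizing balanced
    accuracy on the given scores."""
    uniq = np.unique(scores)
    candidates = np.concatenate([uniq, [uniq[-1] + 1.0]])
    best_t, best_ba = 0.5, -1.0
    pos = y == 1
    neg = ~pos
    for t in candidates:
        pred = scores >= t
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & neg).sum() / neg.sum()
        ba = 0.5 * (sens + spec)
        if ba > best_ba + 1e-12:
            best_ba, best_t = ba, float(t)
    return best_t


def predict_scores(model: CaseModel, table: pd.DataFrame) -> np.ndarray:
    """Per-frame effusion score in [0, 1] (leaf fraction / forest average)."""
    missing = [c for c in model.feature_columns if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks feature columns {missing}")
    X = table[list(model.feature_columns)].to_numpy(dtype=float)
    proba = model.estimator.predict_proba(X)
    return proba[:, model.positive_index]


def predict_labels(model: CaseModel, table: pd.DataFrame) -> np.ndarray:
    scores = predict_scores(model, table)
    return np.where(scores >= model.threshold, POSITIVE, "no_effusion")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _as_binary(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "SUO":
        return (arr == POSITIVE).astype(int)
    return arr.astype(int)


def confusion_metrics(pred, truth) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and balanced accuracy.

    ``effusion`` (or 1) is the positive class; a truth vector missing a
    class raises instead of silently dividing 0/0.
    """
    p = _as_binary(pred)
    t = _as_binary(truth)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("pred and truth must be equal-length and nonempty")
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth is missing a class; metrics undefined")
    tp = int(((p == 1) & (t == 1)).sum())
    tn = int(((p == 0) & (t == 0)).sum())
    sens = tp / n_pos
    spec = tn / n_neg
    return {
        "accuracy": (tp + tn) / t.size,
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": 0.5 * (sens + spec),
    }


def roc_auc(scores, truth) -> tuple[np.ndarray, float]:
    """ROC points by sweeping all distinct thresholds and trapezoid AUC.

    Returns ``(points, auc)`` where ``points`` is an (m, 2) array of
    (FPR, TPR) running from (0, 0) to (1, 1).  Tied scores contribute half,
    which the trapezoid rule realizes exactly.
    """
    s = np.asarray(scores, dtype=float)
    t = _as_binary(truth)
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined with a single-class truth")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    t_sorted = t[order]
    tps = np.cumsum(t_sorted)
    fps = np.cumsum(1 - t_sorted)
    # keep only the last index of each tied score block
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


# ---------------------------------------------------------------------------
# Evaluation harness
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-iteration and averaged metrics for one case."""

    case_id: int
    per_iteration: pd.DataFrame  # iteration, accuracy, sensitivity, ...
    roc_curves: list[np.ndarray] = field(default_factory=list)
    means: dict[str, float] = field(default_factory=dict)
    intensity_summary: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "per_iteration": self.per_iteration.to_dict(orient="records"),
            "means": self.means,
            "intensity_summary": self.intensity_summary,
            "roc_curves": [c.tolist() for c in self.roc_curves],
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path


METRIC_KEYS = ("accuracy", "sensitivity", "specificity", "balanced_accuracy", "auc")


def evaluate_case(
    table: pd.DataFrame, case: CaseSpec, spec: SplitSpec
) -> EvaluationReport:
    """Run the full repeated hold-out evaluation of one case."""
    splits = make_splits(table, spec)
    records = []
    curves = []
    for it, (tr, te) in enumerate(splits):
        model = fit_case(table.iloc[tr], case, seed=spec.seed + it)
        test = table.iloc[te]
        scores = predict_scores(model, test)
        truth = test["label"].to_numpy()
        pred = np.where(scores >= model.threshold, POSITIVE, "no_effusion")
        m = confusion_metrics(pred, truth)
        points, auc = roc_auc(scores, truth)
        m["auc"] = auc
        m["iteration"] = it
        records.append(m)
        curves.append(points)
    per_iter = pd.DataFrame(records)[["iteration", *METRIC_KEYS]]
    means = {k: float(per_iter[k].mean()) for k in METRIC_KEYS}
    summary = {}
    if "mean_intensity" in table.columns:
        for label, grp in table.groupby("label"):
            v = grp["mean_intensity"].to_numpy(dtype=float)
            summary[str(label)] = {
                "mean": float(v.mean()),
                "median": float(np.median(v)),
                "q1": float(np.quantile(v, 0.25)),
                "q3": float(np.quantile(v, 0.75)),
                "n": int(v.size),
            }
    return EvaluationReport(
        case_id=case.case_id,
        per_iteration=per_iter,
        roc_curves=curves,
        means=means,
        intensity_summary=summary,
    )
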