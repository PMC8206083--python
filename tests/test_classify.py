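import numpy as np
import pandas as pd
import pytest

from swirotome.classify import (
    CaseSpec,
    SplitSpec,
    confusion_metrics,
    evaluate_case,
    fit_case,
    make_splits,
    predict_labels,
    predict_scores,
    roc_auc,
)
from swirotome.features import FEATURE_NAMES


def make_table(n, n_eff, rng, n_ears=None, feature_fn=None):
    """Synthetic feature table with controllable feature-label coupling."""
    labels = np.array(["effusion"] * n_eff + ["no_effusion"] * (n - n_eff))
    rng.shuffle(labels)
    if n_ears is None:
        ears = [f"E{i:03d}" for i in range(n)]
    else:
        ears = [f"E{i % n_ears:03d}" for i in range(n)]
    rows = []
    for i in range(n):
        feats = (
            feature_fn(labels[i], rng)
            if feature_fn
            else {k: rng.normal(5000, 1000) for k in FEATURE_NAMES}
        )
        rows.append(
            {"patient_id": "P", "ear_id": ears[i], "frame_index": i,
             "label": labels[i], **feats}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def test_split_counts_frame_grouping():
    rng = np.random.default_rng(0)
    table = make_table(100, 35, rng)
    spec = SplitSpec(n_iterations=10, grouping="frame", seed=1)
    for tr, te in make_splits(table, spec):
        assert len(tr) == 62 and len(te) == 38
        y_tr = table.iloc[tr]["label"]
        y_te = table.iloc[te]["label"]
        assert (y_tr == "effusion").sum() == 22
        assert (y_te == "effusion").sum() == 13


def test_split_determinism():
    rng = np.random.default_rng(1)
    table = make_table(60, 20, rng)
    spec = SplitSpec(n_iterations=1, grouping="frame", seed=7)
    s1 = make_splits(table, spec)
    s2 = make_splits(table, spec)
    np.testing.assert_array_equal(s1[0][0], s2[0][0])
    np.testing.assert_array_equal(s1[0][1], s2[0][1])


def test_ear_grouping_never_splits_an_ear():
    rng = np.random.default_rng(2)
    table = make_table(120, 40, rng, n_ears=12)
    # frames of one ear share a label: relabel by ear
    ear_label = {e: l for e, l in zip(table.ear_id, table.label)}
    table["label"] = table["ear_id"].map(ear_label)
    if len(set(table[table.label == "effusion"].ear_id)) < 2:
        pytest.skip("degenerate relabeling")
    spec = SplitSpec(n_iterations=5, grouping="ear", seed=3)
    for tr, te in make_splits(table, spec):
        assert not set(table.iloc[tr].ear_id) & set(table.iloc[te].ear_id)


def test_split_stratification_within_one_frame():
    rng = np.random.default_rng(3)
    table = make_table(97, 31, rng)
    frac = 31 / 97
    spec = SplitSpec(n_iterations=10, grouping="frame", seed=5)
    for tr, te in make_splits(table, spec):
        for idx in (tr, te):
            side = table.iloc[idx]
            eff = (side.label == "effusion").sum()
            assert abs(eff - frac * len(side)) <= 1.0


def test_split_single_class_errors():
    rng = np.random.default_rng(4)
    table = make_table(20, 20, rng)
    with pytest.raises(ValueError):
        make_splits(table, SplitSpec())


def test_ear_grouping_needs_two_ears_per_class():
    rng = np.random.default_rng(5)
    table = make_table(40, 20, rng, n_ears=2)
    ear_label = {"E000": "effusion", "E001": "no_effusion"}
    table["label"] = table["ear_id"].map(ear_label)
    with pytest.raises(ValueError, match="2 ears"):
        make_splits(table, SplitSpec(grouping="ear"))


# ---------------------------------------------------------------------------
# Cases
# ---------------------------------------------------------------------------

def _separable_fn(label, rng):
    mean = 1000 if label == "effusion" else 9000
    base = rng.normal(mean, 50)
    return {k: base for k in FEATURE_NAMES}


def test_case1_separable_threshold():
    rng = np.random.default_rng(6)
    table = make_table(80, 30, rng, feature_fn=_separable_fn)
    model = fit_case(table, CaseSpec.case(1), seed=0)
    pred = predict_labels(model, table)
    assert (pred == table["label"].to_numpy()).all()
    thr = model.estimator.tree_.threshold[0]
    assert 1050 < thr < 8950


def test_case_spec_consistency():
    with pytest.raises(ValueError):
        CaseSpec(1, "set2", "decision_tree")
    with pytest.raises(ValueError):
        CaseSpec(3, "set2", "decision_tree")


def test_case3_deterministic():
    rng = np.random.default_rng(7)
    table = make_table(120, 40, rng, feature_fn=_separable_fn)
    m1 = fit_case(table, CaseSpec.case(3), seed=11)
    m2 = fit_case(table, CaseSpec.case(3), seed=11)
    np.testing.assert_array_equal(predict_scores(m1, table),
                                  predict_scores(m2, table))
    assert m1.threshold == m2.threshold


def test_iqr_only_signal_case2_beats_case1():
    # label carried only by the dispersion features; location features noise
    def fn(label, rng):
        feats = {k: rng.normal(5000, 800) for k in FEATURE_NAMES[:8]}
        spread = 900 if label == "effusion" else 300
        feats["iqr"] = rng.normal(spread, 60)
        feats["diff_max_median"] = rng.normal(spread, 60)
        feats["diff_median_min"] = rng.normal(spread, 60)
        return feats

    rng = np.random.default_rng(8)
    table = make_table(400, 140, rng, feature_fn=fn)
    spec = SplitSpec(n_iterations=5, grouping="frame", seed=2)
    ba1 = evaluate_case(table, CaseSpec.case(1), spec).means["balanced_accuracy"]
    ba2 = evaluate_case(table, CaseSpec.case(2), spec).means["balanced_accuracy"]
    assert ba2 >= 0.9
    assert ba1 <= 0.6


def test_single_class_training_errors():
    rng = np.random.default_rng(9)
    table = make_table(30, 30, rng)
    with pytest.raises(ValueError, match="single class"):
        fit_case(table, CaseSpec.case(2), seed=0)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def test_pure_leaf_scores_binary():
    rng = np.random.default_rng(10)
    table = make_table(60, 20, rng, feature_fn=_separable_fn)
    model = fit_case(table, CaseSpec.case(2), seed=0)
    scores = predict_scores(model, table)
    assert set(np.unique(scores)) <= {0.0, 1.0}


def test_identical_stumps_average_to_stump_score():
    # two well-separated clusters: every bootstrap yields the same pure stump
    def fn(label, rng):
        v = 100.0 if label == "effusion" else 15000.0
        return {k: v for k in FEATURE_NAMES}

    rng = np.random.default_rng(11)
    table = make_table(100, 50, rng, feature_fn=fn)
    model = fit_case(table, CaseSpec.case(3), seed=1)
    scores = predict_scores(model, table)
    truth = (table["label"] == "effusion").to_numpy()
    np.testing.assert_allclose(scores, truth.astype(float))


def test_forest_score_equals_mean_of_tree_scores():
    rng = np.random.default_rng(12)
    table = make_table(150, 50, rng, feature_fn=_separable_fn)
    model = fit_case(table, CaseSpec.case(3), seed=3)
    X = table[list(model.feature_columns)].to_numpy(dtype=float)
    per_tree = np.stack(
        [t.predict_proba(X)[:, model.positive_index]
         for t in model.estimator.estimators_]
    )
    np.testing.assert_allclose(predict_scores(model, table),
                               per_tree.mean(axis=0), atol=1e-12)


def test_feature_mismatch_errors():
    rng = np.random.default_rng(13)
    table = make_table(60, 20, rng, feature_fn=_separable_fn)
    model = fit_case(table, CaseSpec.case(2), seed=0)
    with pytest.raises(ValueError, match="lacks feature"):
        predict_scores(model, table[["ear_id", "label", "mean_intensity"]])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def test_confusion_worked_example():
    m = confusion_metrics([1, 0, 0, 0], [1, 1, 0, 0])
    assert m == {
        "accuracy": 0.75,
        "sensitivity": 0.5,
        "specificity": 1.0,
        "balanced_accuracy": 0.75,
    }


def test_confusion_perfect():
    m = confusion_metrics(["effusion", "no_effusion"], ["effusion", "no_effusion"])
    assert all(v == 1.0 for v in m.values())


def test_confusion_missing_class_errors():
    with pytest.raises(ValueError, match="missing a class"):
        confusion_metrics([1, 1], [1, 1])


def test_confusion_random_vs_bruteforce():
    rng = np.random.default_rng(14)
    for _ in range(500):
        n = int(rng.integers(2, 40))
        t = rng.integers(0, 2, n)
        if t.min() == t.max():
            t[0] = 1 - t[0]
        p = rng.integers(0, 2, n)
        m = confusion_metrics(p, t)
        tp = sum(1 for a, b in zip(p, t) if a == 1 and b == 1)
        tn = sum(1 for a, b in zip(p, t) if a == 0 and b == 0)
        fp = sum(1 for a, b in zip(p, t) if a == 1 and b == 0)
        fn = sum(1 for a, b in zip(p, t) if a == 0 and b == 1)
        assert m["accuracy"] == (tp + tn) / n
        assert m["sensitivity"] == tp / (tp + fn)
        assert m["specificity"] == tn / (tn + fp)
        assert m["balanced_accuracy"] == pytest.approx(
            (m["sensitivity"] + m["specificity"]) / 2
        )


def test_auc_perfect_and_ties():
    _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert auc == 1.0
    _, auc = roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
    assert auc == 0.5


def test_roc_points_monotone():
    rng = np.random.default_rng(15)
    scores = rng.uniform(size=50)
    truth = rng.integers(0, 2, 50)
    truth[0], truth[1] = 0, 1
    points, _ = roc_auc(scores, truth)
    assert tuple(points[0]) == (0.0, 0.0)
    assert tuple(points[-1]) == (1.0, 1.0)
    assert (np.diff(points[:, 0]) >= 0).all()
    assert (np.diff(points[:, 1]) >= 0).all()


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


def test_auc_matches_mannwhitney_oracle():
    rng = np.random.default_rng(16)
    for _ in range(200):
        n = int(rng.integers(4, 60))
        t = rng.integers(0, 2, n)
        if t.min() == t.max():
            t[0] = 1 - t[0]
        s = np.round(rng.uniform(size=n), int(rng.integers(1, 4)))
        _, auc = roc_auc(s, t)
        pos = s[t == 1]
        neg = s[t == 0]
        gt = sum(1.0 for a in pos for b in neg if a > b)
        eq = sum(0.5 for a in pos for b in neg if a == b)
        expected = (gt + eq) / (len(pos) * len(neg))
        assert abs(auc - expected) < 1e-12


# ---------------------------------------------------------------------------
# Evaluation harness
# ---------------------------------------------------------------------------

def test_single_iteration_equals_manual_chain():
    rng = np.random.default_rng(17)
    table = make_table(200, 70, rng, feature_fn=_separable_fn)
    spec = SplitSpec(n_iterations=1, grouping="frame", seed=9)
    case = CaseSpec.case(3)
    report = evaluate_case(table, case, spec)

    tr, te = make_splits(table, spec)[0]
    model = fit_case(table.iloc[tr], case, seed=spec.seed)
    scores = predict_scores(model, table.iloc[te])
    pred = np.where(scores >= model.threshold, "effusion", "no_effusion")
    m = confusion_metrics(pred, table.iloc[te]["label"].to_numpy())
    _, auc = roc_auc(scores, table.iloc[te]["label"].to_numpy())
    row = report.per_iteration.iloc[0]
    for key, val in m.items():
        assert row[key] == pytest.approx(val)
    assert row["auc"] == pytest.approx(auc)


def test_report_structure_and_determinism(default_table):
    spec = SplitSpec(n_iterations=2, seed=1)
    r1 = evaluate_case(default_table, CaseSpec.case(2), spec)
    r2 = evaluate_case(default_table, CaseSpec.case(2), spec)
    pd.testing.assert_frame_equal(r1.per_iteration, r2.per_iteration)
    assert r1.means == r2.means
    assert len(r1.per_iteration) == 2
    assert set(r1.intensity_summary) == {"effusion", "no_effusion"}
    assert all(0 <= v <= 1 for v in r1.means.values())


def test_balanced_accuracy_identity(case_reports):
    for rep in case_reports.values():
        pi = rep.per_iteration
        np.testing.assert_allclose(
            pi["balanced_accuracy"],
            (pi["sensitivity"] + pi["specificity"]) / 2,
        )
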