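"""Metrics, ROC/AUC vs the Mann-Whitney oracle, split planning, comparison."""

import numpy as np
import pandas as pd
import pytest

from cytogan import evalstats
from cytogan.evalstats import (ConfusionMatrix2x2, SplitPlan, UndefinedMetricError,
                               comparison_table, confusion, make_splits, roc_auc,
                               summary_metrics)


def _records(scores, labels):
    return pd.DataFrame({"score": scores, "true_label": labels})


def _published_records():
    """Prediction records reproducing the published 620-image confusion matrix."""
    rows = ([(0.2, "benign")] * 261 + [(0.8, "benign")] * 45
            + [(0.2, "malignant")] * 46 + [(0.8, "malignant")] * 268)
    return _records(*zip(*rows))


def test_confusion_reproduces_published_matrix():
    m = confusion(_published_records(), 0.5)
    assert (m.tn, m.fp, m.fn, m.tp) == (261, 45, 46, 268)


def test_confusion_edge_cutoffs():
    r = _records([0.3, 0.7, 0.4, 0.9], ["benign", "benign", "malignant", "malignant"])
    m = confusion(r, 0.0)
    assert m.tn == 0 and m.fn == 0 and m.tp == 2 and m.fp == 2
    perfect = _records([0.1, 0.9], ["benign", "malignant"])
    m = confusion(perfect, 0.5)
    assert m.fp == m.fn == 0


def test_tie_at_cutoff_counts_as_malignant():
    m = confusion(_records([0.5], ["malignant"]), 0.5)
    assert m.tp == 1


def test_summary_metrics_published_values():
    sens, spec, acc = summary_metrics(ConfusionMatrix2x2(tn=261, fp=45, fn=46, tp=268))
    assert round(acc, 3) == 0.853
    assert round(sens, 3) == 0.854
    assert round(spec, 3) == 0.853


def test_summary_metrics_perfect_and_undefined():
    assert summary_metrics(ConfusionMatrix2x2(10, 0, 0, 10)) == (1.0, 1.0, 1.0)
    with pytest.raises(UndefinedMetricError):
        summary_metrics(ConfusionMatrix2x2(5, 5, 0, 0))


def test_accuracy_is_convex_combination_of_sens_spec():
    m = ConfusionMatrix2x2(261, 45, 46, 268)
    sens, spec, acc = summary_metrics(m)
    assert min(sens, spec) <= acc <= max(sens, spec)


def test_roc_extremes():
    perfect = _records([0.1, 0.2, 0.8, 0.9],
                       ["benign", "benign", "malignant", "malignant"])
    assert roc_auc(perfect).auc == 1.0
    flat = _records([0.5] * 6, ["benign"] * 3 + ["malignant"] * 3)
    assert roc_auc(flat).auc == 0.5
    with pytest.raises(UndefinedMetricError):
        roc_auc(_records([0.5, 0.6], ["benign", "benign"]))


def _mann_whitney_auc(scores, labels):
    """Oracle: P(random positive outscores random negative), ties = 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == "malignant"]
    neg = [s for s, l in zip(scores, labels) if l == "benign"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_equals_mann_whitney_oracle():
    rng = np.random.default_rng(42)
    for trial in range(5):
        scores = np.round(rng.uniform(0, 1, 50), 2)  # rounding forces ties
        labels = rng.choice(["benign", "malignant"], 50).tolist()
        if len(set(labels)) < 2:
            continue
        curve = roc_auc(_records(scores, labels))
        assert abs(curve.auc - _mann_whitney_auc(scores, labels)) < 1e-9


def test_roc_curve_endpoints_and_monotonicity():
    rng = np.random.default_rng(7)
    curve = roc_auc(_records(rng.uniform(0, 1, 80),
                             rng.choice(["benign", "malignant"], 80)))
    assert curve.fpr[0] == 0 and curve.tpr[0] == 0
    assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
    assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()


def _manifest(n, n_cases=40, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.where(np.arange(n) < n * 0.49, "benign", "malignant")
    return pd.DataFrame({
        "path": [f"p{i}.png" for i in range(n)],
        "case_id": rng.integers(0, n_cases, n).astype(str),
        "label": labels,
        "split": "unassigned",
    })


def test_make_splits_published_pool_size():
    """A 793-patch manifest with a 173-patch holdout leaves a 620-patch pool."""
    assigned = make_splits(_manifest(793), SplitPlan(validation_holdout=173, seed=1,
                                                    grouping="patch"))
    counts = assigned["split"].value_counts()
    assert counts["validation"] == 173
    assert sum(counts[f"fold{k}"] for k in range(3)) == 620


def test_folds_partition_the_pool():
    assigned = make_splits(_manifest(400), SplitPlan(validation_holdout=100, grouping="patch"))
    pool = assigned[assigned["split"].str.startswith("fold")]
    assert len(pool) == 300
    assert set(assigned["split"]) == {"validation", "fold0", "fold1", "fold2"}


def test_case_grouping_keeps_cases_in_one_fold():
    assigned = make_splits(_manifest(400), SplitPlan(validation_holdout=100, grouping="case"))
    pool = assigned[assigned["split"].str.startswith("fold")]
    assert (pool.groupby("case_id")["split"].nunique() == 1).all()


def test_make_splits_deterministic_and_stratified():
    plan = SplitPlan(validation_holdout=100, grouping="patch", seed=5)
    a = make_splits(_manifest(400), plan)
    b = make_splits(_manifest(400), plan)
    assert a["split"].equals(b["split"])
    hold = a[a["split"] == "validation"]
    frac = (hold["label"] == "malignant").mean()
    overall = (a["label"] == "malignant").mean()
    assert abs(frac - overall) < 0.05


def test_make_splits_requires_enough_patches():
    with pytest.raises(ValueError):
        make_splits(_manifest(150), SplitPlan(validation_holdout=173))


def test_pooled_confusion_equals_sum_of_fold_confusions():
    rng = np.random.default_rng(3)
    parts = []
    for _ in range(3):
        parts.append(_records(rng.uniform(0, 1, 40),
                              rng.choice(["benign", "malignant"], 40)))
    pooled = confusion(pd.concat(parts, ignore_index=True))
    total = ConfusionMatrix2x2(0, 0, 0, 0)
    for p in parts:
        total = total + confusion(p)
    assert pooled == total


def test_comparison_table_published_deltas():
    """Accuracy and specificity gains of progressive-GAN pretraining vs ImageNet."""
    published = {
        "ImageNet": {"sensitivity": 0.850, "specificity": 0.768, "accuracy": 0.810, "auc": 0.872},
        "DCGAN": {"sensitivity": 0.793, "specificity": 0.797, "accuracy": 0.795, "auc": 0.867},
        "PGGAN": {"sensitivity": 0.854, "specificity": 0.853, "accuracy": 0.853, "auc": 0.901},
    }
    table = comparison_table(published, baseline="ImageNet")
    assert round(table.loc["PGGAN", "delta_accuracy"], 3) == 0.043
    assert round(table.loc["PGGAN", "delta_specificity"], 3) == 0.085
    assert (table.loc["ImageNet", [c for c in table.columns if c.startswith("delta")]] == 0).all()


def test_comparison_table_identical_methods_zero_delta():
    rep = {"sensitivity": 0.8, "specificity": 0.8, "accuracy": 0.8, "auc": 0.9}
    table = comparison_table({"ImageNet": rep, "PGGAN": dict(rep)})
    assert table.loc["PGGAN", "delta_accuracy"] == 0.0
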