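"""Confusion-matrix metrics, ROC/AUC, split planning and the method comparison.

Benign is the negative class, malignant the positive class.  A prediction is
malignant when its score is at or above the cut-off (default 0.5; ties go to
malignant, favoring sensitivity in a screening context).  Fold predictions
are pooled into a single confusion matrix before metrics are computed, so the
reported accuracy corresponds to one matrix over the whole evaluation pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

POSITIVE = "malignant"
NEGATIVE = "benign"


class UndefinedMetricError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self):
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def __add__(self, other: "ConfusionMatrix2x2") -> "ConfusionMatrix2x2":
        return ConfusionMatrix2x2(self.tn + other.tn, self.fp + other.fp,
                                  self.fn + other.fn, self.tp + other.tp)


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class SplitPlan:
    validation_holdout: int = 173
    cv_folds: int = 3
    grouping: str = "case"  # or "patch"
    seed: int = 0

    def __post_init__(self):
        if self.grouping not in ("case", "patch"):
            raise ValueError("grouping must be 'case' or 'patch'")


def _check_records(records: pd.DataFrame) -> None:
    labels = set(records["true_label"].unique())
    if not labels.issubset({POSITIVE, NEGATIVE}):
        raise ValueError(f"unknown labels {labels - {POSITIVE, NEGATIVE}}")


def confusion(records: pd.DataFrame, cutoff: float = 0.5) -> ConfusionMatrix2x2:
    """Pool prediction records (columns score, true_label) into a 2x2 matrix."""
    if len(records) == 0:
        raise ValueError("no prediction records")
    _check_records(records)
    pos = records["true_label"].to_numpy() == POSITIVE
    pred_pos = records["score"].to_numpy() >= cutoff
    return ConfusionMatrix2x2(
        tn=int((~pos & ~pred_pos).sum()),
        fp=int((~pos & pred_pos).sum()),
        fn=int((pos & ~pred_pos).sum()),
        tp=int((pos & pred_pos).sum()),
    )


def summary_metrics(m: ConfusionMatrix2x2) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy); errors on an empty class row."""
    if m.tp + m.fn == 0 or m.tn + m.fp == 0:
        raise UndefinedMetricError("a class row of the confusion matrix is empty")
    sensitivity = m.tp / (m.tp + m.fn)
    specificity = m.tn / (m.tn + m.fp)
    accuracy = (m.tp + m.tn) / m.total
    return sensitivity, specificity, accuracy


def roc_auc(records: pd.DataFrame) -> RocCurve:
    """ROC by sweeping the cut-off over distinct scores; trapezoidal AUC.

    Equal scores collapse into one step, which makes the trapezoidal area
    equal to the Mann-Whitney statistic with ties counted 1/2.
    """
    _check_records(records)
    y = (records["true_label"].to_numpy() == POSITIVE).astype(int)
    if y.min() == y.max():
        raise UndefinedMetricError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, records["score"].to_numpy())
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


def make_splits(manifest: pd.DataFrame, plan: SplitPlan) -> pd.DataFrame:
    """Assign each manifest row to 'validation' or a CV fold 'fold0..k-1'.

    The holdout is sampled stratified by label at patch level; the remaining
    evaluation pool is split into ``cv_folds`` stratified folds, keeping all
    patches of a case together when grouping='case'.  Rows labeled 'excluded'
    are ignored (split 'excluded').
    """
    usable = manifest[manifest["label"].isin([POSITIVE, NEGATIVE])]
    if len(usable) <= plan.validation_holdout:
        raise ValueError(
            f"manifest has {len(usable)} usable patches, need more than the "
            f"{plan.validation_holdout}-patch holdout")
    rng = np.random.default_rng(plan.seed)

    split = pd.Series("excluded", index=manifest.index, dtype=object)
    # stratified holdout, proportional per label, largest-remainder on ties
    idx = usable.index.to_numpy()
    labels = usable["label"].to_numpy()
    n_hold = plan.validation_holdout
    holdout = []
    by_label = {lab: idx[labels == lab] for lab in np.unique(labels)}
    quotas = {lab: n_hold * len(v) / len(idx) for lab, v in by_label.items()}
    base = {lab: int(np.floor(q)) for lab, q in quotas.items()}
    rem = n_hold - sum(base.values())
    for lab in sorted(quotas, key=lambda l: quotas[l] - base[l], reverse=True)[:rem]:
        base[lab] += 1
    for lab, members in sorted(by_label.items()):
        take = rng.choice(members, size=base[lab], replace=False)
        holdout.extend(take.tolist())
    split.loc[holdout] = "validation"

    pool = usable.drop(index=holdout)
    y = (pool["label"] == POSITIVE).astype(int).to_numpy()
    if plan.grouping == "case":
        splitter = StratifiedGroupKFold(n_splits=plan.cv_folds, shuffle=True,
                                        random_state=int(rng.integers(2**31)))
        folds = splitter.split(np.zeros(len(pool)), y, groups=pool["case_id"].to_numpy())
    else:
        splitter = StratifiedKFold(n_splits=plan.cv_folds, shuffle=True,
                                   random_state=int(rng.integers(2**31)))
        folds = splitter.split(np.zeros(len(pool)), y)
    for k, (_, test_idx) in enumerate(folds):
        split.loc[pool.index[test_idx]] = f"fold{k}"

    out = manifest.copy()
    out["split"] = split
    return out


@dataclass
class EvalReport:
    matrix: ConfusionMatrix2x2
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    roc: RocCurve | None = None

    @classmethod
    def from_records(cls, records: pd.DataFrame, cutoff: float = 0.5) -> "EvalReport":
        m = confusion(records, cutoff)
        sens, spec, acc = summary_metrics(m)
        curve = roc_auc(records)
        return cls(matrix=m, sensitivity=sens, specificity=spec,
                   accuracy=acc, auc=curve.auc, roc=curve)


def comparison_table(reports: dict[str, "EvalReport | dict"],
                     baseline: str = "ImageNet") -> pd.DataFrame:
    """Per-method metric table with row-wise deltas against the baseline method.

    ``reports`` maps method name -> EvalReport or a plain dict with keys
    sensitivity/specificity/accuracy/auc (so published rows can be compared).
    """
    rows = {}
    for name, rep in reports.items():
        if isinstance(rep, EvalReport):
            rows[name] = {"sensitivity": rep.sensitivity, "specificity": rep.specificity,
                          "accuracy": rep.accuracy, "auc": rep.auc}
        else:
            rows[name] = {k: float(rep[k]) for k in ("sensitivity", "specificity", "accuracy", "auc")}
    table = pd.DataFrame(rows).T
    if baseline in table.index:
        for col in table.columns:
            table[f"delta_{col}"] = table[col] - table.loc[baseline, col]
    return table


def run_comparison(manifest: pd.DataFrame, methods: dict, plan: SplitPlan,
                   trainer, cutoff: float = 0.5, baseline: str = "ImageNet"):
    """Cross-validated comparison of pretraining methods.

    ``methods`` maps method name -> an opaque method config passed to
    ``trainer(method_config, train_manifest, test_manifest, fold_index)``,
    which must return prediction records (columns score, true_label).
    Per-fold predictions are pooled per method before metrics are computed.
    Returns (table, reports, split_manifest).
    """
    assigned = make_splits(manifest, plan)
    fold_names = [f"fold{k}" for k in range(plan.cv_folds)]
    reports = {}
    for name, cfg in methods.items():
        parts = []
        for k, fold in enumerate(fold_names):
            test = assigned[assigned["split"] == fold]
            train = assigned[assigned["split"].isin([f for f in fold_names if f != fold])]
            parts.append(trainer(cfg, train, test, k))
        pooled = pd.concat(parts, ignore_index=True)
        reports[name] = EvalReport.from_records(pooled, cutoff)
    return comparison_table(reports, baseline=baseline), reports, assigned
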