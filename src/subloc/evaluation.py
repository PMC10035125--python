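"""Binary classification metrics and the holdout + k-fold CV harness.

Six metrics are computed from the confusion counts: sensitivity (recall),
specificity, accuracy, precision, F1 and the Matthews correlation
coefficient. Any metric whose denominator is zero is reported as 0 and named
in ``degenerate`` rather than raised, so reports stay total and
machine-readable. Values live on [0, 1] (MCC on [-1, 1]) internally and are
formatted as percentages only at the reporting edge.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import (OvRDataset, SplitPlan, build_ovr_dataset, make_cv_folds,
                      split_train_test)
from .errors import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float
    mcc: float
    counts: ConfusionCounts | None = None
    degenerate: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict[str, float]:
        return {"sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy,
                "precision": self.precision,
                "f1": self.f1,
                "mcc": self.mcc}

    def as_percent_row(self) -> dict[str, str]:
        """Tabular style: Sn/Sp/Acc/Pre/F1 as two-decimal percentages,
        MCC as a plain coefficient."""
        d = self.as_dict()
        out = {k: f"{100 * v:.2f}" for k, v in d.items() if k != "mcc"}
        out["mcc"] = f"{self.mcc:.3f}"
        return out


def confusion_counts(y_true: Sequence[int],
                     y_pred: Sequence[int]) -> ConfusionCounts:
    """Standard binary confusion counting; positive class = 1."""
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape or yt.size == 0:
        raise ValidationError("y_true and y_pred must be equal-length, >= 1")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()))


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Evaluate the six metric formulas on the confusion counts.

    Sn = tp/(tp+fn); Sp = tn/(fp+tn); Acc = (tp+tn)/total;
    Pre = tp/(tp+fp); F1 = 2*Pre*Sn/(Pre+Sn);
    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)).
    """
    if c.total == 0:
        raise ValidationError("cannot compute metrics on zero samples")
    degenerate: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    sn = ratio(c.tp, c.tp + c.fn, "sensitivity")
    sp = ratio(c.tn, c.fp + c.tn, "specificity")
    acc = (c.tp + c.tn) / c.total
    pre = ratio(c.tp, c.tp + c.fp, "precision")
    f1 = ratio(2 * pre * sn, pre + sn, "f1")
    mcc_den = math.sqrt(float(c.tp + c.fp) * (c.tp + c.fn)
                        * (c.tn + c.fp) * (c.tn + c.fn))
    mcc = ratio(c.tp * c.tn - c.fp * c.fn, mcc_den, "mcc")
    return MetricsReport(sn, sp, acc, pre, f1, mcc, c, tuple(degenerate))


def evaluate_predictions(y_true: Sequence[int],
                         y_pred: Sequence[int]) -> MetricsReport:
    return compute_metrics(confusion_counts(y_true, y_pred))


def mean_report(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Unweighted average of the six metrics across reports (CV mean)."""
    if not reports:
        raise ValidationError("no reports to average")
    keys = reports[0].as_dict().keys()
    means = {k: float(np.mean([r.as_dict()[k] for r in reports]))
             for k in keys}
    return MetricsReport(**means, counts=None,
                         degenerate=tuple(sorted(
                             {d for r in reports for d in r.degenerate})))


@dataclass(frozen=True)
class CVResult:
    location: str
    fold_reports: tuple[MetricsReport, ...]
    mean: MetricsReport
    dataset: OvRDataset
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rep in enumerate(self.fold_reports, 1):
            rows.append({"location": self.location, "split": f"fold{i}",
                         **rep.as_dict()})
        rows.append({"location": self.location, "split": "cv_mean",
                     **self.mean.as_dict()})
        return pd.DataFrame(rows)


def cross_validate(corpus, spec, plan: SplitPlan, tables=None, cfg=None,
                   threshold: float = 0.5) -> CVResult:
    """Run the one-vs-rest CV harness for one location.

    Builds the OvR dataset for ``spec.location`` at ``spec.ratio``, sets the
    holdout fraction aside untouched, then fits ``spec`` on each CV fold's
    fit split and scores its validation split. Returns per-fold reports and
    their unweighted mean; the holdout ids are carried along for a later,
    single, test-set evaluation.
    """
    from .encoders import PseKNCConfig, build_feature_matrix, default_tables
    from .models import train_location_model

    tables = tables or default_tables()
    cfg = cfg or PseKNCConfig()
    ds = build_ovr_dataset(corpus, spec.location, spec.ratio, seed=plan.seed)
    train_ids, test_ids = split_train_test(ds, plan)
    labels = ds.labels()
    fm = build_feature_matrix(corpus.subset(ds.ids), spec.feature_groups,
                              cfg, tables)
    folds = make_cv_folds(train_ids, labels, plan.n_folds, plan.seed)
    reports = []
    for fit_ids, val_ids in folds:
        assert not set(fit_ids) & set(test_ids), "holdout leaked into CV fit"
        scorer = train_location_model(
            fm.data.loc[fit_ids].to_numpy(),
            np.array([labels[i] for i in fit_ids]), spec, seed=plan.seed)
        scores = scorer.score_matrix(fm.data.loc[val_ids].to_numpy())
        y_pred = (scores >= threshold).astype(int)
        reports.append(evaluate_predictions(
            [labels[i] for i in val_ids], y_pred))
    return CVResult(spec.location, tuple(reports), mean_report(reports), ds,
                    tuple(train_ids), tuple(test_ids))
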