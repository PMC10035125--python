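"""End-to-end training, evaluation and prediction over a labeled corpus.

``train_bundle`` reproduces the modelling protocol: for every location it
builds the one-vs-rest dataset at that location's ratio, sets 20% aside as
an untouched holdout, runs stratified five-fold CV on the remainder, refits
the final scorer on the full training side and evaluates it once on the
holdout. The full feature battery is encoded once and sliced per location,
so each scorer still sees exactly its own feature groups.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import (SplitPlan, build_ovr_dataset, make_cv_folds,
                      split_train_test)
from .encoders import (CANONICAL_GROUPS, EncoderTables, FeatureMatrix,
                       PseKNCConfig, build_feature_matrix, default_tables)
from .errors import LengthError, ValidationError
from .evaluation import MetricsReport, evaluate_predictions, mean_report
from .models import (LocationModelSpec, OvRModelBundle, assign_location,
                     predict_scores, train_location_model)
from .sequence_io import LabeledCorpus, NucleotideSequence


def default_specs(locations: Sequence[str],
                  algorithm: str = "RF") -> dict[str, LocationModelSpec]:
    """One spec per location with the default group mapping and ratios."""
    return {loc: LocationModelSpec(loc, algorithm=algorithm)
            for loc in locations}


@dataclass
class TrainResult:
    bundle: OvRModelBundle
    report: pd.DataFrame  # rows: (location, algorithm, split, six metrics)
    holdout: dict[str, tuple[tuple[str, ...], dict[str, int]]]
    """Per location: (holdout ids, id -> binary label), for assignment-level
    evaluation on sequences no scorer saw in training."""


def _derive_seed(seed: int, index: int) -> int:
    return (seed * 1000003 + 7919 * (index + 1)) % (2 ** 31)


def train_bundle(corpus: LabeledCorpus,
                 specs: Mapping[str, LocationModelSpec] | None = None,
                 plan: SplitPlan | None = None,
                 tables: EncoderTables | None = None,
                 cfg: PseKNCConfig | None = None,
                 seed: int = 0,
                 threshold: float = 0.5) -> TrainResult:
    plan = plan or SplitPlan(seed=seed)
    tables = tables or default_tables()
    cfg = cfg or PseKNCConfig()
    specs = dict(specs) if specs else default_specs(corpus.locations)

    union_groups = sorted({g for s in specs.values() for g in s.feature_groups},
                          key=CANONICAL_GROUPS.index)
    full = build_feature_matrix(corpus, union_groups, cfg, tables)

    scorers, schemas = {}, {}
    rows = []
    holdout = {}
    for idx, (loc, spec) in enumerate(specs.items()):
        loc_seed = _derive_seed(seed, idx)
        ds = build_ovr_dataset(corpus, loc, spec.ratio, seed=loc_seed)
        train_ids, test_ids = split_train_test(
            ds, SplitPlan(plan.test_fraction, plan.n_folds, loc_seed))
        labels = ds.labels()
        sub = full.select(ds.ids, spec.feature_groups)
        y_of = lambda ids: np.array([labels[i] for i in ids])

        fold_reports = []
        folds = make_cv_folds(train_ids, labels, plan.n_folds, loc_seed)
        for fit_ids, val_ids in folds:
            assert not set(fit_ids) & set(test_ids)
            scorer = train_location_model(
                sub.data.loc[fit_ids].to_numpy(), y_of(fit_ids), spec,
                seed=loc_seed)
            pred = (scorer.score_matrix(sub.data.loc[val_ids].to_numpy())
                    >= threshold).astype(int)
            fold_reports.append(evaluate_predictions(y_of(val_ids), pred))

        final = train_location_model(
            sub.data.loc[train_ids].to_numpy(), y_of(train_ids), spec,
            seed=loc_seed)
        test_pred = (final.score_matrix(sub.data.loc[test_ids].to_numpy())
                     >= threshold).astype(int)
        test_report = evaluate_predictions(y_of(test_ids), test_pred)

        scorers[loc] = final
        schemas[loc] = sub.schema
        holdout[loc] = (tuple(test_ids), {i: labels[i] for i in test_ids})
        for i, rep in enumerate(fold_reports, 1):
            rows.append({"location": loc, "algorithm": spec.algorithm,
                         "split": f"fold{i}", **rep.as_dict()})
        rows.append({"location": loc, "algorithm": spec.algorithm,
                     "split": "cv_mean",
                     **mean_report(fold_reports).as_dict()})
        rows.append({"location": loc, "algorithm": spec.algorithm,
                     "split": "test", **test_report.as_dict()})

    bundle = OvRModelBundle(dict(specs), scorers, schemas)
    return TrainResult(bundle, pd.DataFrame(rows), holdout)


def predict_corpus(bundle: OvRModelBundle,
                   sequences: Sequence[NucleotideSequence],
                   tables: EncoderTables | None = None,
                   cfg: PseKNCConfig | None = None) -> pd.DataFrame:
    """Score every sequence with every location model and assign by argmax.

    Sequences that fail an encoder precondition (for example, too short) get
    a row flagged ``failed``; the rest proceed.
    """
    tables = tables or default_tables()
    cfg = cfg or PseKNCConfig()
    rows = []
    for seq in sequences:
        row: dict[str, object] = {"id": seq.id}
        try:
            scores = predict_scores(bundle, seq, tables, cfg)
        except (LengthError, ValidationError) as exc:
            for loc in bundle.locations:
                row[f"score_{loc}"] = float("nan")
            row.update(assigned="", tie=False, failed=True, error=str(exc))
            rows.append(row)
            continue
        label, tie = assign_location(scores, bundle.priority)
        for loc in bundle.locations:
            row[f"score_{loc}"] = scores[loc]
        row.update(assigned=label, tie=tie, failed=False, error="")
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def assignment_accuracy(bundle: OvRModelBundle, corpus: LabeledCorpus,
                        ids: Sequence[str],
                        tables: EncoderTables | None = None,
                        cfg: PseKNCConfig | None = None) -> float:
    """Fraction of the given sequences assigned to their true location."""
    sub = corpus.subset(ids)
    pred = predict_corpus(bundle, sub.sequences, tables, cfg)
    truth = sub.labels
    ok = [pred.loc[i, "assigned"] == truth[i]
          for i in sub.ids if not pred.loc[i, "failed"]]
    if not ok:
        raise ValidationError("no sequences could be scored")
    return float(np.mean(ok))
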