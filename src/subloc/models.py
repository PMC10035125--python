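"""Per-location one-vs-rest classifiers, score-based assignment and
feature attribution.

Each location gets its own binary scorer trained on that location's feature
groups only — compositional features (k-mer, PseKNC) for cytoplasm, nucleus
and ER; physicochemical + Z-curve features for the extracellular region and
mitochondria — and an unknown transcript is assigned to the location whose
scorer emits the highest positive-class probability.

Candidate algorithms: decision tree (DT), Gaussian naive Bayes (GNB),
RBF-kernel SVC, random forest (RF), XGBoost (XGB) and LightGBM (LGBM).
Feature attribution uses the boosted models' built-in TreeSHAP contributions
where available, an exactly additive decision-path attribution for sklearn
trees and forests, and a label-free score-permutation fallback otherwise.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataset import CORE_LOCATION_PRIORITY, SplitPlan, default_ratio
from .encoders import (CANONICAL_GROUPS, EncoderTables, FeatureSchema,
                       PseKNCConfig, encode_group)
from .errors import ValidationError
from .sequence_io import NucleotideSequence

ALGORITHMS = ("DT", "GNB", "SVC", "RF", "XGB", "LGBM")
_TREE_ALGOS = {"DT", "RF"}
_BOOSTED_ALGOS = {"XGB", "LGBM"}

#: Location -> feature groups used by its scorer. Compositional features for
#: cytoplasm/nucleus/ER, physicochemical + Z-curve for ExR/mitochondria;
#: locations not listed default to all four groups.
DEFAULT_GROUP_MAP: Mapping[str, tuple[str, ...]] = {
    "cytoplasm": ("kmer", "pseknc"),
    "nucleus": ("kmer", "pseknc"),
    "ER": ("kmer", "pseknc"),
    "ExR": ("physicochemical", "zcurve"),
    "mitochondria": ("physicochemical", "zcurve"),
}


def default_feature_groups(location: str) -> tuple[str, ...]:
    return DEFAULT_GROUP_MAP.get(location, tuple(CANONICAL_GROUPS))


@dataclass(frozen=True)
class LocationModelSpec:
    """What to train for one location: groups, algorithm, hyperparameters,
    positive:negative ratio."""

    location: str
    feature_groups: tuple[str, ...] = ()
    algorithm: str = "RF"
    hyperparams: Mapping[str, object] = field(default_factory=dict)
    ratio: tuple[int, int] = ()  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        if not self.feature_groups:
            object.__setattr__(self, "feature_groups",
                               default_feature_groups(self.location))
        unknown = set(self.feature_groups) - set(CANONICAL_GROUPS)
        if unknown:
            raise ValidationError(f"unknown feature groups {sorted(unknown)}")
        if not self.ratio:
            object.__setattr__(self, "ratio", default_ratio(self.location))


def make_estimator(algorithm: str, hyperparams: Mapping[str, object],
                   seed: int):
    hp = dict(hyperparams)
    if algorithm == "DT":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if algorithm == "GNB":
        return GaussianNB(**hp)
    if algorithm == "SVC":
        hp.setdefault("kernel", "rbf")
        return SVC(probability=True, random_state=seed, **hp)
    if algorithm == "RF":
        hp.setdefault("n_estimators", 200)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if algorithm == "XGB":
        from xgboost import XGBClassifier
        hp.setdefault("n_estimators", 200)
        hp.setdefault("max_depth", 6)
        hp.setdefault("learning_rate", 0.1)
        return XGBClassifier(random_state=seed, n_jobs=1,
                             eval_metric="logloss", verbosity=0, **hp)
    if algorithm == "LGBM":
        from lightgbm import LGBMClassifier
        hp.setdefault("n_estimators", 200)
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **hp)
    raise ValidationError(f"unknown algorithm {algorithm!r}")


@dataclass
class LocationScorer:
    """A fitted binary scorer returning positive-class probabilities.

    Distance-based algorithms (SVC, GNB) see standardized features via the
    stored scaler; tree ensembles train on the raw feature scale.
    """

    algorithm: str
    estimator: object
    scaler: StandardScaler | None
    n_features: int

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValidationError(
                f"expected {self.n_features} features, got {X.shape}")
        return self.scaler.transform(X) if self.scaler is not None else X

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(self._prepare(X))
        pos_col = list(self.estimator.classes_).index(1)
        return np.clip(proba[:, pos_col], 0.0, 1.0)

    def score(self, vector: np.ndarray) -> float:
        return float(self.score_matrix(np.asarray(vector)[None, :])[0])


def train_location_model(X: np.ndarray, y: Sequence[int],
                         spec: LocationModelSpec,
                         seed: int = 0) -> LocationScorer:
    """Fit the spec's algorithm on a (samples x features) matrix with binary
    labels. Fully seeded; both classes must be present and features finite."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValidationError("X and y shapes disagree")
    if not np.isfinite(X).all():
        raise ValidationError("feature matrix contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValidationError("labels contain a single class")
    scaler = None
    if spec.algorithm in ("SVC", "GNB"):
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    est = make_estimator(spec.algorithm, spec.hyperparams, seed)
    est.fit(X, y)
    return LocationScorer(spec.algorithm, est, scaler, X.shape[1])


def tune_hyperparameters(X: np.ndarray, y: Sequence[int],
                         spec: LocationModelSpec,
                         grid: Mapping[str, Sequence[object]],
                         plan: SplitPlan):
    """Exhaustive grid search by stratified-CV accuracy.

    Ties break toward the first grid cell in iteration order. Returns
    (best hyperparameter map, per-cell DataFrame of params and mean score).
    """
    import pandas as pd

    if not grid:
        raise ValidationError("hyperparameter grid is empty")
    base = make_estimator(spec.algorithm, spec.hyperparams, plan.seed)
    known = set(base.get_params())
    unknown = set(grid) - known
    if unknown:
        raise ValidationError(
            f"grid keys unknown to {spec.algorithm}: {sorted(unknown)}")
    cv = StratifiedKFold(n_splits=plan.n_folds, shuffle=True,
                         random_state=plan.seed)
    search = GridSearchCV(base, dict(grid), scoring="accuracy", cv=cv,
                          n_jobs=1)
    search.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
    cells = pd.DataFrame(search.cv_results_["params"])
    cells["mean_cv_accuracy"] = search.cv_results_["mean_test_score"]
    return dict(search.best_params_), cells


# ---------------------------------------------------------------------------
# one-vs-rest bundle

def tie_priority(locations: Sequence[str]) -> tuple[str, ...]:
    """Fixed tie-break order: the five core locations by descending training
    set size, then any further locations alphabetically."""
    core = [loc for loc in CORE_LOCATION_PRIORITY if loc in locations]
    extra = sorted(set(locations) - set(CORE_LOCATION_PRIORITY))
    return tuple(core + extra)


def schema_hash(schema: FeatureSchema) -> str:
    payload = "\n".join(schema.names).encode()
    return hashlib.sha256(payload).hexdigest()


@dataclass
class OvRModelBundle:
    """One fitted scorer per location plus the schema it was trained on."""

    specs: dict[str, LocationModelSpec]
    scorers: dict[str, LocationScorer]
    schemas: dict[str, FeatureSchema]
    priority: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.specs) != set(self.scorers) or set(self.specs) != set(self.schemas):
            raise ValidationError("specs, scorers and schemas must share keys")
        for loc, scorer in self.scorers.items():
            if scorer.n_features != len(self.schemas[loc]):
                raise ValidationError(
                    f"scorer for {loc!r} expects {scorer.n_features} features "
                    f"but its schema has {len(self.schemas[loc])}")
        if not self.priority:
            self.priority = tie_priority(list(self.specs))

    @property
    def locations(self) -> tuple[str, ...]:
        return tuple(self.specs)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "priority": list(self.priority),
            "locations": {
                loc: {
                    "algorithm": spec.algorithm,
                    "feature_groups": list(spec.feature_groups),
                    "hyperparams": dict(spec.hyperparams),
                    "ratio": list(spec.ratio),
                    "schema_hash": schema_hash(self.schemas[loc]),
                } for loc, spec in self.specs.items()},
        }
        (directory / "bundle.json").write_text(
            json.dumps(manifest, indent=2) + "\n")
        for loc in self.specs:
            safe = loc.replace("/", "_")
            (directory / f"schema_{safe}.json").write_text(
                json.dumps(self.schemas[loc].to_json_dict()) + "\n")
            joblib.dump(self.scorers[loc], directory / f"scorer_{safe}.joblib")

    @staticmethod
    def load(directory: str | Path) -> "OvRModelBundle":
        directory = Path(directory)
        manifest = json.loads((directory / "bundle.json").read_text())
        specs, scorers, schemas = {}, {}, {}
        for loc, info in manifest["locations"].items():
            safe = loc.replace("/", "_")
            schema = FeatureSchema.from_json_dict(
                json.loads((directory / f"schema_{safe}.json").read_text()))
            if schema_hash(schema) != info["schema_hash"]:
                raise ValidationError(
                    f"schema hash mismatch for {loc!r}: bundle expects "
                    f"{info['schema_hash'][:12]}...")
            specs[loc] = LocationModelSpec(
                loc, tuple(info["feature_groups"]), info["algorithm"],
                info["hyperparams"], tuple(info["ratio"]))
            scorers[loc] = joblib.load(directory / f"scorer_{safe}.joblib")
            schemas[loc] = schema
        return OvRModelBundle(specs, scorers, schemas,
                              tuple(manifest["priority"]))


def predict_scores(bundle: OvRModelBundle, seq: NucleotideSequence,
                   tables: EncoderTables, cfg: PseKNCConfig | None = None,
                   policy: str = "skip") -> dict[str, float]:
    """Score one sequence with every location's scorer.

    Each feature group is encoded once and reused across the locations that
    request it; each scorer sees exactly its own groups.
    """
    cfg = cfg or PseKNCConfig()
    cache: dict[str, np.ndarray] = {}
    scores: dict[str, float] = {}
    for loc, spec in bundle.specs.items():
        parts = []
        for g in CANONICAL_GROUPS:
            if g not in spec.feature_groups:
                continue
            if g not in cache:
                try:
                    cache[g] = encode_group(seq, g, cfg, tables, policy).values
                except Exception as exc:
                    raise ValidationError(
                        f"encoding group {g!r} failed for sequence "
                        f"{seq.id!r}: {exc}") from exc
            parts.append(cache[g])
        vector = np.concatenate(parts)
        if vector.size != len(bundle.schemas[loc]):
            raise ValidationError(
                f"feature width {vector.size} does not match the schema of "
                f"{loc!r} ({len(bundle.schemas[loc])})")
        scores[loc] = bundle.scorers[loc].score(vector)
    return scores


def assign_location(scores: Mapping[str, float],
                    priority: Sequence[str] | None = None) -> tuple[str, bool]:
    """Argmax assignment with a documented fixed tie-break priority.

    Returns (winning location, tie flag); the flag is set when two or more
    locations share the exact maximum score.
    """
    if not scores:
        raise ValidationError("empty score map")
    order = list(priority) if priority else list(tie_priority(list(scores)))
    for loc in scores:
        if loc not in order:
            order.append(loc)
    best = max(scores.values())
    winners = [loc for loc in order if scores.get(loc) == best]
    return winners[0], len(winners) > 1


# ---------------------------------------------------------------------------
# feature attribution

@dataclass(frozen=True)
class FeatureRanking:
    """Ranked mean-|attribution| per feature plus the attribution method."""

    entries: tuple[tuple[str, float], ...]
    method: str
    base_value: float | None = None


def _sklearn_tree_contributions(tree, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Decision-path (Saabas) attributions for one sklearn tree.

    The change in positive-class fraction between a node and the child the
    sample descends into is credited to the node's split feature; base value
    + per-feature credits reconstruct the leaf probability exactly.
    """
    t = tree.tree_
    value = t.value[:, 0, :].astype(float)
    value = value / value.sum(axis=1, keepdims=True)
    pos = value[:, 1] if value.shape[1] > 1 else value[:, 0]
    path = tree.decision_path(X)
    contrib = np.zeros_like(X, dtype=float)
    for row in range(X.shape[0]):
        nodes = path.indices[path.indptr[row]:path.indptr[row + 1]]
        for parent, child in zip(nodes[:-1], nodes[1:]):
            contrib[row, t.feature[parent]] += pos[child] - pos[parent]
    return contrib, float(pos[0])


def attribution_matrix(scorer: LocationScorer,
                       X: np.ndarray) -> tuple[np.ndarray, float, str]:
    """Per-sample additive attributions (n x features), base value, method.

    Tree models satisfy base + sum(attributions) == model output per row
    (probability scale for sklearn trees, margin scale for boosted models).
    """
    X = np.asarray(X, dtype=float)
    if scorer.algorithm == "XGB":
        import xgboost as xgb
        booster = scorer.estimator.get_booster()
        contrib = booster.predict(xgb.DMatrix(X), pred_contribs=True)
        return contrib[:, :-1], float(contrib[0, -1]), "treeshap"
    if scorer.algorithm == "LGBM":
        contrib = scorer.estimator.booster_.predict(X, pred_contrib=True)
        return contrib[:, :-1], float(contrib[0, -1]), "treeshap"
    if scorer.algorithm == "DT":
        contrib, base = _sklearn_tree_contributions(scorer.estimator, X)
        return contrib, base, "tree_path"
    if scorer.algorithm == "RF":
        contribs = []
        bases = []
        for est in scorer.estimator.estimators_:
            c, b = _sklearn_tree_contributions(est, X)
            contribs.append(c)
            bases.append(b)
        return (np.mean(contribs, axis=0), float(np.mean(bases)), "tree_path")
    raise ValidationError(
        f"no additive attribution backend for {scorer.algorithm}")


def _permutation_importance(scorer: LocationScorer, X: np.ndarray,
                            seed: int = 0) -> np.ndarray:
    """Label-free permutation importance: mean |score shift| per feature
    when that feature's column is shuffled."""
    rng = np.random.default_rng(seed)
    base = scorer.score_matrix(X)
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        out[j] = np.mean(np.abs(scorer.score_matrix(Xp) - base))
    return out


def rank_features(scorer: LocationScorer, X: np.ndarray,
                  schema: FeatureSchema, top_n: int = 10,
                  seed: int = 0) -> FeatureRanking:
    """Rank features by mean absolute additive attribution.

    Tree-based scorers use exact additive attributions; other algorithms
    fall back to score-permutation importance, recorded in ``method``.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(schema):
        raise ValidationError("feature matrix does not match schema")
    try:
        contrib, base, method = attribution_matrix(scorer, X)
        importance = np.mean(np.abs(contrib), axis=0)
    except ValidationError:
        importance = _permutation_importance(scorer, scorer._prepare(X), seed)
        base, method = None, "score_permutation"
    order = np.argsort(-importance)[:top_n]
    entries = tuple((schema.names[i], float(importance[i])) for i in order)
    return FeatureRanking(entries, method, base)
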