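"""Splitting, classifier sweep, role selection, evaluation and persistence.

The sweep trains every registered classifier on the training partition,
scores it on the held-out test partition, and tags three role models:
``most_sensitive`` (best recall on the positive, anti-angiogenic class),
``most_specific`` (best true-negative rate) and ``most_accurate``.
Downstream users pick the role matching their question — a broad
candidate list that misses few true positives, or a narrow confident
list with few false positives.

Role-equivalent classifier families (the registry is extensible):

* ``cost_sensitive_tree`` — CART with an asymmetric misclassification
  cost expressed as class weights (the sensitivity lever);
* ``rule_list`` — an entropy-split, cost-complexity-pruned decision
  tree whose root-to-leaf paths form a compact rule list;
* ``boosting`` — gradient boosting with shrinkage/subsampling as the
  margin regularizer (the specificity lever).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Callable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.tree import DecisionTreeClassifier

from antiangio.seqio import LabeledDataset, NEGATIVE, POSITIVE

BUNDLE_FORMAT_VERSION = 1

ROLES = ("most_sensitive", "most_specific", "most_accurate")


class SchemaError(ValueError):
    """A matrix does not carry the features a trained model expects."""


class BundleFormatError(ValueError):
    """A saved model bundle is unreadable or has an incompatible version."""


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partitioning parameters (stratified by class by default)."""

    test_fraction: float = 0.2
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ModelSpec:
    """A named entry of the classifier registry.

    ``class_weights`` is a (positive, negative) weight pair; families
    that do not use it ignore it.
    """

    name: str
    family: str
    hyperparameters: dict = field(default_factory=dict)
    class_weights: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.class_weights is not None:
            cw = tuple(float(x) for x in self.class_weights)
            if len(cw) != 2 or any(x <= 0 for x in cw):
                raise ValueError("class_weights must be a positive (pos, neg) pair")
            object.__setattr__(self, "class_weights", cw)


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts and the three headline ratios.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    accuracy = (TP+TN)/n. A ratio with a zero denominator is NaN.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_binary(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        mapping = {POSITIVE: 1, NEGATIVE: 0, "pos": 1, "neg": 0, "1": 1, "0": 0}
        try:
            arr = np.array([mapping[str(x).strip().lower()] for x in arr])
        except KeyError as exc:
            raise ValueError(f"unrecognized label {exc}") from exc
    arr = arr.astype(int)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("labels must be binary (1 = positive)")
    return arr


def evaluate(predicted: Sequence, truth: Sequence) -> EvalResult:
    """Confusion counts of ``predicted`` against ``truth`` plus the three ratios."""
    p, t = _as_binary(predicted), _as_binary(truth)
    if len(p) != len(t):
        raise ValueError(f"length mismatch: {len(p)} predictions vs {len(t)} truths")

    tp = int(np.sum((p == 1) & (t == 1)))
    tn = int(np.sum((p == 0) & (t == 0)))
    fp = int(np.sum((p == 1) & (t == 0)))
    fn = int(np.sum((p == 0) & (t == 1)))

    def ratio(num: int, den: int, what: str) -> float:
        if den == 0:
            warnings.warn(f"{what} undefined (zero denominator); reporting NaN", stacklevel=3)
            return float("nan")
        return num / den

    return EvalResult(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        accuracy=ratio(tp + tn, tp + tn + fp + fn, "accuracy"),
    )


# ---------------------------------------------------------------------------
# splitting

def split_indices(labels: np.ndarray, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of the train and test partitions."""
    labels = _as_binary(labels)
    rng = np.random.default_rng(spec.seed)
    test: list[int] = []
    groups = [np.flatnonzero(labels == c) for c in (1, 0)] if spec.stratified else [np.arange(len(labels))]
    for idxs in groups:
        n = len(idxs)
        n_test = int(np.floor(n * spec.test_fraction + 0.5))  # round half up
        if n_test == 0 or n_test == n:
            raise ValueError(
                f"group of size {n} cannot populate both partitions at "
                f"test_fraction={spec.test_fraction}"
            )
        test.extend(rng.permutation(idxs)[:n_test].tolist())
    test_idx = np.array(sorted(test))
    train_idx = np.setdiff1d(np.arange(len(labels)), test_idx)
    return train_idx, test_idx


def split_dataset(dataset: LabeledDataset, spec: SplitSpec) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/test split: per class, round(n * test_fraction) test instances."""
    if dataset.labels is None:
        raise ValueError("cannot split an unlabeled dataset")
    if (dataset.labels == 1).sum() == 0 or (dataset.labels == 0).sum() == 0:
        raise ValueError("both classes must be non-empty")
    train_idx, test_idx = split_indices(dataset.labels, spec)
    return dataset.subset(train_idx), dataset.subset(test_idx)


# ---------------------------------------------------------------------------
# training

FamilyBuilder = Callable[[ModelSpec, int], Any]

_FAMILY_BUILDERS: dict[str, FamilyBuilder] = {}


def register_family(name: str, builder: FamilyBuilder) -> None:
    """Register (or replace) a classifier family constructor."""
    _FAMILY_BUILDERS[name] = builder


def _build_cost_sensitive_tree(spec: ModelSpec, seed: int) -> DecisionTreeClassifier:
    cw = spec.class_weights or (1.0, 1.0)
    return DecisionTreeClassifier(
        random_state=seed, class_weight={1: cw[0], 0: cw[1]}, **spec.hyperparameters
    )


def _build_rule_list(spec: ModelSpec, seed: int) -> DecisionTreeClassifier:
    hp = {"criterion": "entropy", "ccp_alpha": 0.01, **spec.hyperparameters}
    return DecisionTreeClassifier(random_state=seed, **hp)


def _build_boosting(spec: ModelSpec, seed: int) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(random_state=seed, **spec.hyperparameters)


register_family("cost_sensitive_tree", _build_cost_sensitive_tree)
register_family("rule_list", _build_rule_list)
register_family("boosting", _build_boosting)


def default_registry() -> list[ModelSpec]:
    """The default classifier sweep: cost-sensitive trees, rule lists, boosting."""
    return [
        ModelSpec("tree_cost5", "cost_sensitive_tree", {"max_depth": 6}, class_weights=(5.0, 1.0)),
        ModelSpec("tree_cost2", "cost_sensitive_tree", {"max_depth": 6}, class_weights=(2.0, 1.0)),
        ModelSpec("tree_cart", "cost_sensitive_tree", {"max_depth": 6}),
        ModelSpec("rules_pruned", "rule_list", {"min_samples_leaf": 5}),
        ModelSpec("gboost", "boosting", {"n_estimators": 60, "learning_rate": 0.1, "max_depth": 2}),
        ModelSpec(
            "gboost_reg", "boosting",
            {"n_estimators": 60, "learning_rate": 0.05, "max_depth": 2, "subsample": 0.8},
        ),
    ]


@dataclass
class FittedModel:
    """A fitted estimator plus the frozen feature schema it expects."""

    spec: ModelSpec
    estimator: Any
    schema: list[str]
    seed: int

    def predict_scores(self, matrix: pd.DataFrame) -> np.ndarray:
        """Positive-class score for each row; columns are aligned by name."""
        missing = [f for f in self.schema if f not in matrix.columns]
        if missing:
            raise SchemaError(
                f"matrix lacks {len(missing)} feature(s) required by model "
                f"{self.spec.name!r}: {missing[:10]}"
            )
        X = matrix[self.schema].to_numpy(dtype=float)
        proba = self.estimator.predict_proba(X)
        pos_col = int(np.flatnonzero(self.estimator.classes_ == 1)[0])
        return proba[:, pos_col]


def train_model(matrix: pd.DataFrame, labels: Sequence, spec: ModelSpec, seed: int = 0) -> FittedModel:
    """Fit one registry entry; reproducible for a fixed (spec, seed)."""
    y = _as_binary(labels)
    if len(y) != matrix.shape[0]:
        raise ValueError("label count does not match matrix rows")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 instances per class")
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    if spec.family not in _FAMILY_BUILDERS:
        raise ValueError(
            f"unknown classifier family {spec.family!r}; "
            f"registered: {sorted(_FAMILY_BUILDERS)}"
        )
    est = _FAMILY_BUILDERS[spec.family](spec, seed)
    est.fit(X, y)
    return FittedModel(spec=spec, estimator=est, schema=[str(c) for c in matrix.columns], seed=seed)


# ---------------------------------------------------------------------------
# sweep and bundle

@dataclass
class TrainedModelBundle:
    """Three role-tagged fitted classifiers sharing one feature schema.

    Roles may point at the same underlying model. ``thresholds`` holds
    the per-role decision threshold on the positive-class score.
    """

    roles: dict[str, FittedModel]
    schema: list[str]
    metadata: dict = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for role in ROLES:
            if role not in self.roles:
                raise ValueError(f"bundle missing role {role!r}")
            self.thresholds.setdefault(role, 0.5)


def sweep_models(
    registry: Sequence[ModelSpec],
    train_matrix: pd.DataFrame,
    train_labels: Sequence,
    test_matrix: pd.DataFrame,
    test_labels: Sequence,
    seed: int = 0,
) -> tuple[pd.DataFrame, TrainedModelBundle]:
    """Train every spec, score on the test partition, select the role models.

    Returns a leaderboard (one row per spec, in registry order) and a
    bundle whose roles are the argmax of sensitivity / specificity /
    accuracy, ties going to the earlier registry entry. A spec that
    fails to train is recorded with status ``failed`` and excluded from
    role selection; the sweep continues.
    """
    if not registry:
        raise ValueError("registry must be non-empty")
    names = [s.name for s in registry]
    if len(set(names)) != len(names):
        raise ValueError("registry names must be unique")

    y_test = _as_binary(test_labels)
    rows: list[dict] = []
    fitted: dict[str, FittedModel] = {}
    for spec in registry:
        row: dict[str, Any] = {"name": spec.name, "family": spec.family}
        try:
            model = train_model(train_matrix, train_labels, spec, seed=seed)
            scores = model.predict_scores(test_matrix)
            res = evaluate((scores >= 0.5).astype(int), y_test)
        except Exception as exc:  # noqa: BLE001 - sweep must survive one bad spec
            row.update(status="failed", error=str(exc))
            rows.append(row)
            continue
        fitted[spec.name] = model
        row.update(
            status="ok", error="",
            tp=res.tp, tn=res.tn, fp=res.fp, fn=res.fn,
            sensitivity=res.sensitivity, specificity=res.specificity, accuracy=res.accuracy,
        )
        rows.append(row)

    leaderboard = pd.DataFrame(rows)
    ok = leaderboard[leaderboard["status"] == "ok"]
    if ok.empty:
        raise RuntimeError("every registry entry failed to train")

    def argmax_first(metric: str) -> str:
        vals = ok[metric].to_numpy(dtype=float)
        vals = np.where(np.isnan(vals), -np.inf, vals)
        return str(ok.iloc[int(np.argmax(vals))]["name"])  # first max = registry order

    roles = {
        "most_sensitive": fitted[argmax_first("sensitivity")],
        "most_specific": fitted[argmax_first("specificity")],
        "most_accurate": fitted[argmax_first("accuracy")],
    }
    bundle = TrainedModelBundle(
        roles=roles,
        schema=[str(c) for c in train_matrix.columns],
        metadata={
            "seed": seed,
            "specs": [s.name for s in registry],
            "role_specs": {r: m.spec.name for r, m in roles.items()},
            "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        },
    )
    return leaderboard, bundle


def predict(bundle: TrainedModelBundle, matrix: pd.DataFrame, role: str = "most_accurate") -> pd.DataFrame:
    """Per-peptide label and positive-class score from one role model.

    Extra matrix columns are ignored and column order is irrelevant; a
    missing schema feature raises :class:`SchemaError` listing the names.
    """
    if role not in bundle.roles:
        raise ValueError(f"unknown role {role!r}; available: {sorted(bundle.roles)}")
    model = bundle.roles[role]
    scores = model.predict_scores(matrix)
    threshold = bundle.thresholds.get(role, 0.5)
    labels = [POSITIVE if s >= threshold else NEGATIVE for s in scores]
    return pd.DataFrame({"label": labels, "score": scores}, index=matrix.index)


def save_bundle(bundle: TrainedModelBundle, path: str | Path) -> None:
    """Persist a bundle as a directory: meta.json + models.joblib."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "schema": bundle.schema,
        "thresholds": bundle.thresholds,
        "metadata": bundle.metadata,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    joblib.dump(bundle.roles, path / "models.joblib")


def load_bundle(path: str | Path) -> TrainedModelBundle:
    """Load a bundle saved by :func:`save_bundle`; checks the format version."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise BundleFormatError(f"{path}: not a model bundle (no meta.json)")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise BundleFormatError(f"{path}: corrupted meta.json: {exc}") from exc
    version = meta.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise BundleFormatError(
            f"{path}: bundle format version {version!r} != supported {BUNDLE_FORMAT_VERSION}"
        )
    try:
        roles = joblib.load(path / "models.joblib")
    except Exception as exc:
        raise BundleFormatError(f"{path}: corrupted model archive: {exc}") from exc
    return TrainedModelBundle(
        roles=roles,
        schema=list(meta["schema"]),
        metadata=meta.get("metadata", {}),
        thresholds={k: float(v) for k, v in meta.get("thresholds", {}).items()},
    )
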