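"""Model training and the cross-validated evaluation protocols.

Four learner families are supported: elastic-net logistic regression, random
forest (1,000 trees), gradient boosting, and a fully-connected neural
network. The first three use balanced class weighting (gradient boosting via
balanced sample weights); the neural net handles imbalance by seeded
oversampling of the positive class. Hyperparameters are chosen by exhaustive
grid search with internal 5-fold stratified cross-validation on each
training set, selecting the configuration with the best mean inner AUROC.

Evaluation protocols: outer 5-fold cross-validation with ROC curves pooled
over test-fold predictions, learning curves by unstratified subsampling of
each training set, feature-group ablations (subgraph groups source / target
/ st_relation, or evidence-type groups abundance / localization / go / ppi),
and cross-phenotype transfer with phenotype-specific columns dropped.

Leakage discipline: min-max scaling, tuning, and fitting see training rows
only; injected target-as-source instances join every training set and are
never scored as test instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.utils.class_weight import compute_sample_weight

from perturbgraph.features import FeatureMatrix, MinMaxScaler
from perturbgraph.labels import TRAIN_ONLY_FOLD

FAMILIES = ("elastic_net", "random_forest", "gboost", "neural_net")


def _expand(grid_axes: dict[str, list]) -> list[dict]:
    keys = list(grid_axes)
    return [dict(zip(keys, combo)) for combo in itertools.product(*grid_axes.values())]


_DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "elastic_net": {"C": [0.01, 0.1, 1.0, 10.0], "l1_ratio": [0.1, 0.5, 0.9]},
    "random_forest": {
        "max_depth": [None, 10, 20],
        "min_samples_split": [2, 10],
        "min_samples_leaf": [1, 5],
    },
    "gboost": {
        "learning_rate": [0.05, 0.1, 0.3],
        "max_depth": [3, 6],
        "min_samples_leaf": [1, 5],
        "subsample": [0.8, 1.0],
        "max_features": [0.8, 1.0],
    },
    "neural_net": {
        "batch_size": [64, 256],
        "learning_rate_init": [1e-3, 1e-2],
        "max_iter": [20, 50],
        "hidden": [64, 256],
        "n_layers": [1, 2],
        "activation": ["relu", "logistic"],
    },
}

_DEFAULT_FIXED: dict[str, dict] = {
    "elastic_net": {"max_iter": 5000},
    "random_forest": {"n_estimators": 1000},
    "gboost": {"n_estimators": 100},
    "neural_net": {},
}


@dataclass(frozen=True)
class ModelSpec:
    """A learner family with fixed constants and a hyperparameter grid."""

    family: str
    fixed: dict = field(default_factory=dict)
    grid: tuple[dict, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; choose from {FAMILIES}")
        if not self.grid:
            object.__setattr__(self, "grid", tuple(_expand(_DEFAULT_GRIDS[self.family])))
        fixed = {**_DEFAULT_FIXED[self.family], **self.fixed}
        object.__setattr__(self, "fixed", fixed)


def default_spec(family: str, grid_axes: dict[str, list] | None = None, **fixed) -> ModelSpec:
    grid = tuple(_expand(grid_axes)) if grid_axes else ()
    return ModelSpec(family=family, fixed=fixed, grid=grid)


def _build(spec: ModelSpec, params: dict, seed: int):
    p = {**spec.fixed, **params}
    if spec.family == "elastic_net":
        return LogisticRegression(
            solver="saga",
            class_weight="balanced",
            max_iter=p["max_iter"],
            C=p.get("C", 1.0),
            l1_ratio=p.get("l1_ratio", 0.5),
            random_state=seed,
        )
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=p["n_estimators"],
            class_weight="balanced",
            max_depth=p.get("max_depth"),
            min_samples_split=p.get("min_samples_split", 2),
            min_samples_leaf=p.get("min_samples_leaf", 1),
            random_state=seed,
            n_jobs=1,
        )
    if spec.family == "gboost":
        return GradientBoostingClassifier(
            n_estimators=p["n_estimators"],
            learning_rate=p.get("learning_rate", 0.1),
            max_depth=p.get("max_depth", 3),
            min_samples_leaf=p.get("min_samples_leaf", 1),
            subsample=p.get("subsample", 1.0),
            max_features=p.get("max_features"),
            random_state=seed,
        )
    if spec.family == "neural_net":
        hidden = p.get("hidden", 64)
        layers = (hidden,) if p.get("n_layers", 1) == 1 else (hidden, max(1, hidden // 4))
        return MLPClassifier(
            hidden_layer_sizes=layers,
            activation=p.get("activation", "relu"),
            batch_size=min(p.get("batch_size", 64), 200),
            learning_rate_init=p.get("learning_rate_init", 1e-3),
            max_iter=p.get("max_iter", 50),
            random_state=seed,
        )
    raise AssertionError(spec.family)


def _fit(spec: ModelSpec, est, X: np.ndarray, y: np.ndarray, seed: int):
    if spec.family == "gboost":
        est.fit(X, y, sample_weight=compute_sample_weight("balanced", y))
    elif spec.family == "neural_net":
        # oversample the minority class to balance (MLP has no class weights)
        rng = np.random.default_rng(seed)
        counts = np.bincount(y, minlength=2)
        minority = int(np.argmin(counts))
        extra = counts.max() - counts.min()
        if extra > 0 and counts.min() > 0:
            pool = np.flatnonzero(y == minority)
            add = rng.choice(pool, size=extra, replace=True)
            order = rng.permutation(len(y) + extra)
            X = np.vstack([X, X[add]])[order]
            y = np.concatenate([y, y[add]])[order]
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
            est.fit(X, y)
    else:
        est.fit(X, y)
    return est


def _scores(est, X: np.ndarray) -> np.ndarray:
    proba = est.predict_proba(X)
    if proba.shape[1] == 1:  # degenerate single-class fit
        return np.full(len(X), 0.5)
    return proba[:, list(est.classes_).index(1)]


def tune(spec: ModelSpec, X: np.ndarray, y: np.ndarray, seed: int, inner_folds: int = 5):
    """Grid search by internal stratified CV on AUROC; refit on the full split."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    if len(spec.grid) == 1:
        best = spec.grid[0]
    else:
        n_splits = min(inner_folds, int(np.bincount(y).min()))
        skf = StratifiedKFold(n_splits=max(2, n_splits), shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
        best, best_score = None, -np.inf
        for params in spec.grid:
            aucs = []
            for tr, va in splits:
                if len(np.unique(y[va])) < 2:
                    continue
                est = _fit(spec, _build(spec, params, seed), X[tr], y[tr], seed)
                aucs.append(roc_auc_score(y[va], _scores(est, X[va])))
            score = float(np.mean(aucs)) if aucs else -np.inf
            if score > best_score:
                best, best_score = params, score
    est = _fit(spec, _build(spec, best, seed), X, y, seed)
    return est, best


@dataclass
class EvalResult:
    """Pooled cross-validation outcome."""

    pooled_auroc: float
    fold_aurocs: dict[int, float]
    predictions: pd.DataFrame  # source, fold, label, score
    roc: tuple[np.ndarray, np.ndarray]  # pooled (fpr, tpr)
    chosen_params: dict[int, dict]


def _outer_folds(table: pd.DataFrame) -> list[int]:
    folds = sorted(int(f) for f in table["fold"].unique() if f != TRAIN_ONLY_FOLD)
    if not folds:
        raise ValueError("instance table has no fold assignments; run make_folds first")
    return folds


def cross_validate(
    spec: ModelSpec,
    fmatrix: FeatureMatrix,
    table: pd.DataFrame,
    seed: int = 0,
    columns: list[str] | None = None,
) -> EvalResult:
    """Outer k-fold CV with per-fold scaling + tuning; ROC pooled over folds."""
    cols = columns if columns is not None else list(fmatrix.X.columns)
    X_raw = fmatrix.X[cols]
    y = table["label"].to_numpy(dtype=int)
    fold = table["fold"].to_numpy(dtype=int)
    is_tgt = table["is_target_instance"].to_numpy(dtype=int)

    preds, params_by_fold, fold_aurocs = [], {}, {}
    for f in _outer_folds(table):
        train = fold != f  # includes train-only target instances
        test = (fold == f) & (is_tgt == 0)
        scaler = MinMaxScaler().fit(X_raw[train])
        Xtr = scaler.transform(X_raw[train]).to_numpy()
        Xte = scaler.transform(X_raw[test]).to_numpy()
        est, best = tune(spec, Xtr, y[train], seed=seed * 100 + f)
        params_by_fold[f] = best
        s = _scores(est, Xte)
        preds.append(
            pd.DataFrame(
                {
                    "source": table.loc[test, "source"].values,
                    "fold": f,
                    "label": y[test],
                    "score": s,
                }
            )
        )
        if len(np.unique(y[test])) == 2:
            fold_aurocs[f] = float(roc_auc_score(y[test], s))
        else:
            fold_aurocs[f] = float("nan")

    predictions = pd.concat(preds, ignore_index=True)
    pooled = float(roc_auc_score(predictions["label"], predictions["score"]))
    fpr, tpr, _ = roc_curve(predictions["label"], predictions["score"])
    return EvalResult(pooled, fold_aurocs, predictions, (fpr, tpr), params_by_fold)


def learning_curve(
    spec: ModelSpec,
    fmatrix: FeatureMatrix,
    table: pd.DataFrame,
    fractions: list[float],
    seed: int = 0,
) -> dict[float, float]:
    """Pooled AUROC per training-set fraction (unstratified subsampling)."""
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    X_raw = fmatrix.X
    y = table["label"].to_numpy(dtype=int)
    fold = table["fold"].to_numpy(dtype=int)
    is_tgt = table["is_target_instance"].to_numpy(dtype=int)

    out: dict[float, float] = {}
    for frac in fractions:
        preds = []
        for f in _outer_folds(table):
            train_idx = np.flatnonzero(fold != f)
            test = (fold == f) & (is_tgt == 0)
            rng = np.random.default_rng(seed * 1000 + f)
            if frac < 1.0:
                size = max(2, int(round(frac * len(train_idx))))
                for _ in range(10):
                    sub = rng.choice(train_idx, size=size, replace=False)
                    if len(np.unique(y[sub])) == 2:
                        break
                else:
                    raise ValueError(f"could not draw a two-class subsample at fraction {frac}")
            else:
                sub = train_idx
            scaler = MinMaxScaler().fit(X_raw.iloc[sub])
            est, _ = tune(
                spec, scaler.transform(X_raw.iloc[sub]).to_numpy(), y[sub], seed=seed * 100 + f
            )
            preds.append(
                pd.DataFrame(
                    {"label": y[test], "score": _scores(est, scaler.transform(X_raw[test]).to_numpy())}
                )
            )
        pool = pd.concat(preds, ignore_index=True)
        out[frac] = float(roc_auc_score(pool["label"], pool["score"]))
    return out


SUBGRAPH_GROUPS = ("source", "target", "st_relation")
EVIDENCE_GROUPS = ("abundance", "localization", "go", "ppi")


def ablate(
    spec: ModelSpec,
    fmatrix: FeatureMatrix,
    table: pd.DataFrame,
    grouping: str = "subgraph",
    seed: int = 0,
) -> dict[str, EvalResult]:
    """Cross-validate on each feature group alone, plus all features."""
    if grouping == "subgraph":
        groups = {g: fmatrix.columns_by_tag(subgraph=g) for g in SUBGRAPH_GROUPS}
    elif grouping == "evidence_type":
        groups = {g: fmatrix.columns_by_tag(evidence=g) for g in EVIDENCE_GROUPS}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    empty = [g for g, cols in groups.items() if not cols]
    if empty:
        raise ValueError(f"feature groups with no columns: {empty}")
    out = {"all": cross_validate(spec, fmatrix, table, seed=seed)}
    for g, cols in groups.items():
        out[g] = cross_validate(spec, fmatrix, table, seed=seed, columns=cols)
    return out


def transferable_columns(fmatrix: FeatureMatrix, feature_mode: str = "transferable_all") -> list[str]:
    """Columns retained for cross-phenotype transfer.

    Diffusion (RWR) columns are phenotype-specific and always dropped;
    ``st_relation_only`` additionally drops every source/target-tagged column.
    """
    cols = [c for c in fmatrix.X.columns if not c.startswith("rel_rwr_")]
    if feature_mode == "st_relation_only":
        cols = [c for c in cols if fmatrix.subgraph_tags[c] == "st_relation"]
    elif feature_mode != "transferable_all":
        raise ValueError(f"unknown feature mode {feature_mode!r}")
    return cols


def transfer(
    spec: ModelSpec,
    fmatrix_train: FeatureMatrix,
    table_train: pd.DataFrame,
    fmatrix_test: FeatureMatrix,
    table_test: pd.DataFrame,
    feature_mode: str = "transferable_all",
    seed: int = 0,
) -> float:
    """Train on all of one phenotype, score all of another; returns AUROC."""
    cols = transferable_columns(fmatrix_train, feature_mode)
    if cols != transferable_columns(fmatrix_test, feature_mode):
        raise ValueError("column layouts differ between phenotypes after restriction")
    Xtr_raw = fmatrix_train.X[cols]
    ytr = table_train["label"].to_numpy(dtype=int)
    test_mask = table_test["is_target_instance"] == 0
    Xte_raw = fmatrix_test.X.loc[test_mask.values, cols]
    yte = table_test.loc[test_mask, "label"].to_numpy(dtype=int)

    scaler = MinMaxScaler().fit(Xtr_raw)
    est, _ = tune(spec, scaler.transform(Xtr_raw).to_numpy(), ytr, seed=seed)
    return float(roc_auc_score(yte, _scores(est, scaler.transform(Xte_raw).to_numpy())))
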