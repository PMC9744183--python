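"""Cross-validated random-forest classification of PYR vs PV units.

Each experiment repeats a nested procedure over ``n_partitions`` (default
50) random 80:20 stratified, unit-disjoint train/test splits: a fivefold
grid search on the training set selects forest hyperparameters by ROC AUC,
a forest with class weights inversely proportional to class frequency is fit
on the full training set, and performance is the unit-level test AUC. For
chunked tables the hyperparameters are reused from the no-chunking
equivalent on the same partition, every chunk is scored independently, and
per-unit predictions are pooled by majority vote (the continuous unit score
is the fraction of chunks voting PV). Chance baselines shuffle the training
labels (at the unit level) and leave the test set intact.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold

from .registry import MODALITIES, META_COLUMNS, chunk_stat_columns
from .chunking import pool_votes

POSITIVE = "PV"


def _make_grid(**axes: tuple) -> list[dict]:
    keys = list(axes)
    return [dict(zip(keys, combo)) for combo in product(*axes.values())]


#: Full hyperparameter grid (declaration order breaks ties).
DEFAULT_GRID: list[dict] = _make_grid(
    n_estimators=(10, 50, 100, 500),
    max_depth=(None, 5, 10, 20),
    min_samples_split=(2, 5, 10),
    min_samples_leaf=(1, 2, 5),
)

#: Reduced grid used by the test suite and desk-scale experiments.
SMALL_GRID: list[dict] = _make_grid(
    n_estimators=(50, 100),
    max_depth=(None, 10),
    min_samples_split=(2,),
    min_samples_leaf=(1,),
)


@dataclass
class ModelRun:
    """One train/test partition's model and its evaluation."""

    partition: int
    params: dict
    unit_ids: list[str]
    y_true: np.ndarray  # 1 = PV
    scores: np.ndarray  # unit-level PV scores
    auc: float
    shuffled: bool = False
    attributions: dict | None = None  # mean |Shapley value| per feature


@dataclass
class GeneralizationReport:
    """Cross-region generalization of models trained on one region."""

    training_region: str
    auc_train_region: np.ndarray
    auc_other_region: np.ndarray

    @property
    def generalization_error(self) -> np.ndarray:
        """(AUC_train - AUC_other) / AUC_train, per partition."""
        return (self.auc_train_region - self.auc_other_region) / self.auc_train_region

    def summary(self) -> dict:
        return {
            "training_region": self.training_region,
            "median_auc_train_region": float(np.median(self.auc_train_region)),
            "median_auc_other_region": float(np.median(self.auc_other_region)),
            "median_generalization_error": float(
                np.median(self.generalization_error)
            ),
        }


def modality_view(table: pd.DataFrame, modality: str | None) -> pd.DataFrame:
    """Restrict a feature table to one modality's base + chunk-stat columns."""
    if modality is None:
        return table
    base = MODALITIES[modality]
    cols = list(META_COLUMNS) + list(base) + chunk_stat_columns(base)
    return table[[c for c in cols if c in table.columns]]


def _unit_labels(table: pd.DataFrame) -> pd.Series:
    per_unit = table.groupby("unit_id", sort=False)["label"].first()
    return per_unit


def stratified_partition(
    labels_by_unit: pd.Series | dict,
    fraction: float = 0.8,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[str], list[str]]:
    """Split unit ids into stratified, disjoint train/test sets.

    ``labels_by_unit`` maps unit_id -> label. Per class, floor(fraction *
    count) units go to the training set and the remainder to the test set.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ser = pd.Series(labels_by_unit)
    train: list[str] = []
    test: list[str] = []
    for label in sorted(ser.unique()):
        ids = ser.index[ser == label].to_numpy()
        if ids.size < 2:
            raise ValueError(f"class {label!r} has fewer than 2 units")
        perm = rng.permutation(ids)
        n_train = int(np.floor(fraction * ids.size))
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return train, test


def class_weights(train_labels: np.ndarray | pd.Series) -> dict[str, float]:
    """n_samples / (n_classes * n_class_samples), per class."""
    labels = pd.Series(train_labels)
    counts = labels.value_counts()
    if (counts == 0).any() or counts.size < 2:
        raise ValueError("both classes must be present in the training set")
    n = len(labels)
    return {cls: n / (counts.size * cnt) for cls, cnt in counts.items()}


def _feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    return table[[c for c in table.columns if c not in META_COLUMNS]]


def _impute(train_X: pd.DataFrame, *others: pd.DataFrame):
    """Median-impute missing values using the training-set medians."""
    med = train_X.median()
    med = med.fillna(0.0)
    return tuple(X.fillna(med).to_numpy(float) for X in (train_X, *others))


def _fit_forest(
    params: dict, X: np.ndarray, y: np.ndarray, weights: dict, seed: int
) -> RandomForestClassifier:
    clf = RandomForestClassifier(
        **params,
        class_weight={1: weights[POSITIVE], 0: weights["PYR"]},
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


def grid_search(
    train_table: pd.DataFrame,
    grid: list[dict] | None = None,
    k: int = 5,
    seed: int = 0,
    max_rows: int | None = None,
) -> dict:
    """Fivefold unit-grouped grid search maximizing mean ROC AUC.

    Ties keep the earliest grid member. ``max_rows`` subsamples the
    development rows (used by the generalization analysis, capped at 5000
    chunks there).
    """
    grid = grid if grid is not None else DEFAULT_GRID
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if len(grid) == 1:
        return dict(grid[0])
    rng = np.random.default_rng(seed)
    table = train_table
    if max_rows is not None and len(table) > max_rows:
        table = table.iloc[np.sort(rng.choice(len(table), max_rows, replace=False))]
    X_df = _feature_matrix(table)
    y = (table["label"] == POSITIVE).to_numpy(int)
    groups = table["unit_id"].to_numpy()
    k_eff = min(k, pd.Series(groups[y == 1]).nunique(), pd.Series(groups[y == 0]).nunique())
    splitter = StratifiedGroupKFold(n_splits=max(2, k_eff), shuffle=True, random_state=int(rng.integers(2**31)))
    folds = list(splitter.split(X_df, y, groups))
    weights = class_weights(table["label"])

    best_params, best_score = None, -np.inf
    for params in grid:
        scores = []
        for tr, te in folds:
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            Xtr, Xte = _impute(X_df.iloc[tr], X_df.iloc[te])
            clf = _fit_forest(params, Xtr, y[tr], weights, seed)
            proba = clf.predict_proba(Xte)[:, list(clf.classes_).index(1)]
            scores.append(roc_auc_score(y[te], proba))
        score = float(np.mean(scores)) if scores else 0.5
        if score > best_score:  # strict: first grid member wins ties
            best_params, best_score = params, score
    return dict(best_params)


def _evaluate_partition(
    fit_table: pd.DataFrame,
    train_units: list[str],
    test_units: list[str],
    params: dict,
    seed: int,
    shuffle_labels: bool,
    pooled: bool,
    rng: np.random.Generator,
    compute_shap: bool = False,
    shap_max_samples: int = 1000,
) -> tuple[np.ndarray, np.ndarray, list[str], dict, dict | None]:
    train_rows = fit_table[fit_table["unit_id"].isin(train_units)]
    test_rows = fit_table[fit_table["unit_id"].isin(test_units)]

    train_labels = train_rows["label"].copy()
    if shuffle_labels:
        unit_label = train_rows.groupby("unit_id", sort=False)["label"].first()
        permuted = pd.Series(
            rng.permutation(unit_label.to_numpy()), index=unit_label.index
        )
        train_labels = train_rows["unit_id"].map(permuted)

    weights = class_weights(train_labels)
    Xtr_df = _feature_matrix(train_rows)
    Xte_df = _feature_matrix(test_rows)
    Xtr, Xte = _impute(Xtr_df, Xte_df)
    ytr = (train_labels == POSITIVE).to_numpy(int)
    clf = _fit_forest(params, Xtr, ytr, weights, seed)
    pos_col = list(clf.classes_).index(1)
    proba = clf.predict_proba(Xte)[:, pos_col]

    if pooled:
        pred_label = np.where(proba >= 0.5, "PV", "PYR")
        unit_ids, y_true, scores = [], [], []
        for uid, idx in test_rows.groupby("unit_id", sort=False).indices.items():
            _, score = pool_votes(pred_label[idx])
            unit_ids.append(uid)
            scores.append(score)
            y_true.append(int(test_rows["label"].iloc[idx[0]] == POSITIVE))
    else:
        unit_ids = test_rows["unit_id"].tolist()
        y_true = (test_rows["label"] == POSITIVE).to_numpy(int).tolist()
        scores = proba.tolist()

    attributions = None
    if compute_shap:
        from .shap_trees import forest_shap_values

        n = Xte.shape[0]
        take = np.arange(n)
        if n > shap_max_samples:
            take = np.sort(rng.choice(n, shap_max_samples, replace=False))
        shap_vals = forest_shap_values(clf, Xte[take])
        mean_abs = np.abs(shap_vals).mean(axis=0)
        attributions = dict(zip(Xte_df.columns, mean_abs))

    return (
        np.asarray(y_true, int),
        np.asarray(scores, float),
        unit_ids,
        weights,
        attributions,
    )


def run_experiment(
    nochunk_table: pd.DataFrame,
    chunk_table: pd.DataFrame | None = None,
    n_partitions: int = 50,
    fraction: float = 0.8,
    grid: list[dict] | None = None,
    seed: int = 0,
    shuffle_labels: bool = False,
    compute_shap: bool = False,
    shap_max_samples: int = 1000,
) -> list[ModelRun]:
    """Repeated stratified train/test evaluation; one :class:`ModelRun` each.

    The grid search always runs on the no-chunking table of the same
    partition; when ``chunk_table`` is given the selected hyperparameters are
    applied to it, predictions are pooled per unit by majority vote, and the
    unit-level AUC uses the PV vote fraction as score.
    """
    labels_by_unit = _unit_labels(nochunk_table)
    fit_table = chunk_table if chunk_table is not None else nochunk_table
    pooled = chunk_table is not None
    runs: list[ModelRun] = []
    for p in range(n_partitions):
        part_seed = (seed + 1000003 * p) % (2**31)
        rng = np.random.default_rng(part_seed)
        train_units, test_units = stratified_partition(labels_by_unit, fraction, rng)
        dev = nochunk_table[nochunk_table["unit_id"].isin(train_units)]
        params = grid_search(dev, grid=grid, seed=part_seed)
        y_true, scores, unit_ids, _, attributions = _evaluate_partition(
            fit_table,
            train_units,
            test_units,
            params,
            part_seed,
            shuffle_labels,
            pooled,
            rng,
            compute_shap=compute_shap,
            shap_max_samples=shap_max_samples,
        )
        auc = float(roc_auc_score(y_true, scores))
        runs.append(
            ModelRun(
                partition=p,
                params=params,
                unit_ids=unit_ids,
                y_true=y_true,
                scores=scores,
                auc=auc,
                shuffled=shuffle_labels,
                attributions=attributions,
            )
        )
    return runs


def median_auc(runs: list[ModelRun]) -> float:
    return float(np.median([r.auc for r in runs]))


def region_generalization(
    nochunk_table: pd.DataFrame,
    chunk_table: pd.DataFrame | None,
    training_region: str,
    n_partitions: int = 50,
    fraction: float = 0.8,
    grid: list[dict] | None = None,
    seed: int = 0,
    max_dev_rows: int = 5000,
) -> GeneralizationReport:
    """Train on ~80% of one region's units; test on the held-out same-region
    units and on all units of the other region."""
    regions = set(nochunk_table["region"].unique())
    if training_region not in regions or len(regions) < 2:
        raise ValueError("both regions must be present in the table")
    other_region = (regions - {training_region}).pop()

    fit_table = chunk_table if chunk_table is not None else nochunk_table
    pooled = chunk_table is not None
    region_units = nochunk_table[nochunk_table["region"] == training_region]
    other_units = nochunk_table.loc[
        nochunk_table["region"] == other_region, "unit_id"
    ].unique().tolist()
    labels_by_unit = _unit_labels(region_units)

    auc_same, auc_other = [], []
    for p in range(n_partitions):
        part_seed = (seed + 1000003 * p) % (2**31)
        rng = np.random.default_rng(part_seed)
        train_units, test_units = stratified_partition(labels_by_unit, fraction, rng)
        dev = fit_table[fit_table["unit_id"].isin(train_units)]
        params = grid_search(dev, grid=grid, seed=part_seed, max_rows=max_dev_rows)
        for test_set, sink in ((test_units, auc_same), (other_units, auc_other)):
            y_true, scores, _, _, _ = _evaluate_partition(
                fit_table, train_units, test_set, params, part_seed,
                shuffle_labels=False, pooled=pooled, rng=rng,
            )
            sink.append(float(roc_auc_score(y_true, scores)))
    return GeneralizationReport(
        training_region=training_region,
        auc_train_region=np.asarray(auc_same),
        auc_other_region=np.asarray(auc_other),
    )
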