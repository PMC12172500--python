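"""Multi-class AGA-stage classification.

Random forests on genus-level (and coarser) relative abundances, with the
evaluation discipline a paired two-region cohort demands: both samples of
a subject always land on the same side of every split, train/test splits
are stratified by stage at the subject level, and cross-validation uses
stratified grouped folds.  Performance is summarized by Cohen's kappa,
accuracy, and macro one-vs-rest ROC AUC.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, cohen_kappa_score, roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold

from ._seeds import child_int, child_rng
from .data_model import STAGES, AbundanceTable, CohortMetadata

__all__ = [
    "StageClassifier",
    "LevelKingdomGrid",
    "FeatureSelectionCurve",
    "EvaluationReport",
    "subject_split",
    "level_kingdom_grid",
    "select_top_features",
    "tune_hyperparameters",
    "fit_stage_classifier",
    "repeated_evaluation",
]


def _stage_order(labels) -> list[str]:
    """Classes present, in canonical severity order."""
    present = set(labels)
    return [s for s in STAGES if s in present]


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def subject_split(
    metadata: CohortMetadata, train_fraction: float = 0.7, seed: int | None = None
) -> tuple[list[str], list[str]]:
    """Subject-exclusive train/test split, stratified by stage.

    Per stage, ``ceil(train_fraction * n_subjects)`` subjects go to the
    training side (rounding toward train); all samples of a subject travel
    together.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = child_rng(seed, "subject_split")
    df = metadata.df
    train_ids: list[str] = []
    test_ids: list[str] = []
    subj_stage = df.groupby("subject_id")["stage"].first()
    for stage in _stage_order(subj_stage):
        subjects = sorted(subj_stage.index[subj_stage == stage])
        if len(subjects) < 2:
            raise ValueError(f"stage {stage} has fewer than 2 subjects")
        perm = rng.permutation(len(subjects))
        n_train = math.ceil(train_fraction * len(subjects))
        train_subj = {subjects[i] for i in perm[:n_train]}
        for sid, row in df[df["stage"] == stage].iterrows():
            (train_ids if row["subject_id"] in train_subj else test_ids).append(sid)
    return train_ids, test_ids


# ---------------------------------------------------------------------------
# fitted classifier
# ---------------------------------------------------------------------------


@dataclass
class StageClassifier:
    """Fitted multi-class model with a fixed severity-ordered class axis."""

    model: RandomForestClassifier
    features: list[str]
    classes: list[str]

    def predict_proba(self, table: AbundanceTable) -> pd.DataFrame:
        missing = [t for t in self.features if t not in table.data.columns]
        if missing:
            raise ValueError(f"table lacks classifier features: {missing}")
        X = table.data[self.features].to_numpy()
        raw = self.model.predict_proba(X)
        cols = list(self.model.classes_)
        proba = pd.DataFrame(raw, index=table.sample_ids, columns=cols)
        return proba[self.classes]

    def predict(self, table: AbundanceTable) -> pd.Series:
        proba = self.predict_proba(table)
        return proba.idxmax(axis=1).rename("predicted_stage")


def fit_stage_classifier(
    table: AbundanceTable,
    labels: pd.Series,
    params: dict | None = None,
    seed: int | None = None,
) -> StageClassifier:
    """Fit a random forest on a labeled table.

    ``params`` overrides the forest's constructor arguments.  The output
    class order is always (Healthy, AGA3, AGA5, AGA7) restricted to the
    classes present, whatever the label order in the input.
    """
    labels = labels.loc[table.sample_ids]
    classes = _stage_order(labels)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to fit a classifier")
    kwargs = dict(n_jobs=1, random_state=child_int(seed, "fit-rf"))
    if params:
        kwargs.update(params)
    rf = RandomForestClassifier(**kwargs)
    rf.fit(table.values, labels.to_numpy())
    return StageClassifier(rf, table.taxon_ids, classes)


# ---------------------------------------------------------------------------
# grouped stratified CV kappa
# ---------------------------------------------------------------------------


def _grouped_cv_kappa(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    folds: int,
    seed: int | None,
    params: dict | None = None,
    cv_repeats: int = 1,
) -> float:
    """Pooled-prediction Cohen's kappa from stratified grouped K-fold CV.

    With ``cv_repeats > 1`` the fold assignment is reshuffled and the
    pooled kappa averaged, trading compute for a smoother estimate.
    """
    kappas = []
    for r in range(cv_repeats):
        cv = StratifiedGroupKFold(
            n_splits=folds, shuffle=True, random_state=child_int(seed, f"sgkf/{r}")
        )
        pred = np.empty(len(y), dtype=object)
        for i, (tr, te) in enumerate(cv.split(X, y, groups)):
            kwargs = dict(n_jobs=1, random_state=child_int(seed, f"cv-rf/{r}/{i}"))
            if params:
                kwargs.update(params)
            rf = RandomForestClassifier(**kwargs)
            rf.fit(X[tr], y[tr])
            pred[te] = rf.predict(X[te])
        kappas.append(float(cohen_kappa_score(y, pred.astype(str))))
    return float(np.mean(kappas))


# ---------------------------------------------------------------------------
# level x kingdom model grid
# ---------------------------------------------------------------------------


@dataclass
class LevelKingdomGrid:
    kappa: pd.DataFrame  # rows: taxonomic level, columns: feature set
    folds: int
    seed: int | None

    def best_cell(self) -> tuple[str, str]:
        idx = self.kappa.stack().idxmax()
        return (str(idx[0]), str(idx[1]))


def level_kingdom_grid(
    tables: dict[str, dict[str, AbundanceTable]],
    metadata: CohortMetadata,
    folds: int = 10,
    seed: int | None = None,
    params: dict | None = None,
) -> LevelKingdomGrid:
    """CV kappa for every (taxonomic level) x (feature set) cell.

    ``tables[level][feature_set]`` with feature sets drawn from
    {bacteria, fungi, combined}.  All tables must share one sample set.
    """
    sample_ids = None
    for level, by_kingdom in tables.items():
        for kset, table in by_kingdom.items():
            if sample_ids is None:
                sample_ids = list(table.sample_ids)
            elif set(table.sample_ids) != set(sample_ids):
                raise ValueError(
                    f"table ({level}, {kset}) has a different sample set"
                )
    meta = metadata.df.loc[sample_ids]
    y = meta["stage"].to_numpy()
    groups = meta["subject_id"].to_numpy()
    grid: dict[str, dict[str, float]] = {}
    for level, by_kingdom in tables.items():
        grid[level] = {}
        for kset, table in by_kingdom.items():
            X = table.data.loc[sample_ids].to_numpy()
            grid[level][kset] = _grouped_cv_kappa(
                X, y, groups, folds, None if seed is None else seed, params
            )
    frame = pd.DataFrame(grid).T
    frame.index.name = "level"
    return LevelKingdomGrid(frame, folds, seed)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------


@dataclass
class FeatureSelectionCurve:
    ks: list[int]
    kappas: list[float]
    k_star: int
    ranking: list[str]

    @property
    def selected(self) -> list[str]:
        return self.ranking[: self.k_star]


def select_top_features(
    table: AbundanceTable,
    metadata: CohortMetadata,
    k_max: int | None = None,
    folds: int = 10,
    seed: int | None = None,
    k_grid: list[int] | None = None,
    params: dict | None = None,
    cv_repeats: int = 1,
    ranking_trees: int = 500,
) -> FeatureSelectionCurve:
    """Importance-ranked prefix search for the kappa-maximizing feature set.

    A forest of ``ranking_trees`` trees fit on all data ranks taxa by Gini
    importance (a large ensemble keeps the ranking stable); prefixes of
    the ranking are scored by grouped stratified CV kappa (averaged over
    ``cv_repeats`` fold reshuffles) using ``params`` forests.  ``k_star``
    is the first k attaining the curve maximum (tolerance 1e-9), favoring
    smaller marker panels.
    """
    meta = metadata.df.loc[table.sample_ids]
    y = meta["stage"].to_numpy()
    groups = meta["subject_id"].to_numpy()
    n_taxa = table.n_taxa
    if k_max is None:
        k_max = n_taxa
    if k_max > n_taxa:
        warnings.warn(f"k_max {k_max} exceeds taxon count {n_taxa}; clipping")
        k_max = n_taxa
    kwargs = dict(n_jobs=1, random_state=child_int(seed, "rank-rf"))
    if params:
        kwargs.update(params)
    kwargs["n_estimators"] = ranking_trees
    rf = RandomForestClassifier(**kwargs)
    rf.fit(table.values, y)
    imp = pd.Series(rf.feature_importances_, index=table.taxon_ids)
    ranking = list(imp.sort_values(ascending=False, kind="mergesort").index)
    if k_grid is None:
        ks = list(range(1, min(k_max, 30) + 1))
        ks += list(range(35, k_max + 1, 5))
        if ks[-1] != k_max:
            ks.append(k_max)
    else:
        ks = sorted({k for k in k_grid if 1 <= k <= k_max})
    kappas = []
    for k in ks:
        X = table.data[ranking[:k]].to_numpy()
        kappas.append(
            _grouped_cv_kappa(
                X, y, groups, folds, None if seed is None else seed + k,
                params, cv_repeats,
            )
        )
    best = max(kappas)
    k_star = next(k for k, v in zip(ks, kappas) if v >= best - 1e-9)
    return FeatureSelectionCurve(ks, kappas, k_star, ranking)


# ---------------------------------------------------------------------------
# hyperparameter tuning
# ---------------------------------------------------------------------------

_BROAD_SPACE = {
    "n_estimators": [100, 200, 300, 500, 800, 1000],
    "max_depth": [None, 5, 10, 20, 30],
    "min_samples_split": [2, 5, 10, 20],
    "min_samples_leaf": [1, 2, 4],
    "max_features": ["sqrt", "log2", 0.3, 0.5],
    "class_weight": [None, "balanced"],
}


def _neighbors(space: list, value) -> list:
    i = space.index(value)
    lo, hi = max(i - 1, 0), min(i + 1, len(space) - 1)
    return list(dict.fromkeys(space[lo : hi + 1]))


def tune_hyperparameters(
    table: AbundanceTable,
    metadata: CohortMetadata,
    broad_budget: int = 200,
    folds: int = 10,
    seed: int | None = None,
    space: dict | None = None,
) -> dict:
    """Two-phase forest tuning on grouped CV kappa.

    Phase 1 samples ``broad_budget`` random configurations from the broad
    space; phase 2 exhaustively enumerates the grid of +/-1 neighbors per
    dimension around the incumbent.  Returns ``{"best_params", "best_kappa",
    "log"}`` where ``log`` has one row per evaluated configuration.
    """
    if broad_budget < 1:
        raise ValueError("broad_budget must be >= 1")
    space = space or _BROAD_SPACE
    meta = metadata.df.loc[table.sample_ids]
    y = meta["stage"].to_numpy()
    groups = meta["subject_id"].to_numpy()
    X = table.values
    rng = child_rng(seed, "tune")
    names = list(space)
    log_rows = []

    def evaluate(cfg: dict, phase: str, i: int) -> float:
        kappa = _grouped_cv_kappa(
            X, y, groups, folds, None if seed is None else seed, cfg
        )
        log_rows.append({"phase": phase, **cfg, "kappa": kappa, "eval": i})
        return kappa

    best_cfg, best_kappa = None, -np.inf
    for i in range(broad_budget):
        cfg = {k: space[k][rng.integers(len(space[k]))] for k in names}
        kappa = evaluate(cfg, "broad", i)
        if kappa > best_kappa:
            best_cfg, best_kappa = cfg, kappa

    fine_axes = [
        _neighbors(space[k], best_cfg[k]) for k in names
    ]
    for i, combo in enumerate(itertools.product(*fine_axes)):
        cfg = dict(zip(names, combo))
        kappa = evaluate(cfg, "fine", i)
        if kappa > best_kappa:
            best_cfg, best_kappa = cfg, kappa

    return {
        "best_params": best_cfg,
        "best_kappa": float(best_kappa),
        "log": pd.DataFrame(log_rows),
    }


# ---------------------------------------------------------------------------
# repeated evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    per_repeat: pd.DataFrame  # columns: repeat, auc, accuracy, kappa
    n_repeats: int
    train_fraction: float
    means: dict[str, float] = field(init=False)

    def __post_init__(self):
        self.means = {
            m: float(self.per_repeat[m].mean()) for m in ("auc", "accuracy", "kappa")
        }


def _macro_ovr_auc(y_true: np.ndarray, proba: pd.DataFrame) -> float:
    """One-vs-rest AUC per class, arithmetic mean over defined classes."""
    aucs = []
    undefined = []
    for cls in proba.columns:
        pos = y_true == cls
        if pos.all() or not pos.any():
            undefined.append(cls)
            continue
        aucs.append(roc_auc_score(pos, proba[cls].to_numpy()))
    if undefined:
        warnings.warn(f"AUC undefined for classes {undefined}; macro over the rest")
    if not aucs:
        return float("nan")
    return float(np.mean(aucs))


def repeated_evaluation(
    table: AbundanceTable,
    metadata: CohortMetadata,
    n_repeats: int = 10,
    train_fraction: float = 0.7,
    seed: int | None = None,
    params: dict | None = None,
) -> EvaluationReport:
    """Repeat subject-exclusive splits; report OvR AUC, accuracy and kappa.

    Each repeat draws a fresh stratified subject split, fits a forest on
    the training side and scores the held-out side; the report carries
    per-repeat values and their arithmetic means.
    """
    labels = metadata.df.loc[table.sample_ids, "stage"]
    rows = []
    for rep in range(n_repeats):
        rep_seed = child_int(seed, f"repeat/{rep}")
        train_ids, test_ids = subject_split(metadata, train_fraction, rep_seed)
        train_ids = [s for s in train_ids if s in table.data.index]
        test_ids = [s for s in test_ids if s in table.data.index]
        clf = fit_stage_classifier(
            table.subset(train_ids), labels.loc[train_ids], params, seed=rep_seed
        )
        test = table.subset(test_ids)
        proba = clf.predict_proba(test)
        y_true = labels.loc[test_ids].to_numpy()
        y_pred = proba.idxmax(axis=1).to_numpy()
        rows.append(
            {
                "repeat": rep,
                "auc": _macro_ovr_auc(y_true, proba),
                "accuracy": float(accuracy_score(y_true, y_pred)),
                "kappa": float(cohen_kappa_score(y_true, y_pred)),
            }
        )
    return EvaluationReport(pd.DataFrame(rows), n_repeats, train_fraction)
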