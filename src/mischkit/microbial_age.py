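"""Microbial age: subsampled importance ranking, forward selection, prediction.

The microbial age of a sample is the chronological age predicted from its
genus-level composition by a random-forest regressor trained on healthy
subjects.  Feature selection follows a two-step protocol: (1) Gini
importances are averaged over repeated fits on random 90% subsamples;
(2) ranked features are added one at a time and each prefix is scored by
grouped cross-validated mean absolute error (folds grouped by subject so
the two regions of one person never straddle a fold).  The selected set is
the smallest prefix within one standard error of the best CV error, then
the model is refit on all training samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GroupKFold, KFold

from ._seeds import child_int, child_rng
from .data_model import AbundanceTable, CohortMetadata, age_bin_center

__all__ = [
    "FeatureRanking",
    "AgeModel",
    "rank_age_features",
    "forward_select_age_features",
    "train_age_model",
    "predict_microbial_age",
    "age_curve",
    "age_curve_slopes",
]

DEFAULT_TREES = 500


@dataclass
class FeatureRanking:
    importances: pd.Series  # taxon -> mean Gini importance, non-increasing
    n_iterations: int
    subsample: float

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.importances.index)


@dataclass
class AgeModel:
    selected: list[str]
    regressor: RandomForestRegressor
    cv_curve: pd.DataFrame  # columns: k, mae, se
    seed: int | None


def rank_age_features(
    table: AbundanceTable,
    ages: pd.Series,
    n_iterations: int = 10,
    subsample: float = 0.9,
    seed: int | None = None,
    n_estimators: int = DEFAULT_TREES,
) -> FeatureRanking:
    """Rank taxa by mean Gini importance over subsampled regressor fits.

    Each iteration fits a random forest on a random ``subsample`` fraction
    of the samples; the final ranking averages the impurity importances
    across iterations.  A master seed spawns one stream per iteration, so
    increasing ``n_iterations`` extends — never reshuffles — the sequence.
    """
    ages = ages.loc[table.sample_ids]
    n = table.n_samples
    if n < 10:
        raise ValueError(f"need >= 10 samples to rank features, got {n}")
    n_sub = int(round(subsample * n))
    if n_sub < 2:
        raise ValueError("subsample fraction leaves fewer than 2 samples")
    X = table.values
    y = ages.to_numpy(dtype=float)
    total = np.zeros(table.n_taxa)
    for it in range(n_iterations):
        rng = child_rng(seed, f"rank/{it}")
        idx = rng.choice(n, size=n_sub, replace=False)
        rf = RandomForestRegressor(
            n_estimators=n_estimators,
            random_state=child_int(seed, f"rank-rf/{it}"),
            n_jobs=1,
        )
        rf.fit(X[idx], y[idx])
        total += rf.feature_importances_
    mean_imp = pd.Series(total / n_iterations, index=table.taxon_ids)
    mean_imp = mean_imp.sort_values(ascending=False, kind="mergesort")
    return FeatureRanking(mean_imp, n_iterations, subsample)


def _cv_mae(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None,
    folds: int,
    seed: int | None,
    n_estimators: int,
) -> tuple[float, float]:
    """Grouped K-fold CV mean absolute error (mean, standard error)."""
    if groups is not None:
        splitter = GroupKFold(n_splits=folds)
        split = splitter.split(X, y, groups)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=child_int(seed, "kf"))
        split = splitter.split(X, y)
    errs = []
    for i, (tr, te) in enumerate(split):
        rf = RandomForestRegressor(
            n_estimators=n_estimators,
            random_state=child_int(seed, f"cv-rf/{i}"),
            n_jobs=1,
        )
        rf.fit(X[tr], y[tr])
        errs.append(float(np.mean(np.abs(rf.predict(X[te]) - y[te]))))
    errs = np.asarray(errs)
    return float(errs.mean()), float(errs.std(ddof=1) / math.sqrt(len(errs)))


def forward_select_age_features(
    ranking: FeatureRanking,
    table: AbundanceTable,
    ages: pd.Series,
    folds: int = 10,
    seed: int | None = None,
    groups: pd.Series | None = None,
    n_estimators: int = DEFAULT_TREES,
    k_max: int | None = None,
) -> AgeModel:
    """Evaluate ranking prefixes by CV error; keep the most parsimonious.

    The selection criterion is cross-validated MAE; ties are broken toward
    fewer features via the one-standard-error rule.  The returned model is
    refit on every sample using the selected taxa.
    """
    ages = ages.loc[table.sample_ids]
    n = table.n_samples
    if folds > n:
        raise ValueError(f"folds ({folds}) exceeds sample count ({n})")
    order = [t for t in ranking.taxon_ids if t in table.data.columns]
    if not order:
        raise ValueError("ranking shares no taxa with the table")
    k_hi = min(k_max or 20, len(order))
    y = ages.to_numpy(dtype=float)
    grp = None if groups is None else groups.loc[table.sample_ids].to_numpy()
    rows = []
    for k in range(1, k_hi + 1):
        X = table.data[order[:k]].to_numpy()
        mae, se = _cv_mae(X, y, grp, folds, None if seed is None else seed + k, n_estimators)
        rows.append({"k": k, "mae": mae, "se": se})
    curve = pd.DataFrame(rows)
    best = curve["mae"].idxmin()
    threshold = curve.loc[best, "mae"] + curve.loc[best, "se"]
    k_sel = int(curve.loc[curve["mae"] <= threshold, "k"].min())
    selected = order[:k_sel]
    rf = RandomForestRegressor(
        n_estimators=n_estimators,
        random_state=child_int(seed, "final-rf"),
        n_jobs=1,
    )
    rf.fit(table.data[selected].to_numpy(), y)
    return AgeModel(selected, rf, curve, seed)


def train_age_model(
    table: AbundanceTable,
    metadata: CohortMetadata,
    n_iterations: int = 10,
    subsample: float = 0.9,
    folds: int = 10,
    seed: int | None = None,
    n_estimators: int = DEFAULT_TREES,
    k_max: int | None = None,
    allow_non_healthy: bool = False,
) -> AgeModel:
    """Rank + forward-select + fit on a healthy training cohort.

    Training mixes of healthy and diseased subjects defeat the purpose of
    a healthy reference clock, so non-healthy samples are rejected unless
    ``allow_non_healthy=True``.  CV folds are grouped by subject.
    """
    meta = metadata.df.loc[table.sample_ids]
    if not allow_non_healthy and (meta["stage"] != "Healthy").any():
        bad = sorted(meta.loc[meta["stage"] != "Healthy"].index)
        raise ValueError(
            f"training set contains non-healthy samples (e.g. {bad[:3]}); "
            "pass allow_non_healthy=True to override"
        )
    ages = meta["age"]
    ranking = rank_age_features(
        table, ages, n_iterations, subsample, seed, n_estimators
    )
    return forward_select_age_features(
        ranking,
        table,
        ages,
        folds=folds,
        seed=seed,
        groups=meta["subject_id"],
        n_estimators=n_estimators,
        k_max=k_max,
    )


def predict_microbial_age(model: AgeModel, table: AbundanceTable) -> pd.Series:
    """Predict microbial age for each sample (column order irrelevant)."""
    missing = [t for t in model.selected if t not in table.data.columns]
    if missing:
        raise ValueError(f"table lacks selected taxa: {missing}")
    X = table.data[model.selected].to_numpy()
    pred = model.regressor.predict(X)
    return pd.Series(pred, index=table.sample_ids, name="microbial_age")


def age_curve(
    predictions: pd.Series, metadata: CohortMetadata, bin_width: int = 5
) -> pd.DataFrame:
    """Mean +/- sd of predicted age per (Healthy vs AGA) group and age bin."""
    meta = metadata.df.loc[predictions.index]
    group = np.where(meta["stage"] == "Healthy", "Healthy", "AGA")
    df = pd.DataFrame(
        {"group": group, "age_bin": meta["age_bin"], "pred": predictions.to_numpy()}
    )
    out = (
        df.groupby(["group", "age_bin"], observed=True)["pred"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    out["bin_center"] = out["age_bin"].map(age_bin_center)
    return out.sort_values(["group", "bin_center"]).reset_index(drop=True)


def age_curve_slopes(curve: pd.DataFrame) -> dict[str, float]:
    """Least-squares slope of mean predicted age vs bin center, per group."""
    slopes = {}
    for group, sub in curve.groupby("group"):
        if len(sub) < 2:
            slopes[group] = float("nan")
            continue
        slope = np.polyfit(sub["bin_center"], sub["mean"], 1)[0]
        slopes[group] = float(slope)
    return slopes
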