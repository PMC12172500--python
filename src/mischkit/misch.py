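"""The Microbial Index of Scalp Health (MiSCH).

MiSCH condenses a multi-class stage classifier and Jensen-Shannon
community distances into a single 0-100 score per sample:

1.  For each AGA stage c, d_c is the mean JSD between every healthy sample
    and every stage-c sample on the merged bacteria+fungi table;
    d_Healthy := 0.  Weights are w_c = d_c / max_c d_c, so the most
    dysbiotic stage anchors w = 1.
2.  Class probabilities p_c per sample are averaged over repeated
    subject-exclusive 70/30 splits (a sample contributes only from repeats
    in which it was held out).
3.  score = 100 * (1 - sum_c p_c * w_c), guaranteed in [0, 100]; moving
    probability mass toward a higher-weight stage strictly lowers the
    score.

Scores map to severity categories with upper-closed intervals —
healthy (75, 100], mild (25, 75], moderate (15, 25], severe [0, 15] —
and a sample whose category maps to a more severe stage than its clinical
label is flagged high-risk (e.g. "H–A3", "A5–A7").  Subject-level scores
take the lower of the two regions, the conservative reading of a paired
design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway

from ._seeds import child_int
from .data_model import STAGES, AbundanceTable, CohortMetadata, stage_index
from .diversity import DistanceMatrix, PermanovaResult, jsd, permanova
from .stage_classifier import fit_stage_classifier, subject_split

__all__ = [
    "StageDistanceWeights",
    "MischResult",
    "RiskFlag",
    "stage_distance_weights",
    "averaged_probabilities",
    "misch_score",
    "misch_scores",
    "categorize",
    "subject_score",
    "subject_scores",
    "flag_high_risk",
    "flag_table",
    "compare_flagged_group",
    "score_association_anova",
    "evaluate_flags",
]

CATEGORIES = ("healthy", "mild", "moderate", "severe")

#: category -> the clinical stage it proxies
STAGE_OF_CATEGORY = {
    "healthy": "Healthy",
    "mild": "AGA3",
    "moderate": "AGA5",
    "severe": "AGA7",
}
CATEGORY_OF_STAGE = {v: k for k, v in STAGE_OF_CATEGORY.items()}

_SHORT = {"Healthy": "H", "AGA3": "A3", "AGA5": "A5", "AGA7": "A7"}


@dataclass
class StageDistanceWeights:
    distances: pd.Series  # stage -> mean JSD from healthy group (d_Healthy = 0)
    weights: pd.Series  # stage -> d / max(d)

    @property
    def stage_order(self) -> list[str]:
        return list(self.weights.index)


@dataclass(frozen=True)
class RiskFlag:
    sample_id: str
    clinical_stage: str
    category: str
    mapped_stage: str
    flag: str | None  # e.g. "A5–A7" when mapped is more severe
    direction: str  # "more-severe" | "less-severe" | "concordant"


@dataclass
class MischResult:
    """Per-sample MiSCH output bundle."""

    probabilities: pd.DataFrame  # samples x stages, rows sum to 1
    scores: pd.Series
    categories: pd.Series
    flags: list[RiskFlag]
    weights: StageDistanceWeights
    n_probability_repeats: int


def stage_distance_weights(
    merged: AbundanceTable,
    metadata: CohortMetadata,
    isotonic: bool = False,
) -> StageDistanceWeights:
    """Mean healthy-to-stage JSD per AGA stage, normalized to max 1.

    ``isotonic=True`` enforces monotone non-decreasing weights across
    severity (pool-adjacent-violators), for data sets where empirical
    distances invert the clinical ordering; by default inversions are kept
    as-is with a warning.
    """
    meta = metadata.df.loc[merged.sample_ids]
    healthy_ids = list(meta.index[meta["stage"] == "Healthy"])
    if not healthy_ids:
        raise ValueError("no Healthy samples to anchor stage distances")
    H = merged.data.loc[healthy_ids].to_numpy()
    d = {"Healthy": 0.0}
    for stage in STAGES[1:]:
        ids = list(meta.index[meta["stage"] == stage])
        if not ids:
            raise ValueError(f"stage {stage} has no samples")
        G = merged.data.loc[ids].to_numpy()
        vals = [jsd(h, g) for h in H for g in G]
        d[stage] = float(np.mean(vals))
    dist = pd.Series(d, index=list(STAGES))
    if isotonic:
        vals = dist.to_numpy().copy()
        for i in range(1, len(vals)):  # pool adjacent violators, forward pass
            if vals[i] < vals[i - 1]:
                vals[i] = vals[i - 1]
        dist = pd.Series(vals, index=dist.index)
    elif not dist.is_monotonic_increasing:
        warnings.warn(
            "empirical stage distances are not monotone in severity; "
            "using them as-is (isotonic=True to correct)"
        )
    dmax = dist.max()
    if dmax <= 0:
        raise ValueError("all stage distances are zero; weights undefined")
    return StageDistanceWeights(dist, dist / dmax)


def averaged_probabilities(
    table: AbundanceTable,
    metadata: CohortMetadata,
    n_repeats: int = 20,
    train_fraction: float = 0.7,
    seed: int | None = None,
    params: dict | None = None,
    ensure_coverage: bool = False,
) -> pd.DataFrame:
    """Held-out class probabilities averaged over repeated subject splits.

    Each repeat trains a stage classifier on the training side of a fresh
    subject-exclusive split and records probabilities for the held-out
    side only.  A sample's final p_c is the mean over the repeats in which
    it was held out; a sample never held out raises an error suggesting
    more repeats.  ``ensure_coverage=True`` instead keeps drawing further
    repeats from the same seed stream (up to 3x ``n_repeats``) until every
    sample has been held out at least once.
    """
    labels = metadata.df.loc[table.sample_ids, "stage"]
    stages = [s for s in STAGES if s in set(labels)]
    acc = pd.DataFrame(0.0, index=table.sample_ids, columns=stages)
    counts = pd.Series(0, index=table.sample_ids)
    max_repeats = 3 * n_repeats if ensure_coverage else n_repeats
    rep = 0
    while rep < n_repeats or (ensure_coverage and (counts == 0).any() and rep < max_repeats):
        rep_seed = child_int(seed, f"misch-repeat/{rep}")
        train_ids, test_ids = subject_split(metadata, train_fraction, rep_seed)
        train_ids = [s for s in train_ids if s in table.data.index]
        test_ids = [s for s in test_ids if s in table.data.index]
        clf = fit_stage_classifier(
            table.subset(train_ids), labels.loc[train_ids], params, seed=rep_seed
        )
        proba = clf.predict_proba(table.subset(test_ids))
        acc.loc[test_ids, proba.columns] += proba
        counts.loc[test_ids] += 1
        rep += 1
    never = list(counts.index[counts == 0])
    if never:
        raise ValueError(
            f"samples never assigned to a test side: {never[:5]}; "
            "increase n_repeats"
        )
    out = acc.div(counts, axis=0)
    return out.div(out.sum(axis=1), axis=0)


def misch_score(p, w: StageDistanceWeights | pd.Series) -> float:
    """MiSCH score of one probability vector: 100 * (1 - sum p_c w_c)."""
    weights = w.weights if isinstance(w, StageDistanceWeights) else w
    p = pd.Series(p, index=weights.index) if not isinstance(p, pd.Series) else p
    p = p.reindex(weights.index)
    if p.isna().any():
        raise ValueError("probability vector does not cover all stages")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities sum to {p.sum():.6g}, not 1")
    if (p < -1e-12).any():
        raise ValueError("negative probabilities")
    wv = weights.to_numpy(dtype=float)
    if (wv < 0).any() or (wv > 1).any() or not np.isclose(wv.max(), 1.0):
        raise ValueError("weights must lie in [0,1] with max 1")
    score = 100.0 * (1.0 - float(p.to_numpy() @ wv))
    return min(max(score, 0.0), 100.0)


def misch_scores(
    probabilities: pd.DataFrame, w: StageDistanceWeights
) -> pd.Series:
    """Vectorized :func:`misch_score` over a probability matrix."""
    return pd.Series(
        [misch_score(probabilities.loc[s], w) for s in probabilities.index],
        index=probabilities.index,
        name="misch",
    )


def categorize(score: float) -> str:
    """Severity category of a score; intervals are upper-closed.

    healthy (75, 100], mild (25, 75], moderate (15, 25], severe [0, 15].
    """
    if not (0.0 <= score <= 100.0):
        raise ValueError(f"score {score} outside [0, 100]")
    if score > 75:
        return "healthy"
    if score > 25:
        return "mild"
    if score > 15:
        return "moderate"
    return "severe"


def subject_score(score_t: float | None, score_h: float | None) -> float:
    """Subject-level MiSCH: the lower (more conservative) of the regions."""
    present = [s for s in (score_t, score_h) if s is not None]
    if not present:
        raise ValueError("no region score available")
    if len(present) == 1:
        warnings.warn("only one region score available; using it as-is")
        return float(present[0])
    return float(min(present))


def subject_scores(scores: pd.Series, metadata: CohortMetadata) -> pd.Series:
    """Per-subject min-of-regions score."""
    meta = metadata.df.loc[scores.index]
    out = {}
    for subj, grp in meta.groupby("subject_id"):
        vals = [scores[s] for s in grp.index]
        out[subj] = float(min(vals))
    return pd.Series(out, name="misch")


def flag_high_risk(clinical_stage: str, category: str) -> RiskFlag:
    """Compare a MiSCH category against the clinical stage.

    The flag label ``<clinical>–<mapped>`` (short stage names) is set only
    when the microbiome points to a *more* severe stage than the clinic.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    mapped = STAGE_OF_CATEGORY[category]
    ci, mi = stage_index(clinical_stage), stage_index(mapped)
    if mi > ci:
        direction = "more-severe"
        flag = f"{_SHORT[clinical_stage]}–{_SHORT[mapped]}"
    elif mi < ci:
        direction, flag = "less-severe", None
    else:
        direction, flag = "concordant", None
    return RiskFlag("", clinical_stage, category, mapped, flag, direction)


def flag_table(
    scores: pd.Series, metadata: CohortMetadata
) -> tuple[pd.DataFrame, list[RiskFlag]]:
    """Categorize and flag every sample; returns a frame plus flag objects."""
    meta = metadata.df.loc[scores.index]
    rows, flags = [], []
    for sid in scores.index:
        category = categorize(scores[sid])
        base = flag_high_risk(meta.loc[sid, "stage"], category)
        flag = RiskFlag(sid, base.clinical_stage, base.category,
                        base.mapped_stage, base.flag, base.direction)
        flags.append(flag)
        rows.append(
            {"sample_id": sid, "score": scores[sid], "category": category,
             "clinical_stage": flag.clinical_stage, "mapped_stage": flag.mapped_stage,
             "flag": flag.flag or "", "direction": flag.direction}
        )
    return pd.DataFrame(rows).set_index("sample_id"), flags


def compare_flagged_group(
    dm: DistanceMatrix,
    flagged_ids: list[str],
    reference_groups: dict[str, list[str]],
    n_permutations: int = 999,
    seed: int | None = None,
) -> dict[str, PermanovaResult]:
    """Two-group PERMANOVA of the flagged set against each reference stage.

    A smaller pseudo-F against a stage means the flagged microbiota are
    harder to tell apart from that stage's — the similarity reading used
    to corroborate high-risk calls.
    """
    if not flagged_ids:
        raise ValueError("flagged group is empty")
    results = {}
    for i, (stage, ref_ids) in enumerate(reference_groups.items()):
        ref_ids = [s for s in ref_ids if s not in set(flagged_ids)]
        if len(ref_ids) < 2:
            raise ValueError(f"reference group {stage} has fewer than 2 samples")
        ids = list(flagged_ids) + list(ref_ids)
        sub = dm.submatrix(ids)
        grouping = ["flagged"] * len(flagged_ids) + [stage] * len(ref_ids)
        results[stage] = permanova(
            sub,
            grouping,
            n_permutations,
            seed=None if seed is None else seed + i,
            factor=f"flagged_vs_{stage}",
        )
    return results


def score_association_anova(
    scores: pd.Series, stages: pd.Series
) -> tuple[float, float]:
    """One-way ANOVA of MiSCH scores across clinical stages: (F, p)."""
    stages = stages.loc[scores.index]
    levels = stages.unique()
    if len(levels) < 2:
        raise ValueError("need >= 2 stages for an ANOVA")
    groups = [scores[stages == lvl].to_numpy() for lvl in levels]
    if np.ptp(scores.to_numpy()) == 0:
        return 0.0, 1.0
    f_stat, p = f_oneway(*groups)
    return float(f_stat), float(p)


def evaluate_flags(
    flags: list[RiskFlag],
    truth_ids: list[str],
    flag_label: str | None = None,
    population: list[str] | None = None,
) -> dict[str, float]:
    """Score high-risk flags against a caller-supplied ground truth.

    ``truth_ids`` are the samples that truly belong to the more severe
    group; a flag counts as positive when its label matches ``flag_label``
    (or any non-empty flag when None).  Returns sensitivity, specificity,
    precision and F1 over ``population`` (default: all flagged-table ids).
    """
    by_id = {f.sample_id: f for f in flags}
    ids = population if population is not None else list(by_id)
    truth = set(truth_ids)
    tp = fp = tn = fn = 0
    for sid in ids:
        f = by_id.get(sid)
        positive = bool(f and f.flag and (flag_label is None or f.flag == flag_label))
        if sid in truth:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    f1 = (2 * prec * sens / (prec + sens)) if prec + sens else 0.0
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }


def compute_misch(
    merged: AbundanceTable,
    metadata: CohortMetadata,
    n_repeats: int = 20,
    train_fraction: float = 0.7,
    seed: int | None = None,
    params: dict | None = None,
    isotonic: bool = False,
) -> MischResult:
    """End-to-end MiSCH: weights, averaged probabilities, scores, flags."""
    w = stage_distance_weights(merged, metadata, isotonic=isotonic)
    proba = averaged_probabilities(
        merged, metadata, n_repeats, train_fraction, seed, params,
        ensure_coverage=True,
    )
    scores = misch_scores(proba, w)
    _, flags = flag_table(scores, metadata)
    categories = pd.Series(
        [categorize(s) for s in scores], index=scores.index, name="category"
    )
    return MischResult(proba, scores, categories, flags, w, n_repeats)
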