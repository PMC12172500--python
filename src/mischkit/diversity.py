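"""Alpha diversity, Jensen-Shannon beta diversity, ordination and PERMANOVA.

Alpha diversity covers the Shannon index (natural log by default, with a
configurable base), the Gini-Simpson index 1 - sum(p^2), and the
bias-corrected Chao1 richness estimator on integer counts.

Beta diversity is the Jensen-Shannon divergence (JSD) in base 2, so
distances live in [0, 1]: JSD(p, q) = H(m) - (H(p) + H(q)) / 2 with
m = (p + q)/2 and the 0*log(0) := 0 convention.  The divergence itself is
reported (not its metric square root); pass ``sqrt=True`` for the metric.

PERMANOVA follows Anderson's direct decomposition of the squared-distance
sum into within- and between-group parts, with an add-one permutation
p-value.  For tiny designs an exact mode enumerates every relabeling.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway, mannwhitneyu, spearmanr
from skbio.diversity.alpha import chao1 as _skbio_chao1

from .data_model import AbundanceTable, CohortMetadata

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "OrdinationResult",
    "shannon",
    "simpson",
    "chao1",
    "alpha_diversity",
    "jsd",
    "jsd_matrix",
    "pcoa",
    "permanova",
    "factor_effect_sizes",
    "alpha_factor_anova",
    "rank_sum_test",
    "spearman_age_correlations",
    "fdr_bh",
]


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------


def shannon(p: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy -sum p log p of a composition (natural log default)."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def simpson(p: np.ndarray) -> float:
    """Gini-Simpson index 1 - sum p^2."""
    p = np.asarray(p, dtype=float)
    return float(1.0 - (p**2).sum())


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1: S_obs + F1 (F1 - 1) / (2 (F2 + 1)).

    Requires integer counts — singleton/doubleton frequencies are undefined
    on relative abundances.
    """
    counts = np.asarray(counts)
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("chao1 requires integer counts, not relative abundances")
    return float(_skbio_chao1(counts.astype(int), bias_corrected=True))


def alpha_diversity(
    table: AbundanceTable,
    metric: str = "shannon",
    counts: pd.DataFrame | None = None,
    base: float | None = None,
) -> pd.Series:
    """Per-sample alpha diversity.

    ``metric`` is one of ``shannon``, ``simpson``, ``chao1``.  Chao1 needs
    an integer count matrix aligned with the table's samples.
    """
    if metric == "shannon":
        vals = [shannon(row, base=base) for row in table.values]
    elif metric == "simpson":
        vals = [simpson(row) for row in table.values]
    elif metric == "chao1":
        if counts is None:
            raise ValueError("chao1 requires a count matrix")
        counts = counts.loc[table.sample_ids]
        vals = [chao1(row) for row in counts.to_numpy()]
    else:
        raise ValueError(f"unknown alpha metric {metric!r}")
    return pd.Series(vals, index=table.sample_ids, name=metric)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

_LN2 = math.log(2.0)


def jsd(p: np.ndarray, q: np.ndarray, sqrt: bool = False) -> float:
    """Jensen-Shannon divergence in base 2 between two compositions."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = (p + q) / 2.0
    val = shannon(m) - (shannon(p) + shannon(q)) / 2.0
    val = min(max(val / _LN2, 0.0), 1.0)
    return math.sqrt(val) if sqrt else val


@dataclass
class DistanceMatrix:
    """Symmetric sample x sample distances with a zero diagonal."""

    sample_ids: list[str]
    data: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.shape[0] != d.shape[1] or d.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise ValueError("negative distances")
        self.data = np.clip(d, 0.0, None)
        self.sample_ids = [str(s) for s in self.sample_ids]

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)


def jsd_matrix(table: AbundanceTable, sqrt: bool = False) -> DistanceMatrix:
    """All-pairs Jensen-Shannon divergence (base 2) of a normalized table."""
    if not table.is_normalized(tol=1e-6):
        raise ValueError("table rows must sum to 1 before computing JSD")
    X = table.values
    # scipy's jensenshannon metric is sqrt(JSD) in nats; square and rescale
    d = pdist(X, metric="jensenshannon") ** 2 / _LN2
    d = np.clip(d, 0.0, 1.0)
    if sqrt:
        d = np.sqrt(d)
    return DistanceMatrix(table.sample_ids, squareform(d))


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: pd.DataFrame  # samples x axes, axes ordered by eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per retained axis, over positive eigs


def pcoa(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Principal coordinate analysis (classical scaling).

    Eigendecomposition of the double-centered ``-D^2/2`` matrix.  Negative
    eigenvalues (non-Euclidean input) are reported but never used for axes;
    if ``k`` exceeds the number of positive eigenvalues the result is
    truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D2 = dm.data**2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10
    pos = eigval > tol
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating"
        )
        k = max(n_pos, 1)
    coords = eigvec[:, :k] * np.sqrt(np.clip(eigval[:k], 0.0, None))
    frame = pd.DataFrame(
        coords, index=dm.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    pos_sum = eigval[pos].sum() if n_pos else 1.0
    proportions = np.clip(eigval[:k], 0.0, None) / pos_sum
    return OrdinationResult(dm.sample_ids, frame, eigval, proportions)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    factor: str
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int

    def as_dict(self) -> dict:
        return {
            "factor": self.factor,
            "pseudo_F": self.pseudo_f,
            "R2": self.r_squared,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
        }


def _ss_parts(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """Total and within-group squared-distance sums (Anderson's identity)."""
    n = len(codes)
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def _pseudo_f(ss_total: float, ss_within: float, n: int, a: int) -> float:
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
    factor: str = "grouping",
    method: str = "permutation",
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    ``method='permutation'`` uses ``n_permutations`` random relabelings and
    the add-one estimator p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    ``method='exact'`` enumerates all n! label orderings (n <= 9 only) and
    reports p = #{F_perm >= F_obs} / n! (the identity is included, so p > 0).
    """
    labels = pd.Series(list(grouping))
    if len(labels) != len(dm.sample_ids):
        raise ValueError("grouping length does not match distance matrix")
    cats = pd.Categorical(labels)
    codes = np.asarray(cats.codes)
    a = len(cats.categories)
    if a < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 groups")
    sizes = np.bincount(codes, minlength=a)
    if (sizes < 2).any():
        singles = [str(cats.categories[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"singleton group(s) in {factor!r}: {singles}")
    n = len(codes)
    d2 = dm.data**2
    ss_total, ss_within = _ss_parts(d2, codes, a)
    if ss_within <= 0:
        raise ValueError("degenerate distances: zero within-group variation")
    f_obs = _pseudo_f(ss_total, ss_within, n, a)
    r2 = (ss_total - ss_within) / ss_total

    eps = 1e-12 * max(abs(f_obs), 1.0)
    if method == "exact":
        if n > 9:
            raise ValueError("exact enumeration supported only for n <= 9")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            _, ssw = _ss_parts(d2, codes[list(perm)], a)
            if _pseudo_f(ss_total, ssw, n, a) >= f_obs - eps:
                count += 1
            total += 1
        return PermanovaResult(factor, f_obs, r2, count / total, total)

    rng = np.random.default_rng(seed)
    perm_codes = rng.permuted(
        np.tile(codes, (n_permutations, 1)), axis=1
    )
    # within-group pair sums, vectorized over permutations
    ssw = np.zeros(n_permutations)
    for g in range(a):
        Z = (perm_codes == g).astype(float)
        pair = np.einsum("pi,ij,pj->p", Z, d2, Z) / 2.0
        ssw += pair / sizes[g]
    f_perm = (ss_total - ssw) / (a - 1) / (ssw / (n - a))
    count = int((f_perm >= f_obs - eps).sum())
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(factor, f_obs, r2, p, n_permutations)


def factor_effect_sizes(
    dm: DistanceMatrix,
    metadata: CohortMetadata,
    factors: list[str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> list[PermanovaResult]:
    """Single-factor PERMANOVA per metadata factor, ordered by pseudo-F.

    ``age`` is tested through its 5-year bins.
    """
    df = metadata.df.loc[dm.sample_ids]
    results = []
    for i, factor in enumerate(factors):
        col = "age_bin" if factor == "age" else factor
        if col not in df.columns:
            raise ValueError(f"unknown factor {factor!r}")
        values = df[col]
        if values.nunique() < 2:
            raise ValueError(f"factor {factor!r} has a single level")
        child = None if seed is None else seed + i
        results.append(
            permanova(dm, values, n_permutations, seed=child, factor=factor)
        )
    return sorted(results, key=lambda r: r.pseudo_f, reverse=True)


# ---------------------------------------------------------------------------
# univariate statistics
# ---------------------------------------------------------------------------


def alpha_factor_anova(
    alpha: pd.Series, metadata: CohortMetadata, factors: list[str]
) -> pd.DataFrame:
    """One-way ANOVA of an alpha-diversity vector per categorical factor."""
    df = metadata.df.loc[alpha.index]
    rows = []
    for factor in factors:
        col = "age_bin" if factor == "age" else factor
        if col not in df.columns:
            raise ValueError(f"unknown factor {factor!r}")
        groups = [alpha[df[col] == lvl].to_numpy() for lvl in df[col].unique()]
        if len(groups) < 2:
            raise ValueError(f"factor {factor!r} has fewer than 2 levels")
        if np.ptp(np.concatenate(groups)) == 0:
            f_stat, p = 0.0, 1.0  # identical values everywhere
        else:
            f_stat, p = f_oneway(*groups)
            if np.isnan(f_stat):
                f_stat, p = 0.0, 1.0
        rows.append({"factor": factor, "F": float(f_stat), "p_value": float(p)})
    return pd.DataFrame(rows).set_index("factor")


def rank_sum_test(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) with normal approximation for ties."""
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def spearman_age_correlations(
    table: AbundanceTable, ages: pd.Series
) -> pd.DataFrame:
    """Per-taxon Spearman correlation with age, with BH-FDR q-values."""
    ages = ages.loc[table.sample_ids]
    rows = []
    for taxon in table.taxon_ids:
        rho, p = spearmanr(table.data[taxon], ages)
        rows.append({"taxon": taxon, "rho": float(rho), "p_value": float(p)})
    out = pd.DataFrame(rows).set_index("taxon")
    out["q_value"] = fdr_bh(out["p_value"].to_numpy())
    return out


def fdr_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    return multipletests(pvals, method="fdr_bh")[1]
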