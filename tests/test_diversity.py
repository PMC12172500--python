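"""Alpha diversity, JSD, PCoA and PERMANOVA against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import mischkit as mk
from mischkit.diversity import (
    DistanceMatrix,
    alpha_factor_anova,
    chao1,
    jsd,
    shannon,
    simpson,
)

from conftest import random_table


class TestAlphaDiversity:
    def test_shannon_uniform_is_log_k(self):
        assert shannon(np.full(4, 0.25)) == pytest.approx(math.log(4), abs=1e-12)

    def test_single_taxon_has_zero_diversity(self):
        assert shannon([1.0, 0.0]) == 0.0
        assert simpson([1.0, 0.0]) == pytest.approx(0.0)

    def test_simpson_uniform(self):
        assert simpson([0.5, 0.5]) == pytest.approx(0.5)

    def test_chao1_bias_corrected_formula(self):
        # S_obs=4, F1=2 singletons, F2=1 doubleton: 4 + 2*1/(2*(1+1)) = 4.5
        assert chao1([5, 2, 1, 1]) == pytest.approx(4.5)

    def test_chao1_rejects_relative_abundance(self):
        with pytest.raises(ValueError, match="integer"):
            chao1([0.5, 0.3, 0.2])

    def test_shannon_maximized_by_uniform(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(6))
            assert shannon(p) <= math.log(6) + 1e-12

    def test_per_sample_series(self, tiny_table):
        vals = mk.alpha_diversity(tiny_table, "shannon")
        assert list(vals.index) == tiny_table.sample_ids
        assert vals["s1"] == pytest.approx(math.log(2))


class TestJsd:
    def test_identical_distributions_diverge_zero(self):
        assert jsd([0.2, 0.8], [0.2, 0.8]) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_maximal(self):
        assert jsd([1, 0], [0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_term_by_term_oracle(self):
        # independent evaluation: H2(m) - (H2(p) + H2(q))/2 with base-2 logs
        p, q = np.array([1.0, 0.0]), np.array([0.5, 0.5])
        m = (p + q) / 2

        def h2(v):
            return -sum(x * math.log2(x) for x in v if x > 0)

        expected = h2(m) - (h2(p) + h2(q)) / 2
        assert expected == pytest.approx(h2([0.75, 0.25]) - 0.5)
        assert jsd(p, q) == pytest.approx(expected, abs=1e-12)

    def test_matrix_matches_pairwise_and_is_bounded(self, tiny_table):
        dm = mk.jsd_matrix(tiny_table)
        for i, si in enumerate(tiny_table.sample_ids):
            for j, sj in enumerate(tiny_table.sample_ids):
                expected = jsd(tiny_table.values[i], tiny_table.values[j])
                assert dm.data[i, j] == pytest.approx(expected, abs=1e-12)
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        assert np.allclose(dm.data, dm.data.T)

    def test_unnormalized_table_rejected(self):
        df = pd.DataFrame([[1.0, 1.0]], index=["s1"], columns=["a", "b"])
        table = mk.AbundanceTable(df, "bacteria")
        with pytest.raises(ValueError, match="sum to 1"):
            mk.jsd_matrix(table)


class TestPcoa:
    def test_three_equidistant_points_give_equal_axes(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = mk.pcoa(DistanceMatrix(["a", "b", "c"], d), k=2)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_collinear_points_have_one_dominant_axis(self):
        x = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
        d = np.abs(x[:, None] - x[None, :])
        res = mk.pcoa(DistanceMatrix([f"s{i}" for i in range(5)], d), k=1)
        assert res.proportion_explained[0] >= 0.99

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = mk.pcoa(DistanceMatrix([f"s{i}" for i in range(6)], d), k=3)
        coords = res.coordinates.to_numpy()
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_matches_skbio_ordination(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DistanceMatrix([f"s{i}" for i in range(5)], d)
        ours = mk.pcoa(dm, k=2)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.data, ids=dm.sample_ids)
        )
        ref = theirs.samples.to_numpy()[:, :2]
        got = ours.coordinates.to_numpy()
        for axis in range(2):  # eigenvectors are sign-ambiguous
            assert min(
                np.abs(got[:, axis] - ref[:, axis]).max(),
                np.abs(got[:, axis] + ref[:, axis]).max(),
            ) < 1e-8

    def test_excess_axes_truncated_with_warning(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.warns(UserWarning, match="truncating"):
            res = mk.pcoa(DistanceMatrix(list("abc"), d), k=5)
        assert res.coordinates.shape[1] == 2


def _brute_force_permanova_f(d, labels):
    """Independent pseudo-F oracle from the definition."""
    n = len(labels)
    groups = sorted(set(labels))
    a = len(groups)
    sst = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ssw = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        ssw += sum(
            d[i, j] ** 2 for ii, i in enumerate(idx) for j in idx[ii + 1:]
        ) / len(idx)
    ssb = sst - ssw
    return (ssb / (a - 1)) / (ssw / (n - a))


class TestPermanova:
    @pytest.fixture()
    def toy(self):
        rng = np.random.default_rng(8)
        table = random_table(rng, 6, 5)
        return mk.jsd_matrix(table), ["g1", "g1", "g1", "g2", "g2", "g2"]

    def test_exact_enumeration_matches_brute_force(self, toy):
        dm, labels = toy
        res = mk.permanova(dm, labels, method="exact")
        # oracle: enumerate all 720 orderings with the independent F
        f_obs = _brute_force_permanova_f(dm.data, labels)
        assert res.pseudo_f == pytest.approx(f_obs, rel=1e-10)
        count = 0
        for perm in itertools.permutations(range(6)):
            relabeled = [labels[i] for i in perm]
            if _brute_force_permanova_f(dm.data, relabeled) >= f_obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / math.factorial(6))
        assert res.n_permutations == 720

    def test_matches_skbio_pseudo_f(self, toy):
        skbio = pytest.importorskip("skbio")
        dm, labels = toy
        ours = mk.permanova(dm, labels, n_permutations=99, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.data, ids=dm.sample_ids),
            grouping=labels,
            permutations=0,
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_strong_separation_saturates_p(self):
        rng = np.random.default_rng(1)
        a = rng.dirichlet([50, 5, 1], size=8)
        b = rng.dirichlet([1, 5, 50], size=8)
        df = pd.DataFrame(
            np.vstack([a, b]),
            index=[f"s{i}" for i in range(16)],
            columns=["t1", "t2", "t3"],
        )
        dm = mk.jsd_matrix(mk.AbundanceTable(df, "bacteria"))
        res = mk.permanova(dm, ["a"] * 8 + ["b"] * 8, n_permutations=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_singleton_group_rejected(self, toy):
        dm, _ = toy
        with pytest.raises(ValueError, match="singleton"):
            mk.permanova(dm, ["a", "b", "b", "b", "b", "b"])

    def test_r_squared_in_unit_interval(self, toy):
        dm, labels = toy
        res = mk.permanova(dm, labels, n_permutations=99, seed=1)
        assert 0.0 <= res.r_squared <= 1.0
        assert res.p_value >= 1 / 100

    def test_deterministic_under_seed(self, toy):
        dm, labels = toy
        r1 = mk.permanova(dm, labels, n_permutations=199, seed=42)
        r2 = mk.permanova(dm, labels, n_permutations=199, seed=42)
        assert r1.p_value == r2.p_value


class TestFactorEffects:
    def test_planted_stage_effect_dominates(self, small_merged, small_cohort):
        _, _, meta = small_cohort
        dm = mk.jsd_matrix(small_merged)
        results = mk.factor_effect_sizes(
            dm, meta, ["stage", "region", "age"], n_permutations=99, seed=0
        )
        assert results[0].factor == "stage"
        assert results[0].pseudo_f == max(r.pseudo_f for r in results)

    def test_single_level_factor_rejected(self, small_merged, small_cohort):
        _, _, meta = small_cohort
        dm = mk.jsd_matrix(small_merged)
        df = meta.df.copy()
        df["region"] = "T"
        with pytest.raises(ValueError, match="single level"):
            mk.factor_effect_sizes(dm, mk.CohortMetadata(df), ["region"], 49)


class TestAlphaAnova:
    def test_textbook_two_group_f(self):
        # groups (1,2,3) vs (4,5,6): SSB=13.5, SSW=4 on 4 df -> F = 13.5
        alpha = pd.Series(
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=[f"s{i}" for i in range(6)]
        )
        meta = mk.CohortMetadata(
            pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(6)],
                    "subject_id": [f"u{i}" for i in range(6)],
                    "region": ["T"] * 6,
                    "age": [30] * 6,
                    "stage": ["Healthy"] * 3 + ["AGA3"] * 3,
                }
            )
        )
        out = alpha_factor_anova(alpha, meta, ["stage"])
        assert out.loc["stage", "F"] == pytest.approx(13.5)

    def test_identical_values_give_zero_f(self):
        alpha = pd.Series([2.0] * 6, index=[f"s{i}" for i in range(6)])
        meta = mk.CohortMetadata(
            pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(6)],
                    "subject_id": [f"u{i}" for i in range(6)],
                    "region": ["T"] * 6,
                    "age": [30] * 6,
                    "stage": ["Healthy"] * 3 + ["AGA3"] * 3,
                }
            )
        )
        out = alpha_factor_anova(alpha, meta, ["stage"])
        assert out.loc["stage", "F"] == 0.0
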