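"""Correlation ranking, shuffle nulls, significance flagging, U tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from smrlink._exceptions import InputError
from smrlink.qc import ExpressionMatrix
from smrlink.stats import (
    CorrelationModel,
    correlate_genes,
    flag_significant,
    mannwhitney_groups,
    pc_biophysics_test,
    shuffle_null,
    spearman,
    wilcoxon_de,
)


def rank_then_pearson(x, y):
    """Independent oracle: mid-ranks by sorting, then Pearson via corrcoef."""

    def midrank(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks

    return np.corrcoef(midrank(x), midrank(y))[0, 1]


def logtpm_matrix(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cells), layer="logTPM")


class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
            ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0),
        ],
    )
    def test_monotone_extremes(self, x, y, expected):
        assert spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_rank_then_pearson_oracle(self):
        cases = [
            ([1, 2, 3, 4], [2, 1, 4, 3]),
            ([1.0, 1.0, 2.0, 3.0, 3.0], [5.0, 1.0, 2.0, 2.0, 4.0]),  # ties both sides
            (np.random.default_rng(0).normal(size=30), np.random.default_rng(1).normal(size=30)),
        ]
        for x, y in cases:
            assert spearman(x, y) == pytest.approx(rank_then_pearson(x, y), abs=1e-12)

    def test_constant_vector_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(-100, 100), min_size=5, max_size=20, unique=True),
        st.floats(0.1, 5.0),
        st.floats(-5.0, 5.0),
    )
    def test_invariant_under_strictly_monotone_transform(self, xs, scale, shift):
        rng = np.random.default_rng(42)
        y = rng.normal(size=len(xs))
        x = np.array(xs, dtype=float)
        assert spearman(np.exp(scale * x / 100.0) + shift, y) == pytest.approx(
            spearman(x, y), abs=1e-12
        )


class TestCorrelateGenes:
    def test_gene_equal_to_covariate_tops_list(self):
        rng = np.random.default_rng(0)
        cov = rng.uniform(0.0, 5.0, size=20)
        values = rng.uniform(0.0, 5.0, size=(10, 20))
        values[3] = cov
        ranked = correlate_genes(logtpm_matrix(values), cov)
        assert ranked.entries.index[0] == "g3"
        assert ranked.entries.iloc[0]["rho"] == pytest.approx(1.0, abs=1e-12)

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(InputError):
            correlate_genes(logtpm_matrix(np.ones((3, 5))), np.zeros(4))

    def test_permuted_covariate_coefficients_concentrate_near_zero(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(200, 200)) ** 2
        cov = rng.permutation(rng.normal(size=200))
        ranked = correlate_genes(logtpm_matrix(values), cov)
        assert abs(ranked.entries["rho"].mean()) < 0.05

    def test_agrees_with_scipy_per_gene(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(15, 40)) ** 2
        cov = rng.normal(size=40)
        ranked = correlate_genes(logtpm_matrix(values), cov)
        for gene in ranked.entries.index:
            i = int(gene[1:])
            expected, _ = sps.spearmanr(values[i], cov)
            assert ranked.entries.loc[gene, "rho"] == pytest.approx(expected, abs=1e-12)


class TestShuffleNull:
    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(3)
        m = logtpm_matrix(rng.normal(size=(20, 30)) ** 2)
        cov = rng.normal(size=30)
        a = shuffle_null(m, cov, n_iterations=200, seed=5)
        b = shuffle_null(m, cov, n_iterations=200, seed=5)
        assert (a.mean, a.sd) == (b.mean, b.sd)

    def test_null_mean_is_centered(self):
        rng = np.random.default_rng(4)
        m = logtpm_matrix(rng.normal(size=(50, 40)) ** 2)
        cov = rng.normal(size=40)
        null = shuffle_null(m, cov, n_iterations=2000, seed=6)
        pool = 50 * 2000
        assert abs(null.mean) < 3.0 * null.sd / np.sqrt(pool) + 1e-3

    def test_null_sd_matches_analytic_spearman_sd(self):
        # for a single gene over n cells the permutation SD is ~1/sqrt(n-1)
        rng = np.random.default_rng(5)
        n = 20
        m = logtpm_matrix(rng.normal(size=(1, n)) ** 2)
        null = shuffle_null(m, rng.normal(size=n), n_iterations=20_000, seed=7)
        assert null.sd == pytest.approx(1.0 / np.sqrt(n - 1), rel=0.1)

    def test_seed_required(self):
        m = logtpm_matrix(np.ones((2, 5)) * np.arange(5))
        with pytest.raises(InputError):
            shuffle_null(m, np.arange(5), n_iterations=10)

    def test_bad_iterations_rejected(self):
        m = logtpm_matrix(np.ones((2, 5)) * np.arange(5))
        with pytest.raises(InputError):
            shuffle_null(m, np.arange(5), n_iterations=0, seed=1)


class TestFlagSignificant:
    def make_ranked(self, rhos):
        from smrlink.stats import RankedGeneList

        entries = pd.DataFrame(
            {"rho": rhos}, index=[f"g{i}" for i in range(len(rhos))]
        )
        entries.index.name = "gene"
        return RankedGeneList(covariate_name="mass", entries=entries)

    def test_two_sd_rule_boundaries(self):
        from smrlink.stats import NullDistribution

        null = NullDistribution(n_iterations=100, mean=0.1, sd=0.05, seed=0)
        # exactly at the mean, just beyond +/- 2 SD, and just inside 2 SD
        ranked = self.make_ranked([0.1, 0.1 + 2.0001 * 0.05, 0.1 - 2.0001 * 0.05, 0.19])
        flagged = flag_significant(ranked, null).entries.sort_index()
        assert flagged["significant"].tolist() == [False, True, True, False]
        sig = flagged[flagged["significant"]].sort_values("rho", ascending=False)
        assert sig["direction"].tolist() == ["+", "-"]

    def test_zero_null_sd_warns(self):
        from smrlink.stats import NullDistribution

        null = NullDistribution(n_iterations=10, mean=0.0, sd=0.0, seed=0)
        with pytest.warns(UserWarning, match="null SD is zero"):
            flagged = flag_significant(self.make_ranked([0.2, 0.0]), null).entries
        assert flagged.sort_index()["significant"].tolist() == [True, False]

    def test_per_gene_null_mode(self):
        rng = np.random.default_rng(9)
        m = logtpm_matrix(rng.normal(size=(5, 25)) ** 2)
        cov = rng.normal(size=25)
        ranked = correlate_genes(m, cov)
        null = shuffle_null(m, cov, n_iterations=500, seed=2, per_gene=True)
        flagged = flag_significant(ranked, null).entries
        assert flagged["null_sd"].nunique() > 1  # per-gene moments in use


class TestPCBiophysics:
    def test_covariate_equal_to_pc1_is_significant(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(40, 30))
        base[:10] += 3.0 * rng.normal(size=30)[None, :]  # strong PC1
        m = logtpm_matrix(base**2)
        first = pc_biophysics_test(m, rng.normal(size=30), n_pcs=3, n_iterations=200, seed=1)
        cov = None
        # rerun with the PC1 coordinates themselves as the covariate
        from sklearn.decomposition import PCA

        values = m.values.to_numpy()
        sub = values[np.argsort(np.where(values.mean(1) > 0, values.var(1) / values.mean(1), 0))[::-1]]
        sub = sub[sub.std(axis=1) > 0]
        scaled = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
        cov = PCA(n_components=3, random_state=0).fit_transform(scaled.T)[:, 0]
        verdicts = pc_biophysics_test(m, cov, n_pcs=3, n_iterations=500, seed=1)
        assert verdicts.loc["PC1", "rho"] == pytest.approx(1.0, abs=1e-9)
        assert bool(verdicts.loc["PC1", "significant"])

    def test_permuted_covariate_rarely_significant(self):
        rng = np.random.default_rng(11)
        m = logtpm_matrix(rng.normal(size=(100, 50)) ** 2)
        hits = []
        for seed in range(5):
            cov = np.random.default_rng(seed).permutation(50).astype(float)
            verdicts = pc_biophysics_test(m, cov, n_pcs=10, n_iterations=1000, seed=seed)
            hits.append(int(verdicts["significant"].sum()))
        assert sum(h <= 1 for h in hits) >= 3  # majority of seeds

    def test_too_few_cells_rejected(self):
        m = logtpm_matrix(np.ones((5, 2)))
        with pytest.raises(InputError):
            pc_biophysics_test(m, np.arange(2), seed=0)


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        assert mannwhitney_groups([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_exact_enumeration_small_case(self):
        assert mannwhitney_groups([1.0, 2.0], [3.0, 4.0]) == pytest.approx(2.0 / 6.0)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 8))
            b = rng.normal(size=rng.integers(3, 8)) + rng.normal() * 0.5
            ours = mannwhitney_groups(a, b, method="exact")
            theirs = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            n_a, n_b = rng.choice([(8, 8), (5, 7), (6, 8), (8, 4)])
            a = rng.normal(size=n_a)
            b = rng.normal(size=n_b) + rng.normal() * 0.5
            assert mannwhitney_groups(a, b, method="normal") == pytest.approx(
                mannwhitney_groups(a, b, method="exact"), abs=0.01
            )

    def test_power_on_shifted_normals(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.0, 1.0, size=50)
            b = rng.normal(2.0, 1.0, size=50)
            if mannwhitney_groups(a, b) < 0.001:
                hits += 1
        assert hits >= 95

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            mannwhitney_groups([], [1.0])


class TestWilcoxonDE:
    def test_identical_groups_give_p_one_and_zero_lfc(self):
        # group B repeats group A's values exactly
        values = np.tile(np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0]), (4, 1))
        m = logtpm_matrix(values)
        res = wilcoxon_de(m, np.array(["A"] * 3 + ["B"] * 3))
        assert (res.table["p_raw"] == 1.0).all()
        assert np.allclose(res.table["log_fold_change"], 0.0)

    def test_exact_p_matches_brute_force_enumeration(self):
        from itertools import combinations

        values = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        m = logtpm_matrix(values)
        res = wilcoxon_de(m, np.array(["A"] * 3 + ["B"] * 3))
        # oracle: enumerate all C(6,3)=20 assignments of the pooled sample
        pooled = values[0]
        ranks = sps.rankdata(pooled)
        mu = 3 * 3 / 2.0
        u_obs = ranks[:3].sum() - 6.0
        count = sum(
            1
            for comb in combinations(range(6), 3)
            if abs(ranks[list(comb)].sum() - 6.0 - mu) >= abs(u_obs - mu) - 1e-12
        )
        assert res.table["p_raw"].iloc[0] == pytest.approx(count / 20.0, abs=1e-12)
        assert res.table["p_raw"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_bonferroni_scales_with_genes_tested(self):
        rng = np.random.default_rng(14)
        m = logtpm_matrix(rng.normal(size=(30, 20)) ** 2)
        res = wilcoxon_de(m, np.array(["A"] * 10 + ["B"] * 10))
        expected = np.minimum(1.0, res.table["p_raw"] * 30)
        assert np.allclose(res.table["p_bonferroni"], expected)

    def test_group_size_validation(self):
        m = logtpm_matrix(np.ones((2, 4)) * np.arange(4))
        with pytest.raises(InputError):
            wilcoxon_de(m, np.array(["A", "A", "B", "B"]))  # only 2 per group

    def test_planted_shift_enriches_significant_set(self):
        rng = np.random.default_rng(15)
        values = rng.normal(5.0, 1.0, size=(100, 40))
        values[:10, 20:] += 3.0  # planted up-shift in group B
        m = logtpm_matrix(np.abs(values))
        res = wilcoxon_de(m, np.array(["A"] * 20 + ["B"] * 20))
        sig = res.table[res.table["p_bonferroni"] < 0.05].index
        planted = {f"g{i}" for i in range(10)}
        assert planted <= set(sig)


class TestCorrelationModel:
    def test_fit_summary_and_roundtrip(self, tmp_path):
        rng = np.random.default_rng(16)
        cov = rng.normal(size=30)
        values = rng.normal(size=(20, 30))
        values[0] = cov + rng.normal(scale=0.1, size=30)
        m = logtpm_matrix(np.abs(values))
        results = CorrelationModel(m, cov, covariate_name="mass").fit(
            n_iterations=300, seed=4
        )
        text = results.summary()
        assert "mass" in text and "shuffles" in text
        out = tmp_path / "ranked.tsv"
        results.to_tsv(out)
        table = pd.read_csv(out, sep="\t")
        assert {"gene", "rho", "significant", "direction"} <= set(table.columns)

    def test_from_linked_orders_covariate_by_well(self):
        values = np.arange(12, dtype=float).reshape(3, 4)
        m = logtpm_matrix(values, cells=["w1", "w2", "w3", "w4"])
        linked = pd.DataFrame(
            {"well_id": ["w3", "w1"], "mass": [30.0, 10.0]}
        )
        model = CorrelationModel.from_linked(linked, m, covariate="mass")
        assert list(model.matrix.values.columns) == ["w3", "w1"]
        assert model.covariate.tolist() == [30.0, 10.0]
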