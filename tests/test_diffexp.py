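"""Moderated t, preranked GSEA, and feature-pool construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from amlsig.diffexp import (
    EmptyPoolError,
    _enrichment_score,
    build_feature_pool,
    moderated_t,
    preranked_gsea,
)
from amlsig.genesets import GeneSetCollection
from conftest import make_matrix


def _two_group(n_genes=200, n1=8, n2=8, shift_genes=0, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_genes, n1 + n2))
    x[:shift_genes, :n1] += shift
    df = pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)],
                      columns=[f"s{j}" for j in range(n1 + n2)])
    y = np.array([1] * n1 + [0] * n2)
    return df, y


class TestModeratedT:
    def test_no_shrinkage_limit_equals_ordinary_t(self):
        df, y = _two_group(seed=1)
        res = moderated_t(df, y, prior_df=0)
        t_ref = stats.ttest_ind(df.iloc[:, :8], df.iloc[:, 8:], axis=1)
        got = res.loc[df.index, "moderated_t"].to_numpy()
        np.testing.assert_allclose(got, t_ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(res.loc[df.index, "p_value"], t_ref.pvalue, rtol=1e-10)

    def test_signed_score_formula(self):
        df, y = _two_group(shift_genes=20, shift=2.0, seed=2)
        res = moderated_t(df, y)
        expected = res["log2_fc"] * (-np.log10(res["p_value"]))
        np.testing.assert_allclose(res["signed_score"], expected)

    def test_constant_gene_is_null(self):
        df, y = _two_group(n_genes=50, seed=3)
        df.iloc[0] = 5.0
        res = moderated_t(df, y)
        assert res.loc["g0", "moderated_t"] == 0.0
        assert res.loc["g0", "p_value"] == 1.0

    def test_shrinkage_tempers_small_variance_genes(self):
        # heterogeneous gene variances activate finite d0: moderated |t| of the
        # smallest-variance genes is pulled below the ordinary |t|
        rng = np.random.default_rng(4)
        sd = rng.choice([0.2, 1.0, 5.0], size=300)
        x = rng.normal(size=(300, 16)) * sd[:, None]
        df = pd.DataFrame(x, index=[f"g{i}" for i in range(300)],
                          columns=[f"s{j}" for j in range(16)])
        y = np.array([1] * 8 + [0] * 8)
        mod = moderated_t(df, y)
        assert np.isfinite(mod.attrs["prior_df"])
        ord_ = moderated_t(df, y, prior_df=0)
        small = [f"g{i}" for i in np.nonzero(sd == 0.2)[0]]
        ratio = (mod.loc[small, "moderated_t"].abs() + 1e-12) / (
            ord_.loc[small, "moderated_t"].abs() + 1e-12
        )
        assert ratio.median() < 1.0

    def test_requires_two_groups_of_two(self):
        df, _ = _two_group(n_genes=10)
        with pytest.raises(ValueError):
            moderated_t(df, np.array([1] * 15 + [0]))
        with pytest.raises(ValueError):
            moderated_t(df, np.zeros(16))


def _brute_force_es(abs_scores, hit_mask):
    """Literal running-sum enumeration, position by position."""
    n = len(abs_scores)
    n_miss = n - hit_mask.sum()
    total = abs_scores[hit_mask].sum()
    running, best, best_pos = 0.0, 0.0, 0
    for i in range(n):
        running += abs_scores[i] / total if hit_mask[i] else -1.0 / n_miss
        if abs(running) > abs(best):
            best, best_pos = running, i
    return best, best_pos


class TestEnrichmentScore:
    @pytest.mark.parametrize("hits", [(0, 3), (1, 4), (0, 1), (4, 5), (2, 5)])
    def test_matches_brute_force_on_six_gene_list(self, hits):
        abs_scores = np.array([3.0, 2.5, 2.0, 1.0, 0.5, 0.2])
        mask = np.zeros(6, dtype=bool)
        mask[list(hits)] = True
        es, pos = _enrichment_score(abs_scores, mask)
        es_bf, pos_bf = _brute_force_es(abs_scores, mask)
        assert es == pytest.approx(es_bf)
        assert pos == pos_bf

    def test_random_lists_match_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 11))
            scores = np.sort(rng.uniform(0, 5, n))[::-1]
            k = int(rng.integers(1, n))
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, k, replace=False)] = True
            es, _ = _enrichment_score(scores, mask)
            es_bf, _ = _brute_force_es(scores, mask)
            assert es == pytest.approx(es_bf)
            assert abs(es) <= 1.0 + 1e-12


def _ranked_frame(scores):
    genes = [f"g{i}" for i in range(len(scores))]
    return pd.DataFrame({"signed_score": scores}, index=genes)


class TestPrerankedGsea:
    def test_top_block_set_positive_and_leading_edge_complete(self):
        ranked = _ranked_frame(np.linspace(5, -5, 40))
        sets = GeneSetCollection({"top": [f"g{i}" for i in range(5)]})
        res = preranked_gsea(ranked, sets, n_permutations=200, seed=0)
        assert res.table.loc["top", "es"] > 0.8
        assert set(res.leading_edges["top"]) == {f"g{i}" for i in range(5)}
        # permutation floor: 1 / (1 + same-sign permutations)
        assert res.table.loc["top", "p_value"] < 0.02

    def test_bottom_block_set_negative(self):
        ranked = _ranked_frame(np.linspace(5, -5, 40))
        sets = GeneSetCollection({"bottom": [f"g{i}" for i in range(35, 40)]})
        res = preranked_gsea(ranked, sets, n_permutations=200, seed=0)
        assert res.table.loc["bottom", "es"] < -0.8
        assert set(res.leading_edges["bottom"]) <= {f"g{i}" for i in range(30, 40)}

    def test_adjusted_p_monotone_in_raw_p(self):
        rng = np.random.default_rng(1)
        ranked = _ranked_frame(np.linspace(4, -4, 60))
        sets = {f"s{i}": [f"g{j}" for j in rng.choice(60, 6, replace=False)]
                for i in range(12)}
        res = preranked_gsea(ranked, GeneSetCollection(sets), n_permutations=100, seed=2)
        ordered = res.table.sort_values("p_value")
        assert ordered["p_adjusted"].is_monotonic_increasing
        assert (res.table["p_adjusted"] >= res.table["p_value"] - 1e-12).all()

    def test_null_permutation_p_roughly_uniform(self):
        rng = np.random.default_rng(3)
        pvals = []
        for rep in range(40):
            ranked = _ranked_frame(rng.normal(size=30))
            ranked = ranked.sort_values("signed_score", ascending=False)
            sets = GeneSetCollection({"s": list(rng.choice(ranked.index, 5, replace=False))})
            res = preranked_gsea(ranked, sets, n_permutations=50, seed=rep)
            pvals.append(res.table.loc["s", "p_value"])
        # two-sided split p-values are conservative-ish but should span (0, 1]
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_disjoint_set_skipped(self):
        ranked = _ranked_frame(np.linspace(2, -2, 10))
        sets = GeneSetCollection({"in": ["g0", "g1"], "out": ["x", "y"]})
        with pytest.warns(UserWarning):
            res = preranked_gsea(ranked, sets, n_permutations=20, seed=0)
        assert list(res.table.index) == ["in"]


class TestFeaturePool:
    @staticmethod
    def _gsea_with_knee(n_strong=20):
        """Synthetic GSEA outcome: one significant set of strong genes, one of
        weak genes, so the pooled score decay curve has a knee at the
        strong/weak boundary."""
        from amlsig.diffexp import GseaResult

        scores = np.concatenate([
            np.linspace(30, 20, n_strong),  # planted strong genes
            np.linspace(0.5, 0.01, 180),    # flat background
        ])
        ranked = _ranked_frame(scores)
        strong = [f"g{i}" for i in range(n_strong)]
        weak = [f"g{i}" for i in range(100, 110)]
        table = pd.DataFrame(
            {
                "es": [0.9, 0.6, 0.2],
                "nes": [2.0, 1.5, 0.8],
                "p_value": [0.001, 0.002, 0.5],
                "p_adjusted": [0.003, 0.003, 0.5],
                "n_genes": [n_strong, 10, 8],
            },
            index=pd.Index(["sig", "weakset", "null"], name="set"),
        )
        leading = {"sig": strong, "weakset": weak, "null": [f"g{i}" for i in range(150, 158)]}
        res = GseaResult(table, leading, 400, 0)
        return res, ranked, strong

    def test_knee_cutoff_recovers_planted_block(self):
        res, ranked, strong = self._gsea_with_knee()
        pool = build_feature_pool(res, ranked, alpha=0.05)
        assert set(pool) == set(strong)

    def test_universe_filter_drops_external_genes(self):
        res, ranked, strong = self._gsea_with_knee()
        universe = strong[:10]
        pool = build_feature_pool(res, ranked, external_universe=universe, alpha=0.05)
        assert set(pool) <= set(universe)

    def test_no_significant_set_raises(self):
        rng = np.random.default_rng(5)
        ranked = _ranked_frame(np.sort(rng.normal(size=40))[::-1])
        sets = GeneSetCollection({"s": [f"g{i}" for i in rng.choice(40, 5, replace=False)]})
        res = preranked_gsea(ranked, sets, n_permutations=30, seed=6)
        if (res.table["p_adjusted"] < 0.05).any():
            pytest.skip("random draw produced a significant set")
        with pytest.raises(EmptyPoolError):
            build_feature_pool(res, ranked, alpha=0.05)
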