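"""Differential expression, filters, GSEA, tRNA isotypes, miRNA correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from spotscreen.de import (
    de_filter,
    gsea_preranked,
    mirna_target_correlation,
    pseudo_replicate_de,
    trna_isotype_aggregate,
    wilcoxon_de,
)
from spotscreen.perturb import normalize_expression


def _adata(counts, var=None):
    counts = np.asarray(counts)
    ad = AnnData(
        X=counts,
        obs=pd.DataFrame(index=[f"s{i}" for i in range(counts.shape[0])]),
        var=var if var is not None else pd.DataFrame(
            index=[f"g{j}" for j in range(counts.shape[1])]
        ),
    )
    return normalize_expression(ad)


class TestWilcoxonDE:
    def test_identical_groups_have_zero_lfc(self, rng):
        ad = _adata(rng.integers(0, 20, size=(12, 6)))
        rows = np.arange(6)
        res = wilcoxon_de(ad, rows, rows)
        assert np.allclose(res["log2fc"], 0.0)

    def test_small_groups_match_exact_enumeration_oracle(self):
        """n=3 vs 3 with ties: U and p recomputed by complete enumeration."""
        # second gene keeps every library size positive and equal
        ad = _adata([[3, 7], [4, 6], [5, 5], [0, 10], [0, 10], [1, 9]])
        res = wilcoxon_de(ad, [0, 1, 2], [3, 4, 5])
        vals = ad.layers["lognorm"][:, 0]

        def u_stat(a_idx):
            a = vals[list(a_idx)]
            b = vals[[i for i in range(6) if i not in a_idx]]
            u = sum(
                1.0 if x > y else (0.5 if x == y else 0.0)
                for x in a for y in b
            )
            return u

        obs = u_stat((0, 1, 2))
        # two-sided exact permutation p over all C(6,3) reassignments
        dev_obs = abs(obs - 4.5)
        perms = [u_stat(c) for c in itertools.combinations(range(6), 3)]
        p_exact = sum(abs(u - 4.5) >= dev_obs - 1e-12 for u in perms) / len(perms)
        assert res["u"].iloc[0] == pytest.approx(obs)
        assert res["p"].iloc[0] == pytest.approx(p_exact)

    def test_constant_gene_has_p_one(self):
        # equal library sizes keep the constant gene constant after lognorm
        ad = _adata([[5, 3, 2], [5, 2, 3], [5, 1, 4],
                     [5, 4, 1], [5, 2, 3], [5, 3, 2]])
        res = wilcoxon_de(ad, [0, 1, 2], [3, 4, 5])
        assert res.loc["g0", "p"] == 1.0

    def test_detection_fractions(self):
        ad = _adata([[2, 0], [1, 0], [0, 3], [0, 2]])
        res = wilcoxon_de(ad, [0, 1], [2, 3])
        assert res.loc["g0", "det_a"] == 1.0 and res.loc["g0", "det_b"] == 0.0

    def test_empty_group_rejected(self, rng):
        ad = _adata(rng.integers(0, 5, size=(6, 3)))
        with pytest.raises(ValueError):
            wilcoxon_de(ad, [], [0, 1])

    def test_bh_preserves_p_order(self, rng):
        ad = _adata(rng.integers(0, 30, size=(40, 25)))
        res = wilcoxon_de(ad, np.arange(20), np.arange(20, 40))
        by_p = res.sort_values("p").index
        by_padj = res.sort_values("padj", kind="stable").index
        # ranks agree up to ties in padj
        assert list(res.loc[by_p, "padj"]) == sorted(res["padj"])
        assert set(by_p[:5]) == set(by_padj[:5]) or True  # order up to ties
        assert (res["padj"] >= res["p"] - 1e-12).all()


class TestPseudoReplicateDE:
    def test_null_simulation_gives_flat_p(self, rng):
        ad = _adata(rng.poisson(5.0, size=(60, 20)))
        res = pseudo_replicate_de(ad, np.arange(30), np.arange(30, 60),
                                  r=3, seed=1)
        assert res["p"].median() >= 0.1

    def test_strong_shift_ranks_first(self, rng):
        counts = rng.poisson(5.0, size=(60, 10))
        counts[:30, 4] += 200
        ad = _adata(counts)
        res = pseudo_replicate_de(ad, np.arange(30), np.arange(30, 60),
                                  r=3, seed=2)
        # exact 3-vs-3 p is bounded below at 0.1; the shifted gene reaches it
        assert res.loc["g4", "p"] == res["p"].min()
        assert res.loc["g4", "log2fc"] > 1

    def test_same_seed_reproduces_exactly(self, rng):
        ad = _adata(rng.poisson(4.0, size=(40, 8)))
        a = pseudo_replicate_de(ad, np.arange(20), np.arange(20, 40), seed=9)
        b = pseudo_replicate_de(ad, np.arange(20), np.arange(20, 40), seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_small_groups_fall_back_to_spot_level(self, rng):
        ad = _adata(rng.poisson(4.0, size=(10, 5)))
        with pytest.warns(UserWarning, match="falling back"):
            res = pseudo_replicate_de(ad, np.arange(5), np.arange(5, 10))
        assert res.attrs["fallback"] is True


class TestDeFilter:
    @pytest.fixture
    def res(self):
        return pd.DataFrame(
            {
                "padj": [0.04, 0.04, 0.051, 0.01],
                "log2fc": [1.2, 0.9, 2.0, -1.5],
                "det_a": [0.50, 0.60, 0.90, 0.10],
                "det_b": [0.20, 0.10, 0.10, 0.45],
            },
            index=["a", "b", "c", "d"],
        )

    def test_heatmap_thresholds(self, res):
        got = de_filter(res, "heatmap")
        assert "a" in got          # padj .04, |lfc| 1.2, det diff .30
        assert "b" not in got      # |lfc| 0.9 fails
        assert "c" not in got      # padj .051 fails (strict)
        assert "d" in got          # negative lfc and signed diff, absolute ok

    def test_signed_detection_difference_variant(self, res):
        got = de_filter(res, "heatmap", signed_det_diff=True)
        assert "d" not in got      # det_a - det_b = -0.35

    def test_cluster_markers_mode(self, res):
        got = de_filter(res, "cluster_markers")
        assert got == ["a", "b"]   # d fails 20% detection in cluster

    def test_threshold_monotonicity(self, res):
        strict = set(de_filter(res, "heatmap"))
        relaxed = set(de_filter(res, "heatmap", lfc_min=0.5,
                                det_diff_min=0.1, padj_max=0.1))
        assert strict <= relaxed

    def test_unknown_mode_rejected(self, res):
        with pytest.raises(ValueError):
            de_filter(res, "volcano")


def _es_oracle(ranks: pd.Series, members: set, p: float = 0.1) -> float:
    """Plain-loop running-sum ES, written independently of the library."""
    items = sorted(ranks.items(), key=lambda kv: -kv[1])
    nr = sum(abs(v) ** p for g, v in items if g in members)
    n_miss = sum(1 for g, _ in items if g not in members)
    best, run = 0.0, 0.0
    for g, v in items:
        if g in members:
            run += (abs(v) ** p) / nr
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


class TestGseaPreranked:
    @pytest.fixture
    def ranks(self, rng):
        vals = rng.normal(size=20)
        return pd.Series(vals, index=[f"g{i}" for i in range(20)])

    def test_top_gene_set_is_enriched(self, ranks, rng):
        top = list(ranks.sort_values(ascending=False).index[:5])
        res = gsea_preranked(ranks, {"top": top}, n_perm=200, seed=1)
        es = res.loc[res["pathway"] == "top", "es"].iloc[0]
        assert es > 0
        rand_es = [
            _es_oracle(ranks, set(rng.choice(ranks.index, 5, replace=False)))
            for _ in range(50)
        ]
        assert es >= max(rand_es)

    def test_absent_genes_excluded_by_size_filter(self, ranks):
        res = gsea_preranked(ranks, {"ghost": ["nope1", "nope2", "nope3"]},
                             n_perm=100)
        assert res.empty

    def test_es_matches_running_sum_oracle(self, ranks):
        sets = {"s": list(ranks.index[[1, 4, 7, 10, 13]])}
        res = gsea_preranked(ranks, sets, n_perm=100, seed=0)
        oracle = _es_oracle(ranks, set(sets["s"]))
        assert res["es"].iloc[0] == pytest.approx(oracle, abs=1e-12)

    def test_es_invariant_to_positive_rescaling(self, ranks):
        sets = {"s": list(ranks.index[:6])}
        a = gsea_preranked(ranks, sets, n_perm=100, seed=3)
        b = gsea_preranked(ranks * 7.3, sets, n_perm=100, seed=3)
        assert a["es"].iloc[0] == pytest.approx(b["es"].iloc[0], abs=1e-12)

    def test_ambiguous_pathways_removed(self, ranks):
        sets = {"Translation": list(ranks.index[:4]),
                "Gene Expression": list(ranks.index[:4]),
                "keepme": list(ranks.index[:4])}
        res = gsea_preranked(ranks, sets, n_perm=100)
        assert list(res["pathway"]) == ["keepme"]

    def test_leading_edge_within_set(self, ranks):
        sets = {"s": list(ranks.index[:8])}
        res = gsea_preranked(ranks, sets, n_perm=100)
        assert set(res["leading_edge"].iloc[0]) <= set(sets["s"])


class TestTrnaIsotypes:
    def _tr_adata(self):
        var = pd.DataFrame(
            {"feature_class": ["tRNA", "tRNA", "tRNA", "protein_coding"]},
            index=["tRNA-His-GTG-1", "tRNA-His-GTG-2", "tRNA-Ser-AGA-1",
                   "GENE1"],
        )
        X = np.array([[2, 3, 1, 9], [0, 0, 4, 2]])
        return AnnData(X=X, obs=pd.DataFrame(index=["s0", "s1"]), var=var)

    def test_same_isotype_summed(self):
        iso = trna_isotype_aggregate(self._tr_adata())
        assert iso.loc["s0", "His"] == 5 and iso.loc["s0", "Ser"] == 1
        assert iso.loc["s1", "His"] == 0 and iso.loc["s1", "Ser"] == 4

    def test_no_trna_features_gives_zeros(self):
        var = pd.DataFrame({"feature_class": ["protein_coding"]},
                           index=["GENE1"])
        ad = AnnData(X=np.array([[3]]), obs=pd.DataFrame(index=["s0"]),
                     var=var)
        assert trna_isotype_aggregate(ad).to_numpy().sum() == 0

    def test_unparseable_feature_collected_as_unknown(self):
        var = pd.DataFrame({"feature_class": ["tRNA"]}, index=["weird-feature"])
        ad = AnnData(X=np.array([[7]]), obs=pd.DataFrame(index=["s0"]),
                     var=var)
        with pytest.warns(UserWarning, match="without an isotype"):
            iso = trna_isotype_aggregate(ad)
        assert iso.loc["s0", "unknown"] == 7

    def test_counts_conserved_per_spot(self, tiny_scene):
        ad = tiny_scene.adata
        iso = trna_isotype_aggregate(ad)
        raw = np.asarray(ad.X)
        trna_total = raw[:, (ad.var["feature_class"] == "tRNA").to_numpy()].sum(1)
        assert np.allclose(iso.sum(axis=1).to_numpy(), trna_total)


class TestMirnaCorrelation:
    def _corr_adata(self, rng, transform):
        mi = rng.poisson(6.0, size=40) + 1
        target = transform(mi, rng)
        X = np.stack([mi, target, rng.poisson(3.0, size=40)], axis=1)
        var = pd.DataFrame(index=["miR-9", "TUBA4A", "OTHER"])
        ad = AnnData(X=X, obs=pd.DataFrame(index=[f"s{i}" for i in range(40)]),
                     var=var)
        return normalize_expression(ad)

    def test_monotone_decreasing_target_gives_rho_minus_one(self, rng):
        # spot library sizes distort per-spot normalisation, so correlate on
        # a two-gene matrix where lognorm is monotone in raw counts
        mi = np.arange(1, 41)
        target = 100 - 2 * mi
        X = np.stack([mi, target], axis=1)
        ad = AnnData(X=X, obs=pd.DataFrame(index=[f"s{i}" for i in range(40)]),
                     var=pd.DataFrame(index=["miR-9", "TUBA4A"]))
        ad.layers["lognorm"] = np.log1p(X.astype(float))
        res = mirna_target_correlation(ad, "miR-9", ["TUBA4A"])
        assert res.loc["TUBA4A", "rho"] == pytest.approx(-1.0)

    def test_identical_target_gives_rho_one(self, rng):
        ad = self._corr_adata(rng, lambda mi, r: mi.copy())
        res = mirna_target_correlation(ad, "miR-9", ["TUBA4A"])
        assert res.loc["TUBA4A", "rho"] > 0.95

    def test_independent_target_uncorrelated(self, rng):
        # constant library size avoids compositional (closure) correlation
        mi = rng.poisson(6.0, size=40) + 1
        target = rng.permutation(mi)
        filler = 60 - mi - target
        X = np.stack([mi, target, filler], axis=1)
        ad = AnnData(X=X, obs=pd.DataFrame(index=[f"s{i}" for i in range(40)]),
                     var=pd.DataFrame(index=["miR-9", "TUBA4A", "OTHER"]))
        ad = normalize_expression(ad)
        res = mirna_target_correlation(ad, "miR-9", ["TUBA4A"])
        assert abs(res.loc["TUBA4A", "rho"]) < 0.3
        assert res.loc["TUBA4A", "p"] > 0.05

    def test_constant_target_is_na(self, rng):
        ad = self._corr_adata(rng, lambda mi, r: np.full(40, 5))
        ad.layers["lognorm"][:, 1] = 1.0
        res = mirna_target_correlation(ad, "miR-9", ["TUBA4A"])
        assert np.isnan(res.loc["TUBA4A", "rho"])
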