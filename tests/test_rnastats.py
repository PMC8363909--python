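"""Small-RNA statistics: filtering, normalization, DE, composition, GSEA,
exact Mann-Whitney."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plasmafrac import rnastats as rs
from plasmafrac import synthdata as sd


class TestFilterFeatures:
    def test_all_zero_removed(self):
        matrix = pd.DataFrame({"s1": [0, 5], "s2": [0, 5], "s3": [0, 0], "s4": [0, 0]},
                              index=["zero", "ok"])
        groups = pd.Series(["A", "A", "B", "B"], index=matrix.columns)
        kept = rs.filter_features(matrix, groups)
        assert list(kept.index) == ["ok"]

    def test_half_of_six_boundary_kept(self):
        samples = [f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)]
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=samples)
        row = [1, 1, 1, 0, 0, 0] + [0] * 6  # 3 of 6 in group A = ceil(6/2)
        matrix = pd.DataFrame([row], index=["f"], columns=samples)
        assert "f" in rs.filter_features(matrix, groups).index

    def test_matches_bruteforce_oracle(self, rng):
        samples = [f"A{i}" for i in range(5)] + [f"B{i}" for i in range(3)]
        groups = pd.Series(["A"] * 5 + ["B"] * 3, index=samples)
        matrix = pd.DataFrame(
            rng.integers(0, 3, size=(80, 8)),
            index=[f"f{i}" for i in range(80)], columns=samples,
        )
        kept = set(rs.filter_features(matrix, groups).index)
        for feat in matrix.index:
            ok = False
            for g, need in (("A", math.ceil(5 / 2)), ("B", math.ceil(3 / 2))):
                cols = groups.index[groups == g]
                ok = ok or (matrix.loc[feat, cols] >= 1).sum() >= need
            ok = ok and matrix.loc[feat].sum() > 0
            assert (feat in kept) == ok

    def test_monotone_in_strictness(self, rng):
        samples = [f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)]
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=samples)
        matrix = pd.DataFrame(rng.integers(0, 2, size=(60, 12)), columns=samples)
        lenient = set(rs.filter_features(matrix, groups, any_group=True).index)
        strict = set(rs.filter_features(matrix, groups, any_group=False).index)
        assert strict <= lenient


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        matrix = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        assert np.allclose(rs.size_factors(matrix), 1.0)

    def test_doubled_sample_doubles_factor(self, rng):
        base = rng.integers(5, 100, size=50)
        matrix = pd.DataFrame({"s1": base, "s2": base, "s3": 2 * base})
        factors = rs.size_factors(matrix)
        assert factors["s3"] / factors["s1"] == pytest.approx(2.0, rel=1e-9)

    def test_hand_computed_toy(self):
        # samples are 1x, 2x, 4x a common base: factors (0.5, 1, 2) around the
        # geometric mean of each feature
        matrix = pd.DataFrame(
            {"s1": [2, 3, 4, 5], "s2": [4, 6, 8, 10], "s3": [8, 12, 16, 20]}
        )
        factors = rs.size_factors(matrix)
        assert factors.tolist() == pytest.approx([0.5, 1.0, 2.0])

    def test_feature_order_invariance(self, rng):
        matrix = pd.DataFrame(rng.integers(1, 200, size=(40, 4)))
        shuffled = matrix.sample(frac=1.0, random_state=3)
        assert np.allclose(rs.size_factors(matrix), rs.size_factors(shuffled))

    def test_fallback_warns_without_common_feature(self):
        matrix = pd.DataFrame({"s1": [5, 0], "s2": [0, 5]})
        with pytest.warns(UserWarning, match="library-size"):
            factors = rs.size_factors(matrix)
        assert stats.gmean(factors) == pytest.approx(1.0)

    def test_matches_pydeseq2_reference(self, rng):
        # independent reference implementation of median-of-ratios
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        matrix = pd.DataFrame(rng.integers(1, 500, size=(100, 6)))
        ours = rs.size_factors(matrix).to_numpy()
        _, theirs = pydeseq2.deseq2_norm(matrix.T.to_numpy())
        assert np.allclose(ours, theirs, rtol=1e-9)


class TestNBWald:
    def test_identical_groups_flat(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 500, size=60)
        samples = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
        matrix = pd.DataFrame(
            rng.poisson(np.tile(base[:, None], (1, 8))), columns=samples
        )
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=samples)
        res = rs.nb_wald_test(matrix, groups, "A", "B")
        assert res["log2fc"].abs().mean() < 0.3
        assert not res["de"].any()

    def test_planted_fourfold_power(self):
        planted = {f"tRNA-{aa}-frag1": {"plasma": 4.0} for aa in ("Ala", "Arg", "Asn")}
        planted.update({m: {"plasma": 4.0} for m in sd.HDL_MIRNAS})
        design = sd.OmicsDesign(groups={"EV": 6, "plasma": 6},
                                planted_effects=planted, dispersion=0.1, seed=17)
        # identical baseline compositions so the planted 4x is the only signal
        composition = sd.default_smallrna_composition()
        composition["plasma"] = composition["EV"]
        counts, groups, _ = sd.simulate_smallrna(design, composition)
        filtered = rs.filter_features(counts, groups)
        res = rs.nb_wald_test(filtered, groups, "plasma", "EV")
        idx = [f for f in planted if f in res.index]
        assert res.loc[idx, "de"].mean() >= 0.8

    def test_bh_adjustment_textbook_oracle(self):
        from statsmodels.stats.multitest import multipletests

        padj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(padj, [0.04, 0.04, 0.04, 0.04])

    def test_adjusted_at_least_raw(self, rng):
        samples = [f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)]
        matrix = pd.DataFrame(rng.integers(1, 300, size=(50, 6)), columns=samples)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=samples)
        res = rs.nb_wald_test(matrix, groups, "A", "B")
        assert (res["padj"] >= res["p"] - 1e-12).all()


class TestComposition:
    def _annot(self, biotypes):
        return pd.DataFrame(
            {"biotype": biotypes, "isotype": "", "essential": ""},
            index=[f"f{i}" for i in range(len(biotypes))],
        )

    def test_single_biotype_is_one(self):
        annot = self._annot(["miRNA", "miRNA"])
        matrix = pd.DataFrame({"s1": [10, 20], "s2": [5, 5]}, index=annot.index)
        groups = pd.Series(["g", "g"], index=matrix.columns)
        comp = rs.biotype_composition(matrix, annot, groups)
        assert comp.loc["miRNA", "g"] == pytest.approx(1.0)

    def test_toy_seventy_thirty(self):
        annot = self._annot(["miRNA", "tRNA"])
        matrix = pd.DataFrame({"s1": [70, 30]}, index=annot.index)
        matrix["s2"] = matrix["s1"]
        groups = pd.Series(["g", "g"], index=matrix.columns)
        comp = rs.biotype_composition(matrix, annot, groups)
        assert comp["g"].tolist() == pytest.approx([0.7, 0.3])
        assert comp["g"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_exclusion_renormalizes(self):
        annot = self._annot(["miRNA", "tRNA", "other"])
        matrix = pd.DataFrame({"s1": [10, 30, 60]}, index=annot.index)
        matrix["s2"] = matrix["s1"]
        groups = pd.Series(["g", "g"], index=matrix.columns)
        comp = rs.biotype_composition(matrix, annot, groups, exclude={"other"})
        assert comp.loc["miRNA", "g"] == pytest.approx(0.25)


class TestCodonUsage:
    def _toy(self, g2_gly=0.8):
        aas = ["Gly", "Ala", "Val"]
        annot = pd.DataFrame(
            {"biotype": "tRNA", "isotype": aas, "essential": [0, 0, 1]},
            index=[f"tRNA-{a}" for a in aas],
        )
        g1 = [100, 100, 100]
        g2 = [int(g2_gly * 1000), 100, 100]
        matrix = pd.DataFrame(
            {"g1a": g1, "g1b": g1, "g2a": g2, "g2b": g2}, index=annot.index
        )
        groups = pd.Series(["G1", "G1", "G2", "G2"], index=matrix.columns)
        return matrix, annot, groups

    def test_identical_groups_unit_fold_change(self):
        matrix, annot, groups = self._toy()
        matrix[["g2a", "g2b"]] = matrix[["g1a", "g1b"]].to_numpy()
        prof = rs.codon_usage_profile(matrix, annot, groups, "G1", "G2")
        assert np.allclose(prof["fold_change"], 1.0)

    def test_gly_dominated_group_hand_computation(self):
        matrix, annot, groups = self._toy()
        prof = rs.codon_usage_profile(matrix, annot, groups, "G1", "G2")
        # group2 proportions (0.8, 0.1, 0.1); group1 uniform -> (1/3)/0.8 etc.
        assert prof.loc["Gly", "fold_change"] == pytest.approx((1 / 3) / 0.8, rel=1e-9)
        assert (prof.drop("Gly")["fold_change"] > 1).all()
        for g in ("G1", "G2"):
            assert prof[f"prop_{g}"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_most_isotypes_enriched_in_ev_vs_plasma(self):
        counts, groups, annot = sd.simulate_smallrna(sd.default_rna_design(seed=0))
        prof = rs.codon_usage_profile(counts, annot, groups, "EV", "plasma")
        fc = prof["fold_change"].dropna()
        assert fc.idxmin() == "Gly"
        assert (fc > 1).sum() >= 0.7 * len(fc)

    def test_library_size_invariance(self):
        matrix, annot, groups = self._toy()
        scaled = matrix.copy()
        scaled["g1a"] *= 5
        scaled["g2b"] *= 3
        a = rs.codon_usage_profile(matrix, annot, groups, "G1", "G2")
        b = rs.codon_usage_profile(scaled, annot, groups, "G1", "G2")
        assert np.allclose(a["fold_change"], b["fold_change"], rtol=1e-9)


def bruteforce_es(ranked, gene_set):
    """Independent running-sum oracle."""
    hits = [r in gene_set for r in ranked]
    nh = sum(hits)
    n = len(ranked)
    best, running = 0.0, 0.0
    for h in hits:
        running += 1.0 / nh if h else -1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best


class TestGSEA:
    def test_top_block_maximal_es(self):
        ranked = [f"g{i}" for i in range(10)]
        res = rs.gsea_classic(ranked, set(ranked[:3]), n_permutations=200, seed=0)
        assert res.es == pytest.approx(bruteforce_es(ranked, set(ranked[:3])))
        assert res.es == pytest.approx(1.0)
        assert res.p < 0.05

    def test_matches_bruteforce_on_random_sets(self, rng):
        ranked = [f"g{i}" for i in range(20)]
        for _ in range(25):
            members = set(rng.choice(ranked, size=rng.integers(2, 10), replace=False))
            res = rs.gsea_classic(ranked, members, n_permutations=50, seed=1)
            assert res.es == pytest.approx(bruteforce_es(ranked, members), rel=1e-12)

    def test_interleaved_set_not_significant(self):
        ranked = [f"g{i}" for i in range(20)]
        members = set(ranked[::2])  # perfectly interleaved
        res = rs.gsea_classic(ranked, members, n_permutations=500, seed=2)
        assert abs(res.es) <= 1.0 / 10 + 1.0 / 10 + 1e-12
        assert res.p > 0.5

    def test_es_bounds_and_nes_sign(self, rng):
        ranked = [f"g{i}" for i in range(30)]
        for seed in range(10):
            members = set(rng.choice(ranked, size=5, replace=False))
            res = rs.gsea_classic(ranked, members, n_permutations=100, seed=seed)
            assert -1.0 <= res.es <= 1.0
            if not math.isnan(res.nes) and res.es != 0:
                assert math.copysign(1, res.nes) == math.copysign(1, res.es)

    def test_mirror_identity(self, rng):
        # ES of a set equals ES of its complement on the reversed ranking
        ranked = [f"g{i}" for i in range(12)]
        members = set(rng.choice(ranked, size=4, replace=False))
        complement = set(ranked) - members
        forward = bruteforce_es(ranked, members)
        mirrored = bruteforce_es(ranked[::-1], complement)
        assert forward == pytest.approx(mirrored, rel=1e-12)
        res = rs.gsea_classic(ranked, members, n_permutations=50, seed=0)
        assert res.es == pytest.approx(forward, rel=1e-12)

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            rs.gsea_classic(["a", "b", "c"], {"x"}, n_permutations=10)


class TestMannWhitney:
    def test_complete_separation_six_vs_six(self):
        u, p = rs.mannwhitney_exact([1, 2, 3, 4, 5, 6], [10, 11, 12, 13, 14, 15])
        assert u == 0.0
        assert round(p, 4) == 0.0022  # 2 / C(12, 6) = 2/924

    def test_interleaved_near_one(self):
        u, p = rs.mannwhitney_exact([1, 3, 5, 7], [2, 4, 6, 8])
        assert p > 0.5

    def test_enumeration_matches_bruteforce_3v3(self, rng):
        x = rng.normal(size=3)
        y = rng.normal(size=3)
        u_obs, p = rs.mannwhitney_exact(x, y)
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        mu = 9 / 2.0
        obs_dev = abs(u_obs - mu)
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            u = ranks[list(combo)].sum() - 6.0
            count += abs(u - mu) >= obs_dev - 1e-12
            total += 1
        assert p == pytest.approx(count / total, rel=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(loc=1.0, size=6)
        u, p = rs.mannwhitney_exact(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_all_tied_warns(self):
        with pytest.warns(UserWarning, match="tied"):
            _, p = rs.mannwhitney_exact([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_large_samples_use_normal_approximation(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(loc=0.8, size=15)
        _, p = rs.mannwhitney_exact(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestGMT:
    def test_roundtrip(self, tmp_path):
        sets = {"SET_A": ("g1", "g2", "g3"), "SET_B": ("g4", "g5")}
        path = tmp_path / "sets.gmt"
        rs.write_gmt(sets, path)
        assert rs.read_gmt(path) == sets
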