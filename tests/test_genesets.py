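"""Gene-set analyses: chi-square enrichment, GSEA running sum, GO-ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdml.dml import fit_all_loci
from methdml.genesets import (GeneSet, gene_level_stats, go_anova, go_anova_all,
                              go_enrichment, gsea_es, gsea_preranked,
                              select_reported_sets)


def _genes(n, prefix="G"):
    return [f"{prefix}{i:04d}" for i in range(n)]


class TestGoEnrichment:
    def test_chi_square_closed_form(self):
        # 50 significant of 1000 chip genes; the set holds 10 significant of 40
        chip = _genes(1000)
        sig = chip[:50]
        members = chip[:10] + chip[50:80]  # 10 sig + 30 non-sig
        res = go_enrichment(sig, chip, [GeneSet("S", "s", frozenset(members))])
        a, b, c, d = 10, 40, 30, 920
        n = a + b + c + d
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res["chi_square"].iloc[0] == pytest.approx(chi2, rel=1e-9)
        assert chi2 == pytest.approx(35.088, abs=0.01)
        assert res["enrichment_score"].iloc[0] == pytest.approx(8.46, abs=0.05)

    def test_no_enrichment_when_proportions_match(self):
        chip = _genes(100)
        sig = chip[:10]  # 10%
        members = chip[5:15]  # 1 of 10 in set? make proportions equal: 1 sig of 10
        res = go_enrichment(sig, chip, [GeneSet("S", "s", frozenset(members[4:14]))])
        # construct exact proportion instead: set with 2 sig of 20 (10%)
        members = chip[:2] + chip[50:68]
        res = go_enrichment(sig, chip, [GeneSet("S", "s", frozenset(members))])
        assert res["chi_square"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert res["enrichment_score"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_all_significant(self):
        chip = _genes(50)
        res = go_enrichment(chip, chip, [GeneSet("S", "s", frozenset(chip[:5]))])
        assert (res["enrichment_score"] == 0).all()

    def test_empty_sig_list_warns_zero(self, caplog):
        chip = _genes(50)
        res = go_enrichment([], chip, [GeneSet("S", "s", frozenset(chip[:5]))])
        assert (res["enrichment_score"] == 0).all()

    def test_invariant_to_outside_relabeling(self):
        chip = _genes(200)
        sig = chip[:30]
        gs = [GeneSet("S", "s", frozenset(chip[:10] + chip[100:110]))]
        base = go_enrichment(sig, chip, gs)["chi_square"].iloc[0]
        relabeled = [f"Z{g}" for g in chip[110:]]
        chip2 = chip[:110] + relabeled
        sig2 = chip2[:30]
        again = go_enrichment(sig2, chip2, gs)["chi_square"].iloc[0]
        assert base == pytest.approx(again, rel=1e-12)

    def test_sig_outside_chip_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            go_enrichment(["NOPE"], _genes(10), [GeneSet("S", "s", frozenset(_genes(3)))])


def brute_unweighted_ks(n_total, hit_positions):
    """Classical KS statistic by walking the whole list.

    On an exact magnitude tie between the positive and negative extreme the
    positive one is reported (the implementation's convention).
    """
    hits = set(int(i) for i in hit_positions)
    m = len(hits)
    running, hi, lo = 0.0, 0.0, 0.0
    for i in range(n_total):
        running += 1.0 / m if i in hits else -1.0 / (n_total - m)
        hi = max(hi, running)
        lo = min(lo, running)
    return hi if hi >= -lo - 1e-12 else lo


class TestGsea:
    def test_all_members_at_top(self):
        stat = np.linspace(3, -3, 100)
        es = gsea_es(stat, np.arange(5), weight_exponent=1.0)
        assert es > 0.9

    def test_reversal_negates_es(self):
        rng = np.random.default_rng(1)
        stat = np.sort(rng.normal(size=60))[::-1]
        pos = np.array([3, 10, 20, 30])
        es = gsea_es(stat, pos)
        es_rev = gsea_es(-stat[::-1], 59 - pos[::-1])
        assert es_rev == pytest.approx(-es, rel=1e-9)

    @pytest.mark.parametrize("n,members", [(8, (0, 3, 6)), (15, (1, 5, 9, 13)),
                                           (20, (2, 4, 11, 17, 19)), (12, (0, 1, 2))])
    def test_weight_zero_matches_classical_ks(self, n, members):
        rng = np.random.default_rng(n)
        stat = np.sort(rng.normal(size=n))[::-1]
        es = gsea_es(stat, np.array(members), weight_exponent=0.0)
        assert es == pytest.approx(brute_unweighted_ks(n, members), abs=1e-12)

    def test_interleaved_set_not_significant(self):
        stat = pd.Series(np.linspace(2, -2, 200), index=_genes(200))
        members = frozenset(_genes(200)[::20])  # uniformly spread
        res = gsea_preranked(stat, [GeneSet("S", "s", members)], n_perm=1000, seed=4)
        assert res["p"].iloc[0] > 0.5
        assert abs(res["es"].iloc[0]) < 0.4

    def test_top_set_significant_with_positive_nes(self):
        stat = pd.Series(np.linspace(2, -2, 200), index=_genes(200))
        members = frozenset(_genes(200)[:10])
        res = gsea_preranked(stat, [GeneSet("S", "s", members)], n_perm=500, seed=5)
        assert res["p"].iloc[0] <= 0.01
        assert res["nes"].iloc[0] > 1.5
        assert np.sign(res["nes"].iloc[0]) == np.sign(res["es"].iloc[0])
        assert res["p"].iloc[0] >= 1 / 501

    def test_permutation_p_uniform_for_random_sets(self):
        rng = np.random.default_rng(9)
        stat = pd.Series(rng.normal(size=300), index=_genes(300))
        ps = []
        for i in range(60):
            members = frozenset(rng.choice(_genes(300), size=12, replace=False))
            res = gsea_preranked(stat, [GeneSet(f"S{i}", "s", members)],
                                 n_perm=200, seed=100 + i)
            ps.append(res["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_min_permutations_enforced(self):
        stat = pd.Series([1.0, -1.0], index=["A", "B"])
        with pytest.raises(ValueError):
            gsea_preranked(stat, [], n_perm=10)


class TestGoAnova:
    def test_planted_set_recovered(self, planted_study, planted_beta):
        study, _, plan = planted_study
        man = study.manifest
        hyper_genes = frozenset(man.loc[plan[0][0], "gene"])
        gs = GeneSet("hyper", "planted", hyper_genes)
        res = go_anova(planted_beta, study.samples, gs, man)
        assert res["p"] < 1e-4
        # member loci include unplanted loci of the same genes, diluting 0.35
        assert res["mean_delta_beta"] > 0.12

    def test_null_set_mean_near_zero(self, planted_study, planted_beta):
        study, truth, _ = planted_study
        man = study.manifest
        unaffected = truth.loci.index[truth.loci["affected_by"].map(len) == 0]
        genes = frozenset(man.loc[unaffected[:80], "gene"])
        res = go_anova(planted_beta, study.samples, GeneSet("null", "n", genes), man)
        assert abs(res["mean_delta_beta"]) < 0.05

    def test_mean_delta_matches_locus_level(self, planted_study, planted_beta):
        study, _, plan = planted_study
        man = study.manifest
        genes = frozenset(man.loc[plan[0][0][:5], "gene"])
        gs = GeneSet("S", "s", genes)
        res = go_anova(planted_beta, study.samples, gs, man)
        locus_res = fit_all_loci(planted_beta, study.samples)
        member_loci = man.index[man["gene"].str.upper().isin(gs.genes)]
        expected = locus_res.loc[member_loci, "delta_beta"].mean()
        assert res["mean_delta_beta"] == pytest.approx(expected, abs=1e-12)

    def test_single_locus_fallback_flagged(self, planted_study, planted_beta):
        study, _, _ = planted_study
        man = study.manifest
        singles = man.groupby("gene").filter(lambda g: len(g) == 1)
        gene = singles["gene"].iloc[0]
        res = go_anova(planted_beta, study.samples, GeneSet("S", "s", frozenset([gene])), man)
        assert res["single_locus_fallback"]


class TestReportedSets:
    def _gsea(self):
        return pd.DataFrame(
            {"nes": [1.6, 1.8, -1.7, 1.2], "es": [0.5, 0.6, -0.55, 0.3],
             "p": [0.005, 0.004, 0.002, 0.003], "name": list("abcd")},
            index=pd.Index(["s1", "s2", "s3", "s4"], name="set_id"),
        )

    def _goanova(self, db):
        return pd.DataFrame(
            {"p": [1e-4] * 4, "fdr_q": [0.003, 0.002, 0.004, 0.001],
             "mean_delta_beta": db},
            index=pd.Index(["s1", "s2", "s3", "s4"], name="set_id"),
        )

    def test_all_filters_and_sort(self):
        out = select_reported_sets(self._gsea(), self._goanova([0.12, 0.2, -0.15, 0.3]))
        assert list(out.index) == ["s2", "s1", "s3"]  # s4 fails |NES|; NES descending
        assert (out["nes"].diff().dropna() <= 0).all()

    def test_mean_delta_filter_drops(self):
        out = select_reported_sets(self._gsea(), self._goanova([0.05, 0.2, -0.15, 0.3]))
        assert "s1" not in out.index


def test_gene_level_stats_collapses_by_max_magnitude(planted_study, planted_beta):
    study, _, _ = planted_study
    res = fit_all_loci(planted_beta, study.samples)
    ranked = gene_level_stats(res, study.manifest)
    man = study.manifest
    gene = man["gene"].value_counts().index[0]  # a multi-locus gene
    loci = man.index[man["gene"] == gene]
    per_locus = (-np.log10(np.maximum(res.loc[loci, "p_tissue"], 1e-300))
                 * np.sign(res.loc[loci, "delta_beta"]))
    assert ranked[gene.upper()] == pytest.approx(
        per_locus.iloc[np.argmax(np.abs(per_locus.to_numpy()))], rel=1e-12)


def test_go_anova_all_has_fdr(planted_study, planted_beta):
    study, _, plan = planted_study
    man = study.manifest
    sets = [GeneSet("hyper", "h", frozenset(man.loc[plan[0][0][:10], "gene"])),
            GeneSet("rand", "r", frozenset(man["gene"].iloc[500:520]))]
    out = go_anova_all(planted_beta, study.samples, sets, man)
    assert {"p", "fdr_q", "mean_delta_beta"} <= set(out.columns)
    assert (out["fdr_q"] >= out["p"] - 1e-15).all()
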