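"""Mixed-model DML calling: oracles, thresholds, consensus and sex screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdml.dml import (DMLCall, bh_fdr, call_dml, consensus_dml, fit_all_loci,
                         fit_locus_mixed_anova, illumina_diffscore, sex_screen)
from methdml.preprocess import ROUTES


def _paired_samples(n_cases, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cases):
        sex = rng.choice(["M", "F"])
        loc = rng.choice(["proximal", "distal"])
        for t in ("tumor", "normal"):
            rows.append({"sample_id": f"c{i}_{t}", "case_id": f"c{i}", "tissue": t,
                         "sex": sex, "location": loc, "chip_id": f"chip{i % 4}"})
    return pd.DataFrame(rows).set_index("sample_id")


class TestDiffScore:
    def test_identical_groups_score_zero(self):
        score, p, d = illumina_diffscore([0.5] * 6, [True] * 3 + [False] * 3)
        assert score == 0.0 and p == 1.0 and d == 0.0

    def test_score_p_bijection_and_threshold(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            row = rng.random(12)
            score, p, d = illumina_diffscore(row, [True] * 6 + [False] * 6)
            assert abs(score) == pytest.approx(10 * -np.log10(p), rel=1e-12)
            assert np.sign(score) == np.sign(d)
            assert (abs(score) >= 30) == (p <= 0.001)

    def test_p_005_maps_to_13(self):
        # any row with Welch p = 0.05 and negative delta must score -13.0103
        assert 10 * -np.log10(0.05) == pytest.approx(13.0103, abs=1e-4)
        rng = np.random.default_rng(5)
        for _ in range(200):
            row = rng.random(10)
            score, p, d = illumina_diffscore(row, [True] * 5 + [False] * 5)
            if 0.04 < p < 0.06 and d < 0:
                assert -14 < score < -12.2
                break

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            illumina_diffscore([0.1, 0.2, 0.3], [True, False, False])


class TestMixedAnova:
    def test_three_case_oracle(self, tiny_samples):
        res = fit_locus_mixed_anova([0.8, 0.2, 0.7, 0.3, 0.9, 0.1], tiny_samples,
                                    factors=("tissue", "case"))
        assert res.f["tissue"] == pytest.approx(27.0, rel=1e-9)
        # paired t on diffs (0.6, 0.4, 0.8): t = 5.196, F = t^2
        t, p = stats.ttest_rel([0.8, 0.7, 0.9], [0.2, 0.3, 0.1])
        assert res.f["tissue"] == pytest.approx(t**2, rel=1e-9)
        assert res.p["tissue"] == pytest.approx(p, rel=1e-9)

    def test_all_equal_degenerate(self, tiny_samples):
        res = fit_locus_mixed_anova([0.4] * 6, tiny_samples, factors=("tissue", "case"))
        assert res.f["tissue"] == 0.0 and res.p["tissue"] == 1.0
        assert sum(res.variance_fractions.values()) == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, planted_routes, planted_study):
        study, _, _ = planted_study
        res = fit_all_loci(planted_routes["background"], study.samples)
        total = (res[["frac_tissue", "frac_sex", "frac_location", "frac_case", "frac_error"]]
                 .sum(axis=1))
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_paired_t_equivalence_random_designs(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(3, 10))
            samples = _paired_samples(n, seed=int(rng.integers(1 << 30)))
            y = rng.random(2 * n)
            res = fit_locus_mixed_anova(y, samples, factors=("tissue", "case"))
            tumor = y[(samples["tissue"] == "tumor").to_numpy()]
            normal = y[(samples["tissue"] == "normal").to_numpy()]
            t, p = stats.ttest_rel(tumor, normal)
            assert res.f["tissue"] == pytest.approx(t**2, rel=1e-8)
            assert res.p["tissue"] == pytest.approx(p, rel=1e-8)

    def test_planted_effect_raises_tissue_fraction(self, planted_routes, planted_study):
        study, truth, plan = planted_study
        res = fit_all_loci(planted_routes["raw"], study.samples)
        planted = sorted(set(plan[0][0]) | set(plan[1][0]))
        null = res.index.difference(planted)
        assert (res.loc[planted, "frac_tissue"].median()
                > res.loc[null, "frac_tissue"].median() + 0.3)

    def test_missing_values_refit_and_skip(self, planted_study):
        study, _, _ = planted_study
        beta = (study.M / (study.M + study.U)).iloc[:5].copy()
        beta.iloc[0, 0] = np.nan  # one sample missing: still >= 3 complete cases
        beta.iloc[1, 2:] = np.nan  # only one complete case: skipped
        res = fit_all_loci(beta, study.samples)
        assert np.isfinite(res["p_tissue"].iloc[0])
        assert np.isnan(res["p_tissue"].iloc[1])

    def test_variance_components_nonnegative(self, planted_routes, planted_study):
        study, _, _ = planted_study
        res = fit_all_loci(planted_routes["raw"], study.samples)
        assert (res["varcomp_case"].dropna() >= 0).all()
        assert (res["varcomp_error"].dropna() >= 0).all()


class TestBhFdr:
    def test_step_up_oracle(self):
        q = bh_fdr([0.001, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.004, 0.04, 0.04, 0.5])

    def test_ties_all_equal(self):
        assert np.allclose(bh_fdr([0.2] * 5), 0.2)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(2)
        p = rng.random(100)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_empty(self):
        assert bh_fdr([]).size == 0


class TestCallsAndConsensus:
    def _results(self, rows):
        return pd.DataFrame(rows, index=[f"L{i}" for i in range(len(rows))])

    def test_threshold_rules(self):
        res = self._results([
            {"q_tissue": 0.005, "delta_beta": 0.25},
            {"q_tissue": 0.005, "delta_beta": 0.15},
            {"q_tissue": 0.02, "delta_beta": 0.5},
            {"q_tissue": 0.005, "delta_beta": -0.3},
        ])
        call = call_dml(res)
        assert call.hyper == {"L0"} and call.hypo == {"L3"}

    def test_monotone_in_delta_threshold(self, planted_routes, planted_study):
        study, _, _ = planted_study
        res = fit_all_loci(planted_routes["raw"], study.samples)
        sizes = [len(call_dml(res, delta_beta_min=d).loci) for d in (0.1, 0.2, 0.3, 0.4)]
        assert sizes == sorted(sizes, reverse=True)

    def test_consensus_intersection_and_errors(self):
        def mk(route, hyper, hypo=frozenset()):
            return DMLCall(frozenset(hyper), frozenset(hypo), 0.2, 0.01, route)

        calls = {r: mk(r, {"a", "b"}) for r in ROUTES}
        cons = consensus_dml(calls)
        assert cons.hyper == {"a", "b"} and cons.route == "consensus"
        calls["raw"] = mk("raw", {"a"})
        assert consensus_dml(calls).hyper == {"a"}
        # order invariance
        assert consensus_dml(list(calls.values())[::-1]).hyper == {"a"}
        with pytest.raises(ValueError, match="expected routes"):
            consensus_dml([mk("raw", {"a"})] * 4)

    def test_direction_conflict_rejected(self):
        with pytest.raises(ValueError):
            DMLCall(frozenset({"a"}), frozenset({"a"}), 0.2, 0.01, "raw")

    def test_planted_recovery(self, planted_routes, planted_study):
        study, _, plan = planted_study
        calls = {}
        for r in ROUTES:
            res = fit_all_loci(planted_routes[r], study.samples)
            calls[r] = call_dml(res, route=r)
        cons = consensus_dml(calls)
        hyper, hypo = set(plan[0][0]), set(plan[1][0])
        assert len(cons.hyper & hyper) / len(hyper) >= 0.95
        assert len(cons.hypo & hypo) / len(hypo) >= 0.95
        assert len(cons.loci - hyper - hypo) <= 0.01 * max(len(cons.loci), 1)


class TestSexScreen:
    def test_x_linked_enrichment_and_autosome_filter(self, planted_routes, planted_study):
        study, _, _ = planted_study
        man = study.manifest
        screen = sex_screen(planted_routes["background"], study.samples, man)
        sig = screen.significant
        assert len(sig) > 0
        assert (sig["chromosome"] == "X").mean() >= 0.95
        n_sex = man["chromosome"].isin(["X", "Y"]).sum()
        assert len(screen.autosomal_manifest) == len(man) - n_sex

    def test_no_planted_sex_effect_is_null(self, small_manifest):
        from methdml.preprocess import compute_beta
        from methdml.synthetic import generate_paired_study

        study, _ = generate_paired_study(small_manifest, n_cases=24, sex_effect_x=0.0, seed=31)
        screen = sex_screen(compute_beta(study.M, study.U), study.samples, small_manifest)
        assert len(screen.significant) <= 2

    def test_single_sex_still_filters(self, small_manifest, planted_study):
        study, _, _ = planted_study
        beta = study.M / (study.M + study.U)
        samples = study.samples.copy()
        samples["sex"] = "M"
        screen = sex_screen(beta.iloc[:50], samples, small_manifest)
        assert screen.significant.empty
        assert not screen.autosomal_manifest["chromosome"].isin(["X", "Y"]).any()
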