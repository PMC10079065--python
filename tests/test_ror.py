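"""Ratio-of-ratios statistics, Priority Scores, and set extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rorde import diffexp, ror, synth


def _tiny_matched(n_case=4, n_control=4, n_genes=30, seed=11, covariates=[]):
    cohort = synth.generate_cohort(n_case, n_control, covariates, seed=seed)
    expr, truth = synth.generate_expression(
        cohort, n_genes, planted=synth.PlantedSpec(n_per_class=0),
        covariates=covariates, seed=seed,
    )
    return cohort, expr, truth


class TestMatchedDifferences:
    def test_identical_regions_give_zero(self):
        cohort, expr, _ = _tiny_matched()
        vul = cohort.loc[cohort["region"] == "vulnerable", "sample_id"]
        res = cohort.loc[cohort["region"] == "resistant", "sample_id"]
        expr[res.to_numpy()] = expr[vul.to_numpy()].to_numpy()
        d, _ = ror.matched_differences(expr, cohort)
        np.testing.assert_allclose(d.to_numpy(), 0.0, atol=1e-12)

    def test_unit_offset_gives_unit_difference(self):
        cohort, expr, _ = _tiny_matched()
        vul = cohort.loc[cohort["region"] == "vulnerable", "sample_id"]
        res = cohort.loc[cohort["region"] == "resistant", "sample_id"]
        expr[vul.to_numpy()] = expr[res.to_numpy()].to_numpy() + 1.0
        d, _ = ror.matched_differences(expr, cohort)
        np.testing.assert_allclose(d.to_numpy(), 1.0, atol=1e-12)

    def test_equals_direct_subtraction(self):
        cohort, expr, _ = _tiny_matched(2, 2, n_genes=10)
        d, diagnosis = ror.matched_differences(expr, cohort)
        for case_id in d.columns:
            sub = cohort[cohort["case_id"] == case_id].set_index("region")
            direct = (
                expr[sub.loc["vulnerable", "sample_id"]]
                - expr[sub.loc["resistant", "sample_id"]]
            )
            np.testing.assert_allclose(d[case_id], direct, atol=1e-12)
        assert list(diagnosis.index) == list(d.columns)

    def test_unmatched_case_listed_in_error(self):
        cohort, expr, _ = _tiny_matched()
        broken = cohort.iloc[1:]  # drop one region of the first case
        with pytest.raises(ValueError, match="I0001"):
            ror.matched_differences(expr[broken["sample_id"]], broken)


class TestRoRMatched:
    def test_constant_matrix_gives_zero_logror(self):
        cohort, expr, _ = _tiny_matched()
        const = pd.DataFrame(
            5.0, index=expr.index, columns=expr.columns
        )
        d, diagnosis = ror.matched_differences(const, cohort)
        out = ror.ror_matched(d, diagnosis)
        np.testing.assert_allclose(out["logRoR"], 0.0, atol=1e-12)

    @pytest.mark.parametrize(
        "cls,target",
        [
            ("parallel_up", 0.0),
            ("contrasting_resistant_up", -1.0),
            ("contrasting_vulnerable_up", 1.0),
        ],
    )
    def test_planted_class_polarity(self, cls, target):
        """Planted classes land within 3 SE of their population logRoR
        (negative for resistant-region increases, positive for
        vulnerable-region increases, zero for parallel shifts)."""
        cohort = synth.generate_cohort(50, 50, [], seed=31)
        expr, truth = synth.generate_expression(
            cohort, 600, planted=synth.PlantedSpec(n_per_class=100),
            covariates=[], seed=31,
        )
        d, diagnosis = ror.matched_differences(expr, cohort)
        out = ror.ror_matched(d, diagnosis).set_index("probe_id")
        sel = truth.loc[truth["gene_class"] == cls, "probe_id"]
        vals = out.loc[sel, "logRoR"]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - target) < 3 * se


class TestRoRUnmatched:
    def test_trivial_differences(self):
        base = pd.DataFrame({
            "probe_id": ["a", "b"],
            "logFC": [1.0, 0.5],
            "se": [0.1, 0.1],
            "df_total": [10.0, 10.0],
        })
        other = base.assign(logFC=[1.0, -0.5])
        out = ror.ror_unmatched(base, other)
        np.testing.assert_allclose(out["logRoR"], [0.0, 1.0], atol=1e-12)

    def test_probe_universe_mismatch_rejected(self):
        a = pd.DataFrame({"probe_id": ["a"], "logFC": [1.0], "se": [0.1],
                          "df_total": [5.0]})
        b = a.assign(probe_id=["b"])
        with pytest.raises(ValueError, match="universe"):
            ror.ror_unmatched(a, b)

    def test_matched_and_unmatched_estimates_identical(self):
        """On matched data the unmatched rearrangement is algebraically
        the same point estimate, probe by probe, to 1e-12."""
        cohort, expr, _ = _tiny_matched(6, 5, n_genes=200, seed=13)
        fc_v = diffexp.region_contrast(expr, cohort, "vulnerable")
        fc_r = diffexp.region_contrast(expr, cohort, "resistant")
        unmatched = ror.ror_unmatched(fc_v, fc_r)
        d, diagnosis = ror.matched_differences(expr, cohort)
        matched = ror.ror_matched(d, diagnosis)
        np.testing.assert_allclose(
            unmatched["logRoR"], matched["logRoR"], atol=1e-12
        )


class TestPriorityScores:
    def test_extreme_rank_ratio(self):
        """A probe ranked 1 by RoR but last (N=25,852) by fold change gets
        P = 25,852, logP ~ 4.41."""
        n = 25_852
        rng = np.random.default_rng(0)
        fc_mag = np.arange(n, 0, -1, dtype=float)  # probe 0 has largest |logFC|
        ror_mag = rng.permutation(fc_mag)
        probe = [f"p{i:06d}" for i in range(n)]
        fc = pd.DataFrame({"probe_id": probe, "logFC": fc_mag})
        # craft: probe X is last in fc, first in ror
        fc.loc[n - 1, "logFC"] = 0.0001
        rr = pd.DataFrame({"probe_id": probe, "logRoR": ror_mag})
        rr.loc[n - 1, "logRoR"] = fc_mag.max() + 1
        out = ror.priority_scores(fc, rr).set_index("probe_id")
        rec = out.loc[probe[n - 1]]
        assert rec["rank_ror"] == 1
        assert rec["rank_fc"] == n
        assert rec["P"] == pytest.approx(n)
        assert rec["logP"] == pytest.approx(np.log10(n), abs=1e-6)

    def test_equal_ranks_give_logp_zero(self):
        fc = pd.DataFrame({"probe_id": ["a", "b"], "logFC": [2.0, 1.0]})
        rr = pd.DataFrame({"probe_id": ["a", "b"], "logRoR": [2.0, 1.0]})
        out = ror.priority_scores(fc, rr)
        np.testing.assert_allclose(out["logP"], 0.0, atol=1e-12)

    def test_five_probe_hand_enumeration(self):
        """|logFC| ranks 1..5 and |logRoR| ranks 5..1 give
        P = (1/5, 2/4, 3/3, 4/2, 5/1)."""
        fc = pd.DataFrame({"probe_id": list("abcde"),
                           "logFC": [5.0, -4.0, 3.0, -2.0, 1.0]})
        rr = pd.DataFrame({"probe_id": list("abcde"),
                           "logRoR": [1.0, -2.0, 3.0, -4.0, 5.0]})
        out = ror.priority_scores(fc, rr)
        np.testing.assert_allclose(out["rank_fc"], [1, 2, 3, 4, 5])
        np.testing.assert_allclose(out["rank_ror"], [5, 4, 3, 2, 1])
        np.testing.assert_allclose(out["P"], [0.2, 0.5, 1.0, 2.0, 5.0])

    def test_invariant_to_probe_order(self, rng):
        probe = [f"p{i}" for i in range(40)]
        fc = pd.DataFrame({"probe_id": probe, "logFC": rng.normal(size=40)})
        rr = pd.DataFrame({"probe_id": probe, "logRoR": rng.normal(size=40)})
        a = ror.priority_scores(fc, rr)
        perm = rng.permutation(40)
        b = ror.priority_scores(fc.iloc[perm], rr.iloc[perm])
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))

    def test_antisymmetric_under_table_swap(self, rng):
        """Swapping the two inputs maps P -> 1/P (logP -> -logP)."""
        probe = [f"p{i}" for i in range(60)]
        fc = pd.DataFrame({"probe_id": probe, "logFC": rng.normal(size=60)})
        rr = pd.DataFrame({"probe_id": probe, "logRoR": rng.normal(size=60)})
        a = ror.priority_scores(fc, rr)
        b = ror.priority_scores(
            rr.rename(columns={"logRoR": "logFC"}),
            fc.rename(columns={"logFC": "logRoR"}),
        )
        np.testing.assert_allclose(a["logP"], -b["logP"], atol=1e-12)

    def test_empty_input_rejected(self):
        empty = pd.DataFrame({"probe_id": [], "logFC": []})
        with pytest.raises(ValueError):
            ror.priority_scores(empty, empty.rename(columns={"logFC": "logRoR"}))


def _annot(probes, symbols=None):
    return pd.DataFrame({
        "probe_id": probes,
        "gene_symbol": symbols or [f"G_{p}" for p in probes],
    })


class TestExtractSets:
    def _tables(self, logp, pvals):
        probes = [f"p{i}" for i in range(len(logp))]
        priority = pd.DataFrame({
            "probe_id": probes,
            "logP": logp,
            "P": 10.0 ** np.asarray(logp),
        })
        rr = pd.DataFrame({"probe_id": probes, "p": pvals, "q": pvals})
        return priority, rr, probes

    def test_ten_probe_hand_enumeration(self):
        logp = [3.0, 2.5, 2.0, 0.5, 0.1, -0.1, -0.5, -2.0, -2.5, -3.0]
        pvals = [0.01, 0.20, 0.03, 0.5, 0.5, 0.5, 0.04, 0.50, 0.01, 0.30]
        priority, rr, probes = self._tables(logp, pvals)
        out = ror.extract_sets(priority, rr, _annot(probes), n_limb=3, alpha=0.05)
        # top limb = p0,p1,p2; p1 fails p<0.05 -> set1 = {p0, p2}
        assert set(out.set1_probes) == {"p0", "p2"}
        # bottom limb = p7,p8,p9; p8 fails p>=0.05 -> set2 = {p7, p9}
        assert set(out.set2_probes) == {"p7", "p9"}
        assert not set(out.set1_probes) & set(out.set2_probes)

    def test_all_nonsignificant_empties_set1(self):
        logp = [2.0, 1.0, 0.0, -1.0, -2.0, -3.0]
        priority, rr, probes = self._tables(logp, [0.5] * 6)
        out = ror.extract_sets(priority, rr, _annot(probes), n_limb=2, alpha=0.05)
        assert out.set1_probes == ()
        assert set(out.set2_probes) == {"p4", "p5"}

    def test_shared_symbol_counted_once(self):
        logp = [3.0, 2.0, 1.0, -1.0, -2.0, -3.0]
        priority, rr, probes = self._tables(logp, [0.01] * 3 + [0.5] * 3)
        annot = _annot(probes, ["SHARED", "SHARED", "SHARED", "A", "B", "C"])
        out = ror.extract_sets(priority, rr, annot, n_limb=3, alpha=0.05)
        assert len(out.set1_probes) == 3
        assert out.set1_genes == ("SHARED",)

    def test_limb_larger_than_half_universe_rejected(self):
        logp = [1.0, 0.0, -1.0, -2.0]
        priority, rr, probes = self._tables(logp, [0.5] * 4)
        with pytest.raises(ValueError, match="n_limb"):
            ror.extract_sets(priority, rr, _annot(probes), n_limb=3)


class TestSetRecoverySmallScale:
    def test_contrasting_resistant_fills_set1_and_avoids_set2(self):
        """End-to-end at reduced scale: resistant-region contrasting genes
        are strongly enriched in Set 1 and absent from Set 2."""
        cohort = synth.generate_cohort(40, 40, [], seed=77)
        expr, truth = synth.generate_expression(
            cohort, 4000, planted=synth.PlantedSpec(n_per_class=60),
            covariates=[], seed=77,
        )
        fc = diffexp.region_contrast(expr, cohort, "vulnerable")
        d, diagnosis = ror.matched_differences(expr, cohort)
        rr = ror.ror_matched(d, diagnosis)
        pri = ror.priority_scores(fc, rr)
        out = ror.extract_sets(pri, rr, _annot(list(expr.index)), n_limb=200)
        cls = truth.set_index("probe_id")["gene_class"]
        set1 = cls.loc[list(out.set1_probes)]
        set2 = cls.loc[list(out.set2_probes)]
        assert (set1 == "contrasting_resistant_up").sum() >= 0.9 * 60
        assert (set2.str.startswith("contrasting")).sum() == 0
        assert (set2.str.startswith("parallel")).sum() > 0.5 * len(set2)
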