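"""Peptide roll-up and differential protein abundance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parevo import PeptideMatrix, ProteomicsDifferentialModel, PipelineConfig
from parevo.proteomics import (
    differential_test,
    functional_heatmap_table,
    median_align,
    rollup_proteins,
    significance_filter,
)
from parevo.simulate import make_planted_proteome, simulate_peptides


def matrix_from(abundances: dict, protein_map: dict, groups: dict) -> PeptideMatrix:
    ab = pd.DataFrame(abundances).T
    ab.columns = list(groups)
    return PeptideMatrix(ab, pd.Series(protein_map), pd.Series(groups))


GROUPS4 = {"a1": "ancestor", "a2": "ancestor", "e1": "pop01", "e2": "pop01"}


class TestRollup:
    def test_single_peptide_protein_reproduces_peptide(self):
        m = matrix_from({"pep1": [1.0, 2.0, 3.0, 4.0]}, {"pep1": "P1"}, GROUPS4)
        out = rollup_proteins(m, align=False)
        assert np.allclose(out.loc["P1"], [1, 2, 3, 4])

    def test_two_offset_peptides_average_and_permutation_invariance(self):
        base = [1.0, 2.0, 3.0, 4.0]
        m = matrix_from(
            {"pep1": base, "pep2": [x + 5 for x in base]},
            {"pep1": "P1", "pep2": "P1"},
            GROUPS4,
        )
        out = rollup_proteins(m, align=False)
        # centered-mean roll-up preserves the common shape
        assert np.allclose(np.diff(out.loc["P1"]), [1, 1, 1])
        flipped = matrix_from(
            {"pep2": [x + 5 for x in base], "pep1": base},
            {"pep1": "P1", "pep2": "P1"},
            GROUPS4,
        )
        assert np.allclose(rollup_proteins(flipped, align=False).loc["P1"],
                           out.loc["P1"])

    def test_planted_effect_recovered_exactly_without_noise(self):
        # one changed protein among many nulls: alignment medians are stable
        m, _ = simulate_peptides(
            n_proteins=30, noise_sd=0.0, missing_rate=0.0, seed=7,
            group_design={"ancestor": 3, "pop01": 3},
            planted_effects={"prot0002": 1.0},
        )
        prot = rollup_proteins(m, align=False)
        rec = differential_test(prot, m.sample_groups)
        assert rec.loc["prot0002", "log2fc"] == pytest.approx(1.0, abs=1e-9)
        assert rec.loc["prot0000", "log2fc"] == pytest.approx(0.0, abs=1e-9)
        # with median alignment the recovered effect moves by at most the
        # (discrete) median shift the planted peptides induce
        aligned = differential_test(rollup_proteins(m), m.sample_groups)
        assert aligned.loc["prot0002", "log2fc"] == pytest.approx(1.0, abs=0.15)

    def test_missing_values_respected(self):
        m = matrix_from(
            {"pep1": [1.0, np.nan, 3.0, 4.0], "pep2": [np.nan] * 4},
            {"pep1": "P1", "pep2": "P2"},
            GROUPS4,
        )
        out = rollup_proteins(m, align=False)
        assert np.isnan(out.loc["P1", "a2"])
        assert out.loc["P2"].isna().all()

    def test_shift_invariance_of_fold_change(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(20, 1, 4)
        m1 = matrix_from({"pep1": vals, "pep2": vals + 2}, {"pep1": "P1", "pep2": "P1"}, GROUPS4)
        m2 = matrix_from({"pep1": vals, "pep2": vals + 9}, {"pep1": "P1", "pep2": "P1"}, GROUPS4)
        fc1 = differential_test(rollup_proteins(m1, align=False), m1.sample_groups)
        fc2 = differential_test(rollup_proteins(m2, align=False), m2.sample_groups)
        assert fc1.loc["P1", "log2fc"] == pytest.approx(fc2.loc["P1", "log2fc"], abs=1e-10)

    def test_median_alignment_equalizes_sample_medians(self):
        rng = np.random.default_rng(4)
        ab = pd.DataFrame(rng.normal(20, 2, (50, 4)), columns=list(GROUPS4))
        ab.iloc[:, 2] += 3.0  # loading offset
        aligned = median_align(ab)
        med = aligned.median(axis=0)
        assert np.allclose(med, med.iloc[0])


class TestDifferential:
    def test_identical_groups_give_null_result(self):
        m = matrix_from(
            {"pep1": [1.0, 2.0, 1.0, 2.0]}, {"pep1": "P1"}, GROUPS4
        )
        rec = differential_test(rollup_proteins(m, align=False), m.sample_groups)
        assert rec.loc["P1", "log2fc"] == pytest.approx(0.0)
        assert rec.loc["P1", "p_value"] > 0.9

    def test_two_group_f_equals_squared_t(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 2), rng.normal(1, 1, 2)
        f, p_f = stats.f_oneway(a, b)
        t, p_t = stats.ttest_ind(a, b)
        prot = pd.DataFrame([np.concatenate([a, b])], index=["P1"], columns=list(GROUPS4))
        rec = differential_test(prot, pd.Series(GROUPS4))
        assert rec.loc["P1", "F"] == pytest.approx(t**2, abs=1e-10)
        assert rec.loc["P1", "p_value"] == pytest.approx(p_t, abs=1e-10)

    def test_null_type_one_error_rate(self):
        m, _ = simulate_peptides(
            n_proteins=1000, peptides_per_protein=2, noise_sd=0.3,
            missing_rate=0.0, seed=31,
            group_design={"ancestor": 3, "pop01": 3, "pop02": 3},
        )
        rec = differential_test(rollup_proteins(m), m.sample_groups)
        rate = (rec.p_value <= 0.01).mean()
        se = np.sqrt(0.01 * 0.99 / len(rec))
        assert abs(rate - 0.01) < 3 * se

    def test_protein_absent_from_ancestor_untestable(self):
        m = matrix_from(
            {"pep1": [np.nan, np.nan, 3.0, 4.0]}, {"pep1": "P1"}, GROUPS4
        )
        rec = differential_test(rollup_proteins(m, align=False), m.sample_groups)
        assert not rec.loc["P1", "testable"]
        sig = significance_filter(rec)
        assert not sig.loc["P1", "significant"]

    def test_per_population_design_runs(self):
        m, _ = simulate_peptides(
            n_proteins=5, noise_sd=0.1, missing_rate=0.0, seed=2,
            group_design={"ancestor": 3, "pop01": 3, "pop02": 3},
            planted_effects={"prot0001": {"pop01": 2.0}},
        )
        rec = differential_test(rollup_proteins(m), m.sample_groups, design="per_population")
        assert rec.loc["prot0001", "log2fc_pop01"] == pytest.approx(2.0, abs=0.3)
        assert rec.loc["prot0001", "p_value"] < 0.05


class TestSignificance:
    @pytest.mark.parametrize(
        "p,fc,expect_sig,expect_dir",
        [
            (0.005, 1.0, True, "up"),
            (0.005, -1.0, True, "down"),
            (0.005, 0.5, False, "none"),
            (0.02, 2.0, False, "none"),
            (0.01, 1.0, True, "up"),  # p boundary passes
            (0.005, 0.7, False, "none"),  # |FC| boundary fails
        ],
    )
    def test_dual_threshold(self, p, fc, expect_sig, expect_dir):
        rec = pd.DataFrame(
            {"p_value": [p], "log2fc": [fc], "testable": [True]},
            index=pd.Index(["P1"], name="protein"),
        )
        out = significance_filter(rec)
        assert bool(out.significant.iloc[0]) is expect_sig
        assert out.direction.iloc[0] == expect_dir


    def test_bh_adjustment_is_more_conservative(self):
        rng = np.random.default_rng(11)
        rec = pd.DataFrame(
            {
                "p_value": rng.uniform(0, 0.05, 50),
                "log2fc": rng.uniform(1, 2, 50),
                "testable": True,
            },
            index=pd.Index([f"P{i}" for i in range(50)], name="protein"),
        )
        raw = significance_filter(rec, p_max=0.03)
        adj = significance_filter(rec, p_max=0.03, p_adjust="bh")
        assert adj.significant.sum() <= raw.significant.sum()
        assert (adj.p_adjusted >= rec.p_value - 1e-12).all()
        with pytest.raises(ValueError):
            significance_filter(rec, p_adjust="bonferroni")


class TestHeatmapAndRecovery:
    def test_empty_significant_set_gives_empty_table(self):
        rec = pd.DataFrame(
            {"p_value": [0.5], "log2fc": [0.1], "log2fc_pop01": [0.1],
             "testable": [True]},
            index=pd.Index(["P1"], name="protein"),
        )
        out = functional_heatmap_table(significance_filter(rec))
        assert len(out) == 0

    def test_undetected_cell_stays_missing(self):
        rec = pd.DataFrame(
            {
                "p_value": [0.001],
                "log2fc": [1.5],
                "log2fc_pop01": [1.5],
                "log2fc_pop02": [np.nan],
                "testable": [True],
            },
            index=pd.Index(["P1"], name="protein"),
        )
        out = functional_heatmap_table(significance_filter(rec))
        assert np.isnan(out.loc["P1", "log2fc_pop02"])

    def test_planted_classes_recovered_with_directions(self):
        effects, classes = make_planted_proteome(
            n_proteins=60, n_up=10, n_down=5, seed=5
        )
        m, truth = simulate_peptides(
            n_proteins=60, peptides_per_protein=4, noise_sd=0.1,
            missing_rate=0.02, seed=6,
            group_design={"ancestor": 3, "pop01": 3, "pop02": 3, "pop03": 3},
            planted_effects=effects,
        )
        res = ProteomicsDifferentialModel(m, classes).fit()
        sig = res.significant()
        truth_sig = truth[truth != 0]
        recall = len(set(sig.index) & set(truth_sig.index)) / len(truth_sig)
        assert recall >= 0.9
        table = res.heatmap_table
        tca = table[table["class"] == "TCA cycle"].drop(columns="class")
        assert (tca.stack() > 0).all()
        assert res.counts["n_up"] >= 9 and res.counts["n_down"] >= 4

    def test_model_summary_reports_counts(self):
        m, _ = simulate_peptides(
            n_proteins=10, noise_sd=0.05, missing_rate=0.0, seed=9,
            group_design={"ancestor": 3, "pop01": 3},
            planted_effects={"prot0003": 1.5},
        )
        res = ProteomicsDifferentialModel(m, config=PipelineConfig()).fit()
        assert res.counts["n_significant"] == 1
        assert "significant:          1" in res.summary()
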