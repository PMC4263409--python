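"""Variant cascade: floor, effect classification, blacklist, Levene filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from parevo import ExperimentDataset, SimulationConfig, simulate_experiment, simulate_genome
from parevo.filtering import (
    apply_blacklist,
    apply_frequency_floor,
    build_ma_blacklist,
    classify_effect,
    levene_artifact_filter,
    levene_statistic,
    select_nonsynonymous,
)
from parevo.simulate import truth_role_of
from parevo.variants import SiteKey, empty_variants


def make_calls(rows):
    """rows: (population_id, contig, position, frequency[, effect])"""
    if not rows:
        return empty_variants()
    return pd.DataFrame(
        [
            {
                "population_id": r[0],
                "contig": r[1],
                "position": r[2],
                "ref": "A",
                "alt": "G",
                "vtype": "snp",
                "gene_id": "g1",
                "effect": r[4] if len(r) > 4 else "nonsynonymous",
                "frequency": r[3],
            }
            for r in rows
        ]
    )


class TestFrequencyFloor:
    def test_boundary_is_inclusive(self):
        calls = make_calls([("p1", "c", 1, 0.04), ("p1", "c", 2, 0.05), ("p1", "c", 3, 0.50)])
        out = apply_frequency_floor(calls, 0.05)
        assert list(out.frequency) == [0.05, 0.50]

    def test_empty_input(self):
        assert len(apply_frequency_floor(empty_variants(), 0.05)) == 0

    def test_floor_of_one_drops_all_polymorphisms(self):
        calls = make_calls([("p1", "c", 1, 0.9), ("p1", "c", 2, 0.99)])
        assert len(apply_frequency_floor(calls, 1.0)) == 0

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_floor_rejected(self, bad):
        with pytest.raises(ValueError):
            apply_frequency_floor(empty_variants(), bad)

    @given(
        freqs=st.lists(st.floats(0.001, 1.0), max_size=30),
        floor=st.floats(0.01, 1.0),
        floor2=st.floats(0.01, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_subset_idempotence_monotonicity(self, freqs, floor, floor2):
        calls = make_calls([("p", "c", i + 1, f) for i, f in enumerate(freqs)])
        once = apply_frequency_floor(calls, floor)
        assert set(once.index) <= set(calls.index)
        assert apply_frequency_floor(once, floor).equals(once)
        lo, hi = sorted([floor, floor2])
        assert len(apply_frequency_floor(calls, lo)) >= len(
            apply_frequency_floor(calls, hi)
        )


class TestEffectClassification:
    # gene: Met-Leu-Trp-stop
    GENE = "ATGCTGTGGTAA"

    @pytest.mark.parametrize(
        "offset,ref,alt,expected",
        [
            (5, "G", "A", "synonymous"),  # CTG -> CTA, both Leu
            (8, "G", "A", "stop_gained"),  # TGG -> TGA
            (4, "T", "G", "nonsynonymous"),  # CTG -> CGG, Leu -> Arg
            (3, "CTG", "-", "inframe_indel"),  # 3-nt deletion
            (3, "CTGT", "-", "frameshift"),  # 4-nt deletion
            (3, "-", "AC", "frameshift"),  # 2-nt insertion
        ],
    )
    def test_classification(self, offset, ref, alt, expected):
        assert classify_effect(self.GENE, offset, ref, alt) == expected

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_effect(self.GENE, 0, "G", "A")

    def test_position_outside_any_gene_is_intergenic(self):
        assert classify_effect(None, 0, "A", "G") == "intergenic"

    def test_selection_keeps_all_nonsynonymous_classes(self):
        calls = make_calls(
            [
                ("p", "c", 1, 0.1, "synonymous"),
                ("p", "c", 2, 0.1, "nonsynonymous"),
                ("p", "c", 3, 0.1, "frameshift"),
                ("p", "c", 4, 0.1, "stop_gained"),
                ("p", "c", 5, 0.1, "inframe_indel"),
                ("p", "c", 6, 0.1, "intergenic"),
            ]
        )
        out = select_nonsynonymous(calls)
        assert set(out.effect) == {"nonsynonymous", "frameshift", "stop_gained", "inframe_indel"}

    def test_selection_of_all_synonymous_is_empty(self):
        calls = make_calls([("p", "c", 1, 0.1, "synonymous")])
        assert len(select_nonsynonymous(calls)) == 0


class TestMABlacklist:
    @staticmethod
    def ma_calls(lines_per_site):
        rows = []
        for pos, n_lines in lines_per_site.items():
            for i in range(n_lines):
                rows.append((f"MA_{i}", "c", pos, 0.9))
        return make_calls(rows)

    def test_four_or_more_lines_blacklisted_three_not(self):
        bl = build_ma_blacklist(self.ma_calls({100: 4, 200: 3, 300: 12}), min_lines=4)
        assert bl == {SiteKey("c", 100), SiteKey("c", 300)}

    def test_counts_lines_not_calls(self):
        # one line carrying two alleles at one site counts once
        calls = make_calls([("MA_0", "c", 7, 0.5), ("MA_1", "c", 7, 0.5)])
        extra = calls.iloc[[0]].assign(alt="T")
        calls = pd.concat([calls, extra], ignore_index=True)
        assert build_ma_blacklist(calls, min_lines=3) == set()
        assert build_ma_blacklist(calls, min_lines=2) == {SiteKey("c", 7)}

    def test_no_ma_lines_gives_empty_blacklist(self):
        assert build_ma_blacklist(empty_variants(), 4) == set()

    def test_min_lines_validated(self):
        with pytest.raises(ValueError):
            build_ma_blacklist(empty_variants(), 0)

    @given(min_a=st.integers(1, 8), min_b=st.integers(1, 8))
    @settings(max_examples=30, deadline=None)
    def test_blacklist_monotone_in_min_lines(self, min_a, min_b):
        calls = self.ma_calls({10: 2, 20: 5, 30: 7, 40: 1})
        lo, hi = sorted([min_a, min_b])
        assert build_ma_blacklist(calls, hi) <= build_ma_blacklist(calls, lo)

    def test_apply_empty_blacklist_is_identity(self):
        calls = make_calls([("p", "c", 1, 0.2)])
        out, counts = apply_blacklist(calls, set())
        assert out.equals(calls)
        assert counts["total_removed"] == 0

    def test_apply_full_blacklist_empties_output(self):
        calls = make_calls([("p", "c", 1, 0.2), ("p", "c", 2, 0.3)])
        out, counts = apply_blacklist(calls, {SiteKey("c", 1), SiteKey("c", 2)})
        assert len(out) == 0
        assert counts["total_removed"] == 2


class TestLeveneStatistic:
    def test_zero_spread_everywhere_gives_p_one(self):
        res = levene_statistic([[1, 1, 1], [2, 2, 2]])
        assert res.testable and res.W == 0.0 and res.p_value == 1.0

    def test_equal_spread_symmetry_gives_p_one(self):
        res = levene_statistic([[0, 2], [0, 2]])
        assert res.W == 0.0 and res.p_value == 1.0

    def test_zero_within_positive_between_gives_p_zero(self):
        res = levene_statistic([[0, 2, 0, 2], [1, 1, 1, 1]])
        assert res.testable and np.isinf(res.W) and res.p_value == 0.0

    def test_single_observation_group_untestable(self):
        res = levene_statistic([[1.0], [1, 2, 3]])
        assert not res.testable

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            levene_statistic([[1, 2, 3]])

    @pytest.mark.parametrize("center", ["mean", "median"])
    def test_matches_reference_implementation(self, center):
        rng = np.random.default_rng(42)
        for _ in range(300):
            k = rng.integers(2, 5)
            groups = [rng.normal(0, rng.uniform(0.5, 3), rng.integers(2, 10)) for _ in range(k)]
            ours = levene_statistic(groups, center=center)
            W, p = stats.levene(*groups, center=center)
            assert ours.W == pytest.approx(W, abs=1e-10)
            assert ours.p_value == pytest.approx(p, abs=1e-10)

    def test_degrees_of_freedom(self):
        res = levene_statistic([[1, 2, 3], [4, 5], [6, 7]])
        assert (res.df1, res.df2) == (2, 7 - 3)


def _two_treatment_dataset(site_rows):
    """12 LB + 12 BHI populations of one species, calls from site_rows."""
    ann = simulate_genome(5, seed=1, species="sp1")
    pops = pd.DataFrame(
        [
            (f"sp1_{t}_{i:02d}", "sp1", t, i, False, False)
            for t in ("LB", "BHI")
            for i in range(1, 13)
        ],
        columns=["population_id", "species", "treatment", "replicate", "is_ma", "excluded"],
    )
    calls = make_calls(site_rows)
    calls["contig"] = "sp1_contig"
    calls["gene_id"] = ann.genes.gene_id.iloc[0]
    return ExperimentDataset(ann, pops, calls)


class TestLeveneFilter:
    def test_uniform_frequency_site_removed(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"sp1_{t}_{i:02d}", "sp1_contig", 50, 0.12 + rng.normal(0, 0.003))
            for t in ("LB", "BHI")
            for i in range(1, 13)
        ]
        ds = _two_treatment_dataset(rows)
        kept, removed, audit = levene_artifact_filter(ds)
        assert removed == {SiteKey("sp1_contig", 50)}
        assert len(kept) == 0

    def test_treatment_restricted_site_retained(self):
        rng = np.random.default_rng(1)
        rows = [
            (f"sp1_LB_{i:02d}", "sp1_contig", 60, rng.uniform(0.4, 0.8))
            for i in range(1, 13)
        ]
        ds = _two_treatment_dataset(rows)
        kept, removed, audit = levene_artifact_filter(ds)
        assert removed == set()
        assert len(kept) == len(rows)
        # never tested: absent from every BHI population
        assert not audit.testable.any()

    def test_sparse_site_untestable_and_retained(self):
        rows = [("sp1_LB_01", "sp1_contig", 70, 0.3)]
        ds = _two_treatment_dataset(rows)
        kept, removed, audit = levene_artifact_filter(ds)
        assert len(kept) == 1 and removed == set()

    def test_single_treatment_dataset_rejected(self):
        ds = _two_treatment_dataset([("sp1_LB_01", "sp1_contig", 10, 0.3)])
        pops = ds.populations[ds.populations.treatment == "LB"].copy()
        calls = ds.variants
        single = ExperimentDataset(ds.annotation, pops, calls)
        with pytest.raises(ValueError):
            levene_artifact_filter(single)


@pytest.fixture(scope="module")
def filter_outcome(fitted):
    ds = fitted.dataset
    pre = select_nonsynonymous(apply_frequency_floor(ds.evolved_calls(), 0.05))
    roles_pre = truth_role_of(ds, pre)
    roles_post = truth_role_of(ds, fitted.filtered_calls)
    return roles_pre.value_counts(), roles_post.value_counts()


class TestPlantedRecovery:
    """Blacklist + Levene on one simulated experiment with truth labels."""

    def test_artifacts_removed(self, filter_outcome):
        pre, post = filter_outcome
        assert pre.get("artifact", 0) > 0
        assert post.get("artifact", 0) <= 0.05 * pre.get("artifact", 0)

    def test_true_variants_retained(self, filter_outcome):
        pre, post = filter_outcome
        n_pre = pre.get("driver", 0) + pre.get("neutral", 0)
        n_post = post.get("driver", 0) + post.get("neutral", 0)
        assert n_post >= 0.95 * n_pre

    def test_simulated_artifact_sites_all_blacklisted(self, fitted):
        ds = fitted.dataset
        art = ds.truth[ds.truth.role == "artifact"]
        blacklisted = {(b.contig, b.position) for b in fitted.blacklist}
        assert set(zip(art.contig, art.position)) <= blacklisted
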