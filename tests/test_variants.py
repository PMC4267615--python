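"""Single/double variant aggregation, heat-map normalization and synergy."""

import math

import numpy as np
import pandas as pd
import pytest

import cas9rvl as c
from cas9rvl.counting import CountTable
from cas9rvl.errors import AnalysisError
from cas9rvl.library import BASES
from cas9rvl.variants import element_label, synergy


@pytest.fixture(scope="module")
def hand_rt(spec):
    """Hand-built retention table with known per-species scores."""
    entries = []  # (signature, flank_context or None, score)
    entries += [(((4, "A"),), None, -3.0)]
    flanks = ["ACGTAC" + "A" + "GTACGT", "TTTTTT" + "A" + "AAAAAA"]
    entries += [(((4, "A"),), flanks[0].replace("A", "C", 1), -1.0)]
    entries += [(((4, "A"),), flanks[1], -2.0)]
    entries += [((), None, -4.0), ((), flanks[0], -4.5), ((), flanks[1], -3.5)]
    entries += [(((4, "A"), (16, "T")), None, -0.5)]
    species, scores = [], []
    for sig, fc, score in entries:
        sp = c.make_species(spec, sig, fc)
        species.append(sp)
        scores.append(score)
    info = pd.DataFrame(
        {
            "signature": [c.signature_to_str(sp.signature) for sp in species],
            "mismatch_count": [sp.mismatch_count for sp in species],
        },
        index=pd.Index([sp.sequence for sp in species], name="sequence"),
    )
    scores_df = pd.DataFrame({"cut_t60": scores}, index=info.index)
    ref = c.ReferencePopulation("spike_in", frozenset({"placeholder"}), floor=1)
    return c.RetentionTable(scores_df, info, ref, "uncut")


class TestSingleVariantMedians:
    def test_hand_median(self, hand_rt, spec):
        summary = c.single_variant_medians(hand_rt, spec, "cut_t60")
        cell = summary.cell(4, "A")
        assert cell["median"] == -2.0 and cell["n"] == 3
        assert cell["rule"] == "target-region"

    def test_wt_cell_and_rule_assignment(self, hand_rt, spec):
        summary = c.single_variant_medians(hand_rt, spec, "cut_t60")
        assert summary.wt_median == -4.0 and summary.wt_n == 3
        canon = spec.base_at(4)
        assert bool(summary.cell(4, canon)["is_wt"])
        assert summary.cell(-3, "A")["rule"] == "flank-conditioned"

    def test_flank_cells_use_perfect_target_species_only(self, hand_rt, spec):
        summary = c.single_variant_medians(hand_rt, spec, "cut_t60")
        # flank position 24: base G appears in flanks[0] ('GTACGT'[0]); only
        # empty-signature species qualify for flank-conditioned medians
        cell = summary.cell(24, "G")
        assert cell["n"] >= 1
        total_flank_n = summary.grid[summary.grid["rule"] == "flank-conditioned"]["n"]
        assert total_flank_n.max() <= 3  # never more than the 3 WT species

    def test_empty_cells_are_reported_not_errors(self, hand_rt, spec):
        summary = c.single_variant_medians(hand_rt, spec, "cut_t60")
        cell = summary.cell(7, "A" if spec.base_at(7) != "A" else "C")
        assert cell["n"] == 0 and math.isnan(cell["median"])

    def test_median_is_permutation_invariant_and_robust(self, hand_rt, spec):
        base = c.single_variant_medians(hand_rt, spec, "cut_t60").cell(4, "A")["median"]
        shuffled = c.RetentionTable(
            hand_rt.scores.iloc[::-1], hand_rt.info.iloc[::-1],
            hand_rt.reference, hand_rt.uncleaved_sample,
        )
        assert c.single_variant_medians(shuffled, spec, "cut_t60").cell(4, "A")["median"] == base
        # corrupting 1 of the 3 species moves the median only within the rest
        corrupted = hand_rt.scores.copy()
        corrupted.iloc[0, 0] = -13.0
        rt2 = c.RetentionTable(corrupted, hand_rt.info, hand_rt.reference, "uncut")
        med2 = c.single_variant_medians(rt2, spec, "cut_t60").cell(4, "A")["median"]
        assert -2.0 <= med2 <= -1.0


class TestHeatmap:
    def test_ratios(self, hand_rt, spec):
        summary = c.single_variant_medians(hand_rt, spec, "cut_t60")
        heat = c.heatmap_normalize(summary)
        assert heat.loc[(4, "A")] == pytest.approx(0.5)  # -2 / -4
        assert heat.loc[(4, spec.base_at(4))] == pytest.approx(1.0)  # WT cell

    def test_uncleaved_wt_is_an_error(self, hand_rt, spec):
        summary = c.single_variant_medians(hand_rt, spec, "cut_t60")
        with pytest.raises(AnalysisError):
            c.heatmap_normalize(summary, wt_median=0.0)

    def test_cell_equal_double_wt_ratio(self, hand_rt, spec):
        summary = c.single_variant_medians(hand_rt, spec, "cut_t60")
        assert c.heatmap_normalize(summary, wt_median=-1.0).loc[(4, "A")] == 2.0


class TestDoubleVariantMatrix:
    def test_pair_cell_is_that_species_score(self, hand_rt, spec):
        dvm = c.double_variant_matrix(hand_rt, spec, "cut_t60")
        assert dvm.cell((4, "A"), (16, "T")) == -0.5
        assert dvm.cell((16, "T"), (4, "A")) == -0.5  # symmetric fill

    def test_diagonal_equals_single_medians(self, hand_rt, spec):
        dvm = c.double_variant_matrix(hand_rt, spec, "cut_t60")
        summary = c.single_variant_medians(hand_rt, spec, "cut_t60")
        lab = element_label((4, "A"))
        assert dvm.lr.at[lab, lab] == summary.cell(4, "A")["median"]
        assert dvm.lr_wt == summary.wt_median

    def test_masking_below_n_min(self, hand_rt, spec):
        dvm = c.double_variant_matrix(hand_rt, spec, "cut_t60", n_min=2)
        lab1, lab2 = element_label((4, "A")), element_label((16, "T"))
        assert math.isnan(dvm.lr.at[lab1, lab2])  # only 1 qualifying species


class TestSynergy:
    def test_multiplicative_identity_value(self):
        lr_wt, lr1, lr2 = -4.0, -2.0, -1.0
        lr12 = lr1 * lr2 / lr_wt
        assert synergy(lr12, lr1, lr2, lr_wt) == pytest.approx(1.0)

    def test_arithmetic_example(self):
        assert synergy(-0.5, -2.0, -2.0, -4.0) == 0.5

    def test_zero_double_retention(self):
        assert synergy(0.0, -2.0, -2.0, -4.0) == 0.0

    def test_symmetry(self):
        assert synergy(-0.7, -2.0, -1.0, -4.0) == synergy(-0.7, -1.0, -2.0, -4.0)

    def test_uncleaved_wt_refused(self):
        with pytest.raises(AnalysisError):
            synergy(-0.5, -2.0, -2.0, 0.5)

    def test_undetectable_single_excluded(self):
        assert math.isnan(synergy(-0.5, math.nan, -2.0, -4.0))


class TestDetectableCleavage:
    def test_identical_proportions_not_detectable(self):
        assert not c.detectable_cleavage_test(1000, 1000, 100_000, 100_000)

    def test_strong_depletion_detected(self):
        assert c.detectable_cleavage_test(10, 1000, 100_000, 100_000)

    def test_small_fluctuation_not_detected(self):
        assert not c.detectable_cleavage_test(50, 55, 100_000, 100_000)

    def test_enrichment_never_counts_as_cleavage(self):
        assert not c.detectable_cleavage_test(5000, 1000, 100_000, 100_000)

    def test_matches_fisher_oracle(self):
        from scipy import stats

        table = [[40, 100], [10_000, 10_000]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        assert c.detectable_cleavage_test(40, 100, 10_000, 10_000) == (p < 0.05)


class TestSimulatedOrdering:
    def test_seed_transversion_vs_pam_distal(self, recovery_run):
        """An impaired seed variant stays near 0 while a tolerated PAM-
        proximal variant is strongly depleted (G16T vs T20A phenomenology)."""
        singles = recovery_run["result"].singles
        impaired = singles.cell(16, "T")["median"]
        tolerated = singles.cell(20, "A")["median"]
        assert impaired > tolerated
        assert impaired > recovery_run["result"].singles.wt_median / 2

    def test_all_uncleavable_gives_flat_grid(self, spec):
        from cas9rvl.config import AnalysisBlock
        from cas9rvl.simulate import KineticParams, PenaltyProfile

        prof = PenaltyProfile({k: 1.0 for k in c.default_penalty_profile(spec).penalty})
        kin = KineticParams(1.0, 0.0, 0.0, (60.0,))  # no cleavage at all
        lib = c.sample_library(spec, 150, seed=19)
        sim = c.simulate_experiment(spec, lib, prof, kin, 1_000_000, sampling="expected")
        res = c.analyze_counts(sim.counts, spec, AnalysisBlock())
        medians = res.singles.grid["median"].dropna()
        assert np.abs(medians.to_numpy()).max() < 1e-9
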