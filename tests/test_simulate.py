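"""Penalty model, biphasic survival and the experiment simulator."""

import math

import numpy as np
import pytest

import cas9rvl as c
from cas9rvl.config import AnalysisBlock
from cas9rvl.errors import ConfigurationError, ValidationError
from cas9rvl.simulate import KineticParams, PenaltyProfile, is_transition


class TestCleavageWeight:
    def test_perfect_match_weight_is_one(self, spec, profile):
        assert c.cleavage_weight(c.make_species(spec), profile) == 1.0

    def test_zero_multiplier_is_absorbing(self, spec, profile):
        prof = PenaltyProfile({**profile.penalty, (16, "T"): 0.0})
        sp = c.make_species(spec, ((16, "T"), (4, "T")))
        assert c.cleavage_weight(sp, prof) == 0.0

    def test_weight_is_product_of_entries(self, spec, profile):
        """Brute-force product over every enumerated double variant."""
        for sig in c.enumerate_variants(spec, 2)[::97]:
            (p1, b1), (p2, b2) = sig
            expected = profile.penalty[(p1, b1)] * profile.penalty[(p2, b2)]
            assert c.cleavage_weight(c.make_species(spec, sig), profile) == pytest.approx(expected)

    def test_missing_entry_names_position(self, spec):
        prof = PenaltyProfile({(4, "T"): 0.5})
        with pytest.raises(ConfigurationError, match="16"):
            c.cleavage_weight(c.make_species(spec, ((16, "T"),)), prof)

    def test_flank_modifier_applies(self, spec, profile):
        prof = PenaltyProfile(dict(profile.penalty), flank_modifier={(0, "C"): 0.8})
        flank = "TCGATC" + "A" + "CATGCA"  # base C at position 0
        sp = c.make_species(spec, (), flank)
        assert c.cleavage_weight(sp, prof) == pytest.approx(0.8)

    def test_enhancement_cap_enforced(self):
        with pytest.raises(ValidationError, match="max_enhancement"):
            PenaltyProfile({(10, "T"): 2.5})

    def test_default_profile_transversions_harsher(self, spec, profile):
        for pos in (4, 13, 16, 22, 23):
            canon = spec.base_at(pos)
            tv = [v for (p, b), v in profile.penalty.items()
                  if p == pos and not is_transition(canon, b)]
            ts = [v for (p, b), v in profile.penalty.items()
                  if p == pos and is_transition(canon, b)]
            assert max(tv) < min(ts)


class TestSurvival:
    def test_boundaries(self):
        k = KineticParams(0.3, 0.5, 0.01, (10.0,))
        assert c.survival_fraction(2.0, 0.0, k) == 1.0
        assert c.survival_fraction(0.0, 500.0, k) == 1.0

    def test_single_exponential_limit(self):
        k = KineticParams(1.0, 0.2, 0.0, (10.0,))
        for t in (0.5, 5.0, 50.0):
            assert c.survival_fraction(1.0, t, k) == pytest.approx(math.exp(-0.2 * t))

    def test_monotone_in_t_and_w(self):
        k = KineticParams(0.3, 0.5, 0.01, (10.0,))
        ts = np.linspace(0, 300, 40)
        s = [c.survival_fraction(1.0, t, k) for t in ts]
        assert all(a >= b for a, b in zip(s, s[1:]))
        ws = np.linspace(0, 2, 40)
        sw = [c.survival_fraction(w, 60.0, k) for w in ws]
        assert all(a >= b for a, b in zip(sw, sw[1:]))

    def test_invalid_inputs(self):
        k = KineticParams(0.3, 0.5, 0.01, (10.0,))
        with pytest.raises(ValidationError):
            c.survival_fraction(-0.1, 1.0, k)
        with pytest.raises(ValidationError):
            c.survival_fraction(1.0, -1.0, k)
        with pytest.raises(ValidationError):
            KineticParams(0.3, 0.01, 0.5, (10.0,))


class TestSimulateExperiment:
    def test_counts_sum_to_depth(self, small_sim):
        table = small_sim.counts
        for sample in table.samples:
            assert table.counts[sample].sum() == 500_000

    def test_reproducible_under_seed(self, spec, profile, control_spec):
        kin = KineticParams(timepoints=(15.0,))
        lib = c.sample_library(spec, 50, seed=1)
        a = c.simulate_experiment(spec, lib, profile, kin, 10_000, seed=4)
        b = c.simulate_experiment(spec, lib, profile, kin, 10_000, seed=4)
        assert a.counts.counts.equals(b.counts.counts)

    def test_uniform_weights_give_zero_retention(self, spec):
        """If every species survives identically, depletion cancels in scoring."""
        prof = PenaltyProfile({k: 1.0 for k in c.default_penalty_profile(spec).penalty})
        kin = KineticParams(1.0, 0.05, 0.0, (60.0,))
        lib = c.sample_library(spec, 100, seed=8)
        sim = c.simulate_experiment(spec, lib, prof, kin, 1_000_000,
                                    sampling="expected")
        res = c.analyze_counts(sim.counts, spec, AnalysisBlock())
        assert np.nanmax(np.abs(res.retention.scores.to_numpy())) < 1e-9

    def test_spike_in_is_uncleaved(self, spec, profile, control_spec):
        kin = KineticParams(1.0, 0.05, 0.0, (120.0,))
        lib = [c.make_species(spec)]
        spike = c.sample_library(control_spec, 5, seed=2)
        sim = c.simulate_experiment(spec, lib, profile, kin, 10_000,
                                    spike_in=spike, spike_fraction=0.5,
                                    sampling="expected")
        gt = sim.ground_truth
        spike_rows = gt[gt["spike_in"]]
        assert (spike_rows["weight"] == 0).all()
        assert (spike_rows["survival_t120"] == 1.0).all()

    def test_two_species_log2_depletion(self, spec):
        """survival 0.5 vs 1.0 -> retention difference of -1 at high depth."""
        prof = PenaltyProfile({**c.default_penalty_profile(spec).penalty,
                               (16, "T"): 1.0, (3, "T"): 0.0})
        kin = KineticParams(1.0, math.log(2), 0.0, (1.0,))  # s(w=1, t=1) = 0.5
        sp_half = c.make_species(spec, ((16, "T"),))
        sp_ref = c.make_species(spec, ((3, "T"),))  # weight 0 -> survival 1
        sim = c.simulate_experiment(spec, [sp_half, sp_ref], prof, kin,
                                    1_000_000, seed=12)
        counts = sim.counts.counts
        rep = counts.loc[sp_half.sequence] / counts.loc[sp_ref.sequence]
        score = math.log2(rep["cut_t1"] / rep["uncut"])
        assert score == pytest.approx(-1.0, abs=0.02)

    def test_pcr_bias_cancels_in_retention(self, spec, profile):
        kin = KineticParams(1.0, 0.02, 0.0, (60.0,))
        lib = [c.make_species(spec, sig) for sig in c.enumerate_variants(spec, 1)[:10]]
        bias = {sp.sequence: 1.0 + 0.2 * i for i, sp in enumerate(lib)}
        plain = c.simulate_experiment(spec, lib, profile, kin, 1_000_000,
                                      sampling="expected")
        biased = c.simulate_experiment(spec, lib, profile, kin, 1_000_000,
                                       pcr_bias=bias, sampling="expected")
        for sim in (plain, biased):
            counts = sim.counts.counts
            ref = counts.iloc[0]  # same species as reference in both
            scores = np.log2(
                (counts["cut_t60"] / ref["cut_t60"]) / (counts["uncut"] / ref["uncut"])
            )
            sim.scores = scores
        assert np.allclose(plain.scores, biased.scores, atol=1e-12)

    def test_expected_retention_monotone_in_weight(self, expected_run):
        """More severe weights never look better-retained in noise-free mode."""
        gt = expected_run["sim"].ground_truth
        res = expected_run["result"]
        scores = res.retention.scores["cut_t100"]
        main = gt[~gt["spike_in"]]
        merged = main.join(scores.rename("lr"))
        ordered = merged.sort_values("weight")
        lr = ordered["lr"].to_numpy()
        assert (np.diff(lr) <= 1e-9).all()

    def test_fastq_round_trip_matches_counts(self, spec, profile, tmp_path):
        kin = KineticParams(timepoints=(15.0,))
        lib = c.sample_library(spec, 40, seed=3)
        sim = c.simulate_experiment(spec, lib, profile, kin, 10_000, seed=5)
        path = tmp_path / "uncut.fastq"
        n = c.write_fastq(sim.counts, "uncut", path, seed=6)
        assert n == 10_000
        table = c.count_reads(path, spec, sample="uncut")
        assert table.unassigned["uncut"] == 0
        merged = table.counts["uncut"].reindex(sim.counts.counts.index).fillna(0)
        assert (merged == sim.counts.counts["uncut"]).all()
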