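"""Shared fixtures: target specs and reference simulations.

The heavier simulated datasets are session-scoped so the noise-free
enumerated run and the 66-single recovery run are built once.
"""

from __future__ import annotations

import numpy as np
import pytest

import cas9rvl as c
from cas9rvl.config import AnalysisBlock
from cas9rvl.library import BASES, RANDOM_POSITIONS
from cas9rvl.simulate import KineticParams, PenaltyProfile, default_penalty_profile


@pytest.fixture(scope="session")
def spec():
    return c.demo_target_spec()


@pytest.fixture(scope="session")
def control_spec():
    return c.demo_control_spec()


@pytest.fixture(scope="session")
def profile(spec):
    return default_penalty_profile(spec)


def _random_flanks(rng, n):
    return ["".join(rng.choice(list(BASES), size=len(RANDOM_POSITIONS))) for _ in range(n)]


@pytest.fixture(scope="session")
def expected_run(spec, profile, control_spec):
    """Noise-free, single-exponential run over WT + all 66 singles + all 2079 pairs.

    Under f=1 kinetics with multiplicative penalty weights and an uncleavable
    spike-in reference, every double variant's log retention is exactly the
    product rule, so synergy should be 1 throughout.
    """
    kin = KineticParams(burst_fraction=1.0, k_fast=0.03, k_slow=0.0, timepoints=(100.0,))
    library = [c.make_species(spec)]
    for sig in c.enumerate_variants(spec, 1) + c.enumerate_variants(spec, 2):
        library.append(c.make_species(spec, sig))
    spike = c.sample_library(control_spec, 3, seed=11)
    sim = c.simulate_experiment(
        spec, library, profile, kin, depth=100_000_000,
        spike_in=spike, spike_fraction=0.1, sampling="expected",
    )
    acfg = AnalysisBlock(reference="spikein")
    result = c.analyze_counts(
        sim.counts, spec, acfg, spike_members=sim.spike_sequences
    )
    return {"sim": sim, "result": result, "kinetics": kin}


@pytest.fixture(scope="session")
def recovery_run(spec, profile, control_spec):
    """Multinomial run with 5 species per single variant + 20 WT species.

    Used to check that pipeline medians recover the known penalty landscape.
    """
    rng = np.random.default_rng(2024)
    kin = KineticParams(burst_fraction=0.3, k_fast=0.5, k_slow=0.01,
                        timepoints=(15.0, 60.0, 180.0))
    library = [c.make_species(spec, (), fc) for fc in _random_flanks(rng, 20)]
    singles = c.enumerate_variants(spec, 1)
    for sig in singles:
        for fc in _random_flanks(rng, 5):
            library.append(c.make_species(spec, sig, fc))
    spike = c.sample_library(control_spec, 10, seed=13)
    sim = c.simulate_experiment(
        spec, library, profile, kin, depth=1_000_000,
        spike_in=spike, spike_fraction=0.1, sampling="multinomial", seed=97,
    )
    acfg = AnalysisBlock(reference="spikein")
    result = c.analyze_counts(sim.counts, spec, acfg, spike_members=sim.spike_sequences)
    true_lr = {
        sig[0]: float(np.log2(c.survival_fraction(
            c.cleavage_weight(c.make_species(spec, sig), profile), 180.0, kin)))
        for sig in singles
    }
    return {"sim": sim, "result": result, "kinetics": kin, "true_lr": true_lr}


@pytest.fixture(scope="session")
def small_sim(spec, profile, control_spec):
    """A compact doped-library run (multinomial) for generic assertions."""
    kin = KineticParams(timepoints=(15.0, 180.0))
    library = c.sample_library(spec, 250, seed=5)
    spike = c.sample_library(control_spec, 20, seed=6)
    sim = c.simulate_experiment(
        spec, library, profile, kin, depth=500_000,
        spike_in=spike, spike_fraction=0.1, seed=7,
    )
    return sim
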