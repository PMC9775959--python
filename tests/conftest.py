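import numpy as np
import pytest

from gpcrland import (
    BundleSpec, ActivationSpec, make_bundle, make_activation_pair,
    coarse_grain, build_membrane, EnergyParams,
)
from gpcrland.pipeline import RunConfig, run_scenario


@pytest.fixture(scope="session")
def small_bundle():
    """Compact 3-helix bundle (36 residues) for oracle-sized checks."""
    spec = BundleSpec(n_helices=3, helix_length=12, radius=7.5, seed=7,
                      lock_acid_helix=None, interface_band=(5.0, 8.5))
    return coarse_grain(make_bundle(spec))


@pytest.fixture(scope="session")
def canonical_pair():
    """The canonical seed-1 seven-helix activation pair (14 A swing)."""
    spec = BundleSpec(seed=1)
    act = ActivationSpec(swing_distance=14.0)
    inactive, active = make_activation_pair(spec, act)
    return coarse_grain(inactive), coarse_grain(active)


@pytest.fixture(scope="session")
def scenario_a_report():
    return run_scenario(RunConfig(scenario="A", seed=1))


@pytest.fixture(scope="session")
def scenario_b_reports():
    return {seed: run_scenario(RunConfig(scenario="B", seed=seed))
            for seed in (1, 2, 3, 4, 5)}


@pytest.fixture(scope="session")
def scenario_c_report():
    return run_scenario(RunConfig(scenario="C", seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
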