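import numpy as np
import pytest

from ptse import PotentialSpec, SteeringProtocol, jarzynski_estimate, run_msmd


@pytest.fixture(scope="session")
def double_well():
    """Symmetric 5 kT double well in reduced units, wells at ±1."""
    return PotentialSpec(
        family="double_well_1d",
        barrier_height=5.0,
        well_positions=(-1.0, 1.0),
        temperature=1.0,
        units_mode="reduced",
    )


@pytest.fixture(scope="session")
def asymmetric_well():
    """5 kT double well tilted by 2 kT (product above reactant)."""
    return PotentialSpec(
        family="double_well_1d",
        barrier_height=5.0,
        well_positions=(-1.0, 1.0),
        asymmetry=2.0,
        temperature=1.0,
        units_mode="reduced",
    )


@pytest.fixture(scope="session")
def near_equilibrium_msmd(double_well):
    """Shared slow-pull steered run on the symmetric well: 200 replicates
    at v = 0.05 with k = 300, and its Jarzynski profile."""
    protocol = SteeringProtocol(
        lambda_start=-1.2,
        lambda_end=1.2,
        force_constant=300.0,
        velocity=0.05,
        n_replicates=200,
        temperature=1.0,
    )
    profiles = run_msmd(
        double_well,
        protocol,
        seeds=range(200),
        equilibration_steps=4000,
        dt=2.5e-4,
    )
    fep = jarzynski_estimate(profiles, temperature=1.0, seed=0)
    return profiles, fep
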