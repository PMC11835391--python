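import dataclasses

import numpy as np
import pytest

from ptse import (
    PotentialSpec,
    SteeringProtocol,
    jarzynski_estimate,
    run_msmd,
    staged_msmd,
)
from ptse.msmd import StagingError
from ptse.potentials import analytic_rc_profile


def test_protocol_validation():
    with pytest.raises(ValueError):
        SteeringProtocol(lambda_start=0.0, lambda_end=0.0)
    with pytest.raises(ValueError):
        SteeringProtocol(lambda_start=0.0, lambda_end=1.0, direction="backward")
    with pytest.raises(ValueError):
        SteeringProtocol(lambda_start=0.0, lambda_end=1.0, velocity=-1.0)
    p = SteeringProtocol(lambda_start=-1.0, lambda_end=1.0, n_replicates=4)
    r = p.reversed()
    assert r.direction == "backward" and r.lambda_start == 1.0


def test_flat_zero_temperature_zero_work():
    """With no opposing force and no noise, ξ tracks λ and W ≈ 0."""
    spec = PotentialSpec(family="flat", temperature=0.0)
    proto = SteeringProtocol(
        lambda_start=0.0, lambda_end=1.0, velocity=0.01, n_replicates=2, temperature=0.0
    )
    profs = run_msmd(spec, proto, seeds=[0, 1], equilibration_steps=100, dt=2.5e-4)
    for p in profs:
        # dissipation bound γvL; lag bound vγ/k
        assert np.abs(p.work).max() < 0.02
        assert np.abs(p.xi_trace - p.lambda_grid).max() < 1e-3


def test_quasi_static_harmonic_work_equals_energy_difference():
    """At T = 0 and slow pulling the work equals ΔV along the path."""
    spec = PotentialSpec(family="harmonic", force_constant=2.0, temperature=0.0)
    proto = SteeringProtocol(
        lambda_start=0.0, lambda_end=1.0, velocity=0.02, n_replicates=1,
        temperature=0.0,
    )
    (p,) = run_msmd(spec, proto, seeds=[0], equilibration_steps=2000, dt=1e-3)
    # stiff spring: V(λ) = λ²·k_eff/2 with k_eff = kK/(k+K)
    k_eff = 2.0 * 300.0 / 302.0
    expected = 0.5 * k_eff * p.lambda_grid**2
    assert np.abs(p.work - expected).max() < 0.02


def test_default_protocol_is_reference_configuration():
    p = SteeringProtocol(lambda_start=-1.0, lambda_end=1.0)
    assert p.force_constant == 300.0
    assert p.velocity == 0.05
    assert p.n_replicates == 10


def test_run_msmd_determinism(double_well):
    proto = SteeringProtocol(
        lambda_start=-1.1, lambda_end=1.1, velocity=1.0, n_replicates=3, temperature=1.0
    )
    a = run_msmd(double_well, proto, seeds=[5, 6, 7], equilibration_steps=500, dt=5e-4)
    b = run_msmd(double_well, proto, seeds=[5, 6, 7], equilibration_steps=500, dt=5e-4)
    assert np.array_equal(a[2].work, b[2].work)
    assert len(a) == 3 and a[0].work[0] == 0.0


def test_seed_count_mismatch_rejected(double_well):
    proto = SteeringProtocol(
        lambda_start=-1.0, lambda_end=1.0, velocity=1.0, n_replicates=3, temperature=1.0
    )
    with pytest.raises(ValueError):
        run_msmd(double_well, proto, seeds=[1, 2], equilibration_steps=10)


def test_staged_single_stage_matches_plain_jarzynski(double_well):
    """n_stages = 1 degenerates to a plain exponential-average estimate."""
    proto = SteeringProtocol(
        lambda_start=-1.1, lambda_end=1.1, velocity=0.5, n_replicates=12,
        temperature=1.0,
    )
    coarse = run_msmd(double_well, proto, seeds=range(12), equilibration_steps=2000, dt=2.5e-4)
    staged = staged_msmd(
        double_well, proto, n_stages=1, coarse_profiles=coarse, n_select=4,
        seeds=range(100, 112), equilibration_steps=2000, dt=2.5e-4,
        n_grid_per_stage=41,
    )
    direct = jarzynski_estimate(coarse, 1.0, n_bootstrap=20, seed=0)
    assert staged.estimator == "staged-jarzynski"
    assert staged.info["n_stages"] == 1
    assert staged.rc_grid[0] == -1.1 and staged.rc_grid[-1] == 1.1
    # same estimator at near-equilibrium speed: profiles agree closely
    assert np.abs(staged.G - direct.interp(staged.rc_grid)).max() < 0.5


def test_staged_validation(double_well):
    proto = SteeringProtocol(
        lambda_start=-1.0, lambda_end=1.0, velocity=1.0, n_replicates=2, temperature=1.0
    )
    coarse = run_msmd(double_well, proto, seeds=[0, 1], equilibration_steps=100, dt=5e-4)
    with pytest.raises(StagingError):
        staged_msmd(double_well, proto, 2, coarse, n_select=5, seeds=range(4),
                    equilibration_steps=10, dt=5e-4)
    with pytest.raises(ValueError):
        staged_msmd(double_well, proto, 2, coarse, n_select=2, seeds=range(3),
                    equilibration_steps=10, dt=5e-4)


def test_jarzynski_barrier_error_shrinks_with_slower_pulling(double_well):
    """Steering closer to equilibrium reduces the barrier-region error."""
    errors = []
    for v, s0 in [(4.0, 0), (0.4, 1000)]:
        proto = SteeringProtocol(
            lambda_start=-1.2, lambda_end=1.2, velocity=v, n_replicates=40,
            temperature=1.0,
        )
        profs = run_msmd(double_well, proto, seeds=range(s0, s0 + 40),
                         equilibration_steps=2000, dt=2.5e-4)
        est = jarzynski_estimate(profs, 1.0, n_bootstrap=20, seed=0)
        ana = analytic_rc_profile(double_well, est.rc_grid)
        errors.append(np.abs(est.G - ana).max())
    assert errors[1] < errors[0]
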