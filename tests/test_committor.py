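import numpy as np
import pytest

from ptse import (
    BasinDefinition,
    PotentialSpec,
    ShotRecord,
    committor_closed_form_1d,
    committor_curve,
    define_tse,
    equilibrate_restrained,
    run_langevin,
    select_configurations,
    shoot,
)
from ptse.committor import SelectedConfiguration, SelectionError
from ptse.potentials import potential_functions


def test_basin_definition_validation():
    with pytest.raises(ValueError):
        BasinDefinition(1.0, -1.0)
    with pytest.raises(ValueError):
        BasinDefinition(-1.0, 1.0, max_steps=0)


def test_closed_form_flat_is_linear():
    spec = PotentialSpec(family="flat", temperature=1.0)
    p = committor_closed_form_1d(spec, 1.0, -1.0, 1.0)
    xs = np.linspace(-1, 1, 9)
    assert np.allclose(p(xs), (xs + 1) / 2, atol=1e-8)


def test_closed_form_symmetric_well_half_at_saddle(double_well):
    p = committor_closed_form_1d(double_well, 1.0, -1.0, 1.0)
    assert p(0.0) == pytest.approx(0.5, abs=1e-8)
    assert p(-1.0) == pytest.approx(0.0, abs=1e-10)
    assert p(1.0) == pytest.approx(1.0, abs=1e-10)
    xs = np.linspace(-1, 1, 41)
    assert np.all(np.diff(p(xs)) >= -1e-12)


def test_closed_form_matches_riemann_sum(asymmetric_well):
    """Adaptive quadrature agrees with a dense Riemann-sum oracle."""
    p = committor_closed_form_1d(asymmetric_well, 1.0, -1.0, 1.0)
    energy, _ = potential_functions(asymmetric_well)
    ys = np.linspace(-1.0, 1.0, 400_001)
    w = np.exp(energy(ys[:, None]) - energy(ys[:, None]).max())
    cum = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2)])
    cum /= cum[-1]
    for xi in (-0.5, -0.1, 0.2, 0.7):
        oracle = np.interp(xi, ys, cum)
        assert p(xi) == pytest.approx(oracle, abs=1e-8)


def test_select_configurations_brute_force_filter(double_well):
    traj = run_langevin(double_well, [1.0], 50_000, 5e-3, 1.0, 1.0, seed=3,
                        record_stride=5)
    grid = [-1.0, 1.0]
    sel = select_configurations([traj], grid, per_point=15, window_delta=0.1, seed=4)
    assert len(sel) == 30
    for c in sel:
        assert abs(c.launch_rc - c.grid_rc) <= 0.1
        # configuration really is a stored trajectory point
        assert np.any(np.all(np.isclose(traj.coordinates, c.coordinates), axis=1))
    with pytest.raises(SelectionError):
        select_configurations([traj], [4.0], per_point=1, window_delta=0.05, seed=0)


def test_equilibrate_restrained_zero_temperature_flat():
    spec = PotentialSpec(family="flat", temperature=0.0)
    out = equilibrate_restrained(spec, [0.5], anchor_rc=0.1, time=1.0, seed=0)
    assert out[0] == pytest.approx(0.1, abs=1e-6)
    a = equilibrate_restrained(PotentialSpec(family="flat", temperature=1.0),
                               [0.5], 0.0, time=0.5, seed=5)
    b = equilibrate_restrained(PotentialSpec(family="flat", temperature=1.0),
                               [0.5], 0.0, time=0.5, seed=5)
    assert np.array_equal(a, b)


def test_shoot_rejects_launch_outside_basins(double_well):
    basin = BasinDefinition(-1.0, 1.0)
    with pytest.raises(ValueError):
        shoot(double_well, [1.1], basin, 2, 1.0, seeds=[0, 1])


def test_shoot_deep_in_reactant_well_always_relaxes_back():
    """From far down the reactant side of a 10 kT well, all 10 shots
    are absorbed into the reactant basin."""
    spec = PotentialSpec(family="double_well_1d", barrier_height=10.0, temperature=1.0)
    basin = BasinDefinition(-1.0, 1.0, max_steps=100_000)
    records = shoot(spec, [-0.9], basin, 10, 1.0, seeds=range(10), dt=5e-4)
    assert all(r.outcome == "reactant" for r in records)
    assert all(r.steps_to_absorption < 100_000 for r in records)


def test_committor_curve_arithmetic_and_undecided_handling():
    recs = [ShotRecord(0, 0.0, i, "product" if i < 5 else "reactant", 10, grid_rc=0.0)
            for i in range(10)]
    (est,) = committor_curve(recs)
    assert est.p_B == 0.5 and est.n_shots == 10 and est.n_product == 5
    assert est.ci_low < 0.5 < est.ci_high

    recs = [ShotRecord(0, 0.0, i, "reactant", 10, grid_rc=0.0) for i in range(10)]
    (est,) = committor_curve(recs)
    assert est.p_B == 0.0 and est.ci_high > 0.0

    recs += [ShotRecord(0, 0.0, 99, "undecided", 50, grid_rc=0.0)]
    (est,) = committor_curve(recs)
    assert est.n_shots == 10 and est.n_undecided == 1

    with pytest.warns(UserWarning):
        out = committor_curve([ShotRecord(0, 0.0, 1, "undecided", 5, grid_rc=0.0)])
    assert out == []


def test_wilson_interval_coverage():
    """Monte-Carlo coverage of the Wilson interval matches the exact
    enumeration oracle (≈95%, conservatively above nominal at small n)."""
    from scipy.stats import binom
    from statsmodels.stats.proportion import proportion_confint

    rng = np.random.default_rng(0)
    p_true, n = 0.3, 20
    reps = 10_000
    k = rng.binomial(n, p_true, reps)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    coverage = np.mean((lo <= p_true) & (p_true <= hi))
    # brute-force oracle: exact coverage by summing binomial pmf over the
    # outcomes whose interval contains p_true
    ks = np.arange(n + 1)
    lo_all, hi_all = proportion_confint(ks, n, alpha=0.05, method="wilson")
    exact = binom.pmf(ks[(lo_all <= p_true) & (p_true <= hi_all)], n, p_true).sum()
    assert exact == pytest.approx(0.95, abs=0.04)
    assert coverage == pytest.approx(exact, abs=3 * np.sqrt(exact * (1 - exact) / reps))


def _cfg(i, grid_rc, launch_rc=None):
    return SelectedConfiguration(i, grid_rc, np.array([grid_rc]),
                                 launch_rc if launch_rc is not None else grid_rc)


def _est(rc, p):
    n_prod = int(round(p * 10))
    lo, hi = max(0.0, p - 0.1), min(1.0, p + 0.1)
    from ptse import CommittorEstimate
    return CommittorEstimate(rc, 10, n_prod, p, lo, hi)


def test_define_tse_band_membership():
    ests = [_est(-0.1, 0.5), _est(0.0, 0.5), _est(0.1, 0.5)]
    cfgs = [_cfg(0, -0.1), _cfg(1, 0.0), _cfg(2, 0.1)]
    tse = define_tse(ests, cfgs, (0.4, 0.6))
    assert len(tse.members) == 3
    assert tse.rc_range == (-0.1, 0.1)
    assert tse.width == pytest.approx(0.2)

    ests = [_est(-0.1, 0.0), _est(0.1, 1.0)]
    with pytest.warns(UserWarning):
        tse = define_tse(ests, cfgs, (0.4, 0.6))
    assert tse.width == 0.0 and len(tse.members) == 0

    with pytest.raises(ValueError):
        define_tse(ests, cfgs, (0.6, 0.4))
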