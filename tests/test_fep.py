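import numpy as np
import pytest

from ptse import (
    FreeEnergyProfile,
    WorkProfile,
    barrier_summary,
    combine_bidirectional,
    cumulant_estimate,
    jarzynski_estimate,
)
from ptse.fep import CombinationError, SummaryError


def _profiles_from_works(works, grid=None, direction="forward"):
    works = np.asarray(works, dtype=float)
    if grid is None:
        grid = np.linspace(0.0, 1.0, works.shape[1])
    return [
        WorkProfile(
            replicate_id=i,
            lambda_grid=grid,
            xi_trace=grid,
            work=w,
            direction=direction,
            seed=i,
        )
        for i, w in enumerate(works)
    ]


def test_identical_work_profiles_give_back_the_work():
    w = np.array([0.0, 1.0, 3.0, 2.5])
    profs = _profiles_from_works([w, w, w])
    est = jarzynski_estimate(profs, temperature=1.0, n_bootstrap=10)
    assert np.allclose(est.G + est.raw_offset, w)
    cum = cumulant_estimate(profs, temperature=1.0)
    assert np.allclose(cum.G + cum.raw_offset, w)


def test_zero_work_gives_zero_profile():
    profs = _profiles_from_works(np.zeros((4, 5)))
    est = jarzynski_estimate(profs, temperature=1.0, n_bootstrap=10)
    assert np.allclose(est.G, 0.0)


def test_gaussian_work_closed_form():
    """For W ~ N(μ, σ²), the exponential average converges to μ − σ²/2kT
    (4.157 kcal/mol at μ=5, σ=1, kT=0.593)."""
    kT = 0.593
    rng = np.random.default_rng(1)
    n = 10_000
    works = np.zeros((n, 2))
    works[:, 1] = rng.normal(5.0, 1.0, n)
    profs = _profiles_from_works(works)
    expected = 5.0 - 1.0 / (2 * kT)  # = 4.1568...
    est = jarzynski_estimate(profs, temperature=kT, n_bootstrap=5)
    assert (est.G[1] + est.raw_offset) == pytest.approx(expected, abs=0.1)
    cum = cumulant_estimate(profs, temperature=kT)
    assert (cum.G[1] + cum.raw_offset) == pytest.approx(expected, abs=0.1)


def test_jensen_sandwich_on_random_work_sets():
    rng = np.random.default_rng(3)
    for _ in range(20):
        works = np.cumsum(rng.normal(0.3, 0.5, (8, 12)), axis=1)
        works[:, 0] = 0.0
        profs = _profiles_from_works(works)
        est = jarzynski_estimate(profs, temperature=1.0, n_bootstrap=5)
        raw = est.G + est.raw_offset
        assert np.all(works.min(axis=0) <= raw + 1e-9)
        assert np.all(raw <= works.mean(axis=0) + 1e-9)


def test_estimator_ordering_for_right_skewed_work():
    """Exponential averaging gives a higher barrier estimate than the
    cumulant on right-skewed (Gaussian-mixture) work distributions."""
    rng = np.random.default_rng(4)
    n = 60
    tail = rng.random(n) < 0.2
    w_end = np.where(tail, rng.normal(9.0, 1.0, n), rng.normal(5.0, 0.6, n))
    works = np.zeros((n, 2))
    works[:, 1] = w_end
    profs = _profiles_from_works(works)
    jz = jarzynski_estimate(profs, temperature=1.0, n_bootstrap=5)
    cu = cumulant_estimate(profs, temperature=1.0)
    assert (jz.G[1] + jz.raw_offset) >= (cu.G[1] + cu.raw_offset)


def test_single_profile_warns_with_infinite_stderr():
    profs = _profiles_from_works(np.array([[0.0, 2.0]]))
    with pytest.warns(UserWarning):
        est = jarzynski_estimate(profs, temperature=1.0)
    assert np.all(np.isinf(est.stderr))


def test_work_profile_invariants():
    with pytest.raises(ValueError):
        WorkProfile(0, [0.0, 1.0], [0.0, 1.0], [1.0, 2.0])  # W(0) != 0
    with pytest.raises(ValueError):
        WorkProfile(0, [0.0, 1.0], [0.0, 1.0], [0.0, np.nan])
    with pytest.raises(ValueError):
        WorkProfile(0, [1.0, 0.0], [0.0, 1.0], [0.0, 1.0], direction="forward")


def _fep(grid, G, **kw):
    kw.setdefault("stderr", np.zeros_like(np.asarray(G, dtype=float)))
    return FreeEnergyProfile(rc_grid=np.asarray(grid, float), G=np.asarray(G, float), **kw)


def test_combine_identical_inputs_is_identity():
    grid = np.linspace(-1, 1, 41)
    G = (grid**2 - 1) ** 2 * 5
    f = _fep(grid, G)
    b = _fep(grid[::-1], G[::-1])
    comb = combine_bidirectional(f, b)
    assert comb.info["junction_gap"] == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(comb.G, f.G)


def test_combine_consistent_noiseless_inputs_reproduce_analytic():
    grid = np.linspace(-1.2, 1.2, 97)
    G = 5 * (grid**2 - 1) ** 2 + grid  # asymmetric analytic profile
    f = _fep(grid, G + 0.7)  # arbitrary offsets
    b = _fep(grid[::-1], G[::-1] - 1.3)
    comb = combine_bidirectional(f, b)
    assert np.abs((comb.G - comb.G.min()) - (G - G.min())).max() < 1e-9


def test_combine_requires_overlap():
    f = _fep([0.0, 1.0], [0.0, 1.0])
    b = _fep([3.0, 2.0], [0.0, 1.0])
    with pytest.raises(CombinationError):
        combine_bidirectional(f, b)


def test_combine_junction_tolerance_enforced():
    grid = np.linspace(-1, 1, 21)
    f = _fep(grid, np.zeros_like(grid))
    b = _fep(grid[::-1], np.abs(grid[::-1]))  # incompatible shapes
    with pytest.raises(CombinationError):
        combine_bidirectional(f, b, junction_tolerance=1e-6)


def test_barrier_summary_reference_values():
    """A profile with minima at 0 and −6 and barrier 13 yields
    ΔG = −6, Δ_fG‡ = 13, Δ_bG‡ = 19 (and the exact identity)."""
    grid = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
    prof = _fep(grid, [0.0, 5.0, 13.0, 5.0, -6.0])
    bs = barrier_summary(prof)
    assert bs.delta_G == pytest.approx(-6.0)
    assert bs.delta_fG == pytest.approx(13.0)
    assert bs.delta_bG == pytest.approx(19.0)
    assert bs.delta_bG - bs.delta_fG + bs.delta_G == pytest.approx(0.0, abs=1e-12)
    assert bs.reactant_position < bs.ts_position < bs.product_position


def test_barrier_summary_symmetric_well():
    grid = np.linspace(-1.2, 1.2, 121)
    prof = _fep(grid, 5 * (grid**2 - 1) ** 2)
    bs = barrier_summary(prof)
    assert bs.delta_G == pytest.approx(0.0, abs=1e-9)
    assert bs.delta_fG == pytest.approx(bs.delta_bG)
    assert bs.delta_fG == pytest.approx(5.0, abs=1e-3)


def test_barrier_summary_rejects_monotone_and_multiwell():
    grid = np.linspace(0, 1, 20)
    with pytest.raises(SummaryError):
        barrier_summary(_fep(grid, grid**2))  # harmonic, no barrier
    bumpy = np.sin(grid * 12) + grid
    with pytest.raises(SummaryError):
        barrier_summary(_fep(grid, bumpy))
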