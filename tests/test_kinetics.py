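import numpy as np
import pytest

from ptse import RateMeasurement, eyring_fit, eyring_rate, initial_rate


def test_initial_rate_exact_linear_curve():
    t = np.linspace(0, 10, 8)
    k, se, diag = initial_rate(t, 0.3 * t + 2.0, enzyme_conc=0.05)
    assert k == pytest.approx(6.0, abs=1e-12)
    assert se == pytest.approx(0.0, abs=1e-9)
    assert diag["window_points"] == 8 and not diag["trimmed"]


def test_initial_rate_zero_slope():
    t = np.linspace(0, 5, 6)
    k, _, _ = initial_rate(t, np.full_like(t, 1.2), enzyme_conc=1.0)
    assert k == pytest.approx(0.0, abs=1e-12)


def test_initial_rate_se_matches_regression_oracle():
    """Propagated SE equals the closed-form simple-regression slope SE."""
    rng = np.random.default_rng(0)
    t = np.linspace(0, 10, 12)
    y = 0.5 * t + rng.normal(0, 0.1, len(t))
    e = 0.2
    k, se, _ = initial_rate(t, y, enzyme_conc=e)
    # brute-force formulas
    b = np.sum((t - t.mean()) * (y - y.mean())) / np.sum((t - t.mean()) ** 2)
    resid = y - (y.mean() + b * (t - t.mean()))
    s2 = np.sum(resid**2) / (len(t) - 2)
    se_b = np.sqrt(s2 / np.sum((t - t.mean()) ** 2))
    assert k == pytest.approx(b / e, abs=1e-12)
    assert se == pytest.approx(se_b / e, rel=1e-9)


def test_initial_rate_trims_saturating_curve():
    t = np.linspace(0, 20, 15)
    sat = 5 * (1 - np.exp(-t / 3))
    with pytest.warns(UserWarning):
        k, _, diag = initial_rate(t, sat, enzyme_conc=1.0)
    m = diag["window_points"]
    assert diag["trimmed"] and m < 15
    # the fitted slope lies between the window's secant slope and the
    # true initial slope of the exponential (5/3)
    secant = sat[m - 1] / t[m - 1]
    assert secant * 0.99 <= k <= 5 / 3 * 1.01


def test_eyring_round_trip_reference_parameters():
    """Noiseless rates from ΔH‡ = 15.3 kcal/mol, ΔS‡ = −5.7 cal/mol/K
    over 293–333 K are recovered exactly."""
    T = np.linspace(293, 333, 9)
    k = eyring_rate(15.3, -5.7, T)
    ms = [RateMeasurement(t, kk, condition="Ca2+") for t, kk in zip(T, k)]
    fit = eyring_fit(ms)
    assert fit.delta_H == pytest.approx(15.3, abs=1e-9)
    assert fit.delta_S == pytest.approx(-5.7, abs=1e-9)
    assert fit.diagnostics["r_squared"] == pytest.approx(1.0, abs=1e-12)
    back = eyring_rate(fit.delta_H, fit.delta_S, T)
    assert np.allclose(back, k, rtol=1e-9)
    assert fit.delta_G(298.15) == pytest.approx(15.3 + 298.15 * 5.7e-3)


def test_eyring_two_points_flagged_exact():
    ms = [RateMeasurement(300.0, 10.0), RateMeasurement(320.0, 50.0)]
    fit = eyring_fit(ms)
    assert fit.diagnostics["exact_fit"]
    assert np.isnan(fit.delta_H_se) and np.isnan(fit.delta_S_se)
    assert np.allclose(eyring_rate(fit.delta_H, fit.delta_S, [300.0, 320.0]),
                       [10.0, 50.0], rtol=1e-9)


def test_eyring_prefactor_identity():
    assert eyring_rate(0.0, 0.0, 298.15) == pytest.approx(6.21e12, rel=1e-3)


def test_eyring_rate_monotone_in_temperature():
    T = np.linspace(280, 360, 50)
    k = eyring_rate(12.0, -4.0, T)
    assert np.all(np.diff(k) > 0)
    with pytest.raises(ValueError):
        eyring_rate(10.0, 0.0, -5.0)


def test_eyring_monte_carlo_recovery_unbiased():
    """5% multiplicative rate noise, 9 temperatures, 1000 replications:
    mean recovered parameters within 2 SE of the truth."""
    rng = np.random.default_rng(42)
    T = np.linspace(293, 333, 9)
    k0 = eyring_rate(15.3, -5.7, T)
    reps = 1000
    noisy = k0[None, :] * np.exp(rng.normal(0, 0.05, (reps, len(T))))
    x = 1.0 / T
    Y = np.log(noisy / T).T  # (n_T, reps)
    slope, intercept = np.polyfit(x, Y, 1)
    R = 1.98720425864083e-3
    dH = -slope * R
    dS = R * (intercept - np.log(1.380649e-23 / 6.62607015e-34)) * 1000
    # OLS on log-rates is linear in the (log-space Gaussian) noise, so
    # the estimator is exactly unbiased; the z-test below uses a 3 SE
    # band so that its own false-failure rate is negligible
    for est, truth in ((dH, 15.3), (dS, -5.7)):
        se = est.std(ddof=1) / np.sqrt(reps)
        assert abs(est.mean() - truth) < 3 * se

    # and the package fit agrees with the vectorized oracle on one draw
    ms = [RateMeasurement(t, kk) for t, kk in zip(T, noisy[0])]
    fit = eyring_fit(ms)
    assert fit.delta_H == pytest.approx(dH[0], abs=1e-9)
    assert fit.delta_S == pytest.approx(dS[0], abs=1e-9)


def test_weighted_fit_with_equal_ses_matches_unweighted():
    T = np.linspace(293, 333, 7)
    rng = np.random.default_rng(5)
    k = eyring_rate(14.0, -8.0, T) * np.exp(rng.normal(0, 0.03, len(T)))
    ms = [RateMeasurement(t, kk, se=0.05 * kk) for t, kk in zip(T, k)]
    fu = eyring_fit(ms, weighted=False)
    fw = eyring_fit(ms, weighted=True)
    assert fw.delta_H == pytest.approx(fu.delta_H, abs=1e-9)
    assert fw.delta_S == pytest.approx(fu.delta_S, abs=1e-9)


def test_measurement_validation():
    with pytest.raises(ValueError):
        RateMeasurement(0.0, 1.0)
    with pytest.raises(ValueError):
        RateMeasurement(300.0, -1.0)
    with pytest.raises(ValueError):
        eyring_fit([RateMeasurement(300.0, 1.0)])
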