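"""Autocorrelation estimators, ergodicity check and xi(z) profiling."""

import numpy as np
import pytest

from dods.correlation import (
    PhotonTrace,
    acf_subset_deviation,
    autocovariance_fft,
    compute_acf,
    intensity_acf,
    minimal_recording_time,
    xi_profile,
)
from dods.simulate import _ou_trace, preset, simulate_membrane_trace, simulate_photon_trace


def acf_direct(x, max_k):
    """O(N^2) oracle: unbiased autocovariance with global mean removed."""
    d = np.asarray(x, float) - np.mean(x)
    return np.array(
        [np.sum(d[: len(d) - k] * d[k:]) / (len(d) - k) for k in range(max_k + 1)]
    )


def test_fft_autocovariance_matches_bruteforce(rng):
    x = rng.poisson(5.0, size=512).astype(float)
    expected = acf_direct(x, 60)
    np.testing.assert_allclose(autocovariance_fft(x, 60), expected, rtol=1e-10)


def test_multitau_base_octave_matches_bruteforce(rng):
    x = rng.poisson(8.0, size=4096).astype(float)
    trace = PhotonTrace(x.astype(int), 1e-5)
    mt = compute_acf(trace, scheme="multitau", max_lag=200e-5)
    oracle = acf_direct(x, 32) / x.mean() ** 2
    # the first 2*m lags are computed at base resolution: identical sums
    base = mt.lags <= 32 * 1e-5 + 1e-12
    lag_bins = np.round(mt.lags[base] / 1e-5).astype(int)
    np.testing.assert_allclose(mt.xi[base], oracle[lag_bins], rtol=1e-10)


def test_multitau_matches_fft_on_smooth_signal(rng):
    # slowly relaxing OU sampled far above its rate: rebinned lags agree
    # with the linear estimator to within the smoothing error
    n = 200_000
    x = 50.0 + _ou_trace(n, 4.0, 1.0 / (400 * 1e-4), 1e-4, rng)
    lin = intensity_acf(x, 1e-4, scheme="linear", max_lag=0.1)
    mt = intensity_acf(x, 1e-4, scheme="multitau", max_lag=0.1)
    shared = np.isin(np.round(mt.lags / 1e-4), np.round(lin.lags / 1e-4))
    idx = np.round(mt.lags[shared] / 1e-4).astype(int) - 1
    np.testing.assert_allclose(mt.xi[shared], lin.xi[idx],
                               atol=0.02 * lin.xi[0], rtol=0.02)


def test_constant_trace_zero_xi():
    trace = PhotonTrace(np.full(1000, 7), 1e-5)
    curve = compute_acf(trace, scheme="linear", max_lag=50e-5)
    np.testing.assert_allclose(curve.xi, 0.0, atol=1e-15)
    assert curve.amplitude == pytest.approx(0.0, abs=1e-15)


def test_pure_poisson_xi_consistent_with_zero(rng):
    """Shot noise is delta-correlated: xi at lag >= 1 bin is zero within
    statistical error (~1/(lambda sqrt(N)) per lag)."""
    lam, n = 5.0, 100_000
    trace = PhotonTrace(rng.poisson(lam, size=n), 1e-5)
    curve = compute_acf(trace, scheme="linear", max_lag=20e-5)
    se = 1.0 / (lam * np.sqrt(n))
    assert np.all(np.abs(curve.xi) < 4 * se)


def test_ou_intensity_acf_matches_theory(rng):
    """OU intensity with variance v, mean mu, time theta:
    xi(tau) = (v/mu^2) exp(-tau/theta)."""
    dt, theta, v, mu = 1e-4, 2e-2, 9.0, 60.0
    n = 400_000
    x = mu + _ou_trace(n, v, 1.0 / theta, dt, rng)
    curve = intensity_acf(x, dt, scheme="linear", max_lag=0.1)
    expected = (v / mu**2) * np.exp(-curve.lags / theta)
    # statistical tolerance: finite number of correlation times
    assert np.max(np.abs(curve.xi - expected)) < 0.10 * v / mu**2
    assert curve.amplitude == pytest.approx(v / mu**2, rel=0.1)


def test_xi_gain_invariance(rng):
    counts = rng.poisson(6.0, size=20_000)
    c1 = intensity_acf(counts.astype(float), 1e-5, max_lag=30e-5)
    c2 = intensity_acf(counts * 73.5, 1e-5, max_lag=30e-5)
    np.testing.assert_allclose(c1.xi, c2.xi, rtol=1e-10)


def test_rebin_conserves_counts_and_xi(rng):
    cfg = preset("deflated_guv", seed=5, duration=10.0, dt_sim=1e-5)
    truth = simulate_membrane_trace(cfg)
    trace = simulate_photon_trace(truth, cfg.beam, cfg.resolve_h0(), rng=rng)
    coarse = trace.rebin(10)
    assert coarse.counts.sum() == trace.counts.sum()
    assert coarse.bin_width == pytest.approx(1e-4)
    c_fine = compute_acf(trace, scheme="linear", max_lag=0.05)
    c_coarse = compute_acf(coarse, scheme="linear", max_lag=0.05)
    # same xi(tau) for tau >= the coarse bin: no systematic bias beyond
    # the per-lag shot noise, which averages out over the lag grid
    fine_at_coarse = np.interp(c_coarse.lags, c_fine.lags, c_fine.xi)
    assert abs(np.mean(c_coarse.xi - fine_at_coarse)) < 0.05 * c_coarse.xi[0]


def test_all_zero_trace_raises():
    with pytest.raises(ValueError):
        compute_acf(PhotonTrace(np.zeros(100, dtype=int), 1e-5))


def test_short_trace_flagged():
    trace = PhotonTrace(np.random.default_rng(0).poisson(5, 1000), 1e-3)
    curve = compute_acf(trace, max_lag=0.05)
    assert any("minimal recording time" in w for w in curve.warnings)


def test_subset_deviation_identity_and_errors(rng):
    trace = PhotonTrace(rng.poisson(5, 10_000), 1e-3)
    table = acf_subset_deviation(trace, [trace.duration], max_lag=0.05)
    assert table["deviation"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        acf_subset_deviation(trace, [6.0])  # only 1 disjoint window, not full


def test_ergodic_deviation_decreases_with_length(rng):
    """Subset-vs-full ACF deviation decreases with subset length and falls
    below the 0.10 ergodicity threshold by ~25 s for GUV-like dynamics."""
    dt, theta, v, mu_kcps = 1e-3, 0.06, 30.0, 55.0
    n = 130_000  # 130 s
    rate = np.clip(mu_kcps + _ou_trace(n, v, 1.0 / theta, dt, rng), 0.1, None)
    counts = rng.poisson(rate * 1e3 * dt)
    trace = PhotonTrace(counts, dt)
    table = acf_subset_deviation(trace, [1, 2, 5, 10, 25], max_lag=0.1)
    dev = table["deviation"].to_numpy()
    assert dev[0] > dev[-1]
    assert dev[-1] < 0.10
    assert minimal_recording_time(table) <= 25.0


def test_xi_profile_double_peak_and_static_floor(rng):
    cfg = preset("deflated_guv", seed=9, duration=15.0, dt_sim=1e-4, bin_width=1e-4)
    truth = simulate_membrane_trace(cfg)
    beam = cfg.beam
    from dods.profile import inflection_point

    z_lo = inflection_point(beam, "lower").z_ip
    z_hi = inflection_point(beam, "upper").z_ip
    zs = [z_lo, beam.z_c, z_hi]
    traces = [
        simulate_photon_trace(truth, beam, z, rng=rng, dark_kcps=cfg.dark_kcps)
        for z in zs
    ]
    z_out, amps = xi_profile(traces, zs, scheme="linear", max_lag=0.05)
    assert amps[0] > amps[1] and amps[2] > amps[1]  # double peak at the IPs
    assert amps[0] == pytest.approx(amps[2], rel=0.5)  # symmetric flanks
    # static membrane: flat at the noise floor
    static = [
        PhotonTrace(rng.poisson(55.0 * 1e3 * 1e-4, 150_000), 1e-4) for _ in zs
    ]
    _, amps0 = xi_profile(static, zs, scheme="linear", max_lag=0.05)
    assert np.all(np.abs(amps0) < 0.0024)
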