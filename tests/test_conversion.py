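"""Intensity-to-displacement conversion, dACF relation and error budget."""

import numpy as np
import pytest

from dods.conversion import (
    background_error,
    dacf_from_acf,
    dacf_from_trace,
    intensity_to_displacement,
    invert_profile,
    linearization_error_rms,
    noise_floor_displacement,
    taylor_coefficients,
)
from dods.correlation import intensity_acf
from dods.profile import BeamProfile, evaluate_profile, inflection_point
from dods.simulate import _ou_trace


def exact_inverse_lower_flank(intensity, profile, h0):
    """Closed-form inversion of the Gaussian on the lower flank (oracle)."""
    u = -np.sqrt(
        0.5 * profile.z0**2 * np.log(profile.amplitude / (intensity - profile.i_bg))
    )
    return (u - (h0 - profile.z_c)) * 1e3  # nm


def test_linear_conversion_examples(bead_beam):
    m = inflection_point(bead_beam).m
    zero = intensity_to_displacement(np.zeros(10), m, 1e-5)
    np.testing.assert_array_equal(zero.dh_nm, 0.0)
    # dI = m * 0.05 um corresponds to dh = 50 nm
    tr = intensity_to_displacement(np.full(5, m * 0.05), m, 1e-5)
    np.testing.assert_allclose(tr.dh_nm, 50.0, rtol=1e-12)
    with pytest.raises(ValueError):
        intensity_to_displacement(np.zeros(5), 0.0, 1e-5)


def test_taylor_coefficients_at_ip(bead_beam):
    ip = inflection_point(bead_beam)
    c = taylor_coefficients(bead_beam, ip.z_ip, 3)
    assert c[0] == pytest.approx(ip.i_ip)
    assert c[1] == pytest.approx(ip.m, rel=1e-12)
    assert c[2] == pytest.approx(0.0, abs=1e-9)  # IP: quadratic term vanishes
    # cubic coefficient: -(4/3) m / z0^2 (drives the linearization bias)
    assert c[3] == pytest.approx(-(4.0 / 3.0) * ip.m / bead_beam.z0**2, rel=1e-9)


def test_order1_and_order2_match_linear_at_ip(bead_beam, rng):
    ip = inflection_point(bead_beam)
    dh_true_nm = rng.normal(0, 30.0, size=2000)
    intensity = evaluate_profile(bead_beam, ip.z_ip + dh_true_nm / 1e3)
    t1 = invert_profile(intensity, bead_beam, ip.z_ip, order=1)
    lin = intensity_to_displacement(intensity - ip.i_ip, ip.m, 1e-5)
    np.testing.assert_allclose(t1.dh_nm, lin.dh_nm, rtol=1e-12)
    t2 = invert_profile(intensity, bead_beam, ip.z_ip, order=2)
    np.testing.assert_allclose(t2.dh_nm, t1.dh_nm, rtol=1e-9, atol=1e-9)


def test_linear_inversion_cubic_bias(bead_beam):
    """A 90-nm true displacement inverted linearly is biased by
    ~ (4/3) dh^3/z0^2 ~ 0.6 nm; order 3 removes it (root-finding oracle)."""
    ip = inflection_point(bead_beam)
    dh_true = 90.0  # nm
    intensity = evaluate_profile(bead_beam, np.array([ip.z_ip + dh_true / 1e3]))
    t1 = invert_profile(intensity, bead_beam, ip.z_ip, order=1)
    bias = dh_true - t1.dh_nm[0]
    z0_nm = bead_beam.z0 * 1e3
    assert bias == pytest.approx((4.0 / 3.0) * dh_true**3 / z0_nm**2, rel=0.05)
    assert bias == pytest.approx(0.59, abs=0.05)
    t3 = invert_profile(intensity, bead_beam, ip.z_ip, order=3)
    oracle = exact_inverse_lower_flank(intensity, bead_beam, ip.z_ip)
    assert t3.dh_nm[0] == pytest.approx(oracle[0], abs=0.02)
    assert abs(t3.dh_nm[0] - dh_true) < 0.05


def test_order3_roundtrip_against_root_finding_oracle(bead_beam, rng):
    ip = inflection_point(bead_beam)
    dh_true_nm = rng.uniform(-150, 150, size=500)
    intensity = evaluate_profile(bead_beam, ip.z_ip + dh_true_nm / 1e3)
    t3 = invert_profile(intensity, bead_beam, ip.z_ip, order=3)
    oracle = exact_inverse_lower_flank(intensity, bead_beam, ip.z_ip)
    # residual truncation error is O(dh^4 / z0^3): ~0.25 nm at 150 nm
    z0_nm = bead_beam.z0 * 1e3
    bound = 3.0 * np.abs(dh_true_nm) ** 4 / z0_nm**3 + 0.01
    assert np.all(np.abs(t3.dh_nm - oracle) < bound)
    assert t3.clipped is None


def test_non_invertible_samples_clipped_not_dropped(bead_beam):
    ip = inflection_point(bead_beam)
    # an intensity above the peak of the cubic branch cannot be inverted
    intensity = np.array([ip.i_ip, bead_beam.i_max * 1.5, ip.i_ip - 1.0])
    t3 = invert_profile(intensity, bead_beam, ip.z_ip, order=3)
    assert t3.clipped is not None
    assert t3.clipped.tolist() == [False, True, False]
    assert t3.dh_nm.size == 3  # retained with a mask
    assert t3.clipped_fraction == pytest.approx(1 / 3)


def test_invalid_operating_point(bead_beam):
    with pytest.raises(ValueError):
        invert_profile(np.ones(3), bead_beam, bead_beam.z_c + 2 * bead_beam.z0)


def test_route_equivalence_acf_vs_trace(bead_beam, rng):
    """Building the dACF from the converted dh(t) trace equals converting
    the intensity ACF: C(tau) = xi(tau) <I>^2 / m^2 (algebraic identity up
    to the mean used in the normalization)."""
    ip = inflection_point(bead_beam)
    dt = 1e-4
    dh_true = _ou_trace(50_000, 40.0**2, 1 / 0.05, dt, rng)  # nm
    intensity = evaluate_profile(bead_beam, ip.z_ip + dh_true / 1e3)
    curve = intensity_acf(intensity, dt, scheme="linear", max_lag=0.05, unit="kcps")
    via_acf = dacf_from_acf(curve, mean_intensity=float(intensity.mean()), m=ip.m)
    dh_est = intensity_to_displacement(intensity - intensity.mean(), ip.m, dt)
    via_trace = dacf_from_trace(dh_est, max_lag=0.05)
    np.testing.assert_allclose(via_acf.c_nm2, via_trace.c_nm2, rtol=1e-9)


def test_dacf_scaling_and_null(bead_beam):
    ip = inflection_point(bead_beam)
    from dods.correlation import CorrelationCurve

    lags = np.linspace(1e-4, 1e-2, 50)
    curve = CorrelationCurve(lags, np.zeros(50), 0.0, 50.0, 1e-4)
    assert np.all(dacf_from_acf(curve, m=ip.m).c_nm2 == 0.0)
    curve2 = CorrelationCurve(lags, np.full(50, 0.0024), 0.0024, 50.0, 1e-4)
    c = dacf_from_acf(curve2, mean_intensity=50.0, m=130.0)
    assert np.sqrt(c.c_nm2[0]) == pytest.approx(18.84, abs=0.01)
    with pytest.raises(ValueError):
        dacf_from_acf(curve2, m=0.0)


def test_noise_floor_examples_and_scaling():
    assert noise_floor_displacement(0.0024, 50.0, 130.0) == pytest.approx(
        18.84, abs=0.01
    )
    assert noise_floor_displacement(0.0, 50.0, 130.0) == 0.0
    # degrades linearly with brighter uncorrelated signal at fixed slope
    assert noise_floor_displacement(0.0024, 90.0, 130.0) == pytest.approx(
        33.92, abs=0.01
    )
    lo = noise_floor_displacement(0.0024, 25.0, 130.0)
    hi = noise_floor_displacement(0.0024, 50.0, 65.0)
    assert hi == pytest.approx(4 * lo, rel=1e-12)


def test_background_error_examples():
    profile = BeamProfile(z_c=0.0, z0=1.285, i_max=50.0)
    assert background_error(profile, 0.0) == 0.0
    # APD dark counts: ~10.6 nm, below the 20-nm resolution
    assert background_error(profile, 0.5) == pytest.approx(10.59, abs=0.01)
    # phenol-red medium: ~42 nm, above it
    assert background_error(profile, 2.0) == pytest.approx(42.37, abs=0.01)
    with pytest.raises(ValueError):
        background_error(profile, -1.0)


def test_linearization_error_closed_form_matches_simulation(bead_beam, rng):
    ip = inflection_point(bead_beam)
    s = 90.0
    dh_true = rng.normal(0, s, size=400_000)
    intensity = evaluate_profile(bead_beam, ip.z_ip + dh_true / 1e3)
    r1 = invert_profile(intensity, bead_beam, ip.z_ip, order=1).rms_nm
    r3 = invert_profile(intensity, bead_beam, ip.z_ip, order=3).rms_nm
    assert abs(r1 - r3) == pytest.approx(
        linearization_error_rms(s, bead_beam.z0), rel=0.2
    )
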