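"""Conversion of intensity flickers into membrane displacements.

At the inflection point (IP) of the axial Gaussian the second derivative of
I(z) vanishes, so to leading order intensity fluctuations are proportional
to membrane displacements,

    dh(t) = dI(t) / m,

with ``m`` the signed slope of the profile at the IP.  The displacement
autocorrelation function (dACF) follows directly from the normalized
intensity ACF,

    C(tau) = <dh(tau) dh(0)> = xi(tau) * <I>^2 / m^2.

For large excursions the Taylor expansion of the Gaussian around the
operating point is inverted to second or third order instead, and the
module also provides the resolution/error budget: the noise-floor
displacement sqrt(xi_det) <I>/|m|, the background error dI_Bg/|m|, and the
linearization error from comparing inversion orders.

Units: dI and m in kcps and kcps/um; displacements returned in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

from .correlation import CorrelationCurve, autocovariance_fft
from .profile import BeamProfile, evaluate_profile, inflection_point

__all__ = [
    "DisplacementTrace",
    "DisplacementACF",
    "ErrorBudget",
    "intensity_to_displacement",
    "taylor_coefficients",
    "invert_profile",
    "dacf_from_acf",
    "dacf_from_trace",
    "noise_floor_displacement",
    "background_error",
    "linearization_error_rms",
    "resolution_budget",
]

UM_TO_NM = 1e3


@dataclass
class DisplacementTrace:
    """Membrane displacement trace dh(t) in nm on a uniform time grid."""

    dh_nm: np.ndarray
    bin_width: float  # s
    h0_um: float = np.nan  # mean membrane position (operating point)
    source: str = "linear"  # conversion order / provenance
    clipped: np.ndarray | None = None  # mask of non-invertible samples

    def __post_init__(self) -> None:
        self.dh_nm = np.asarray(self.dh_nm, dtype=float)
        if self.dh_nm.ndim != 1:
            raise ValueError("dh_nm must be 1-D")

    @property
    def duration(self) -> float:
        return self.dh_nm.size * self.bin_width

    @property
    def rms_nm(self) -> float:
        """Fluctuation amplitude: rms of the mean-subtracted trace."""
        return float(np.std(self.dh_nm))

    @property
    def clipped_fraction(self) -> float:
        if self.clipped is None:
            return 0.0
        return float(np.mean(self.clipped))

    def to_csv(self, path) -> None:
        t = np.arange(self.dh_nm.size) * self.bin_width
        pd.DataFrame({"time_s": t, "dh_nm": self.dh_nm}).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "DisplacementTrace":
        from .profile import _read_csv_checked

        df = _read_csv_checked(path, ["time_s", "dh_nm"])
        t = df["time_s"].to_numpy(dtype=float)
        return cls(df["dh_nm"].to_numpy(), bin_width=float(t[1] - t[0]))


@dataclass
class DisplacementACF:
    """Displacement autocorrelation C(tau) = <dh(tau) dh(0)> in nm^2."""

    lags: np.ndarray  # s
    c_nm2: np.ndarray
    amplitude_nm: float  # sqrt of the plateau C estimate
    source: str = ""

    def to_csv(self, path) -> None:
        pd.DataFrame({"lag_s": self.lags, "c_nm2": self.c_nm2}).to_csv(
            path, index=False, float_format="%.17g"
        )

    @classmethod
    def from_csv(cls, path) -> "DisplacementACF":
        from .profile import _read_csv_checked

        df = _read_csv_checked(path, ["lag_s", "c_nm2"])
        c = df["c_nm2"].to_numpy(dtype=float)
        amp = float(np.sqrt(max(np.mean(c[: min(10, len(c))]), 0.0)))
        return cls(df["lag_s"].to_numpy(dtype=float), c, amp)


@dataclass
class ErrorBudget:
    """Axial resolution budget of a displacement measurement (all in nm)."""

    noise_floor_nm: float
    background_nm: float
    linearization_nm: float
    assumptions: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def intensity_to_displacement(
    di_kcps: np.ndarray, m: float, bin_width: float, h0_um: float = np.nan
) -> DisplacementTrace:
    """Linear conversion dh = dI/m at the inflection point.

    ``di_kcps`` must be the mean-subtracted intensity fluctuation; ``m`` is
    the signed IP slope in kcps/um.
    """
    if m == 0:
        raise ValueError("degenerate geometry: slope m = 0")
    dh_nm = np.asarray(di_kcps, dtype=float) / m * UM_TO_NM
    return DisplacementTrace(dh_nm, bin_width, h0_um=h0_um, source="order-1")


def taylor_coefficients(profile: BeamProfile, h0_um: float, order: int) -> np.ndarray:
    """Coefficients c_n = I^(n)(h0)/n! of the Gaussian profile, n = 0..order.

    Derivatives are generated from the exact recursion for the polynomial
    prefactor of the Gaussian (p_{n+1} = p_n' - (4u/z0^2) p_n), so any
    order is available without finite differencing.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    z0 = profile.z0
    u0 = h0_um - profile.z_c
    g = np.exp(-2.0 * (u0 / z0) ** 2)
    p = Polynomial([1.0])
    d = Polynomial([0.0, -4.0 / z0**2])
    coeffs = []
    fact = 1.0
    for n in range(order + 1):
        if n > 0:
            fact *= n
        coeffs.append(profile.amplitude * p(u0) * g / fact)
        p = p.deriv() + p * d
    coeffs[0] += profile.i_bg
    return np.asarray(coeffs)


def invert_profile(
    intensity_kcps: np.ndarray,
    profile: BeamProfile,
    h0_um: float,
    order: int = 3,
    bin_width: float = 1e-5,
    max_iter: int = 50,
    tol: float = 1e-12,
) -> DisplacementTrace:
    """Invert the order-``order`` Taylor expansion of I(z) around h0.

    At the inflection point the quadratic Taylor term vanishes, so order 2
    reduces to the linear conversion there.  Samples whose intensity lies
    outside the invertible branch of the truncated polynomial are clamped
    to the branch boundary and flagged in the ``clipped`` mask rather than
    dropped.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    lo, hi = profile.z_c - profile.z0, profile.z_c + profile.z0
    if not (lo < h0_um < hi):
        raise ValueError(
            f"operating point h0={h0_um:.4g} um outside ({lo:.4g}, {hi:.4g}) um"
        )
    c = taylor_coefficients(profile, h0_um, order)
    if c[1] == 0:
        raise ValueError("degenerate geometry: profile slope vanishes at h0")
    di = np.asarray(intensity_kcps, dtype=float) - c[0]
    x = di / c[1]  # linear start
    clipped = np.zeros(di.shape, dtype=bool)
    if order == 1:
        dh_um = x
    else:
        poly = Polynomial(np.concatenate(([0.0], c[1:])))
        dpoly = poly.deriv()
        # invertible branch: the monotone segment of the truncated
        # polynomial through the origin, bounded by its stationary points
        roots = dpoly.roots()
        roots = roots[np.abs(roots.imag) < 1e-12].real if roots.size else roots.real
        lo_b = float(roots[roots < 0].max()) if np.any(roots < 0) else -np.inf
        hi_b = float(roots[roots > 0].min()) if np.any(roots > 0) else np.inf
        ends = sorted(
            (
                poly(lo_b) if np.isfinite(lo_b) else (-np.inf if c[1] > 0 else np.inf),
                poly(hi_b) if np.isfinite(hi_b) else (np.inf if c[1] > 0 else -np.inf),
            )
        )
        di_lo, di_hi = float(ends[0]), float(ends[1])
        clipped = (di <= di_lo) | (di >= di_hi)
        eps = 1e-12 * abs(c[1])
        di_work = np.clip(di, di_lo + eps if np.isfinite(di_lo) else di_lo,
                          di_hi - eps if np.isfinite(di_hi) else di_hi)
        x = np.clip(di_work / c[1], lo_b, hi_b)
        for _ in range(max_iter):
            f = poly(x) - di_work
            step = f / dpoly(x)
            x = np.clip(x - step, lo_b, hi_b)
            if np.max(np.abs(step)) < tol:
                break
        dh_um = x
    return DisplacementTrace(
        dh_um * UM_TO_NM,
        bin_width,
        h0_um=h0_um,
        source=f"order-{order}",
        clipped=clipped if np.any(clipped) else None,
    )


def dacf_from_acf(
    curve: CorrelationCurve, mean_intensity: float | None = None, m: float = None
) -> DisplacementACF:
    """Displacement ACF from the normalized intensity ACF:
    C(tau) = xi(tau) <I>^2 / m^2 (nm^2).

    ``mean_intensity`` defaults to the mean recorded on the curve (kcps);
    ``m`` is the signed IP slope (kcps/um).
    """
    if m is None or m == 0:
        raise ValueError("degenerate geometry: slope m = 0 or missing")
    i_mean = curve.mean_intensity if mean_intensity is None else mean_intensity
    if not np.isfinite(i_mean) or i_mean <= 0:
        raise ValueError("mean intensity must be positive and finite")
    scale_nm2 = (i_mean / m * UM_TO_NM) ** 2
    c = curve.xi * scale_nm2
    amp = float(np.sqrt(max(curve.amplitude, 0.0) * scale_nm2))
    return DisplacementACF(
        lags=np.asarray(curve.lags, dtype=float),
        c_nm2=c,
        amplitude_nm=amp,
        source="acf",
    )


def dacf_from_trace(trace: DisplacementTrace, max_lag: float | None = None) -> DisplacementACF:
    """Displacement ACF built directly from a converted dh(t) trace."""
    n = trace.dh_nm.size
    if max_lag is None:
        max_lag = trace.duration / 10.0
    max_k = max(1, min(n - 1, int(round(max_lag / trace.bin_width))))
    acov = autocovariance_fft(trace.dh_nm, max_k)
    lags = np.arange(1, max_k + 1) * trace.bin_width
    amp = float(np.sqrt(max(acov[0], 0.0)))
    return DisplacementACF(lags=lags, c_nm2=acov[1:], amplitude_nm=amp, source="trace")


def noise_floor_displacement(
    xi_det: float, mean_intensity: float, m: float
) -> float:
    """Smallest resolvable displacement (nm) implied by the noise-floor
    correlation amplitude: sqrt(xi_det) <I> / |m|."""
    if xi_det < 0:
        raise ValueError("xi_det must be >= 0")
    if mean_intensity <= 0 or m == 0:
        raise ValueError("mean intensity must be > 0 and slope nonzero")
    return float(np.sqrt(xi_det) * mean_intensity / abs(m) * UM_TO_NM)


def background_error(profile: BeamProfile, di_bg: float) -> float:
    """Spatial error (nm) from a background increase dI_Bg, evaluated with
    the IP slope m = 2 exp(-1/2) (I_max - I_Bg)/z0 of the profile."""
    if di_bg < 0:
        raise ValueError("background increase must be >= 0")
    m = inflection_point(profile).m
    return float(di_bg / abs(m) * UM_TO_NM)


def linearization_error_rms(rms_nm: float, z0_um: float) -> float:
    """Closed-form bias of the linear inversion on the rms amplitude.

    The linear estimate of a true displacement dh carries a cubic bias
    -(4/3) dh^3/z0^2, so for a Gaussian trace of rms s the linearly
    inverted rms is reduced by about 4 s^3 / z0^2 (nm, to leading order).
    """
    z0_nm = z0_um * UM_TO_NM
    return float(4.0 * rms_nm**3 / z0_nm**2)


def resolution_budget(
    profile: BeamProfile,
    xi_det: float = 0.0024,
    mean_intensity: float | None = None,
    di_bg: float = 0.5,
    rms_nm: float = 90.0,
) -> ErrorBudget:
    """Full axial error budget at the inflection point of ``profile``.

    ``mean_intensity`` defaults to the IP intensity of the profile;
    ``di_bg`` defaults to typical avalanche-photodiode dark counts
    (0.5 kcps); ``rms_nm`` is the fluctuation amplitude used for the
    linearization term.
    """
    ip = inflection_point(profile)
    i_mean = ip.i_ip if mean_intensity is None else mean_intensity
    return ErrorBudget(
        noise_floor_nm=noise_floor_displacement(xi_det, i_mean, ip.m),
        background_nm=background_error(profile, di_bg),
        linearization_nm=linearization_error_rms(rms_nm, profile.z0),
        assumptions={
            "xi_det": xi_det,
            "mean_intensity_kcps": i_mean,
            "slope_kcps_per_um": ip.m,
            "di_bg_kcps": di_bg,
            "rms_nm": rms_nm,
            "z0_um": profile.z0,
        },
    )
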