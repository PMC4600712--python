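"""Intensity autocorrelation analysis of photon-count traces.

The normalized intensity autocorrelation function (ACF)

    xi(tau) = <dI(t) dI(t+tau)> / <I>^2,     dI = I - <I>,

is the primary observable: a membrane flickering at the inflection point of
the confocal profile imprints its displacement autocorrelation on xi(tau).
The zero-lag point is excluded because photon shot noise is
delta-correlated and contaminates only tau = 0.

Two estimators are provided: a linear FFT correlator and a multi-tau
correlator (16 linear lags per octave, counts rebinned x2 per octave), the
standard layout of hardware FCS correlators.  An ergodicity/stationarity
check compares the full-trace ACF against averages over disjoint subsets;
25 s is the default minimal recording time below which curves carry a
warning flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len, rfft, irfft

__all__ = [
    "PhotonTrace",
    "CorrelationCurve",
    "T_MIN_S",
    "compute_acf",
    "intensity_acf",
    "autocovariance_fft",
    "acf_subset_deviation",
    "minimal_recording_time",
    "xi_profile",
]

#: minimal recording time (s) ensuring ergodic build-up of the ACF
T_MIN_S = 25.0

#: lag window (in bins) over which the plateau amplitude xi is averaged
AMPLITUDE_LAG_BINS = (1, 10)


@dataclass
class PhotonTrace:
    """Binned photon counts versus time."""

    counts: np.ndarray  # non-negative integers per bin
    bin_width: float = 1e-5  # s

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        self.counts = counts.astype(np.int64)
        if not (self.bin_width > 0):
            raise ValueError("bin_width must be positive")

    @property
    def duration(self) -> float:
        return self.counts.size * self.bin_width

    @property
    def mean_intensity(self) -> float:
        """Mean detected intensity in kcps."""
        return float(self.counts.mean()) / self.bin_width / 1e3

    def rebin(self, factor: int) -> "PhotonTrace":
        """Sum consecutive bins; conserves total counts (trailing remainder
        bins are dropped)."""
        if factor < 1 or int(factor) != factor:
            raise ValueError("rebin factor must be a positive integer")
        n = (self.counts.size // factor) * factor
        c = self.counts[:n].reshape(-1, factor).sum(axis=1)
        return PhotonTrace(c, self.bin_width * factor)

    def to_csv(self, path) -> None:
        t = np.arange(self.counts.size) * self.bin_width
        pd.DataFrame({"time_s": t, "counts": self.counts}).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "PhotonTrace":
        from .profile import _read_csv_checked

        df = _read_csv_checked(path, ["time_s", "counts"])
        t = df["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError(f"{path}: trace needs at least 2 bins")
        return cls(df["counts"].to_numpy(), bin_width=float(t[1] - t[0]))


@dataclass
class CorrelationCurve:
    """Normalized intensity ACF xi(tau) with its plateau amplitude."""

    lags: np.ndarray  # s, strictly increasing, >= bin_width
    xi: np.ndarray
    amplitude: float  # plateau estimate (mean xi over the first lag decade)
    mean_intensity: float  # kcps used for normalization
    bin_width: float
    warnings: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        pd.DataFrame({"lag_s": self.lags, "xi": self.xi}).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, mean_intensity: float = np.nan) -> "CorrelationCurve":
        from .profile import _read_csv_checked

        df = _read_csv_checked(path, ["lag_s", "xi"])
        lags = df["lag_s"].to_numpy(dtype=float)
        xi = df["xi"].to_numpy(dtype=float)
        amp = float(np.mean(xi[: max(1, min(10, len(xi)))]))
        return cls(lags, xi, amp, mean_intensity, bin_width=float(lags[0]))


def autocovariance_fft(x: np.ndarray, max_k: int) -> np.ndarray:
    """Unbiased sample autocovariance of ``x`` at integer lags 0..max_k.

    Mean is subtracted once over the full series (stationary estimator);
    each lag is normalized by its number of pairs.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_k >= n:
        raise ValueError("max lag must be smaller than the series length")
    d = x - x.mean()
    nfft = next_fast_len(2 * n)
    f = rfft(d, nfft)
    acov = irfft(f * np.conj(f), nfft)[: max_k + 1]
    return acov / (n - np.arange(max_k + 1))


def _amplitude(lag_bins: np.ndarray, xi: np.ndarray) -> float:
    lo, hi = AMPLITUDE_LAG_BINS
    sel = (lag_bins >= lo) & (lag_bins <= hi)
    if not np.any(sel):
        sel = slice(0, 1)
    return float(np.mean(xi[sel]))


def intensity_acf(
    intensity: np.ndarray,
    bin_width: float,
    scheme: str = "linear",
    max_lag: float | None = None,
    m_lags: int = 16,
    unit: str = "counts",
) -> CorrelationCurve:
    """Normalized ACF of an arbitrary (float) intensity series.

    Shared backend of :func:`compute_acf`; also used for noiseless
    synthetic intensities where integer photon counts are not meaningful.
    ``intensity`` may be in any linear unit — xi is gain invariant.
    ``unit`` ("counts" per bin or "kcps") only affects the recorded
    ``mean_intensity``.
    """
    x = np.asarray(intensity, dtype=float)
    mean = x.mean()
    if mean == 0:
        raise ValueError("zero-mean trace: ACF normalization undefined")
    n = x.size
    duration = n * bin_width
    if max_lag is None:
        max_lag = duration / 10.0
    max_k = max(1, min(n - 1, int(round(max_lag / bin_width))))

    if scheme in ("linear", "fft", "linear-FFT"):
        acov = autocovariance_fft(x, max_k)
        lag_bins = np.arange(1, max_k + 1)
        xi = acov[1:] / mean**2
    elif scheme in ("multitau", "multi-tau"):
        lag_bins, xi = _multitau(x, max_k, m_lags)
    else:
        raise ValueError(f"unknown ACF scheme {scheme!r}")

    warnings = []
    if duration < T_MIN_S:
        warnings.append(
            f"trace duration {duration:.3g} s is below the minimal recording "
            f"time t_min = {T_MIN_S:.0f} s; the ACF may not be fully built up"
        )
    return CorrelationCurve(
        lags=lag_bins * bin_width,
        xi=xi,
        amplitude=_amplitude(lag_bins, xi),
        mean_intensity=mean / bin_width / 1e3 if unit == "counts" else float(mean),
        bin_width=bin_width,
        warnings=warnings,
    )


def _multitau(x: np.ndarray, max_k: int, m: int):
    """Multi-tau correlator: 2m linear lags at base resolution, then m lags
    per octave on data rebinned x2.  Returns (lag in base bins, xi)."""
    lag_bins: list[float] = []
    xi: list[float] = []
    level = 0
    data = x.astype(float)
    while True:
        scale = 2**level
        mean_l = data.mean()
        d = data - mean_l
        ks = range(1, 2 * m + 1) if level == 0 else range(m + 1, 2 * m + 1)
        done = False
        for k in ks:
            if k * scale > max_k or k >= data.size:
                done = True
                break
            est = float(np.dot(d[: d.size - k], d[k:]) / (d.size - k))
            lag_bins.append(k * scale)
            xi.append(est / mean_l**2)
        if done:
            break
        n2 = (data.size // 2) * 2
        if n2 < 4 * m:
            break
        data = data[:n2].reshape(-1, 2).sum(axis=1)
        level += 1
    return np.asarray(lag_bins, dtype=float), np.asarray(xi)


def compute_acf(
    trace: PhotonTrace,
    scheme: str = "multitau",
    max_lag: float | None = None,
    m_lags: int = 16,
) -> CorrelationCurve:
    """Normalized intensity ACF xi(tau) of a photon-count trace.

    The shot-noise-dominated zero lag is excluded; the plateau amplitude is
    the mean of xi over lags of 1-10 bins.  An all-zero trace raises
    ``ValueError``; traces shorter than ``T_MIN_S`` return a curve with a
    warning flag.
    """
    if trace.counts.sum() == 0:
        raise ValueError("all-zero photon trace: ACF normalization undefined")
    curve = intensity_acf(
        trace.counts, trace.bin_width, scheme=scheme, max_lag=max_lag, m_lags=m_lags
    )
    curve.mean_intensity = trace.mean_intensity
    return curve


def acf_subset_deviation(
    trace: PhotonTrace,
    subset_lengths,
    max_lag: float | None = None,
    scheme: str = "linear",
    n_subsets: int = 5,
) -> pd.DataFrame:
    """Ergodicity/stationarity check: ACF over disjoint subsets vs full trace.

    For each length L, the ACF is computed on ``n_subsets`` disjoint
    subsets, averaged, and compared with the full-trace ACF via the
    relative L2 deviation.  For an ergodic stationary trace the deviation
    decreases with L.  ``L == duration`` is the degenerate single-window
    identity (deviation 0); otherwise fewer than ``n_subsets`` disjoint
    windows is an input error.
    """
    subset_lengths = np.asarray(list(subset_lengths), dtype=float)
    duration = trace.duration
    if np.any(subset_lengths > duration):
        raise ValueError("subset length exceeds trace duration")
    if max_lag is None:
        max_lag = float(subset_lengths.min()) / 10.0
    full = compute_acf(trace, scheme=scheme, max_lag=max_lag)
    norm = float(np.linalg.norm(full.xi))
    rows = []
    for L in subset_lengths:
        n_bins = int(round(L / trace.bin_width))
        n_avail = trace.counts.size // n_bins
        if n_avail >= n_subsets:
            windows = n_subsets
        elif n_avail == 1 and n_bins == trace.counts.size:
            windows = 1  # full trace: identity case
        else:
            raise ValueError(
                f"subset length {L:.3g} s allows only {n_avail} disjoint "
                f"windows (need {n_subsets})"
            )
        xis = []
        for i in range(windows):
            seg = PhotonTrace(
                trace.counts[i * n_bins : (i + 1) * n_bins], trace.bin_width
            )
            xis.append(compute_acf(seg, scheme=scheme, max_lag=max_lag).xi)
        mean_xi = np.mean(xis, axis=0)
        k = min(len(mean_xi), len(full.xi))
        dev = float(np.linalg.norm(mean_xi[:k] - full.xi[:k])) / norm
        rows.append({"length_s": float(L), "deviation": dev})
    return pd.DataFrame(rows)


def minimal_recording_time(
    deviation_table: pd.DataFrame, threshold: float = 0.10
) -> float:
    """Smallest subset length whose relative ACF deviation is below the
    ergodicity threshold (default 0.10); NaN if never reached."""
    ok = deviation_table[deviation_table["deviation"] < threshold]
    return float(ok["length_s"].min()) if len(ok) else float("nan")


def xi_profile(traces, z_positions, **acf_kwargs):
    """Correlation amplitude xi versus axial position.

    For a fluctuating membrane xi(z) exhibits two maxima at the inflection
    points z_c +/- z0/2 of the intensity profile; for a static membrane it
    stays flat at the noise floor.
    """
    z_positions = np.asarray(list(z_positions), dtype=float)
    traces = list(traces)
    if len(traces) != z_positions.size:
        raise ValueError("need one trace per axial position")
    if len(traces) < 3:
        raise ValueError("xi profile needs at least 3 axial positions")
    amps = np.array(
        [compute_acf(tr, **acf_kwargs).amplitude for tr in traces], dtype=float
    )
    return z_positions, amps
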