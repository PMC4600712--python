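"""Distributional analysis of displacement traces.

For a linear membrane in thermal equilibrium the displacement histogram
N(dh) is Gaussian; active processes show up as deviations.  This module
provides the normalized histogram with a least-squares Gaussian fit and
its residual Delta N(dh), the standardized third and fourth central
moments (skewness S and excess kurtosis K, both zero for a Gaussian), and
the Mann-Whitney U-test used to compare conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import mannwhitneyu

from .conversion import DisplacementTrace

__all__ = [
    "FlucStats",
    "skewness_kurtosis",
    "histogram_and_gaussfit",
    "average_histograms",
    "mann_whitney_u",
    "significance_stars",
    "MOMENT_CONVENTION",
]

#: recorded in every output so downstream comparisons know the definition
MOMENT_CONVENTION = (
    "S = m3/m2^(3/2), K = m4/m2^2 - 3 (biased central sample moments; "
    "excess kurtosis, Gaussian = 0, lower bound -2)"
)


@dataclass
class FlucStats:
    """Histogram, Gaussian fit and moment statistics of a displacement sample."""

    bin_edges: np.ndarray  # nm
    density: np.ndarray  # normalized histogram (integrates to 1)
    gauss_fit: tuple  # (mean, sd, scale)
    delta_n: np.ndarray  # density - Gaussian fit
    skewness: float
    kurtosis: float  # excess
    n: int
    convention: str = MOMENT_CONVENTION

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_csv(self, path) -> None:
        mu, sd, scale = self.gauss_fit
        fit = scale * np.exp(-((self.centers - mu) ** 2) / (2 * sd**2))
        pd.DataFrame(
            {
                "dh_nm": self.centers,
                "N": self.density,
                "gauss_fit": fit,
                "deltaN": self.delta_n,
            }
        ).to_csv(path, index=False, float_format="%.17g")

    def to_json(self, path) -> None:
        out = asdict(self)
        out["bin_edges"] = self.bin_edges.tolist()
        out["density"] = self.density.tolist()
        out["delta_n"] = self.delta_n.tolist()
        out["gauss_fit"] = list(self.gauss_fit)
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2)


def skewness_kurtosis(sample) -> tuple[float, float]:
    """Skewness S = m3/m2^(3/2) and excess kurtosis K = m4/m2^2 - 3.

    Central sample moments without small-sample bias correction; requires
    n >= 4 and nonzero variance.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples for skewness/kurtosis")
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 == 0:
        raise ValueError("zero-variance sample")
    s = float(np.mean(d**3) / m2**1.5)
    k = float(np.mean(d**4) / m2**2 - 3.0)
    return s, k


def _gaussian(x, mu, sd, scale):
    return scale * np.exp(-((x - mu) ** 2) / (2.0 * sd**2))


def histogram_and_gaussfit(
    trace: DisplacementTrace | np.ndarray,
    bins="fd",
    bin_edges: np.ndarray | None = None,
) -> FlucStats:
    """Normalized displacement histogram with a least-squares Gaussian fit.

    ``bins`` follows numpy's histogram bin rules (default
    Freedman-Diaconis); passing explicit ``bin_edges`` overrides it so
    that several objects can be averaged on a common grid.  Requires at
    least 100 samples and nonzero variance.
    """
    dh = trace.dh_nm if isinstance(trace, DisplacementTrace) else np.asarray(trace, float)
    if dh.size < 100:
        raise ValueError("histogram analysis needs at least 100 samples")
    if np.std(dh) == 0:
        raise ValueError("zero-variance (constant) trace")
    edges = bin_edges if bin_edges is not None else np.histogram_bin_edges(dh, bins=bins)
    density, edges = np.histogram(dh, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu0, sd0 = float(dh.mean()), float(dh.std())
    try:
        import warnings as _warnings
        from scipy.optimize import OptimizeWarning

        with _warnings.catch_warnings():
            # the fit covariance is unused; near-perfect fits make it singular
            _warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _gaussian,
                centers,
                density,
                p0=[mu0, sd0, 1.0 / (sd0 * np.sqrt(2 * np.pi))],
                maxfev=10000,
            )
        mu, sd, scale = float(popt[0]), float(abs(popt[1])), float(popt[2])
    except RuntimeError:
        mu, sd, scale = mu0, sd0, 1.0 / (sd0 * np.sqrt(2 * np.pi))
    delta_n = density - _gaussian(centers, mu, sd, scale)
    s, k = skewness_kurtosis(dh)
    return FlucStats(
        bin_edges=edges,
        density=density,
        gauss_fit=(mu, sd, scale),
        delta_n=delta_n,
        skewness=s,
        kurtosis=k,
        n=int(dh.size),
    )


def average_histograms(samples, bin_edges: np.ndarray) -> dict:
    """Average <N(dh)> and <Delta N(dh)> over several objects on a common
    bin grid, plus per-object S and K."""
    stats = [histogram_and_gaussfit(s, bin_edges=bin_edges) for s in samples]
    return {
        "bin_edges": np.asarray(bin_edges, float),
        "mean_density": np.mean([st.density for st in stats], axis=0),
        "mean_delta_n": np.mean([st.delta_n for st in stats], axis=0),
        "skewness": np.array([st.skewness for st in stats]),
        "kurtosis": np.array([st.kurtosis for st in stats]),
    }


def significance_stars(p: float) -> str:
    """Conventional significance stars: *** <0.001, ** <0.01, * <0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mann_whitney_u(sample_a, sample_b, alternative: str = "two-sided"):
    """Mann-Whitney U rank-sum test with the field's star convention.

    Exact null enumeration for small, tie-free samples (both n <= 20);
    tie-corrected normal approximation otherwise.  Returns
    ``(U, p, stars)`` where U is the statistic of ``sample_a``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative=alternative, method=method)
    p = float(min(res.pvalue, 1.0))
    return float(res.statistic), p, significance_stars(p)
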