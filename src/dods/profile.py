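"""Axial intensity profile of the confocal volume.

The detected intensity of a fluorescently labelled membrane scanned through
the focus follows a Gaussian along the optical axis,

    I(z) = I_Bg + (I_max - I_Bg) * exp(-2 (z - z_c)^2 / z0^2),

where ``z0`` and ``omega0`` are the axial and radial 1/e^2 radii of the
confocal volume.  Displacement spectroscopy operates at the inflection
point (IP) of this profile, z_c +/- z0/2, where the slope ``m = dI/dz`` is
maximal and the second derivative vanishes, so intensity flickers map
linearly onto membrane displacements.

Units: axial positions in micrometres (um), intensities in kilo counts per
second (kcps), slopes in kcps/um.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BeamProfile",
    "InflectionPoint",
    "AxialScan",
    "ProfileFit",
    "CalibrationError",
    "evaluate_profile",
    "inflection_point",
    "fit_axial_scan",
]

#: I_IP / I_max for a background-free profile: exp(-1/2)
IP_INTENSITY_FRACTION = float(np.exp(-0.5))


class CalibrationError(RuntimeError):
    """Axial-scan calibration failed (non-convergent or implausible fit)."""


@dataclass
class BeamProfile:
    """Gaussian axial intensity model of the confocal volume.

    Parameters
    ----------
    z_c : float
        Axial centre position (um).
    z0 : float
        Axial 1/e^2 radius (um).
    omega0 : float
        Radial 1/e^2 radius (um).  Stored for geometry bookkeeping; the
        axial analysis does not use it.
    i_max : float
        Peak detected intensity (kcps).
    i_bg : float
        Background intensity far from the membrane (kcps).
    c0 : float
        Fluorophore concentration scale.  A dimensionless multiplier that
        is absorbed into ``i_max``; kept so configurations can record it.
    """

    z_c: float
    z0: float
    omega0: float = 0.280
    i_max: float = 100.0
    i_bg: float = 0.0
    c0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.z0 > 0):
            raise ValueError(f"z0 must be positive, got {self.z0}")
        if not (self.omega0 > 0):
            raise ValueError(f"omega0 must be positive, got {self.omega0}")
        if not (self.i_bg >= 0):
            raise ValueError(f"i_bg must be non-negative, got {self.i_bg}")
        if not (self.i_max > self.i_bg):
            raise ValueError(
                f"i_max ({self.i_max}) must exceed i_bg ({self.i_bg})"
            )

    @property
    def amplitude(self) -> float:
        """Signal amplitude I_max - I_Bg (kcps)."""
        return self.i_max - self.i_bg

    def __call__(self, z):
        return evaluate_profile(self, z)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "BeamProfile":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class InflectionPoint:
    """Location, intensity and signed slope of a profile flank's IP."""

    z_ip: float  # um
    i_ip: float  # kcps
    m: float  # signed slope dI/dz (kcps/um)
    side: str  # "lower" or "upper"


@dataclass
class AxialScan:
    """Sampled (z, intensity) pairs from a fast scan across the membrane."""

    z: np.ndarray  # um, strictly monotone
    intensity: np.ndarray  # kcps, >= 0
    dwell_s: float = 1e-3

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.z.shape != self.intensity.shape or self.z.ndim != 1:
            raise ValueError("z and intensity must be 1-D arrays of equal length")
        dz = np.diff(self.z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if not (self.dwell_s > 0):
            raise ValueError("dwell time must be positive")

    def to_csv(self, path) -> None:
        pd.DataFrame({"z_um": self.z, "intensity_kcps": self.intensity}).to_csv(
            path, index=False, float_format="%.17g"
        )


    @classmethod
    def from_csv(cls, path, dwell_s: float = 1e-3) -> "AxialScan":
        df = _read_csv_checked(path, ["z_um", "intensity_kcps"])
        return cls(df["z_um"].to_numpy(), df["intensity_kcps"].to_numpy(), dwell_s)


@dataclass
class ProfileFit:
    """Result of a least-squares Gaussian fit to an axial scan."""

    profile: BeamProfile
    stderr: dict = field(default_factory=dict)  # per-parameter standard errors
    residual_norm: float = np.nan


def _read_csv_checked(path, required_cols):
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"could not parse CSV {path}: {exc}") from exc
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in required_cols:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: one for the header row, one for 0-based indexing
            raise ValueError(
                f"{path}: non-numeric value in column '{col}' at line {bad[0] + 2}"
            )
    return df


def evaluate_profile(profile: BeamProfile, z):
    """Axial intensity I(z) in kcps; total function of z (um)."""
    z = np.asarray(z, dtype=float)
    u = (z - profile.z_c) / profile.z0
    out = profile.i_bg + profile.amplitude * np.exp(-2.0 * u * u)
    return float(out) if out.ndim == 0 else out


def inflection_point(profile: BeamProfile, side: str = "lower") -> InflectionPoint:
    """Inflection point of the axial Gaussian on the chosen flank.

    The IP sits at z_c -/+ z0/2 with intensity
    I_Bg + exp(-1/2) (I_max - I_Bg); for a background-free profile
    I_IP = 0.61 I_max.  The signed slope is m = +/- 2 exp(-1/2) A / z0:
    positive on the lower flank (intensity rises towards the centre),
    negative on the upper flank.
    """
    if side not in ("lower", "upper"):
        raise ValueError(f"side must be 'lower' or 'upper', got {side!r}")
    sgn = -1.0 if side == "lower" else 1.0
    z_ip = profile.z_c + sgn * profile.z0 / 2.0
    i_ip = profile.i_bg + IP_INTENSITY_FRACTION * profile.amplitude
    m = -sgn * 2.0 * IP_INTENSITY_FRACTION * profile.amplitude / profile.z0
    return InflectionPoint(z_ip=z_ip, i_ip=i_ip, m=m, side=side)


def _gauss(z, z_c, z0, i_max, i_bg):
    return i_bg + (i_max - i_bg) * np.exp(-2.0 * ((z - z_c) / z0) ** 2)


def fit_axial_scan(
    scan: AxialScan, initial_guess: BeamProfile | None = None
) -> ProfileFit:
    """Least-squares Gaussian fit of an axial scan.

    Uses unweighted least squares (equal dwell per sample).  Raises
    ``ValueError`` for scans with fewer than 5 distinct z positions and
    ``CalibrationError`` when the optimiser fails or the fitted width/centre
    fall outside the scanned range.
    """
    z, intensity = scan.z, scan.intensity
    if len(np.unique(z)) < 5:
        raise ValueError("axial scan needs at least 5 distinct z positions")
    span = float(z.max() - z.min())
    if initial_guess is not None:
        p0 = [
            initial_guess.z_c,
            initial_guess.z0,
            initial_guess.i_max,
            initial_guess.i_bg,
        ]
    else:
        i_bg0 = float(intensity.min())
        i_max0 = float(intensity.max())
        z_c0 = float(z[np.argmax(intensity)])
        # 1/e^2-radius guess from the second moment of the excess intensity
        w = np.clip(intensity - i_bg0, 0, None)
        if w.sum() > 0:
            var = float(np.sum(w * (z - z_c0) ** 2) / w.sum())
            z00 = max(2.0 * np.sqrt(var), span / 20.0)
        else:
            z00 = span / 4.0
        p0 = [z_c0, z00, i_max0, max(i_bg0, 1e-9)]
    bounds = (
        [z.min() - span, 1e-6, 0.0, 0.0],
        [z.max() + span, 10.0 * span, np.inf, np.inf],
    )
    try:
        popt, pcov = curve_fit(_gauss, z, intensity, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise CalibrationError(f"Gaussian fit did not converge: {exc}") from exc
    z_c, z0, i_max, i_bg = popt
    if not (z.min() <= z_c <= z.max()):
        raise CalibrationError(f"fitted centre z_c={z_c:.3g} um outside scan range")
    if z0 > span:
        raise CalibrationError(
            f"fitted z0={z0:.3g} um exceeds scan span {span:.3g} um"
        )
    if i_max <= i_bg:
        raise CalibrationError("fitted i_max does not exceed background")
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    resid = intensity - _gauss(z, *popt)
    profile = BeamProfile(z_c=z_c, z0=z0, i_max=i_max, i_bg=i_bg)
    stderr = dict(zip(("z_c", "z0", "i_max", "i_bg"), perr))
    return ProfileFit(profile=profile, stderr=stderr,
                      residual_norm=float(np.linalg.norm(resid)))
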