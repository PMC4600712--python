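"""Seeded forward simulator of membrane flicker experiments.

Ground-truth displacement traces are built as a superposition of
independent Ornstein-Uhlenbeck (OU) modes: wavevectors are sampled on a
log grid between the Helfrich cutoffs, each node carries the trapezoid
quadrature weight of the continuum mode integral as stationary variance
and relaxes at its hydrodynamic rate omega_q.  The OU updates use the
exact discrete-time transition (phi = exp(-omega dt), innovation variance
w (1 - phi^2)), so there is no time-step stability constraint: modes much
faster than the sampling interval correctly degenerate to white noise of
the right variance.

Photon detection sends the displaced membrane through the confocal
Gaussian: per-bin counts are Poisson with rate I(h0 + dh(t)) plus a dark
rate, the shot-noise-limited detection of an avalanche photodiode.
Axial scans are Poisson-sampled intensities of the profile on a z grid.

Presets encode the experimental conditions of the validation study:
giant unilamellar vesicles (GUVs) in hypotonic ("tense") or hypertonic
("deflated") buffer, plus equilibrium surrogates for red blood cells and
macrophages that only match the measured amplitude/timescale — no active
(ATP- or cytokine-driven) dynamics are modelled.  A deliberately
non-physical Poisson "kick" process is available as a positive control
for the non-Gaussianity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
import copy

import numpy as np
from scipy.signal import lfilter

from .conversion import DisplacementTrace
from .correlation import PhotonTrace
from .helfrich import HelfrichModel, _quadrature
from .profile import AxialScan, BeamProfile, evaluate_profile, inflection_point

__all__ = [
    "SimConfig",
    "simulate_membrane_trace",
    "simulate_photon_trace",
    "simulate_axial_scan",
    "simulate_experiment",
    "preset",
    "PRESET_NAMES",
]


@dataclass
class SimConfig:
    """Complete, seeded description of one simulated experiment."""

    seed: int = 0
    dt_sim: float = 1e-5  # s, displacement sampling interval
    duration: float = 60.0  # s
    n_modes: int = 64
    membrane: HelfrichModel = field(default_factory=HelfrichModel)
    beam: BeamProfile = field(
        default_factory=lambda: BeamProfile(z_c=0.0, z0=1.285, omega0=0.280, i_max=90.0)
    )
    h0: float | str = "IP"  # operating point (um) or "IP" for the lower flank IP
    dark_kcps: float = 0.5  # avalanche-photodiode dark counts
    bin_width: float = 1e-5  # s, photon binning
    kick: dict | None = None  # non-physical non-Gaussian control, see kick_trace
    name: str = ""

    def __post_init__(self) -> None:
        if self.dt_sim <= 0 or self.duration <= 0:
            raise ValueError("dt_sim and duration must be positive")
        if self.bin_width < self.dt_sim:
            raise ValueError("bin_width must be >= dt_sim")
        if self.n_modes < 2:
            raise ValueError("need at least 2 modes")

    def resolve_h0(self) -> float:
        if self.h0 == "IP":
            return inflection_point(self.beam, side="lower").z_ip
        return float(self.h0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["membrane"] = self.membrane.to_dict()
        d["beam"] = asdict(self.beam)
        return d


def _rngs(config: SimConfig):
    """Independent child streams (membrane, photons, scan) from one seed."""
    ss = np.random.SeedSequence(config.seed)
    return [np.random.default_rng(s) for s in ss.spawn(3)]


def _ou_trace(n: int, variance: float, rate: float, dt: float, rng) -> np.ndarray:
    """Stationary OU sample path via the exact discrete transition."""
    phi = np.exp(-rate * dt)
    e = rng.standard_normal(n) * np.sqrt(variance * (1.0 - phi * phi))
    e[0] = rng.standard_normal() * np.sqrt(variance)
    return lfilter([1.0], [1.0, -phi], e)


def kick_trace(n: int, dt: float, rng, rate_hz: float = 5.0,
               amplitude_nm: float = 40.0, tau_s: float = 0.05) -> np.ndarray:
    """Poisson shot process (nm): one-sided kicks relaxing exponentially.

    Non-physical positive control producing a skewed, heavy-tailed
    displacement distribution for the statistics module; not a model of
    ATP- or cytokine-driven membrane activity.
    """
    kicks = rng.poisson(rate_hz * dt, size=n).astype(float) * amplitude_nm
    phi = np.exp(-dt / tau_s)
    x = lfilter([1.0], [1.0, -phi], kicks)
    return x - x.mean()


def simulate_membrane_trace(config: SimConfig, rng=None) -> DisplacementTrace:
    """Ground-truth displacement trace dh(t) (nm) of the membrane point.

    Superposes ``n_modes`` OU processes whose stationary variances are the
    trapezoid weights of the Helfrich mode integral and whose rates are
    the hydrodynamic omega_q, sampled every ``dt_sim``.
    """
    if rng is None:
        rng = _rngs(config)[0]
    n = int(round(config.duration / config.dt_sim))
    q, weights, rates = _quadrature(config.membrane, config.n_modes)
    dh_m = np.zeros(n)
    for w, om in zip(weights, rates):
        dh_m += _ou_trace(n, w, om, config.dt_sim, rng)
    dh_nm = dh_m * 1e9
    if config.kick:
        dh_nm = dh_nm + kick_trace(n, config.dt_sim, rng, **config.kick)
    return DisplacementTrace(
        dh_nm, config.dt_sim, h0_um=config.resolve_h0(), source="simulated"
    )


def simulate_photon_trace(
    dh: DisplacementTrace,
    beam: BeamProfile,
    h0_um: float,
    bin_width: float | None = None,
    rng=None,
    seed: int | None = None,
    dark_kcps: float = 0.5,
) -> PhotonTrace:
    """Photon counts of the displaced membrane seen through the beam.

    Rate = I(h0 + dh(t)) + dark (kcps); per-bin counts are Poisson.  When
    ``bin_width`` exceeds the displacement sampling interval the rate is
    averaged within each bin (integrating detector).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if bin_width is None:
        bin_width = dh.bin_width
    rate_kcps = evaluate_profile(beam, h0_um + dh.dh_nm / 1e3) + dark_kcps
    factor = int(round(bin_width / dh.bin_width))
    if factor > 1:
        m = (rate_kcps.size // factor) * factor
        rate_kcps = rate_kcps[:m].reshape(-1, factor).mean(axis=1)
    counts = rng.poisson(rate_kcps * 1e3 * bin_width)
    return PhotonTrace(counts, bin_width)


def simulate_axial_scan(
    beam: BeamProfile,
    z_um: np.ndarray | None = None,
    dwell_s: float = 5e-3,
    rng=None,
    seed: int | None = None,
) -> AxialScan:
    """Poisson-sampled fast scan of the beam profile across the membrane."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if z_um is None:
        z_um = beam.z_c + np.linspace(-2.0, 2.0, 41) * beam.z0
    z_um = np.asarray(z_um, dtype=float)
    rate = evaluate_profile(beam, z_um)
    counts = rng.poisson(rate * 1e3 * dwell_s)
    return AxialScan(z_um, counts / (1e3 * dwell_s), dwell_s)


def simulate_experiment(config: SimConfig):
    """Run one full experiment: axial scan, ground-truth displacement and
    photon trace, with per-component random streams split from the seed.

    Returns ``(scan, truth, photons)``.
    """
    rng_mem, rng_phot, rng_scan = _rngs(config)
    truth = simulate_membrane_trace(config, rng=rng_mem)
    photons = simulate_photon_trace(
        truth,
        config.beam,
        config.resolve_h0(),
        bin_width=config.bin_width,
        rng=rng_phot,
        dark_kcps=config.dark_kcps,
    )
    scan = simulate_axial_scan(config.beam, rng=rng_scan)
    return scan, truth, photons


# Preset conditions.  GUV presets carry the physical parameters of the
# validation experiments (tension in N/m, viscosity in Pa s, kappa ~ 24
# k_B T, vesicle radius from the ~40 um average diameter).  The cell
# presets are equilibrium surrogates whose (sigma, eta, R) were chosen
# once, via the theory module, so that sqrt(C(0)) and tau* land near the
# measured amplitude/relaxation scales for that condition.
_PRESETS: dict[str, dict] = {
    "tense_guv": dict(
        membrane=dict(sigma=4.0e-6, eta=1.2e-3, radius_um=20.0),
        duration=60.0,
    ),
    "deflated_guv": dict(
        membrane=dict(sigma=0.5e-6, eta=1.2e-3, radius_um=20.0),
        duration=60.0,
    ),
    "rbc_atp_minus": dict(
        membrane=dict(sigma=0.4e-6, eta=25.0e-3, radius_um=4.0),
        duration=60.0,
    ),
    "macrophage_resting": dict(
        membrane=dict(sigma=0.65e-6, eta=150.0e-3, radius_um=10.0),
        duration=60.0,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Fully specified seeded configuration for a named condition.

    Overrides are applied on top of the preset (e.g. ``duration=30``,
    ``bin_width=1e-4``); the membrane model can be replaced wholesale via
    ``membrane=HelfrichModel(...)``.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    spec = copy.deepcopy(_PRESETS[name])
    membrane = HelfrichModel(**spec.pop("membrane"))
    cfg = SimConfig(seed=seed, membrane=membrane, name=name, **spec)
    if overrides:
        membrane_override = overrides.pop("membrane", None)
        cfg = replace(cfg, **overrides)
        if membrane_override is not None:
            cfg.membrane = membrane_override
    return cfg
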