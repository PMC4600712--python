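# Methods

## The measurement model

A fluorescently labelled membrane is parked on the axial flank of a
confocal detection volume. The detected intensity along the optical axis
is Gaussian,

    I(z) = I_Bg + (I_max − I_Bg) · exp(−2 (z − z_c)² / z0²),

with `z0` and `ω0` the axial and radial 1/e² radii (defaults 1.285 µm and
0.280 µm, the bead-calibration values of a water-immersion confocal
setup). At the inflection points z_c ± z0/2 the second derivative of I(z)
vanishes and the slope

    m = ± 2 e^(−1/2) (I_max − I_Bg) / z0

is maximal, so small membrane displacements δh(t) around the operating
point h0 map linearly onto intensity flickers:

    δh(t) = δI(t) / m.

The package always works with the *fitted* slope of each experiment's own
axial scan rather than a theoretical factor, so optical aberrations are
absorbed into the calibration. The signed-slope convention (positive on
the lower flank, negative on the upper) means no downstream formula needs
a sign special-case; the lower flank is the default.

The displacement autocorrelation function (dACF) follows from the
normalized intensity ACF ξ(τ) = ⟨δI(t)δI(t+τ)⟩/⟨I⟩² as

    C(τ) = ⟨δh(τ)δh(0)⟩ = ξ(τ) · ⟨I⟩² / m²,

where ⟨I⟩ is the measured mean intensity at the operating point (not
I_max). The zero-lag point is excluded everywhere: photon shot noise is
δ-correlated and contaminates only τ = 0.

### Resolution budget

Three error terms are computed (`resolution_budget`):

* **Noise floor**: √ξ_det · ⟨I⟩/|m|, with ξ_det the correlation amplitude
  measured on a non-fluctuating membrane. The fixture value
  ξ_det = 0.0024 with ⟨I⟩ = 50 kcps and m = 130 kcps/µm gives 18.8 nm,
  the basis of the 20-nm axial resolution figure.
* **Background**: an uncorrelated background increase ΔI_Bg shifts the
  apparent position by Δh = ΔI_Bg/|m|. Dark counts of 0.5 kcps cost
  ~10.6 nm at 50-kcps signals; a 2-kcps background (e.g. phenol-red
  medium) exceeds 40 nm.
* **Linearization**: the linear inversion of a true displacement δh
  carries a cubic bias −(4/3) δh³/z0² (the quadratic term vanishes at the
  inflection point), which reduces the apparent rms amplitude of a
  Gaussian trace of width s by ≈ 4 s³/z0². At s = 90 nm this is ~1.8 nm.
  `invert_profile` inverts the Taylor expansion to order 1, 2 or 3 by
  clamped Newton iteration on the monotone branch; order 2 equals order 1
  at the inflection point by construction. Non-invertible samples are
  clamped and flagged in a mask, never dropped silently; the clipped
  fraction is reported.

## Correlation estimation

Two estimators share one normalization (global mean subtracted once,
per-lag unbiased pair counts):

* a linear FFT correlator for dense lag grids, and
* a multi-tau correlator — 2·16 linear lags at base resolution, then 16
  lags per octave on data rebinned ×2 — the standard hardware-correlator
  layout, which covers 10 µs to seconds in ~16 points per decade.

The scalar "correlation amplitude" ξ is the mean of ξ(τ) over lags of
1–10 bins; this operational definition is recorded in every report, since
a G(0) extrapolation would be an equally defensible choice (sensitivity
to this choice is small because the membrane correlation time is long
compared with the bin).

Stationarity/ergodicity is checked by comparing the full-trace ACF with
the average over five disjoint subsets of increasing length (relative L2
deviation). Traces shorter than t_min = 25 s carry a warning; the pass
threshold for the subset deviation is 0.10 (a choice — the procedure is
standard, the cutoff is not).

## Helfrich theory and fitting

A free fluid membrane patch with tension σ, bending modulus κ in a medium
of viscosity η has mode variance and relaxation rate

    ⟨|h_q|²⟩ ∝ k_B T / (σq² + κq⁴),   ω_q = (σq + κq³) / (4η),

and the sampled membrane point decorrelates as

    C(τ) = (k_B T / 2π) ∫_{q_min}^{q_max} q dq · exp(−ω_q τ) / (σq² + κq⁴),

with q_min = π/R (R the system radius, default 20 µm for the ~40-µm
vesicles), q_max = π/a (a = 10 nm microscopic cutoff), and an optional
lateral spot-averaging weight W(q) = exp(−q²ω0²/4), off by default for
the distal-membrane geometry. The integral is evaluated on a log-spaced
trapezoid grid (400 nodes; agrees with adaptive quadrature to <0.5%).

`fit_membrane` performs least squares over (log σ, log η) with κ
(default 1e−19 J ≈ 24 k_B T), temperature (296 K) and both cutoffs held
fixed — only tension and viscosity are free, as the amplitude of C is
σ-dominated and the decay η-dominated; the (σ, η) → (C(0), τ*) map is
locally invertible (checked numerically in the tests). Standard errors
come from the Jacobian at the optimum. Reported summaries: the
fluctuation amplitude √C(0) of the *fitted* curve, the rms of the
converted trace (both, since either reading of "amplitude" is defensible),
the 1/e decay time τ* of the fitted curve, and the integral correlation
time ∫C dτ/C(0). All conventions and cutoffs are echoed into the JSON
report.

## The simulator

`simulate_membrane_trace` superposes 64 independent Ornstein–Uhlenbeck
modes at log-spaced wavevectors whose stationary variances are the
trapezoid weights of the mode integral (doubling the mode count changes
C(0) by <1%) and whose rates are ω_q. Updates use the exact discrete OU
transition (φ = e^(−ω dt), innovation variance w(1−φ²)), so there is no
Euler error and no time-step stability constraint: modes much faster than
the sampling interval correctly degenerate to white noise of the right
variance, and no subcycling is needed. Default sampling is 10 µs, the
binning of the real acquisition.

`simulate_photon_trace` draws per-bin Poisson counts at rate
I(h0 + δh(t)) plus a dark rate (0.5 kcps, typical avalanche-photodiode
dark counts); `simulate_axial_scan` Poisson-samples the profile on a z
grid. All randomness derives from one seed via independent child streams
(membrane / photons / scan), so identical configurations are bitwise
reproducible.

### Presets

* `deflated_guv` — σ = 0.5 µJ/m², η = 1.2 mPa·s, κ = 1e−19 J, R = 20 µm:
  the floppy-vesicle validation condition; theory amplitude ≈ 59 nm
  (same tens-of-nm scale as measured floppy vesicles).
* `tense_guv` — σ = 4 µJ/m², otherwise as above: amplitude ≈ 25 nm, and
  its photon-trace ξ lands at the ~0.0024 noise-floor scale.
* `rbc_atp_minus`, `macrophage_resting` — equilibrium surrogates with
  R = 4 / 10 µm and η chosen (25 / 150 mPa·s) so amplitude and τ* land
  near the measured scales for those cells. These are *not* physical
  viscosities and no active (ATP- or cytokine-driven) dynamics are
  modelled; they exist so the analysis chain can be exercised at
  cell-like signal levels.

A deliberately non-physical Poisson "kick" process (one-sided,
exponentially relaxing jumps) is available as a positive control for the
non-Gaussianity statistics.

### What the simulator does not emulate

Fluorophore diffusion (suppressed at high labelling in the real
experiment and omitted here), detector afterpulsing/dead time, bleaching,
drift of the operating point, optical aberrations in cells, and any
active fluctuation mechanism. Passing tests therefore demonstrate the
correctness of the analysis chain for shot-noise-limited equilibrium
flicker signals, not the biology of active membranes.

## Fluctuation statistics

Histograms use Freedman–Diaconis bins by default (explicit common edges
for cross-object averages of ⟨N(δh)⟩ and ⟨ΔN(δh)⟩), a least-squares
Gaussian fit, and moment statistics S = m₃/m₂^{3/2},
K = m₄/m₂² − 3 (excess kurtosis, Gaussian = 0, lower bound −2). The
convention string is embedded in every output because published kurtosis
values under other normalizations are not comparable. Mann–Whitney
U-tests use exact enumeration for tie-free samples with n ≤ 20 per group
and the tie-corrected normal approximation otherwise, with the usual
star mapping (*** < 0.001, ** < 0.01, * < 0.05); no multiple-testing
correction is applied, and reports state the number of comparisons where
relevant.

## Numerical choices and known limitations

* Scan fits are unweighted least squares (equal dwell per sample), with
  the background bounded below by zero; fits whose width or centre fall
  outside the scanned range raise a calibration error rather than
  returning silently implausible geometry.
* Membrane fits exclude lags below 0.1 ms by default, where residual
  shot-noise scatter is largest relative to the signal.
* The 1/e time τ* of a mode mixture is shorter than its slowest mode
  time (for the deflated preset ~14 ms vs the 61-ms slowest mode) and is
  cutoff dependent; treat τ* comparisons across instruments as
  order-of-magnitude only.
* Free-membrane equilibrium theory cannot produce the slow relaxation
  measured on *tense* vesicles at water viscosity (it predicts ~1 ms at
  25-nm amplitudes); the tense preset therefore matches amplitude only.
* Problem sizes: the packaged recovery study uses 12 replicates of 60-s
  traces at 10-µs binning; the test suite uses 4 replicates of 20-s
  traces at 100-µs binning. Both recover σ and η well within the ±40%
  acceptance band; longer traces mainly tighten η.
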