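# dods — dynamic optical displacement spectroscopy

Membrane bending fluctuations ("flicker") carry the mechanics of a cell or
vesicle membrane: its tension, its bending rigidity, the viscosity of the
surrounding medium, and — in living cells — signatures of active,
non-thermal driving. `dods` implements the analysis of *dynamic optical
displacement spectroscopy*: a fluorescently labelled membrane is parked at
the inflection point (IP) of a confocal detection volume's axial Gaussian
intensity profile, where photon-count flickers δI(t) map linearly onto
membrane displacements through the locally calibrated slope m = dI/dz,

    δh(t) = δI(t) / m,        C(τ) = ⟨δh(τ)δh(0)⟩ = ξ(τ) · ⟨I⟩² / m²,

with ξ(τ) the normalized intensity autocorrelation function. The technique
reaches ~20 nm axial and 10 µs temporal resolution, far beyond camera-based
flicker spectroscopy, and works on any chosen point of a cell.

The package is aimed at membrane biophysicists running confocal/FCS
hardware. It provides:

* **`dods.profile`** — the Gaussian axial beam model, scan fitting, and the
  inflection-point geometry (I_IP = 0.61·I_max, signed slope m).
* **`dods.correlation`** — linear-FFT and multi-tau ACF estimators, the
  correlation-amplitude ξ, an ergodicity/stationarity subset test
  (t_min = 25 s), and ξ(z) profiling (double peak at the IPs for a
  fluctuating membrane).
* **`dods.conversion`** — intensity→displacement conversion (linear and
  higher-order Taylor inversion with clip masking), ACF→dACF, and the full
  resolution budget (noise floor, background error, linearization error).
* **`dods.helfrich`** — the Helfrich mode spectrum
  ⟨|h_q|²⟩ ∝ k_BT/(σq² + κq⁴) with rates ω_q = (σq + κq³)/4η, the
  theoretical dACF, and tension/viscosity fitting with amplitude and τ*.
* **`dods.stats`** — displacement histograms N(δh) with Gaussian fits and
  ΔN residuals, skewness/excess kurtosis, Mann–Whitney U tests with the
  standard star convention.
* **`dods.simulate`** — a seeded forward simulator (exact-discretization
  Ornstein–Uhlenbeck membrane modes, Poisson photon detection with dark
  counts, noisy axial scans) with presets for tense/deflated vesicles and
  cell-like conditions.

See `docs/methods.md` for the model, conventions and numerical choices.

## Worked example

Simulate a deflated ("floppy") giant unilamellar vesicle experiment —
tension σ = 0.5 µJ/m², viscosity η = 1.2 mPa·s, 30 s of photon counts in
10-µs bins through a beam with z0 = 1.285 µm — then analyse it blind:

```sh
dods simulate --preset deflated_guv --seed 7 --duration 30 --out example
dods analyze --trace example/trace.csv --scan example/scan.csv --out example/analysis
```

The analysis log shows each derived quantity as it is computed:

```
INFO dods: profile: z0=1.271 um, I_max=91.7 kcps, I_Bg=0.1127 kcps
INFO dods: operating point: z_IP=-0.626 um, I_IP=55.67 kcps, m=87.43 kcps/um
INFO dods: ACF amplitude xi=0.007015 at <I>=55.32 kcps
INFO dods: membrane fit: sigma=0.575 uJ/m^2, eta=1.55 mPa s, amp=55.5 nm, tau*=0.0154 s
```

and the command prints the fit report:

```json
{
  "sigma_uJ_m2": 0.5752231494248193,
  "eta_mPas": 1.5483126870421042,
  "amplitude_nm": 55.541107456665294,
  "tau_star_s": 0.01537587585538305,
  "converged": true
}
```

Reading the numbers: the axial scan was refit from its own Poisson noise
(z0 within 1% of truth); the membrane sits at the lower-flank IP where the
intensity is 0.61 of the peak; the correlation amplitude ξ ≈ 7×10⁻³ is
well above the ξ_det ≈ 2.4×10⁻³ noise floor; and the Helfrich fit recovers
the generating tension within ~15% and viscosity within ~30% from a single
30-s trace (averaging replicates tightens both — see below). The fitted
fluctuation amplitude √C(0) ≈ 56 nm is the equilibrium prediction for
these parameters. Full curves (`acf.csv`, `dacf.csv`, `histogram.csv`) and
a `report.json` with every convention used (κ, cutoffs, ξ definition,
moment convention) are written next to it.

The resolution budget for a given geometry comes from:

```sh
dods resolution --i-max 137 --mean-intensity 50
```

which reports the 18.9-nm noise floor and the 10.6-nm dark-count
background error.

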