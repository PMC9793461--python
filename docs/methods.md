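# Methods

## The measurement model

In-situ fiber-optic UV-Vis dissolution monitoring records, per vessel
and time point, an absorbance spectrum A(λ, t) over 200–300 nm. For an
oil-solution depot in a dialysis bag, the measured spectrum is modelled
as three additive parts:

    A(λ, t) = (F(t)/100) · A_drug(λ) + b(t) · s(λ) + ε(λ, t)

* `A_drug(λ)` — the spectrum of the fully released dose, i.e. the
  standard solution prepared at the 100 %-release concentration
  (dose / medium volume, e.g. 2 mg / 500 mL = 0.004 mg/mL). Beer–Lambert
  linearity in concentration is assumed throughout the working range.
* `F(t)` — true cumulative percent released.
* `b(t) · s(λ)` — excipient ("placebo") interference: a spectrally
  near-flat shape `s` whose amplitude `b` is zero until oil components
  start leaking through the dialysis membrane late in the run.
* `ε` — instrument noise.

The single-point readout `100·A(λ₀,t)/A_std(λ₀)` at the band maximum
λ₀ = 241 nm absorbs the full interference term. The derivative readout
replaces absorbances by smoothed first derivatives dA/dλ evaluated at a
band inflection λ*: since ds/dλ ≈ 0, the interference term largely
drops out, and any wavelength-constant offset (stray light, turbidity
pedestal) drops out exactly. Signed derivative values are ratioed, not
magnitudes, so an extreme on the descending band limb (negative
derivative in both sample and standard) still yields a positive
percentage.

## Derivative estimation and wavelength selection

Derivatives are Savitzky–Golay polynomial-smoothing derivatives on the
uniform 1 nm grid (200–300 nm inclusive; this puts 241 and 252 nm
exactly on grid points). Defaults: window 7 points, polynomial order 2,
edges by one-sided polynomial fits. Order 2 was chosen for noise
suppression; its smoothing bias on an 11 nm-wide band is ~2 % of the
peak derivative, but the bias is identical for sample and standard and
cancels exactly in their ratio, so quantification is unbiased (the
noise-free pipeline test confirms identity to 1e-9). When the
derivative itself is the quantity of interest — e.g. validating against
the analytic derivative of a known band — polynomial order 5 reduces
the bias below 1e-6 of the peak and is used in those oracle checks.
Both window and order are exposed everywhere.

The analysis wavelength is the arg-max of |dA_std/dλ| within a search
window, default 245–265 nm: it brackets the long-wavelength inflection
of a band centred near 241 nm while excluding the short-wavelength limb,
where excipient spectra are less flat. Ties break toward the longest
wavelength. If max |dA_std/dλ| in the window is below 1e-4 AU/nm
(about an order of magnitude under the default band's inflection
derivative of 0.044 AU/nm) the standard is considered flat and
selection fails rather than returning noise. A second-derivative
readout is implemented but not the default: each differentiation step
narrows the usable dynamic range, and on desk-scale tests the first
derivative is the more reliable choice.

Negative post-baseline absorbances are kept (not clamped): clamping
would bias derivative ratios near zero. Percent-released values are
likewise not clamped to [0, 100], because readings above 100 % are
precisely the interference signature the method exposes.

## Partitioning and sink conditions

The apparent partition coefficient uses mass balance so that only the
aqueous phase needs assaying:

    P_app = (c_i·V_u − c_v·V_v) / (c_v·V_u)

with c_i the drug concentration of the prepared oil solution, c_v the
equilibrium aqueous concentration, V_u/V_v the oil/aqueous volumes.
Construction rejects c_v = 0 (infinite partitioning) and c_v above the
total-mass bound c_i·V_u/V_v. A directly measured oil/aqueous ratio is
provided separately (`partition_ratio`); the two coincide algebraically
when the oil concentration is the mass-balance one — a property-tested
identity. log P > 1 is reported as the prolonged-release screen.

Sink volume is `factor · dose / solubility` with the classical factor 3
as default and a closed lower bound (`volume ≥ sink volume` passes).
No factor is hard-coded to reproduce any particular published volume:
published sink figures for this system are not mutually consistent with
a single factor and solubility, so the calculator stays explicit about
its inputs.

## Kinetics

First-order model F(t) = f∞(1 − e^{−kt}); biphasic model
F(t) = a(1 − e^{−k₁t}) + m·t. Fits are unweighted least squares
(replicate SDs are reported but no variance model is asserted) via
bounded trust-region least squares with tolerances 1e-15. The
initializer is deterministic: plateau from the observed maximum, rate
from the log-linear slope −ln(1 − F/f∞₀)/t of the first half of the
points, refined over a small multiplicative rate grid {¼, ½, 1, 2, 4}
with the plateau solved in closed form per grid point; the refined fit
never does worse than the best grid point. No random restarts, so a
given profile always yields the same fit. The biphasic fit always
includes the first-order solution (with m = 0) among its starting
points, guaranteeing the nested-model property rss_biphasic ≤
rss_first-order. The slope-change time is reported as the time the
fast phase reaches 95 % of its amplitude, t_break = −ln(0.05)/k₁,
clipped into the fitted span.

Degenerate input (an all-zero profile) makes k unidentifiable; the fit
raises a `KineticsFitError` carrying its initializer state rather than
returning an arbitrary rate, because a `FirstOrderFit` with k = 0 would
violate the type's invariants.

f2 = 50·log10(100/√(1 + MSD)) over all shared time points; the
regulatory "only one point above 85 %" truncation is deliberately not
applied, keeping the statistic a transparent function of the full
profiles.

## Synthetic data

The generator emulates the structure above, not any specific compound:

* Drug band: a single Gaussian, centre 241 nm, sd 11 nm, peak 0.8 AU at
  100 % release. The Gaussian surrogate makes wavelength selection
  analytically testable (inflection exactly at centre + sd = 252 nm);
  it does not claim to match a real dexamethasone spectrum, whose band
  is asymmetric.
* Placebo shape: 1 + tilt·(λ − 241), tilt 1e-3 AU/nm, clipped at 0 —
  flat to within a few percent of the drug band's derivative (the
  unit-amplitude derivative ratio at 252 nm is 2.3 %).
* Release: F(t) = min(100, a(1 − e^{−k₁t}) + m·t) with defaults
  a = 60 %, k₁ = 0.005/min (slope change ≈ 10 h, inside the 6–12 h
  window typical of cosolvent formulations), m = 0.015 %/min (the
  profile tops out within 72 h). Temperature scales both rates by
  Q10^{(T−37)/10} with Q10 = 2; stirring by (rpm/75)^0.3 — a mild
  exponent, as paddle speed affects these systems only moderately.
* Placebo amplitude: 0 before a 2880 min (48 h) onset, then linear at
  `placebo_rate` AU/min (1e-4 in the leakage scenario — at 72 h this
  adds 0.144 AU, an 18 % apparent overshoot at 241 nm). The linear
  ramp is the simplest monotone model for a leak that begins at a
  characteristic breakthrough time.
* Noise: homoscedastic Gaussian in AU, independent per (vessel, λ, t);
  0.002 AU in the standard scenarios (0.25 % of the full-release
  band maximum). Per-vessel streams are spawned from one integer seed
  via `numpy.random.SeedSequence`, so runs are bit-reproducible and
  vessels are independent. Bubble spikes from non-degassed media are
  out of scope.
* Schedule: 5, 10, 15, 20, 30, 45, 60, 90, 120, 150, 180, 240, 300,
  360, 720, 1440 min, extended by 12 h steps for 48 h/72 h scenarios;
  6 vessels per run.

What passing tests on this generator do **not** show about real data:
real excipient spectra are only approximately flat, real noise is
heteroscedastic and correlated across wavelengths, membranes clog, and
probes drift; the derivative method's residual error on real systems is
therefore larger than the sub-percent figures seen here. The generator
establishes correctness of the computations and the *direction* of the
interference cure, not instrument-level accuracy.

## Problem sizes and numerics

Default analyses use 6 vessels × ≤20 time points × 101 wavelengths;
the kinetics Monte-Carlo uses 20 replicates of 6-vessel aggregates at
1 % noise; oracle identities are checked on 1000 random partition
experiments. CSVs are written with 17 significant digits and parsed
with round-trip float precision, making file round-trips lossless.
All tolerances asserted in tests are stated inline next to the
computation they bound.

## Known limitations

* Single-component quantification only — no multivariate calibration
  (CLS/PLS) for overlapping absorbers.
* The placebo model is additive and near-flat; scattering or strongly
  structured excipient spectra would need the second-derivative or
  multivariate route.
* The biphasic model is phenomenological; it nests the first-order
  model but does not attempt mechanistic diffusion/partition transport
  through the bag.
* `t_break` is derived from k₁, not estimated as a free change point.
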