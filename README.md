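# ivrtools

Analytics for fiber-optic in vitro release (IVR) testing of oil-solution
parenterals — slow-releasing drug depots such as a dexamethasone solution
in castor oil held in a dialysis bag inside a USP II dissolution vessel,
monitored in situ by UV-Vis probes.

The package is aimed at formulation and analytical scientists who have
time-resolved absorbance spectra per vessel and want percent-released
profiles, interference diagnostics and kinetics parameters out the other
end. It covers:

* **Spectral plumbing** — a canonical long-format CSV for per-vessel
  spectral time series, wavelength-grid resampling and medium-baseline
  subtraction.
* **Quantification** — percent released by the single-point method,
  `%(t) = 100 · A_sample(λ, t) / A_standard(λ)` at the band maximum
  (241 nm), and by the derivative method,
  `%(t) = 100 · D_sample(λ*, t) / D_standard(λ*)`, where `D` is a
  Savitzky–Golay first derivative and `λ*` is the band inflection
  selected automatically from the standard (252 nm for the default
  band). Spectrally flat excipient contributions differentiate to ~zero,
  so the derivative readout is immune to the late-time leakage of oil
  components through the dialysis membrane that inflates the
  single-point readout.
* **Partitioning and sink conditions** — the apparent partition
  coefficient by mass balance,
  `P_app = (c_i·V_u − c_v·V_v) / (c_v·V_u)`, its log10 (log P > 1 being
  the usual prolonged-release screen), and the minimum medium volume for
  sink conditions, `V = factor · dose / solubility`.
* **Kinetics** — deterministic least-squares fits of the first-order
  model `F(t) = f∞(1 − e^{−kt})` and the biphasic model
  `F(t) = a(1 − e^{−k₁t}) + m·t` (fast cosolvent-assisted phase plus
  linear terminal phase), and the f2 similarity factor
  `f2 = 50·log10(100/√(1 + MSD))` for profile comparison.
* **A synthetic-data generator** — Gaussian drug band, near-flat placebo
  with late-onset leakage, biphasic release, per-vessel noise streams —
  so the whole pipeline is testable with known ground truth and no
  instrument.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data; each writes tables under `results/`:

```
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_partition_and_sink.py
python analysis/03_release_profiles.py
python analysis/04_interference_correction.py
python analysis/05_kinetics_fits.py
```

Step 04 prints, for the 72 h scenario in which placebo absorbance starts
rising at 48 h:

```
          method  max_abs_error_pct  max_abs_error_pre_onset_pct  error_at_72h_pct
first_derivative               0.82                         0.82              0.06
    single_point              18.11                         0.19             18.11
```

Both methods track the true release to within ~1 % before the leak, but
at 72 h the uncorrected single-point profile reads 18 % of the dose too
high, while the derivative-corrected profile is off by 0.06 % — the
interference is eliminated. Step 05 then fits the corrected baseline
profile:

```
  first-order: plateau 90.3 %, k 0.00280/min
  biphasic:    a 61.4 %, k1 0.00481/min, m 0.0138 %/min, slope change at 10.4 h
```

i.e. a fast phase of ~61 % with a slope change near 10 h, inside the
6–12 h window typical of cosolvent-containing oil depots.

The same operations are available from the shell:

```
ivrtools simulate --scenario placebo_leakage_72h --seed 7 --out-dir data/
ivrtools process data/..._series.csv data/..._standard_V1.csv -o single.csv
ivrtools correct data/..._series.csv data/..._standard_V1.csv -o corrected.csv
ivrtools kinetics corrected.csv
ivrtools compare single.csv corrected.csv
ivrtools sink --dose-mg 2 --solubility 0.17 --factor 3
```

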