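"""Convert the simulated spectral series into percent-released profiles.

Runs both quantification methods on the datasets written by
01_simulate_dataset.py: the single-point readout at the 241 nm band
maximum, and the derivative-ratio readout at the automatically selected
252 nm inflection.  Aggregates the six vessels into mean +/- SD
profiles and writes them as one tidy table.
"""

import argparse
from pathlib import Path

import pandas as pd

from ivrtools import (
    ProbeCalibration,
    aggregate_vessels,
    baseline_correct,
    percent_released_derivative,
    percent_released_single,
    read_spectral_series,
    read_spectrum,
)

ROOT = Path(__file__).resolve().parents[1]

PREFIXES = {
    "baseline_48h": "baseline_48h_baseline",
    "placebo_leakage_72h": "placebo_leakage_72h_placebo_leakage",
}


def profiles_for(prefix: Path) -> dict[str, "pd.DataFrame"]:
    series = read_spectral_series(f"{prefix}_series.csv")
    medium = read_spectrum(f"{prefix}_medium.csv")
    out = {}
    for method, fn in (("single_point", percent_released_single),
                       ("first_derivative", percent_released_derivative)):
        per_vessel = []
        for vessel, s in series.items():
            cal = ProbeCalibration(
                vessel, read_spectrum(f"{prefix}_standard_{vessel}.csv"), 0.004
            )
            per_vessel.append(fn(baseline_correct(s, medium), cal))
        agg = aggregate_vessels(per_vessel)
        out[method] = pd.DataFrame(
            {"time_min": agg.times, "percent_released": agg.percent_released,
             "sd": agg.sd, "method": method}
        )
    return out


def main():
    argparse.ArgumentParser().parse_args()
    data_dir = ROOT / "scratch" / "data"
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    tables = []
    for scenario, stem in PREFIXES.items():
        prefix = data_dir / stem
        if not Path(f"{prefix}_series.csv").exists():
            raise SystemExit(f"missing {prefix}_series.csv - run 01_simulate_dataset.py first")
        for method, df in profiles_for(prefix).items():
            df.insert(0, "scenario", scenario)
            tables.append(df)
            print(f"{scenario:22s} {method:16s} final: "
                  f"{df['percent_released'].iloc[-1]:6.1f} % "
                  f"(SD {df['sd'].iloc[-1]:.2f})")

    out = results / "release_profiles.csv"
    pd.concat(tables, ignore_index=True).to_csv(out, index=False)
    print(f"profiles -> {out}")
    print("note the single-point profile of the leakage scenario overshooting "
          "at late times while the derivative profile does not")


if __name__ == "__main__":
    main()
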