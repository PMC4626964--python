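#!/usr/bin/env python
"""Propagate the fitted posteriors into capacity and discharge planning.

For each nutrient and planning year (2015 and 2020 water-quality targets)
the water environmental capacity WEC = C_S*V*(r+S) is evaluated at the
5%, 25%, mean, 75% and 95% posterior levels of S, together with the
allowable discharge capacity ADC = (WEC - W)/alpha, the load-reduction
ratio against the current load, and the period-over-period ADC reduction
from the 2010 emission baseline.  Writes results/capacity_<nutrient>.csv.

A cross-check against the published 2011 Taihu capacity table is printed:
the flushing rate back-solved from the published numbers must agree
between nutrients (same lake, same hydraulic year).
"""

from pathlib import Path

import numpy as np
import pandas as pd

import lakewec.taihu as taihu
from lakewec import (
    Chain,
    QualityScenario,
    conc_mgl_to_model,
    hydraulic_rate_from_capacity,
    read_series,
    scenario_report,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def cross_check() -> float:
    rates = {
        n: hydraulic_rate_from_capacity(
            taihu.REPORTED_WEC_2011[n]["mean"],
            conc_mgl_to_model(taihu.TARGETS_MGL[n][2015]),
            taihu.GEOMETRY.volume,
            taihu.REPORTED_POSTERIOR[n].mean,
        )
        for n in ("TN", "TP")
    }
    print(
        f"flushing rate implied by the published capacity table: "
        f"TN {rates['TN']:.4f} 1/a, TP {rates['TP']:.4f} 1/a "
        f"(agreement {100 * abs(rates['TN'] - rates['TP']) / rates['TN']:.2f}%)"
    )
    return float(np.mean(list(rates.values())))


def main() -> None:
    cross_check()
    for nutrient in ("TN", "TP"):
        series = read_series(
            ROOT / "data" / f"synthetic_{nutrient.lower()}.csv",
            taihu.GEOMETRY, nutrient=nutrient,
        )
        draws = pd.read_csv(ROOT / f"chain_{nutrient}.csv")
        chain = Chain(draws["S"].to_numpy(), draws["sigma"].to_numpy(), acceptance_rate=np.nan)
        mean_r = series.mean_hydraulic_rate()
        scenarios = [
            QualityScenario.from_mgl(
                year, taihu.TARGETS_MGL[nutrient][year],
                taihu.UNCONTROLLED_LOAD[nutrient], taihu.ALPHA[nutrient], mean_r,
            )
            for year in (2015, 2020)
        ]
        tables, transitions = scenario_report(
            chain, scenarios, taihu.GEOMETRY,
            baseline_emission=taihu.EMISSION_2010[nutrient],
            load=taihu.LOAD_2011[nutrient],
        )
        frames = []
        for table, trans in zip(tables, transitions):
            frame = table.to_dataframe()
            frame.insert(0, "scenario_year", table.scenario_year)
            frame["period_adc_reduction_pct"] = [round(100 * trans[k], 2) for k in frame["level"]]
            frame["wec_t_per_a"] = frame["wec_t_per_a"].round().astype(int)
            frame["adc_t_per_a"] = frame["adc_t_per_a"].round().astype(int)
            frame["reduction_ratio_pct"] = frame["reduction_ratio_pct"].round(2)
            frames.append(frame)
        out = ROOT / f"capacity_{nutrient}.csv"
        pd.concat(frames, ignore_index=True).to_csv(out, index=False)
        t2015 = tables[0]
        print(
            f"{nutrient} 2015 target {taihu.TARGETS_MGL[nutrient][2015]} mg/L: "
            f"WEC(mean) {t2015.wec['mean']:.0f} t/a, ADC(mean) {t2015.adc['mean']:.0f} t/a, "
            f"load reduction {100 * t2015.reduction['mean']:.2f}% -> {out.name}"
        )


if __name__ == "__main__":
    main()
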