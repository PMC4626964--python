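"""Reference constants for Taihu Lake (China).

Taihu is a large, shallow, eutrophication-prone freshwater lake; total
nitrogen (TN) and total phosphorus (TP) are its dominant pollutants.  The
values below are the published management constants and previously
reported posterior summaries for the 1987-2010 annual record; they are
used as inputs to capacity planning and as cross-consistency anchors in
the test-suite, not as fitted outputs of this package.

Units follow the package conventions: volumes in 10^8 m^3, loads in t/a,
concentration targets in mg/L at this boundary, decay rates in 1/a.
"""

from __future__ import annotations

from .inference import PosteriorSummary, PriorSpec
from .model import LakeGeometry

__all__ = [
    "GEOMETRY",
    "PRIORS",
    "UNCONTROLLED_LOAD",
    "ALPHA",
    "LOAD_2011",
    "EMISSION_2010",
    "TARGETS_MGL",
    "REPORTED_POSTERIOR",
    "REPORTED_WEC_2011",
    "REPORTED_REDUCTION_PCT_2011",
]

#: average lake storage capacity, 10^8 m^3
GEOMETRY = LakeGeometry(volume=44.3)

#: literature-derived uniform prior intervals on the decay rate S (1/a)
PRIORS = {
    "TN": PriorSpec(s_low=1.0, s_high=2.5),
    "TP": PriorSpec(s_low=3.0, s_high=6.0),
}

#: uncontrolled pollutant input W (river inflow, atmospheric deposition,
#: lake island and seine), t/a
UNCONTROLLED_LOAD = {"TN": 12115.0, "TP": 808.0}

#: delivery coefficient alpha: fraction of discharged pollutant reaching the lake
ALPHA = {"TN": 0.84, "TP": 0.90}

#: historical in-lake loads in 2011, t/a
LOAD_2011 = {"TN": 58336.0, "TP": 3308.0}

#: basin pollutant emissions in 2010, t/a (planning baseline)
EMISSION_2010 = {"TN": 66082.0, "TP": 3301.0}

#: annual-average water-quality targets, mg/L, by planning year
#: (surface-water class levels IV / inferior V / III of GB3838-2002)
TARGETS_MGL = {
    "TN": {2015: 2.2, 2020: 2.0},
    "TP": {2015: 0.06, 2020: 0.05},
}

#: previously reported posterior summaries of the decay rate S (1/a)
REPORTED_POSTERIOR = {
    "TN": PosteriorSummary(
        q05=1.728, q25=1.805, mean=1.861, q75=1.914, q95=2.0,
        sd=0.08329, mc_error=0.0003863,
    ),
    "TP": PosteriorSummary(
        q05=4.148, q25=4.464, mean=4.698, q75=4.918, q95=5.32,
        sd=0.3579, mc_error=0.001441,
    ),
}

#: previously reported 2011 capacities (t/a) under the 2015 targets,
#: by posterior level of S
REPORTED_WEC_2011 = {
    "TN": {"q05": 46743.0, "q25": 47494.0, "mean": 48040.0, "q75": 48556.0, "q95": 49394.0},
    "TP": {"q05": 1918.0, "q25": 2002.0, "mean": 2064.0, "q75": 2123.0, "q95": 2230.0},
}

#: previously reported 2011 load-reduction ratios, percent
REPORTED_REDUCTION_PCT_2011 = {
    "TN": {"q05": 19.87, "q25": 18.59, "mean": 17.65, "q75": 16.76, "q95": 15.33},
    "TP": {"q05": 42.02, "q25": 39.48, "mean": 37.60, "q75": 35.83, "q95": 32.60},
}
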