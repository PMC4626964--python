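"""Water environmental capacity (WEC) and allowable discharge capacity (ADC).

With a concentration target ``C_S`` (canonical t per 10^8 m^3), lake
volume ``V``, long-run flushing rate ``r`` and decay rate ``S``, the
maximum load the lake can absorb while meeting the target is

    WEC = C_S * V * (r + S)                 [t/a]

and the controllable share, after removing the uncontrolled input ``W``
(river inflow, deposition, ...) and dividing by the delivery coefficient
``alpha`` (fraction of discharged pollutant reaching the lake), is

    ADC = (WEC - W) / alpha                 [t/a].

Posterior uncertainty in S is propagated level-wise: WEC is evaluated at
the 5%, 25%, mean, 75% and 95% posterior levels of S.  Because WEC is
strictly increasing in S this coincides with the corresponding quantiles
of the full WEC pushforward distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import Chain, PosteriorSummary, summarize_posterior
from .model import LakeGeometry, conc_mgl_to_model

__all__ = [
    "QualityScenario",
    "CapacityTable",
    "wec",
    "hydraulic_rate_from_capacity",
    "reduction_ratio",
    "adc",
    "wec_table",
    "scenario_report",
]

LEVELS = ("q05", "q25", "mean", "q75", "q95")


def wec(target_conc: float, volume: float, rate: float, decay: float) -> float:
    """Water environmental capacity C_S * V * (r + S) in t/a."""
    if not target_conc > 0:
        raise ValueError(f"target concentration must be positive, got {target_conc}")
    if not volume > 0:
        raise ValueError(f"volume must be positive, got {volume}")
    if rate < 0 or decay < 0:
        raise ValueError("rates must be non-negative")
    return float(target_conc * volume * (rate + decay))


def hydraulic_rate_from_capacity(
    capacity: float, target_conc: float, volume: float, decay: float
) -> float:
    """Back-solve the flushing rate from a known capacity:
    r = WEC / (C_S * V) - S.  Used for cross-consistency checks between
    published capacity tables and posterior decay rates."""
    if not (target_conc > 0 and volume > 0):
        raise ValueError("target concentration and volume must be positive")
    return float(capacity / (target_conc * volume) - decay)


def reduction_ratio(load: float, capacity: float) -> float:
    """Fraction of the current load that must be cut: (load - WEC)/load.

    Negative when capacity exceeds the load (no reduction required)."""
    if not load > 0:
        raise ValueError(f"load must be positive, got {load}")
    return float((load - capacity) / load)


def adc(capacity: float, uncontrolled: float, alpha: float) -> float:
    """Allowable discharge capacity (WEC - W)/alpha in t/a.

    A negative result (capacity below the uncontrolled load) is returned
    with a warning rather than clamped: it is decision-relevant."""
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    out = (capacity - uncontrolled) / alpha
    if out < 0:
        warnings.warn(
            "allowable discharge capacity is negative: the uncontrolled load "
            f"({uncontrolled} t/a) already exceeds the capacity ({capacity:.0f} t/a)",
            stacklevel=2,
        )
    return float(out)


@dataclass(frozen=True)
class QualityScenario:
    """A planning year: concentration target plus the constants needed to
    turn capacity into an allowable discharge."""

    scenario_year: int
    target_conc: float  # canonical t per 10^8 m^3
    uncontrolled_load: float  # W, t/a
    alpha: float
    mean_r: float  # long-run flushing rate, 1/a

    def __post_init__(self) -> None:
        if not self.target_conc > 0:
            raise ValueError("target concentration must be positive")
        if self.uncontrolled_load < 0:
            raise ValueError("uncontrolled load must be non-negative")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.mean_r < 0:
            raise ValueError("mean flushing rate must be non-negative")

    @classmethod
    def from_mgl(
        cls,
        scenario_year: int,
        target_mgl: float,
        uncontrolled_load: float,
        alpha: float,
        mean_r: float,
    ) -> "QualityScenario":
        return cls(
            scenario_year,
            conc_mgl_to_model(target_mgl),
            uncontrolled_load,
            alpha,
            mean_r,
        )


@dataclass(frozen=True)
class CapacityTable:
    """Capacity quantities per posterior level of S (rows ordered
    q05, q25, mean, q75, q95)."""

    scenario_year: int
    s_levels: dict[str, float]
    wec: dict[str, float]
    adc: dict[str, float]
    reduction: dict[str, float] | None = None

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "level": list(LEVELS),
            "S_per_a": [self.s_levels[k] for k in LEVELS],
            "wec_t_per_a": [self.wec[k] for k in LEVELS],
            "adc_t_per_a": [self.adc[k] for k in LEVELS],
        }
        if self.reduction is not None:
            data["reduction_ratio_pct"] = [100 * self.reduction[k] for k in LEVELS]
        return pd.DataFrame(data)


def _s_levels(chain: Chain | PosteriorSummary) -> dict[str, float]:
    if isinstance(chain, PosteriorSummary):
        return chain.quantile_levels()
    return summarize_posterior(chain).quantile_levels()


def wec_table(
    chain: Chain | PosteriorSummary,
    scenario: QualityScenario,
    geometry: LakeGeometry,
    load: float | None = None,
) -> CapacityTable:
    """Capacity table at the posterior levels of S for one scenario.

    When the current ``load`` (t/a) is supplied, the level-wise load
    reduction ratio (load - WEC)/load is included.
    """
    levels = _s_levels(chain)
    wec_by_level = {
        k: wec(scenario.target_conc, geometry.volume, scenario.mean_r, s)
        for k, s in levels.items()
    }
    adc_by_level = {
        k: adc(w, scenario.uncontrolled_load, scenario.alpha)
        for k, w in wec_by_level.items()
    }
    reduction = None
    if load is not None:
        reduction = {k: reduction_ratio(load, w) for k, w in wec_by_level.items()}
    return CapacityTable(scenario.scenario_year, levels, wec_by_level, adc_by_level, reduction)


def scenario_report(
    chain: Chain | PosteriorSummary,
    scenarios: list[QualityScenario],
    geometry: LakeGeometry,
    baseline_emission: float,
    load: float | None = None,
) -> tuple[list[CapacityTable], list[dict[str, float]]]:
    """Capacity tables for a sequence of planning years plus the
    emission-reduction ratio between consecutive periods.

    The first period compares the first scenario's ADC against the fixed
    ``baseline_emission`` (t/a, level-independent); later periods compare
    consecutive scenario ADCs level-wise, as 1 - ADC_next/ADC_prev.
    """
    if not baseline_emission > 0:
        raise ValueError("baseline emission must be positive")
    years = [s.scenario_year for s in scenarios]
    if years != sorted(years):
        raise ValueError("scenarios must be ordered by year")
    tables = [wec_table(chain, sc, geometry, load=load) for sc in scenarios]
    transitions: list[dict[str, float]] = []
    prev_adc: dict[str, float] = {k: baseline_emission for k in LEVELS}
    for table in tables:
        transitions.append(
            {k: 1.0 - table.adc[k] / prev_adc[k] for k in LEVELS}
        )
        prev_adc = table.adc
    return tables, transitions
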