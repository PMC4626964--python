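"""Completely-mixed (Vollenweider) lake nutrient mass balance.

The lake is treated as a single well-mixed box.  With volume ``V``
(10^8 m^3), annual nutrient load ``I`` (t/a), outflow ``Q`` (10^8 m^3/a)
and a first-order in-lake decay rate ``S`` (1/a), the in-lake
concentration ``C`` (t per 10^8 m^3) obeys

    dC/dt = I/V - r*C - S*C,        r = Q/V  (hydraulic flushing rate)

whose steady state is ``C_eq = I / (V * (r + S))``.  The model carries no
thermal stratification, spatial structure or in-lake biogeochemistry:
everything beyond flushing is folded into ``S``.

Canonical internal units are 10^8 m^3 (volume), 10^8 m^3/a (flow), t/a
(load) and t per 10^8 m^3 (concentration).  Concentrations in mg/L appear
only at I/O boundaries; 1 mg/L = 100 t per 10^8 m^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MGL_TO_MODEL",
    "LakeGeometry",
    "AnnualRecord",
    "NutrientSeries",
    "conc_mgl_to_model",
    "conc_model_to_mgl",
    "hydraulic_rate",
    "steady_state_conc",
    "transient_conc",
    "read_series",
    "write_series",
]

#: 1 mg/L = 1 g/m^3 = 10^8 g per 10^8 m^3 = 100 t per 10^8 m^3
MGL_TO_MODEL = 100.0

#: on-disk CSV header for annual records (concentration stored in mg/L)
CSV_COLUMNS = ["year", "load_t_per_a", "outflow_1e8m3_per_a", "conc_mgL"]


def conc_mgl_to_model(c):
    """Convert a concentration from mg/L to t per 10^8 m^3 (factor 100)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = c * MGL_TO_MODEL
    return float(out) if out.ndim == 0 else out


def conc_model_to_mgl(c):
    """Convert a concentration from t per 10^8 m^3 back to mg/L."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = c / MGL_TO_MODEL
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LakeGeometry:
    """Lake storage capacity ``volume`` in 10^8 m^3."""

    volume: float

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValueError(f"lake volume must be positive, got {self.volume}")


@dataclass(frozen=True)
class AnnualRecord:
    """One year's observation: load I (t/a), outflow Q (10^8 m^3/a) and
    observed in-lake concentration C* (t per 10^8 m^3, canonical units)."""

    year: int
    load: float
    outflow: float
    observed_conc: float

    def __post_init__(self) -> None:
        if self.load < 0:
            raise ValueError(f"load must be non-negative, got {self.load}")
        if self.outflow < 0:
            raise ValueError(f"outflow must be non-negative, got {self.outflow}")
        if self.observed_conc < 0:
            raise ValueError(
                f"observed concentration must be non-negative, got {self.observed_conc}"
            )


@dataclass(frozen=True)
class NutrientSeries:
    """An ordered multi-year record for one nutrient (e.g. TN or TP)."""

    nutrient: str
    records: tuple[AnnualRecord, ...]
    geometry: LakeGeometry

    def __init__(
        self,
        nutrient: str,
        records: Iterable[AnnualRecord],
        geometry: LakeGeometry,
    ) -> None:
        records = tuple(sorted(records, key=lambda rec: rec.year))
        if len(records) < 2:
            raise ValueError("a nutrient series needs at least two annual records")
        years = [rec.year for rec in records]
        if len(set(years)) != len(years):
            raise ValueError("years must be unique within a series")
        object.__setattr__(self, "nutrient", nutrient)
        object.__setattr__(self, "records", records)
        object.__setattr__(self, "geometry", geometry)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def years(self) -> np.ndarray:
        return np.array([rec.year for rec in self.records])

    @property
    def loads(self) -> np.ndarray:
        return np.array([rec.load for rec in self.records])

    @property
    def outflows(self) -> np.ndarray:
        return np.array([rec.outflow for rec in self.records])

    @property
    def observed_conc(self) -> np.ndarray:
        return np.array([rec.observed_conc for rec in self.records])

    @property
    def hydraulic_rates(self) -> np.ndarray:
        """Year-specific flushing rates r_i = Q_i / V (1/a)."""
        return self.outflows / self.geometry.volume

    def mean_hydraulic_rate(self) -> float:
        """Long-run flushing rate Q-bar / V used in capacity planning."""
        return float(self.outflows.mean() / self.geometry.volume)

    def predicted_conc(self, decay_rate: float) -> np.ndarray:
        """Steady-state concentration per year at a common decay rate."""
        return steady_state_conc(
            self.loads, self.geometry.volume, self.hydraulic_rates, decay_rate
        )


def hydraulic_rate(outflow: float, volume: float) -> float:
    """Flushing rate r = Q/V (1/a); the reciprocal of the residence time."""
    if not volume > 0:
        raise ValueError(f"volume must be positive, got {volume}")
    if np.any(np.asarray(outflow) < 0):
        raise ValueError("outflow must be non-negative")
    out = np.asarray(outflow, dtype=float) / volume
    return float(out) if out.ndim == 0 else out


def steady_state_conc(load, volume, rate, decay):
    """Equilibrium concentration C = I / (V * (r + S)).

    Vectorised over ``load`` and ``rate``; rejects ``r + S <= 0`` where no
    steady state exists.
    """
    if not volume > 0:
        raise ValueError(f"volume must be positive, got {volume}")
    load = np.asarray(load, dtype=float)
    if np.any(load < 0):
        raise ValueError("load must be non-negative")
    total = np.asarray(rate, dtype=float) + decay
    if np.any(total <= 0):
        raise ValueError("r + S must be positive for a steady state")
    out = load / (volume * total)
    return float(out) if out.ndim == 0 else out


def transient_conc(t, c0: float, load: float, volume: float, rate: float, decay: float):
    """Concentration at time ``t`` (years) from initial concentration ``c0``.

    Solution of dC/dt = I/V - (r+S) C:

        C(t) = C_eq + (C0 - C_eq) * exp(-(r+S) t)

    relaxing exponentially to the steady state on timescale 1/(r+S).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    c_eq = steady_state_conc(load, volume, rate, decay)
    out = c_eq + (c0 - c_eq) * np.exp(-(rate + decay) * t)
    return float(out) if out.ndim == 0 else out


def _frame_to_records(frame: pd.DataFrame) -> list[AnnualRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            AnnualRecord(
                year=int(row.year),
                load=float(row.load_t_per_a),
                outflow=float(row.outflow_1e8m3_per_a),
                observed_conc=conc_mgl_to_model(float(row.conc_mgL)),
            )
        )
    return records


def read_series(
    path: str | Path,
    geometry: LakeGeometry,
    nutrient: str | None = None,
) -> NutrientSeries:
    """Read an annual-record CSV into a :class:`NutrientSeries`.

    The file holds ``year, load_t_per_a, outflow_1e8m3_per_a, conc_mgL``
    with concentrations in mg/L (converted on read).  A combined file may
    carry an extra ``nutrient`` column, in which case ``nutrient`` selects
    the rows to load.
    """
    frame = pd.read_csv(path)
    missing = [col for col in CSV_COLUMNS if col not in frame.columns]
    if missing:
        raise ValueError(f"annual-record CSV {path} missing columns: {missing}")
    if "nutrient" in frame.columns:
        if nutrient is None:
            labels = frame["nutrient"].unique()
            if len(labels) > 1:
                raise ValueError(
                    f"combined file holds nutrients {sorted(labels)}; pass `nutrient`"
                )
            nutrient = str(labels[0])
        frame = frame[frame["nutrient"] == nutrient]
        if frame.empty:
            raise ValueError(f"no rows for nutrient {nutrient!r} in {path}")
    elif nutrient is None:
        nutrient = Path(path).stem
    return NutrientSeries(nutrient, _frame_to_records(frame), geometry)


def write_series(series: NutrientSeries, path: str | Path, include_nutrient: bool = False) -> None:
    """Write a series to the annual-record CSV dialect (mg/L on disk)."""
    frame = pd.DataFrame(
        {
            "year": series.years,
            "load_t_per_a": series.loads,
            "outflow_1e8m3_per_a": series.outflows,
            "conc_mgL": conc_model_to_mgl(series.observed_conc),
        }
    )
    if include_nutrient:
        frame.insert(0, "nutrient", series.nutrient)
    frame.to_csv(path, index=False)
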