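"""Water mass balances for partial-frying experiments.

Each record tracks a disc through the protocol: weigh fresh
(``mass_initial``), optionally stop frying when the center passes the
boiling temperature and weigh again (``mass_at_stop``), then oven-dry to
constant mass (``mass_dried``).  Everything evaporable is water, so the
differences give the initial water load and the fraction that survived the
partial fry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MoistureRecord",
    "initial_water_mass",
    "water_remaining_mass",
    "percent_water_remaining",
    "percent_water_removed",
    "overall_moisture_average",
    "read_moisture_csv",
    "summarize",
]


@dataclass(frozen=True)
class MoistureRecord:
    """Masses (g) of one disc: fresh, after partial frying, after oven drying."""

    mass_initial: float
    mass_dried: float
    mass_at_stop: float | None = None
    sample_id: str = ""

    def __post_init__(self):
        if self.mass_dried <= 0:
            raise ValueError("mass_dried must be > 0")
        if self.mass_initial < self.mass_dried:
            raise ValueError("mass_initial must be >= mass_dried")
        if self.mass_at_stop is not None and not (
            self.mass_initial >= self.mass_at_stop >= self.mass_dried
        ):
            raise ValueError("need mass_initial >= mass_at_stop >= mass_dried")


def initial_water_mass(r: MoistureRecord) -> float:
    """Water in the fresh disc (g): fresh mass minus bone-dry mass."""
    return r.mass_initial - r.mass_dried


def water_remaining_mass(r: MoistureRecord) -> float:
    """Water still present when frying stopped (g)."""
    if r.mass_at_stop is None:
        raise ValueError("record has no mass_at_stop")
    return r.mass_at_stop - r.mass_dried


def percent_water_remaining(r: MoistureRecord) -> float:
    """Percentage of the initial water still present at the stop point."""
    wi = initial_water_mass(r)
    if wi == 0:
        raise ValueError("initial water mass is zero; percentage undefined")
    return 100.0 * water_remaining_mass(r) / wi


def percent_water_removed(r: MoistureRecord) -> float:
    """Complement of :func:`percent_water_remaining` (sums to 100 exactly)."""
    return 100.0 - percent_water_remaining(r)


def overall_moisture_average(surface_avg: float, center_avg: float) -> float:
    """Overall moisture content (wt %) as the mean of the surface and center averages."""
    return 0.5 * (surface_avg + center_avg)


def read_moisture_csv(path) -> list[MoistureRecord]:
    """Read records from CSV: sample_id,mass_initial_g,mass_at_stop_g,mass_dried_g."""
    df = pd.read_csv(path)
    required = {"sample_id", "mass_initial_g", "mass_at_stop_g", "mass_dried_g"}
    if not required.issubset(df.columns):
        raise ValueError(f"moisture CSV must have columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        stop = row["mass_at_stop_g"]
        records.append(
            MoistureRecord(
                mass_initial=float(row["mass_initial_g"]),
                mass_dried=float(row["mass_dried_g"]),
                mass_at_stop=None if pd.isna(stop) else float(stop),
                sample_id=str(row["sample_id"]),
            )
        )
    return records


def summarize(records: list[MoistureRecord]) -> pd.DataFrame:
    """Mean/min/max/sd of the mass-balance quantities across records.

    Percentages are reported two ways, which generally differ: the mean of
    the per-record percentages, and the percentage formed from the mean
    masses.  Both rows are emitted so either convention can be compared.
    """
    if not records:
        raise ValueError("no records")
    rows = {}

    def add(name, values):
        v = np.asarray(values, dtype=float)
        rows[name] = {
            "mean": v.mean(),
            "min": v.min(),
            "max": v.max(),
            "sd": v.std(ddof=1) if v.size > 1 else 0.0,
        }

    add("mass_initial_g", [r.mass_initial for r in records])
    add("initial_water_g", [initial_water_mass(r) for r in records])
    with_stop = [r for r in records if r.mass_at_stop is not None]
    if with_stop:
        add("water_remaining_g", [water_remaining_mass(r) for r in with_stop])
        add("pct_water_remaining", [percent_water_remaining(r) for r in with_stop])
        add("pct_water_removed", [percent_water_removed(r) for r in with_stop])
        mean_remaining = np.mean([water_remaining_mass(r) for r in with_stop])
        mean_initial = np.mean([initial_water_mass(r) for r in with_stop])
        ratio = 100.0 * mean_remaining / mean_initial
        rows["pct_remaining_of_mean_masses"] = {
            "mean": ratio, "min": ratio, "max": ratio, "sd": 0.0,
        }
    return pd.DataFrame(rows).T[["mean", "min", "max", "sd"]]
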