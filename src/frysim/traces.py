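"""Thermocouple traces: synthetic generation, spread profiles, comparison.

Measured frying traces vary strongly between replicate discs once the
center passes the boiling plateau; the dominant drivers are the disc-to-disc
moisture content, the thermocouple tip sitting slightly off-center, and
sensor noise. The synthetic generator emulates exactly those three sources
on top of a solver run, so model-vs-data comparison code can be exercised
without measured data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .properties import BoilingModel, FryingConditions, PropertySet, _DictMixin
from .result import SimulationResult

__all__ = [
    "TraceSet",
    "SyntheticTraceSpec",
    "generate_synthetic_traces",
    "trace_sd_profile",
    "compare_traces",
    "detect_plateau",
]


@dataclass(frozen=True)
class SyntheticTraceSpec(_DictMixin):
    """Variability model for synthetic replicate traces.

    Moisture is drawn uniformly from ``moisture_range`` (the span measured
    across individual tubers), the thermocouple offset from the disc center
    from a zero-mean normal with ``displacement_sd`` (truncated to the
    half-slab), and i.i.d. Gaussian sensor noise with ``noise_sd`` is added
    to each sample.
    """

    n_replicates: int = 10
    moisture_range: tuple = (0.69, 0.80)
    noise_sd: float = 0.5
    displacement_sd: float = 3e-4
    seed: int = 0
    sampling_interval: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "moisture_range", tuple(self.moisture_range))
        lo, hi = self.moisture_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("moisture_range must satisfy 0 < min <= max < 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0 or self.displacement_sd < 0:
            raise ValueError("noise_sd and displacement_sd must be >= 0")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")

    @classmethod
    def default(cls) -> "SyntheticTraceSpec":
        return cls()


@dataclass
class TraceSet:
    """Replicate (time, temperature) series with shared metadata."""

    times: list
    temperatures: list
    replicate_ids: list
    treatment: str = ""
    sampling_interval: float = 1.0

    def __post_init__(self):
        if len(self.times) != len(self.temperatures) or len(self.times) != len(
            self.replicate_ids
        ):
            raise ValueError("times, temperatures and replicate_ids must align")
        for t, T in zip(self.times, self.temperatures):
            t = np.asarray(t, dtype=float)
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError("trace times must be strictly increasing")
            if not np.all(np.isfinite(T)):
                raise ValueError("trace temperatures must be finite")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.concatenate(
                    [np.full(len(t), rid) for t, rid in zip(self.times, self.replicate_ids)]
                ),
                "time_s": np.concatenate([np.asarray(t, float) for t in self.times]),
                "temperature_c": np.concatenate(
                    [np.asarray(T, float) for T in self.temperatures]
                ),
                "treatment": self.treatment,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TraceSet":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"replicate", "time_s", "temperature_c"}
        if not required.issubset(df.columns):
            raise ValueError(f"trace CSV must have columns {sorted(required)}")
        times, temps, ids = [], [], []
        for rid, g in df.groupby("replicate", sort=False):
            times.append(g["time_s"].to_numpy())
            temps.append(g["temperature_c"].to_numpy())
            ids.append(str(rid))
        treatment = str(df["treatment"].iloc[0]) if "treatment" in df.columns else ""
        interval = float(np.median(np.diff(times[0]))) if len(times[0]) > 1 else 1.0
        return cls(times, temps, ids, treatment, interval)


def generate_synthetic_traces(
    spec: SyntheticTraceSpec,
    base_props: PropertySet,
    cond: FryingConditions,
    boil: BoilingModel,
    solver: str = "enthalpy",
    solver_cfg=None,
    treatment: str = "synthetic",
) -> TraceSet:
    """Run the chosen solver per replicate and read a noisy off-center trace.

    Fully reproducible: all randomness flows through one generator seeded
    from ``spec.seed``.
    """
    from . import enthalpy as _enth, vsn as _vsn  # local to avoid cycles

    rng = np.random.default_rng(spec.seed)
    L = cond.half_thickness
    times, temps, ids = [], [], []
    lo, hi = spec.moisture_range
    for i in range(spec.n_replicates):
        w = lo if lo == hi else rng.uniform(lo, hi)
        offset = rng.normal(0.0, spec.displacement_sd) if spec.displacement_sd else 0.0
        offset = float(np.clip(offset, -L * (1 - 1e-9), L * (1 - 1e-9)))
        props = dataclasses.replace(base_props, w=w)
        try:
            if solver == "vsn":
                result = _vsn.simulate_vsn(props, cond, boil, solver_cfg)
            elif solver == "enthalpy":
                result = _enth.simulate_enthalpy(props, cond, boil, solver_cfg)
            else:
                raise ValueError(f"unknown solver {solver!r}")
        except Exception as exc:
            raise RuntimeError(f"solver failed for replicate {i}: {exc}") from exc
        y = L - abs(offset)
        grid = np.arange(0.0, result.times[-1] + 1e-9, spec.sampling_interval)
        series = np.interp(grid, result.times, result.temperature_at(y))
        if spec.noise_sd:
            series = series + rng.normal(0.0, spec.noise_sd, series.size)
        times.append(grid)
        temps.append(series)
        ids.append(f"rep{i:02d}")
    return TraceSet(times, temps, ids, treatment, spec.sampling_interval)


def trace_sd_profile(ts: TraceSet, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Across-replicate sample standard deviation on a common time grid."""
    if len(ts) < 2:
        raise ValueError("need at least 2 traces for a spread profile")
    grid = np.asarray(grid, dtype=float)
    stack = np.vstack(
        [np.interp(grid, t, T) for t, T in zip(ts.times, ts.temperatures)]
    )
    return grid, stack.std(axis=0, ddof=1)


def detect_plateau(
    t: np.ndarray,
    T: np.ndarray,
    band: tuple[float, float] = (95.0, 115.0),
    slope_threshold: float = 0.02,
) -> tuple[float, float] | None:
    """Longest interval with |dT/dt| below threshold inside the band.

    Returns (t_start, t_end) of the boiling plateau, or None if no such
    interval exists.
    """
    t = np.asarray(t, float)
    T = np.asarray(T, float)
    if t.size < 3:
        return None
    slope = np.gradient(T, t)
    ok = (T >= band[0]) & (T <= band[1]) & (np.abs(slope) < slope_threshold)
    best = None
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        if (not flag or i == ok.size - 1) and start is not None:
            end = i if flag else i - 1
            if best is None or t[end] - t[start] > best[1] - best[0]:
                best = (t[start], t[end])
            start = None
    return best


def compare_traces(
    model: SimulationResult | tuple[np.ndarray, np.ndarray],
    measured: TraceSet,
    band: tuple[float, float] = (95.0, 115.0),
    slope_threshold: float = 0.02,
) -> dict:
    """RMSE / max deviation / plateau-timing offsets of model vs each trace.

    The model center temperature is interpolated onto each trace's own time
    grid, restricted to the overlapping time support. ``model`` may be a
    solver result or a bare (time, center-temperature) pair.
    """
    if isinstance(model, SimulationResult):
        mt, mT = model.times, model.center_temperature()
    else:
        mt, mT = (np.asarray(a, float) for a in model)
    per_trace = []
    model_plateau = detect_plateau(mt, mT, band, slope_threshold)
    for rid, t, T in zip(measured.replicate_ids, measured.times, measured.temperatures):
        t = np.asarray(t, float)
        T = np.asarray(T, float)
        sel = (t >= mt[0]) & (t <= mt[-1])
        if not sel.any():
            raise ValueError(f"trace {rid} has no time overlap with the model")
        resid = np.interp(t[sel], mt, mT) - T[sel]
        trace_plateau = detect_plateau(t[sel], T[sel], band, slope_threshold)
        entry = {
            "replicate": rid,
            "rmse_c": float(np.sqrt(np.mean(resid**2))),
            "max_abs_dev_c": float(np.max(np.abs(resid))),
            "plateau_start_offset_s": None,
            "plateau_end_offset_s": None,
        }
        if model_plateau and trace_plateau:
            entry["plateau_start_offset_s"] = float(model_plateau[0] - trace_plateau[0])
            entry["plateau_end_offset_s"] = float(model_plateau[1] - trace_plateau[1])
        per_trace.append(entry)
    return {
        "per_trace": per_trace,
        "rmse_mean_c": float(np.mean([e["rmse_c"] for e in per_trace])),
        "max_abs_dev_c": float(np.max([e["max_abs_dev_c"] for e in per_trace])),
        "model_plateau_s": list(model_plateau) if model_plateau else None,
    }
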