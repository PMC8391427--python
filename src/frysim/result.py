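"""Time-resolved simulation output shared by both solvers."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimulationResult"]


@dataclass
class SimulationResult:
    """Snapshots of the temperature field plus the front trajectory.

    ``positions[i]`` are node coordinates (m, measured from the surface;
    0 = surface, δ/2 = center) for snapshot ``i``; the grid moves while the
    two-region scheme is active, so coordinates are stored per snapshot.
    ``interface_trajectory`` holds (t, Y) pairs of the evaporation front.
    ``events`` maps phase-change milestones to times in seconds
    (``crust_formed_at``, ``switched_single_region_at``, ``completed_at``,
    ``ended_at``; missing milestones are ``None``).
    """

    times: np.ndarray
    positions: list
    temperatures: list
    interface_trajectory: np.ndarray
    events: dict
    method: str
    boiling_mode: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("snapshot times must be strictly increasing")
        self.times = t
        self.interface_trajectory = np.asarray(self.interface_trajectory, dtype=float)

    # -- accessors ----------------------------------------------------------

    def center_temperature(self) -> np.ndarray:
        """Temperature at the symmetry plane, one value per snapshot."""
        return np.array([T[-1] for T in self.temperatures])

    def surface_temperature(self) -> np.ndarray:
        return np.array([T[0] for T in self.temperatures])

    def temperature_at(self, y: float) -> np.ndarray:
        """Linear-interpolated temperature history at depth ``y`` (m)."""
        out = np.empty(self.times.size)
        for i, (pos, T) in enumerate(zip(self.positions, self.temperatures)):
            out[i] = np.interp(y, pos, T)
        return out

    def center_history(self, t_grid: np.ndarray) -> np.ndarray:
        """Center temperature interpolated onto an arbitrary time grid."""
        return np.interp(t_grid, self.times, self.center_temperature())

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: time_s, position_mm, temperature_c."""
        rows = {
            "time_s": np.concatenate(
                [np.full(len(p), t) for t, p in zip(self.times, self.positions)]
            ),
            "position_mm": np.concatenate(self.positions) * 1e3,
            "temperature_c": np.concatenate(self.temperatures),
        }
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def events_payload(self) -> dict:
        return {
            "method": self.method,
            "boiling_mode": self.boiling_mode,
            "events": self.events,
            "interface_trajectory_final_m": (
                float(self.interface_trajectory[-1, 1])
                if self.interface_trajectory.size
                else None
            ),
            "meta": self.meta,
        }

    def write_events(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.events_payload(), fh, indent=2, default=float)
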