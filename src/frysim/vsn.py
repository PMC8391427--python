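"""Two-region Variable Space Network (Murray–Landis) frying solver.

The half-slab [0, δ/2] starts as a single water-saturated core heated
convectively. Once the surface reaches the boiling temperature a thin crust
is seeded and the computation switches to two moving grids with a fixed
number of increments each: the crust grid stretches and the core grid
shrinks as the evaporation front advances. The front velocity comes from
the Stefan balance (net conducted flux / latent load), with temperatures
carried as θ = T − Tb so the front sits at θ = 0. When the front comes
within a small fraction of the thickness from the center the remnant core
is absorbed into a single crust region, which continues sensible heating.

All updates are explicit; the time step is re-limited every step because
the shrinking core increment tightens the diffusion stability bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .properties import (
    BoilingModel,
    FryingConditions,
    PropertySet,
    _DictMixin,
    boiling_temperature,
)
from .result import SimulationResult

__all__ = ["VSNConfig", "simulate_vsn", "stable_timestep"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VSNConfig(_DictMixin):
    """Numerical controls of the two-region scheme.

    ``J`` spatial increments per region; ``dt_safety`` fraction of the
    stability-limited step; ``seed_crust_fraction`` initial crust thickness
    as a fraction of the full thickness δ (1–2.5% is thick enough to keep
    the seeded increment from collapsing the time step and thin enough that
    the assumed linear seed profile is harmless); ``switch_fraction``
    front-to-center distance (fraction of δ) that triggers the collapse to
    a single region; ``dy_cfl`` caps the front advance per step as a
    fraction of the smaller increment.
    """

    J: int = 8
    dt_safety: float = 0.45
    seed_crust_fraction: float = 0.02
    switch_fraction: float = 0.02
    t_max: float = 1800.0
    stop_center_temp: float | None = None
    record_interval: float = 1.0
    dy_cfl: float = 0.25

    def __post_init__(self):
        if self.J < 4:
            raise ValueError("J must be >= 4")
        if not 0 < self.dt_safety <= 1:
            raise ValueError("dt_safety must lie in (0, 1]")
        if not 0.01 <= self.seed_crust_fraction <= 0.025:
            raise ValueError("seed_crust_fraction must lie in [0.01, 0.025]")
        if self.switch_fraction <= 0 or self.switch_fraction >= 0.25:
            raise ValueError("switch_fraction must lie in (0, 0.25)")
        if self.t_max <= 0 or self.record_interval <= 0:
            raise ValueError("t_max and record_interval must be > 0")
        if not 0 < self.dy_cfl <= 1:
            raise ValueError("dy_cfl must lie in (0, 1]")

    @classmethod
    def default(cls) -> "VSNConfig":
        return cls()


def stable_timestep(alpha: float, dy: float, safety: float) -> float:
    """Diffusion-limited explicit step: safety · dy² / (2·α)."""
    if alpha <= 0 or dy <= 0 or safety <= 0:
        raise ValueError("stable_timestep arguments must be > 0")
    return safety * 0.5 * dy * dy / alpha


class _Recorder:
    def __init__(self, interval: float):
        self.interval = interval
        self.times: list[float] = []
        self.positions: list[np.ndarray] = []
        self.temps: list[np.ndarray] = []
        self.front: list[tuple[float, float]] = []
        self._next = 0.0

    def maybe(self, t, pos, T, Y, force=False):
        if force or t >= self._next:
            if not self.times or t > self.times[-1] + 1e-12:
                self.times.append(t)
                self.positions.append(np.array(pos, dtype=float))
                self.temps.append(np.array(T, dtype=float))
                self.front.append((t, Y))
            while self._next <= t:
                self._next += self.interval


def _check_field(T, cond, t, label):
    T = np.asarray(T)
    lo, hi = min(cond.T_init, cond.T_oil) - 1.0, max(cond.T_init, cond.T_oil) + 1.0
    if not np.all(np.isfinite(T)) or T.min() < lo or T.max() > hi:
        raise RuntimeError(
            f"VSN instability in {label} at t={t:.4f} s: field range "
            f"[{np.nanmin(T):.2f}, {np.nanmax(T):.2f}] °C exceeds [{lo}, {hi}]"
        )


def simulate_vsn(
    props: PropertySet,
    cond: FryingConditions,
    boil: BoilingModel,
    cfg: VSNConfig | None = None,
) -> SimulationResult:
    """Run the two-region moving-boundary simulation; see module docstring."""
    cfg = cfg or VSNConfig()
    L = cond.half_thickness
    delta = cond.thickness_delta
    J = cfg.J
    a_co, a_cr = props.alpha_core, props.alpha_crust
    rho_cp_co = props.rho_core * props.cp_core
    rho_cp_cr = props.rho_crust * props.cp_crust
    latent_load = props.rho_core * props.w * props.lambda_w
    stop_T = cond.T_oil - 1.0 if cfg.stop_center_temp is None else cfg.stop_center_temp

    rec = _Recorder(cfg.record_interval)
    events = {
        "crust_formed_at": None,
        "switched_single_region_at": None,
        "completed_at": None,
        "ended_at": None,
    }
    retreat_steps = 0
    t = 0.0

    # ------------------------------------------------------------------ A
    # single-region sensible heating of the fresh disc
    nA = 2 * J + 1
    dyA = L / (nA - 1)
    gridA = np.linspace(0.0, L, nA)
    T = np.full(nA, float(cond.T_init))
    Tb = boiling_temperature(0.0, delta, boil)
    dtA = min(
        stable_timestep(a_co, dyA, cfg.dt_safety),
        cfg.dt_safety * (rho_cp_co * dyA / 2) / (cond.h_sensible + props.k_core / dyA),
    )
    rec.maybe(t, gridA, T, 0.0, force=True)
    while T[0] < Tb and t < cfg.t_max:
        Tn = T.copy()
        Tn[0] = T[0] + dtA * (
            cond.h_sensible * (cond.T_oil - T[0]) - props.k_core * (T[0] - T[1]) / dyA
        ) / (rho_cp_co * dyA / 2)
        Tn[1:-1] = T[1:-1] + a_co * dtA * (T[2:] - 2 * T[1:-1] + T[:-2]) / dyA**2
        Tn[-1] = T[-1] + a_co * dtA * 2 * (T[-2] - T[-1]) / dyA**2
        T = Tn
        t += dtA
        _check_field(T, cond, t, "phase A")
        rec.maybe(t, gridA, T, 0.0)

    if T[0] < Tb:  # never boiled (e.g. equilibrium input)
        events["ended_at"] = t
        rec.maybe(t, gridA, T, 0.0, force=True)
        return _build(rec, events, boil, cfg, retreat_steps, Tb)

    events["crust_formed_at"] = t
    log.info("crust seeded at t=%.2f s (surface %.2f °C)", t, T[0])

    # ------------------------------------------------------------------ B
    # two moving grids, front advanced by the Stefan balance
    Y = cfg.seed_crust_fraction * delta
    Tb = boiling_temperature(Y, delta, boil)
    th_cr = np.linspace(T[0] - Tb, 0.0, J + 1)  # linear seed profile
    core_y = Y + np.arange(J + 1) / J * (L - Y)
    th_co = np.interp(core_y, gridA, T) - Tb
    th_co[0] = 0.0
    rec.maybe(t, _positions(Y, L, J), _temps(th_cr, th_co, Tb), Y, force=True)

    while t < cfg.t_max:
        dy_cr = Y / J
        dy_co = (L - Y) / J
        # Stefan balance with second-order one-sided gradients at the front
        v = (
            props.k_crust * (4 * th_cr[J - 1] - th_cr[J - 2]) / (2 * dy_cr)
            + props.k_core * (4 * th_co[1] - th_co[2]) / (2 * dy_co)
        ) / latent_load
        if v < 0:
            v = 0.0
            retreat_steps += 1
        dt = min(
            stable_timestep(a_cr, dy_cr, cfg.dt_safety),
            stable_timestep(a_co, dy_co, cfg.dt_safety),
            cfg.dt_safety
            * (rho_cp_cr * dy_cr / 2)
            / (cond.h_boiling + props.k_crust / dy_cr),
        )
        if v > 0:
            dt = min(dt, cfg.dy_cfl * min(dy_cr, dy_co) / v)
        dY = v * dt
        Y_new = min(Y + dY, L * (1 - 1e-9))
        dY = Y_new - Y

        new_cr = th_cr.copy()
        j = np.arange(1, J)
        new_cr[j] = (
            th_cr[j]
            + j * (th_cr[j + 1] - th_cr[j - 1]) * dY / (2 * Y)
            + a_cr * dt * J**2 * (th_cr[j + 1] - 2 * th_cr[j] + th_cr[j - 1]) / Y**2
        )
        new_cr[0] = th_cr[0] + dt * (
            cond.h_boiling * (cond.T_oil - (th_cr[0] + Tb))
            - props.k_crust * (th_cr[0] - th_cr[1]) / dy_cr
        ) / (rho_cp_cr * dy_cr / 2)
        new_cr[J] = 0.0

        new_co = th_co.copy()
        m = np.arange(1, J)
        new_co[m] = (
            th_co[m]
            + (J - m) * (th_co[m + 1] - th_co[m - 1]) * dY / (2 * (L - Y))
            + a_co * dt * J**2 * (th_co[m + 1] - 2 * th_co[m] + th_co[m - 1]) / (L - Y) ** 2
        )
        new_co[J] = th_co[J] + a_co * dt * J**2 * 2 * (th_co[J - 1] - th_co[J]) / (L - Y) ** 2
        new_co[0] = 0.0

        th_cr, th_co, Y = new_cr, new_co, Y_new
        t += dt

        if boil.mode == "variable":
            Tb_new = boiling_temperature(Y, delta, boil)
            if Tb_new != Tb:
                shift = Tb - Tb_new  # keep physical temperatures continuous
                th_cr += shift
                th_co += shift
                th_cr[J] = 0.0
                th_co[0] = 0.0
                Tb = Tb_new

        _check_field(_temps(th_cr, th_co, Tb), cond, t, "phase B")
        rec.maybe(t, _positions(Y, L, J), _temps(th_cr, th_co, Tb), Y)
        if L - Y <= cfg.switch_fraction * delta:
            break

    events["switched_single_region_at"] = t
    events["completed_at"] = t
    log.info("single-region switch at t=%.2f s (front %.4f mm)", t, Y * 1e3)
    rec.maybe(t, _positions(Y, L, J), _temps(th_cr, th_co, Tb), Y, force=True)

    # ------------------------------------------------------------------ C
    # remnant core absorbed; sensible heating of an all-crust slab
    gridC = np.linspace(0.0, L, nA)
    T = np.interp(gridC, _positions(Y, L, J), _temps(th_cr, th_co, Tb))
    dyC = L / (nA - 1)
    dtC = min(
        stable_timestep(a_cr, dyC, cfg.dt_safety),
        cfg.dt_safety * (rho_cp_cr * dyC / 2) / (cond.h_sensible + props.k_crust / dyC),
    )
    while t < cfg.t_max and T[-1] < stop_T:
        Tn = T.copy()
        Tn[0] = T[0] + dtC * (
            cond.h_sensible * (cond.T_oil - T[0]) - props.k_crust * (T[0] - T[1]) / dyC
        ) / (rho_cp_cr * dyC / 2)
        Tn[1:-1] = T[1:-1] + a_cr * dtC * (T[2:] - 2 * T[1:-1] + T[:-2]) / dyC**2
        Tn[-1] = T[-1] + a_cr * dtC * 2 * (T[-2] - T[-1]) / dyC**2
        T = Tn
        t += dtC
        _check_field(T, cond, t, "phase C")
        rec.maybe(t, gridC, T, Y)

    events["ended_at"] = t
    rec.maybe(t, gridC, T, Y, force=True)
    return _build(rec, events, boil, cfg, retreat_steps, Tb)


def _positions(Y, L, J):
    crust = np.arange(J + 1) / J * Y
    core = Y + np.arange(1, J + 1) / J * (L - Y)
    return np.concatenate([crust, core])


def _temps(th_cr, th_co, Tb):
    return np.concatenate([th_cr, th_co[1:]]) + Tb


def _build(rec, events, boil, cfg, retreat_steps, Tb):
    return SimulationResult(
        times=np.array(rec.times),
        positions=rec.positions,
        temperatures=rec.temps,
        interface_trajectory=np.array(rec.front) if rec.front else np.empty((0, 2)),
        events=events,
        method="vsn",
        boiling_mode=boil.mode,
        meta={
            "config": cfg.to_dict(),
            "retreat_steps": retreat_steps,
            "Tb_final": Tb,
        },
    )
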