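"""Thermophysical property types and relations for the crust/core frying model.

The disc is treated as two regions separated by a moving evaporation front:
a dry, porous *crust* next to the oil and a water-saturated *core* inside.
This module houses the property containers, the enthalpy--temperature
relation used by the single-domain solver (and its exact inverse), the
mushy-zone mixing rules, the in-tissue boiling-temperature model, and the
least-squares fitter that calibrates the boiling-point-elevation correlation
from (water loss, elevation) measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields, asdict

import numpy as np
import pandas as pd

__all__ = [
    "PropertySet",
    "FryingConditions",
    "BoilingModel",
    "MushyState",
    "ElevationDataset",
    "boiling_temperature",
    "enthalpy_of_temperature",
    "temperature_of_enthalpy",
    "volumetric_enthalpy",
    "thermal_diffusivity",
    "crust_fraction",
    "mushy_density",
    "fit_boiling_elevation",
]

#: Latent heat of vaporization of water at its normal boiling point, J/kg.
LATENT_HEAT_WATER = 2.2565e6


class _DictMixin:
    """Strict dict (de)serialization shared by the config-block dataclasses."""

    @classmethod
    def from_dict(cls, d: dict):
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(
                f"{cls.__name__}: unknown config keys {sorted(unknown)}"
            )
        base = asdict(cls.default()) if hasattr(cls, "default") else {}
        base.update(d)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PropertySet(_DictMixin):
    """Thermophysical constants of the disc, per region.

    Attributes
    ----------
    k_core, k_crust : float
        Thermal conductivities, W/(m·K).
    rho_core, rho_crust : float
        Densities, kg/m³.
    cp_core, cp_crust : float
        Specific heat capacities, J/(kg·K).
    w : float
        Moisture mass fraction of the fresh tissue, dimensionless in (0, 1).
    lambda_w : float
        Latent heat of water vaporization, J/kg.
    """

    k_core: float = 0.73
    k_crust: float = 0.11
    rho_core: float = 1132.0
    rho_crust: float = 386.0
    cp_core: float = 3450.0
    cp_crust: float = 1790.0
    w: float = 0.738
    lambda_w: float = LATENT_HEAT_WATER

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"PropertySet.{f.name} must be finite and > 0, got {v}")
        if not 0.0 < self.w < 1.0:
            raise ValueError(f"moisture fraction w must lie in (0, 1), got {self.w}")

    @classmethod
    def default(cls) -> "PropertySet":
        return cls()

    @property
    def alpha_core(self) -> float:
        return thermal_diffusivity(self.k_core, self.rho_core, self.cp_core)

    @property
    def alpha_crust(self) -> float:
        return thermal_diffusivity(self.k_crust, self.rho_crust, self.cp_crust)


@dataclass(frozen=True)
class FryingConditions(_DictMixin):
    """Bath and geometry parameters of a frying run.

    ``h_sensible`` applies while the disc surface exchanges sensible heat
    only; ``h_boiling`` applies while vapor leaves through the surface and
    agitates the oil film. ``thickness_delta`` is the full disc thickness
    (the solvers work on the symmetric half-slab). ``Tb0`` is the initial
    in-tissue water boiling temperature.
    """

    T_oil: float = 180.0
    T_init: float = 20.0
    h_sensible: float = 250.0
    h_boiling: float = 500.0
    thickness_delta: float = 0.005
    Tb0: float = 103.0

    def __post_init__(self):
        if self.thickness_delta <= 0:
            raise ValueError("thickness_delta must be > 0")
        if self.h_sensible <= 0 or self.h_boiling <= 0:
            raise ValueError("convection coefficients must be > 0")
        if not self.T_oil > self.Tb0 > self.T_init:
            # equilibrium runs (T_oil == T_init) are allowed for diagnostics
            if not (self.T_oil == self.T_init):
                raise ValueError(
                    "a frying run requires T_oil > Tb0 > T_init "
                    f"(got T_oil={self.T_oil}, Tb0={self.Tb0}, T_init={self.T_init})"
                )

    @classmethod
    def default(cls) -> "FryingConditions":
        return cls()

    @property
    def half_thickness(self) -> float:
        return 0.5 * self.thickness_delta


@dataclass(frozen=True)
class BoilingModel(_DictMixin):
    """In-tissue water boiling temperature as the front advances.

    ``mode='fixed'`` keeps the boiling temperature at ``Tb0``. In
    ``mode='variable'`` the elevation grows exponentially with the
    normalized front position x = Ym/(δ/2):

        Tb(x) = min(Tb0 + coeff_A · exp(coeff_B · x), cap)

    reflecting solute concentration in the shrinking wet core.  ``shift``
    is the nucleation correction (°C) added to measured elevations during
    correlation fitting only; the simulation baseline ``Tb0`` already
    embodies the superheat of bubble nucleation at the front.  ``cap``
    clamps the boiling temperature below the oil temperature, since the
    convectively heated surface can never exceed it.
    """

    mode: str = "fixed"
    Tb0: float = 103.0
    coeff_A: float = 7e-10
    coeff_B: float = 25.455
    shift: float = 3.0
    cap: float = 179.5

    def __post_init__(self):
        if self.mode not in ("fixed", "variable"):
            raise ValueError(f"mode must be 'fixed' or 'variable', got {self.mode!r}")
        if self.coeff_A < 0 or self.coeff_B < 0:
            raise ValueError("coeff_A and coeff_B must be >= 0")

    @classmethod
    def default(cls) -> "BoilingModel":
        return cls()


@dataclass(frozen=True)
class MushyState(_DictMixin):
    """State of a node inside the narrow evaporation band Tb ± ε."""

    X: float = 0.0
    rho_mushy: float = 1132.0
    epsilon: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.X <= 1.0:
            raise ValueError("crust fraction X must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass(frozen=True)
class ElevationDataset:
    """Ordered (water-loss %, boiling-temperature elevation °C) pairs."""

    water_loss_percent: np.ndarray
    delta_tb: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.water_loss_percent, dtype=float)
        dt = np.asarray(self.delta_tb, dtype=float)
        if wl.shape != dt.shape or wl.ndim != 1:
            raise ValueError("water_loss_percent and delta_tb must be 1-D and equal length")
        if np.any((wl < 0) | (wl > 100)):
            raise ValueError("water_loss_percent must lie within [0, 100]")
        if np.any(dt < 0):
            raise ValueError("delta_tb must be >= 0")
        object.__setattr__(self, "water_loss_percent", wl)
        object.__setattr__(self, "delta_tb", dt)

    def __len__(self) -> int:
        return self.water_loss_percent.size

    @classmethod
    def from_csv(cls, path) -> "ElevationDataset":
        df = pd.read_csv(path)
        required = {"water_loss_percent", "delta_tb_c"}
        if not required.issubset(df.columns):
            raise ValueError(f"elevation CSV must have columns {sorted(required)}")
        return cls(df["water_loss_percent"].to_numpy(), df["delta_tb_c"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"water_loss_percent": self.water_loss_percent, "delta_tb_c": self.delta_tb}
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# relations


def boiling_temperature(Ym: float, delta: float, model: BoilingModel) -> float:
    """In-tissue boiling temperature for front position ``Ym`` (m from surface).

    Non-decreasing in ``Ym``; clamped at ``model.cap`` in variable mode.
    """
    half = 0.5 * delta
    if not -1e-12 <= Ym <= half * (1 + 1e-9):
        raise ValueError(f"front position Ym={Ym} outside [0, delta/2={half}]")
    if model.mode == "fixed":
        return model.Tb0
    x = min(max(Ym / half, 0.0), 1.0)
    return min(model.Tb0 + model.coeff_A * np.exp(model.coeff_B * x), model.cap)


def enthalpy_of_temperature(T, props: PropertySet, Tb: float, epsilon: float):
    """Specific enthalpy H(T), J/kg, of the evaporation-band formulation.

    Three branches: core sensible below Tb−ε, a steep mixed branch carrying
    the latent load w·λ_w across the band, crust sensible above Tb+ε.
    Continuous and strictly increasing. Accepts scalars or arrays.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    T = np.asarray(T, dtype=float)
    Cco, Ccr = props.cp_core, props.cp_crust
    slope_m = 0.5 * (Cco + Ccr) + props.w * props.lambda_w / (2.0 * epsilon)
    T1, T2 = Tb - epsilon, Tb + epsilon
    H_core = Cco * T
    H_mushy = (T - T1) * slope_m + Cco * T1
    H_crust = Ccr * T + props.w * props.lambda_w + (Cco - Ccr) * Tb
    out = np.where(T < T1, H_core, np.where(T > T2, H_crust, H_mushy))
    return out if out.ndim else float(out)


def temperature_of_enthalpy(H, props: PropertySet, Tb: float, epsilon: float):
    """Exact piecewise-linear inverse of :func:`enthalpy_of_temperature`."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    H = np.asarray(H, dtype=float)
    Cco, Ccr = props.cp_core, props.cp_crust
    slope_m = 0.5 * (Cco + Ccr) + props.w * props.lambda_w / (2.0 * epsilon)
    T1 = Tb - epsilon
    H1 = Cco * T1
    H2 = H1 + 2.0 * epsilon * slope_m
    T_core = H / Cco
    T_mushy = T1 + (H - H1) / slope_m
    T_crust = (H - props.w * props.lambda_w - (Cco - Ccr) * Tb) / Ccr
    out = np.where(H < H1, T_core, np.where(H > H2, T_crust, T_mushy))
    return out if out.ndim else float(out)


def volumetric_enthalpy(
    T, props: PropertySet, Tb: float, epsilon: float, density_rule: str = "core"
):
    """Volumetric enthalpy state function E(T) = ∫₀ᵀ ρ(T') dH(T'), J/m³.

    ``density_rule`` mirrors the capacity-density convention of the
    enthalpy solver: ``"core"`` keeps ρ_core across the evaporation band
    (the wet tissue holds the water being boiled off, so the latent load
    per volume is ρ_core·w·λ_w, consistent with the Stefan balance);
    ``"mixture"`` uses the linear mushy mixture, making the band segment
    quadratic. Used by the energy audit as an independent check.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if density_rule not in ("core", "mixture"):
        raise ValueError(f"unknown density_rule {density_rule!r}")
    T = np.asarray(T, dtype=float)
    Cco, Ccr = props.cp_core, props.cp_crust
    rco, rcr = props.rho_core, props.rho_crust
    slope_m = 0.5 * (Cco + Ccr) + props.w * props.lambda_w / (2.0 * epsilon)
    T1, T2 = Tb - epsilon, Tb + epsilon
    E1 = rco * Cco * T1
    tau = np.clip(T - T1, 0.0, 2.0 * epsilon)
    if density_rule == "core":
        E_mushy = E1 + slope_m * rco * tau
        E2 = E1 + slope_m * rco * 2.0 * epsilon
    else:
        E_mushy = E1 + slope_m * (rco * tau + (rcr - rco) * tau**2 / (4.0 * epsilon))
        E2 = E1 + slope_m * (rco * 2.0 * epsilon + (rcr - rco) * epsilon)
    out = np.where(
        T < T1, rco * Cco * T, np.where(T > T2, E2 + rcr * Ccr * (T - T2), E_mushy)
    )
    return out if out.ndim else float(out)


def thermal_diffusivity(k: float, rho: float, cp: float) -> float:
    """α = k / (ρ·cp), m²/s."""
    if k <= 0 or rho <= 0 or cp <= 0:
        raise ValueError("thermal_diffusivity arguments must all be > 0")
    return k / (rho * cp)


def crust_fraction(T, Tb: float, epsilon: float, *, warn_out_of_band: bool = False):
    """Crust fraction X across the evaporation band: X = (T − (Tb−ε)) / 2ε.

    Linear map of [Tb−ε, Tb+ε] onto [0, 1]. Inputs outside the band are
    clamped (explicit stepping may overshoot by a fraction of a step);
    set ``warn_out_of_band`` to be told when that happens.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    T = np.asarray(T, dtype=float)
    X = (T - (Tb - epsilon)) / (2.0 * epsilon)
    if warn_out_of_band and np.any((X < -1e-9) | (X > 1 + 1e-9)):
        warnings.warn("crust_fraction input outside the mushy band; clamped", stacklevel=2)
    X = np.clip(X, 0.0, 1.0)
    return X if X.ndim else float(X)


def mushy_density(X, props: PropertySet):
    """Mushy-zone density: ρ = (1−X)·ρ_core + X·ρ_crust."""
    X = np.asarray(X, dtype=float)
    if np.any((X < -1e-12) | (X > 1 + 1e-12)):
        raise ValueError("crust fraction X must lie in [0, 1]")
    out = (1.0 - X) * props.rho_core + X * props.rho_crust
    return out if out.ndim else float(out)


def fit_boiling_elevation(
    data: ElevationDataset, shift: float = 3.0
) -> tuple[float, float]:
    """Fit ΔTb = A·exp(B·x) to shifted elevation data; returns (A, B).

    The measured elevations are first raised by ``shift`` (the nucleation
    correction for steam bubbles at the superheated front, absent in the
    extracted-liquid boiling experiment the data come from).  Water-loss
    percentage maps linearly to the normalized front position x = loss/100.
    The fit is least squares on ln(ΔTb) = ln A + B·x, weighted by ΔTb²
    (the inverse delta-method variance when the measurement noise is
    additive in °C), so near-zero elevations do not destabilize the slope.

    Points whose shifted elevation is not strictly positive are dropped
    with a warning; fewer than 3 usable points is an error.
    """
    x_all = data.water_loss_percent / 100.0
    y_all = data.delta_tb + shift
    keep = y_all > 0
    if np.any(~keep):
        warnings.warn(
            f"fit_boiling_elevation: dropped {int(np.sum(~keep))} point(s) with "
            "non-positive shifted elevation",
            stacklevel=2,
        )
    x, y = x_all[keep], y_all[keep]
    if x.size < 3:
        raise ValueError(f"need at least 3 usable points, have {x.size}")
    # np.polyfit weights multiply residuals, so pass sqrt of the weight
    coeffs = np.polyfit(x, np.log(y), 1, w=y)
    B, lnA = float(coeffs[0]), float(coeffs[1])
    return float(np.exp(lnA)), B


def elevation_curve(x, A: float, B: float):
    """Evaluate the fitted elevation correlation ΔTb = A·exp(B·x)."""
    return A * np.exp(B * np.asarray(x, dtype=float))
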