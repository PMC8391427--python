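"""Closed-form quasi-steady estimate of the complete frying time.

Sensible heat is neglected (it is a few percent of the latent load), the
crust conducts in quasi-steady state, and the front consumes latent heat
ρ_core·λ_w·w per unit volume swept.  The time for the front to cross the
half-slab splits into an oil-film term and a crust-conduction term:

    β = (T_oil − Tb0) / (ρ_core · λ_w · w)
    t = (1/β) · ( δ/(2·h_boiling) + δ²/(8·k_crust) )
"""

from __future__ import annotations

from .properties import FryingConditions, PropertySet

__all__ = ["frying_time", "frying_time_terms"]


def frying_time_terms(
    props: PropertySet,
    cond: FryingConditions,
    moisture_override: float | None = None,
) -> tuple[float, float]:
    """Return the (oil-film, crust-conduction) contributions in seconds."""
    w_eff = props.w if moisture_override is None else moisture_override
    if not 0.0 < w_eff < 1.0:
        raise ValueError(f"moisture fraction must lie in (0, 1), got {w_eff}")
    drive = cond.T_oil - cond.Tb0
    if drive <= 0:
        raise ValueError("frying requires T_oil > Tb0")
    denom = props.rho_core * props.lambda_w * w_eff
    beta = drive / denom
    delta = cond.thickness_delta
    film = (delta / (2.0 * cond.h_boiling)) / beta
    conduction = (delta**2 / (8.0 * props.k_crust)) / beta
    return film, conduction


def frying_time(
    props: PropertySet,
    cond: FryingConditions,
    moisture_override: float | None = None,
) -> float:
    """Quasi-steady complete-frying time of the disc, seconds."""
    film, conduction = frying_time_terms(props, cond, moisture_override)
    return film + conduction
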