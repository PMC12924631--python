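"""Metabolizable energy intake, feed intake, thermal environment, and space.

The intake curves saturate in body weight. Feed intake is capped at the
environmental maximum; when the cap binds, metabolizable energy intake is
rescaled to the energy actually consumable from the capped feed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Environment",
    "EnergyBudget",
    "mei",
    "feed_intake",
    "lct",
    "min_space",
    "max_fi",
    "maintenance_me",
    "energy_budget",
]


@dataclass(frozen=True)
class Environment:
    temperature: float  # degC
    space_per_pig: float = float("inf")  # m^2
    pen_id: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature):
            raise ValueError("temperature must be finite")
        if self.space_per_pig <= 0:
            raise ValueError("space_per_pig must be > 0")


@dataclass(slots=True)
class EnergyBudget:
    mei: float      # kcal/d
    stdm_me: float  # kcal/d
    me_therm: float  # kcal/d
    m_me: float     # kcal/d
    adj: float      # kcal/d
    fi: float       # kg/d, after capping
    max_fi: float   # g/d
    lct: float      # degC
    min_space: float  # m^2
    fi_capped: bool = False


def mei(bw: float, params) -> float:
    """Metabolizable energy intake, kcal/d: a * (1 - exp(-exp(b) * BW^c))."""
    return params.mei_a * (1.0 - math.exp(-math.exp(params.mei_b) * bw**params.mei_c))


def feed_intake(bw: float, params, config) -> float:
    """Ad libitum feed intake, kg/d (uncapped).

    Sexes with an intake curve use ``x * (1 - exp(-exp(y) * BW^z))``; sexes
    without one (boars by default) fall back to the energy route
    ``MEI / (me_content * (1 - feed_wastage))`` so the feed and energy books
    stay consistent.
    """
    if params.fi_x is not None:
        return params.fi_x * (1.0 - math.exp(-math.exp(params.fi_y) * bw**params.fi_z))
    return mei(bw, params) / (config.me_content * (1.0 - config.feed_wastage))


def lct(bw: float) -> float:
    """Lower critical temperature, degC."""
    return 17.9 - 0.0375 * bw


def min_space(bw: float) -> float:
    """Minimum floor space for unconstrained energy intake, m^2/pig."""
    return 0.0336 * bw**0.667


def max_fi(bw: float, temperature: float) -> float:
    """Maximum daily feed intake, g/d, floored at zero.

    Temperatures below the lower critical temperature raise the ceiling by
    2.5% per degC; temperatures above it lower it (heat-stress reading, no
    upper clamp).
    """
    base = 111.0 * bw**0.803
    return max(0.0, base * (1.0 + (lct(bw) - temperature) * 0.025))


def maintenance_me(bw: float, temperature: float, adj: float = 0.0) -> tuple[float, float, float]:
    """(standard maintenance, thermogenesis, total maintenance) in kcal/d.

    Thermogenesis is clamped at zero for temperatures at or above the lower
    critical temperature; maintenance never falls below standard.
    """
    stdm = 197.0 * bw**0.6
    below = lct(bw) - temperature
    therm = 0.07425 * below * stdm if below > 0 else 0.0
    return stdm, therm, stdm + therm + adj


def energy_budget(bw: float, params, config) -> EnergyBudget:
    """Full daily energy/feed budget for one pig at one body weight."""
    lct_v = lct(bw)
    maxfi_g = max_fi(bw, config.temperature)
    stdm, therm, m_me = maintenance_me(bw, config.temperature, config.me_adj)
    mei_v = mei(bw, params)
    fi_v = feed_intake(bw, params, config)
    cap_kg = maxfi_g / 1000.0
    capped = fi_v > cap_kg
    if capped:
        fi_v = cap_kg
        mei_v = fi_v * config.me_content * (1.0 - config.feed_wastage)
    return EnergyBudget(
        mei=mei_v, stdm_me=stdm, me_therm=therm, m_me=m_me, adj=config.me_adj,
        fi=fi_v, max_fi=maxfi_g, lct=lct_v, min_space=min_space(bw),
        fi_capped=capped,
    )
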