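"""Daily growth and body-composition bookkeeping for a single pig.

Body weight is driven by the gain polynomial (g/d, bridged to kg by /1000);
the composition account (protein, lipid, water, ash + gut fill) runs in
parallel and is deliberately not forced to agree with body weight — the
discrepancy is surfaced as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BodyComposition",
    "PigState",
    "bwg_deterministic",
    "bwg_stochastic",
    "update_bw",
    "pd",
    "ld",
    "update_composition",
    "gut_fill",
    "backfat",
    "initialize_composition",
    "water_mass",
]

ASH_PER_PROTEIN = 0.189
WATER_EXPONENT = 0.855


@dataclass(slots=True)
class BodyComposition:
    """Whole-body mass pools (kg) plus derived quantities."""

    bp: float   # protein
    bl: float   # lipid
    bwt: float  # water
    ba: float   # ash
    ebw: float  # empty body weight = bp + bl + bwt + ba
    gutf: float  # gut fill
    pbt: float  # probe backfat thickness, mm


@dataclass(slots=True)
class PigState:
    """One agent's daily state."""

    pig_id: int
    sex: str
    pen_id: str
    barn: int
    day: int
    bw: float
    bw0: float
    composition: BodyComposition
    rng: np.random.Generator
    bwg_today: float = 0.0
    pd_today: float = 0.0
    ld_today: float = 0.0
    removed: bool = False
    removal_day: int | None = None


def bwg_deterministic(bw: float, coeffs: Sequence[float]) -> float:
    """Body-weight gain in g/d from the quadratic polynomial in BW (kg)."""
    c0, c1, c2 = coeffs
    return c0 + c1 * bw + c2 * bw * bw


def bwg_stochastic(
    bw: float,
    coeffs: Sequence[float],
    noise_cv: float,
    rng: np.random.Generator,
) -> float:
    """Gain drawn from Normal(mean, noise_cv * mean), truncated at zero.

    ``noise_cv = 0`` returns the deterministic value exactly (no draw is
    consumed, so deterministic runs do not advance the stream).
    """
    mean = bwg_deterministic(bw, coeffs)
    if noise_cv == 0.0:
        return mean
    return max(0.0, rng.normal(mean, noise_cv * abs(mean)))


def update_bw(state: PigState, bwg: float) -> PigState:
    """Apply one day's gain (g/d, divided by 1000) and advance the day index."""
    if state.removed:
        raise ValueError(f"pig {state.pig_id} was removed on day {state.removal_day}")
    state.bw += bwg / 1000.0
    state.day += 1
    state.bwg_today = bwg
    return state


def pd(bw: float, params) -> float:
    """Protein deposition, g/d: a * (b + c*BW + d*BW^2 + e*BW^3)."""
    return params.pd_a * (
        params.pd_b + params.pd_c * bw + params.pd_d * bw * bw + params.pd_e * bw**3
    )


def ld(mei: float, m_me: float, pd: float) -> float:
    """Lipid deposition, g/d, from the energy balance.

    May be negative under an energy deficit; callers decide how to floor the
    lipid pool.
    """
    return (mei - m_me - 10.6 * pd) / 12.5


def water_mass(bp: float, pd_max: float) -> float:
    """Whole-body water (kg) allometric in protein mass."""
    return (4.322 + 0.0044 * pd_max) * bp**WATER_EXPONENT


def gut_fill(bw0: float) -> float:
    """Gut content mass (kg) from the pig's initial body weight."""
    return 0.277 * bw0**0.612


def backfat(bp: float, bl: float) -> float:
    """Probe backfat thickness, mm."""
    if bp <= 0:
        raise ValueError("backfat is undefined for non-positive protein mass")
    return -5.0 + 12.3 * (bl / bp) + 0.13 * bp


def update_composition(
    state: PigState, pd: float, ld: float, pd_max: float
) -> BodyComposition:
    """Deposit one day's protein and lipid and recompute the derived pools.

    Lipid mass is floored at zero even when ``ld`` is negative.
    """
    comp = state.composition
    comp.bp += pd / 1000.0
    comp.bl = max(0.0, comp.bl + ld / 1000.0)
    comp.bwt = water_mass(comp.bp, pd_max)
    comp.ba = ASH_PER_PROTEIN * comp.bp
    comp.ebw = comp.bp + comp.bl + comp.bwt + comp.ba
    comp.pbt = backfat(comp.bp, comp.bl)
    state.pd_today = pd
    state.ld_today = ld
    return comp


def initialize_composition(
    bw0: float, pd_max: float, lipid_protein_ratio: float = 0.84
) -> BodyComposition:
    """Solve for a starting composition consistent with the initial BW.

    Finds ``bp0`` such that protein + lipid + water + ash + gut fill equals
    ``bw0``, with lipid pinned at ``lipid_protein_ratio * bp0``; bisection to
    |residual| < 1e-9 kg.
    """
    gutf = gut_fill(bw0)
    target = bw0 - gutf
    if target <= 0:
        raise ValueError(f"initial BW {bw0} kg does not exceed its gut fill {gutf:.3f} kg")
    linear = 1.0 + ASH_PER_PROTEIN + lipid_protein_ratio
    w_coef = 4.322 + 0.0044 * pd_max

    def residual(bp: float) -> float:
        return linear * bp + w_coef * bp**WATER_EXPONENT - target

    lo, hi = 0.0, bw0
    if residual(hi) < 0:
        raise ValueError(f"no feasible protein mass in (0, {bw0}) for initial BW {bw0} kg")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-13 * max(1.0, bw0):
            break
    bp0 = 0.5 * (lo + hi)
    if abs(residual(bp0)) > 1e-9:
        raise ValueError("bisection failed to reach 1e-9 kg residual")
    bl0 = lipid_protein_ratio * bp0
    bwt0 = w_coef * bp0**WATER_EXPONENT
    ba0 = ASH_PER_PROTEIN * bp0
    return BodyComposition(
        bp=bp0, bl=bl0, bwt=bwt0, ba=ba0,
        ebw=bp0 + bl0 + bwt0 + ba0, gutf=gutf,
        pbt=backfat(bp0, bl0),
    )
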