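"""Daily nutrient requirements: the SID lysine chain, amino-acid expansion,
phosphorus/calcium, and log-linear mineral/vitamin requirements."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from ._tables import AA_RATIOS, PD_MAX_REFERENCE
from .params import NutrientCoeffs

__all__ = [
    "RequirementReport",
    "git_lysine_loss",
    "integument_lysine_loss",
    "sid_lysine",
    "expand_amino_acids",
    "body_phosphorus_mass",
    "max_p_retention",
    "sttd_p",
    "total_calcium",
    "micronutrients",
    "fdmi",
    "requirement_report",
    "CA_PER_STTD_P",
]

CA_PER_STTD_P = 2.15


@dataclass
class RequirementReport:
    """One pig-day's full requirement set, units embedded in field docs."""

    pig_id: int
    day: int
    sex: str
    bw: float                 # kg
    fdmi: float               # kg/d
    git_lys: float            # g/d
    i_lys: float              # g/d
    sid_lys1: float           # g/d
    sid_lys2: float           # g/d
    sid_lysine: float         # g/d
    amino_acids: dict[str, float]   # g/d
    body_p_mass: float        # g
    max_p_retention: float    # g/d
    sttd_p: float             # g/d
    total_ca: float           # g/d
    minerals: dict[str, float] = field(default_factory=dict)
    vitamins: dict[str, float] = field(default_factory=dict)


def fdmi(fi: float, fdm: float) -> float:
    """Feed dry-matter intake, kg/d."""
    if not 0 < fdm <= 1:
        raise ValueError(f"fdm must lie in (0, 1], got {fdm}")
    return fdm * fi


def git_lysine_loss(fdmi_g: float) -> float:
    """Basal endogenous gastrointestinal lysine loss, g/d, from dry-matter
    intake expressed in grams."""
    return 1.1 * 4.17e-4 * fdmi_g


def integument_lysine_loss(bw: float) -> float:
    """Integument lysine loss, g/d."""
    return 0.0045 * bw**0.75


def _efficiency_denominator(max_pd: float) -> float:
    denom = 0.75 + 0.002 * (max_pd - PD_MAX_REFERENCE)
    if denom <= 0:
        raise ValueError(
            f"lysine efficiency denominator is non-positive ({denom:.4f}) "
            f"for max Pd {max_pd} g/d"
        )
    return denom


def sid_lysine(
    git: float, integ: float, pd: float, bw: float, max_pd: float
) -> tuple[float, float, float]:
    """(maintenance part, deposition part, total) SID lysine, g/d."""
    denom = _efficiency_denominator(max_pd)
    sid1 = (git + integ) / denom
    sid2 = (0.071 * pd) * (1.0547 + 0.002215 * bw) / denom
    return sid1, sid2, sid1 + sid2


def expand_amino_acids(
    sid_lys: float, ratios: Mapping[str, float] = AA_RATIOS
) -> dict[str, float]:
    """Every other essential amino acid (and N) as ratio x total SID lysine."""
    if sid_lys < 0:
        raise ValueError("sid_lysine must be non-negative")
    return {name: ratio * sid_lys for name, ratio in ratios.items()}


def body_phosphorus_mass(bp: float) -> float:
    """Whole-body phosphorus, g, quadratic in protein mass (kg)."""
    return 1.1613 + 26.012 * bp + 0.2299 * bp * bp


def max_p_retention(bp: float, pd: float) -> float:
    """Maximum daily phosphorus retention, g/d.

    Operationalized as the day's increment of whole-body phosphorus along the
    protein trajectory (no closed-form retention model exists).
    """
    return body_phosphorus_mass(bp + pd / 1000.0) - body_phosphorus_mass(bp)


def sttd_p(
    max_p_ret: float, fdmi_kg: float, bw: float, retention_multiplies: bool = False
) -> float:
    """Standardized total-tract digestible phosphorus requirement, g/d.

    The retention term is divided by the 0.77 efficiency by default;
    ``retention_multiplies`` switches to the multiplicative reading.
    """
    ret_term = max_p_ret * 0.77 if retention_multiplies else max_p_ret / 0.77
    return 0.85 * (ret_term + 0.19 * fdmi_kg + 0.007 * bw)


def total_calcium(sttd_p_value: float) -> float:
    """Total calcium requirement, g/d: a fixed multiple of STTD P."""
    return CA_PER_STTD_P * sttd_p_value


def micronutrients(
    bw: float, coeffs: Iterable[NutrientCoeffs]
) -> dict[str, dict[str, float]]:
    """Evaluate all log-linear mineral/vitamin requirements at one BW.

    Returns ``{"minerals": {name: value}, "vitamins": {name: value}}`` in each
    nutrient's own printed units.
    """
    out: dict[str, dict[str, float]] = {"minerals": {}, "vitamins": {}}
    log_bw = math.log(bw)
    for nc in coeffs:
        bucket = "minerals" if nc.klass == "mineral" else "vitamins"
        out[bucket][nc.nutrient] = nc.intercept + nc.slope * log_bw
    return out


def requirement_report(
    *,
    pig_id: int,
    day: int,
    sex: str,
    bw: float,
    bp: float,
    pd: float,
    fi: float,
    fdm: float,
    max_pd: float,
    retention_multiplies: bool = False,
    micronutrient_coeffs: Iterable[NutrientCoeffs] | None = None,
) -> RequirementReport:
    """Assemble the full requirement chain for one pig-day."""
    fdmi_kg = fdmi(fi, fdm)
    git = git_lysine_loss(fdmi_kg * 1000.0)
    integ = integument_lysine_loss(bw)
    sid1, sid2, total = sid_lysine(git, integ, pd, bw, max_pd)
    ret = max_p_retention(bp, pd)
    p_req = sttd_p(ret, fdmi_kg, bw, retention_multiplies)
    report = RequirementReport(
        pig_id=pig_id, day=day, sex=sex, bw=bw, fdmi=fdmi_kg,
        git_lys=git, i_lys=integ, sid_lys1=sid1, sid_lys2=sid2,
        sid_lysine=total, amino_acids=expand_amino_acids(total),
        body_p_mass=body_phosphorus_mass(bp), max_p_retention=ret,
        sttd_p=p_req, total_ca=total_calcium(p_req),
    )
    if micronutrient_coeffs is not None:
        micro = micronutrients(bw, micronutrient_coeffs)
        report.minerals = micro["minerals"]
        report.vitamins = micro["vitamins"]
    return report
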