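"""Coefficient containers, run configuration, and the two least-squares fits.

This module owns everything that parameterizes a run: the per-sex growth and
intake coefficients (:class:`SexParams`), the herd-level configuration
(:class:`HerdConfig`, loadable from a flat JSON/YAML file), and the fitted
log-linear micronutrient coefficients (:class:`NutrientCoeffs`), which are
reconstructed by least squares from the three printed (body weight,
requirement) points per nutrient.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import _tables
from ._tables import (
    AA_RATIOS,
    DEFAULT_BWG_COEFFS,
    MICRONUTRIENT_POINTS,
    MICRONUTRIENT_REFERENCE_BWS,
    SEXES,
)

__all__ = [
    "SexParams",
    "HerdConfig",
    "NutrientCoeffs",
    "ConfigError",
    "load_config",
    "fit_bwg_polynomial",
    "fit_loglinear_coefficients",
    "compute_pd_max",
    "default_sex_params",
    "build_micronutrient_table",
    "load_micronutrient_table",
    "write_micronutrient_csv",
    "AA_RATIOS",
    "SEXES",
]

BW_RANGE = (20.0, 130.0)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass(frozen=True)
class SexParams:
    """All sex-specific coefficients, plus the derived Pd maximum."""

    sex: str
    pd_a: float
    pd_b: float
    pd_c: float
    pd_d: float
    pd_e: float
    mei_a: float
    mei_b: float
    mei_c: float
    fi_x: float | None
    fi_y: float | None
    fi_z: float | None
    bwg_coeffs: tuple[float, float, float] = DEFAULT_BWG_COEFFS
    pd_max: float = float("nan")

    def __post_init__(self) -> None:
        if self.mei_a <= 0:
            raise ConfigError(f"mei_a must be > 0, got {self.mei_a}")
        if self.fi_x is not None and self.fi_x <= 0:
            raise ConfigError(f"fi_x must be > 0, got {self.fi_x}")


def compute_pd_max(params: SexParams, bw_range: tuple[float, float] = BW_RANGE) -> float:
    """Maximum of the protein-deposition cubic over the working BW interval.

    The stationary points of ``a*(b + c*x + d*x^2 + e*x^3)`` solve the
    quadratic ``c + 2d*x + 3e*x^2 = 0``; interior real roots are compared with
    the interval endpoints.
    """
    a, b, c, d, e = params.pd_a, params.pd_b, params.pd_c, params.pd_d, params.pd_e
    lo, hi = bw_range
    candidates = [lo, hi]
    if e != 0.0:
        disc = (2 * d) ** 2 - 4 * (3 * e) * c
        if disc >= 0:
            r = math.sqrt(disc)
            for root in ((-2 * d + r) / (6 * e), (-2 * d - r) / (6 * e)):
                if lo < root < hi:
                    candidates.append(root)
    elif d != 0.0:
        root = -c / (2 * d)
        if lo < root < hi:
            candidates.append(root)
    value = lambda x: a * (b + c * x + d * x * x + e * x**3)  # noqa: E731
    return max(value(x) for x in candidates)


def default_sex_params(
    sex: str,
    bwg_coeffs: Sequence[float] | None = None,
    fi_coeffs: Sequence[float] | None = None,
) -> SexParams:
    """Build the shipped coefficient set for one sex.

    ``fi_coeffs`` provides the (x, y, z) intake-curve override; it is the only
    way to give boars a direct intake curve.
    """
    if sex not in SEXES:
        raise ConfigError(f"unknown sex {sex!r}; expected one of {SEXES}")
    cub = _tables.PD_CUBIC[sex]
    mei = _tables.MEI_COEFFS[sex]
    fi = _tables.FI_COEFFS[sex] if fi_coeffs is None else dict(zip("xyz", fi_coeffs))
    bwg = tuple(bwg_coeffs) if bwg_coeffs is not None else DEFAULT_BWG_COEFFS
    if len(bwg) != 3:
        raise ConfigError(f"bwg_coeffs for {sex} must have 3 entries, got {len(bwg)}")
    base = SexParams(
        sex=sex,
        pd_a=cub["a"], pd_b=cub["b"], pd_c=cub["c"], pd_d=cub["d"], pd_e=cub["e"],
        mei_a=mei["a"], mei_b=mei["b"], mei_c=mei["c"],
        fi_x=fi["x"] if fi else None,
        fi_y=fi["y"] if fi else None,
        fi_z=fi["z"] if fi else None,
        bwg_coeffs=bwg,
    )
    return dataclasses.replace(base, pd_max=compute_pd_max(base))


# ---------------------------------------------------------------------------
# Herd configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HerdConfig:
    n_barns: int = 5
    n_pigs_per_sex: int = 10
    run_days: int = 140
    bw_initial_mean: float = 20.0
    bw_initial_sd: float = 1.0
    bw_final: float = 130.0
    me_content: float = 3300.0
    feed_wastage: float = 0.05
    fdm: float = 0.88
    temperature: float = 20.0
    noise_cv: float = 0.05
    me_adj: float = 0.0
    ractopamine_level: float = 0.0  # inert hook, no response model
    seed: int = 42
    n_replications: int = 500
    sexes: tuple[str, ...] = SEXES
    lipid_protein_ratio: float = 0.84
    gut_fill_uses_current_bw: bool = False
    sttd_p_retention_multiplies: bool = False
    mixed_pens: bool = False
    bwg_coeffs: Mapping[str, tuple[float, float, float]] | None = None
    boar_fi_coeffs: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "n_barns", "n_pigs_per_sex", "run_days", "bw_initial_mean",
            "bw_final", "me_content", "fdm", "n_replications",
        )
        for key in positive:
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be strictly positive, got {getattr(self, key)}")
        for key in ("bw_initial_sd", "noise_cv", "ractopamine_level"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be non-negative, got {getattr(self, key)}")
        if not 0 <= self.feed_wastage < 1:
            raise ConfigError(f"feed_wastage must lie in [0, 1), got {self.feed_wastage}")
        if not 0 < self.fdm <= 1:
            raise ConfigError(f"fdm must lie in (0, 1], got {self.fdm}")
        if self.temperature < -273.15:
            raise ConfigError(f"temperature below absolute zero: {self.temperature}")
        if self.bw_initial_mean >= self.bw_final:
            raise ConfigError(
                f"bw_initial_mean ({self.bw_initial_mean}) must be below bw_final ({self.bw_final})"
            )
        if self.lipid_protein_ratio < 0:
            raise ConfigError(f"lipid_protein_ratio must be >= 0, got {self.lipid_protein_ratio}")
        for sex in self.sexes:
            if sex not in SEXES:
                raise ConfigError(f"sexes contains unknown sex {sex!r}")

    def sex_params(self, sex: str) -> SexParams:
        """Sex coefficients with any per-config overrides applied."""
        bwg = None
        if self.bwg_coeffs is not None:
            bwg = self.bwg_coeffs.get(sex)
        fi = self.boar_fi_coeffs if sex == "boar" else None
        return default_sex_params(sex, bwg_coeffs=bwg, fi_coeffs=fi)

    def all_sex_params(self) -> dict[str, SexParams]:
        return {sex: self.sex_params(sex) for sex in self.sexes}


_CONFIG_FIELDS = {f.name: f for f in dataclasses.fields(HerdConfig)}
_INT_KEYS = {"n_barns", "n_pigs_per_sex", "run_days", "seed", "n_replications"}
_BOOL_KEYS = {"gut_fill_uses_current_bw", "sttd_p_retention_multiplies", "mixed_pens"}


def _coerce(key: str, value):
    if key in _BOOL_KEYS:
        if not isinstance(value, bool):
            raise ConfigError(f"{key} must be a boolean, got {value!r}")
        return value
    if key in _INT_KEYS:
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"{key} must be an integer, got {value!r}")
        return value
    if key == "sexes":
        if isinstance(value, str):
            value = [value]
        if not isinstance(value, (list, tuple)):
            raise ConfigError(f"sexes must be a list of sex names, got {value!r}")
        return tuple(value)
    if key == "bwg_coeffs":
        if isinstance(value, (list, tuple)):
            if len(value) != 3:
                raise ConfigError(f"bwg_coeffs must have 3 entries, got {len(value)}")
            return {sex: tuple(float(v) for v in value) for sex in SEXES}
        if isinstance(value, Mapping):
            out = {}
            for sex, coeffs in value.items():
                if sex not in SEXES:
                    raise ConfigError(f"bwg_coeffs has unknown sex {sex!r}")
                if len(coeffs) != 3:
                    raise ConfigError(f"bwg_coeffs[{sex}] must have 3 entries")
                out[sex] = tuple(float(v) for v in coeffs)
            return out
        raise ConfigError(f"bwg_coeffs must be a 3-list or a sex->3-list mapping, got {value!r}")
    if key == "boar_fi_coeffs":
        if not isinstance(value, (list, tuple)) or len(value) != 3:
            raise ConfigError(f"boar_fi_coeffs must be a 3-list, got {value!r}")
        return tuple(float(v) for v in value)
    # remaining keys are scalars
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{key} must be a number, got {value!r}")
    return float(value)


def config_from_dict(data: Mapping) -> HerdConfig:
    """Validate a flat key-value mapping into a :class:`HerdConfig`."""
    unknown = set(data) - set(_CONFIG_FIELDS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs = {key: _coerce(key, value) for key, value in data.items() if value is not None}
    return HerdConfig(**kwargs)


def load_config(path: str | Path) -> HerdConfig:
    """Load and validate a flat JSON/YAML configuration file.

    An empty file yields all defaults. Unknown keys, type mismatches, and
    violated physical bounds raise :class:`ConfigError` naming the key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"configuration must be a flat key-value document, got {type(data).__name__}")
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# Least-squares fits
# ---------------------------------------------------------------------------

def fit_bwg_polynomial(
    points: Sequence[tuple[float, float]], degree: int = 2
) -> np.ndarray:
    """Least-squares polynomial of BWG (g/d) on BW (kg), ascending coefficients.

    Raises ``ValueError`` when fewer than ``degree + 1`` points are given or
    the body weights are collinear (rank-deficient design).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (BW, BWG) pairs")
    if len(pts) < degree + 1:
        raise ValueError(f"need at least {degree + 1} points for degree {degree}, got {len(pts)}")
    design = np.vander(pts[:, 0], degree + 1, increasing=True)
    if np.linalg.matrix_rank(design) < degree + 1:
        raise ValueError("body-weight values are collinear; polynomial fit is singular")
    coeffs, *_ = np.linalg.lstsq(design, pts[:, 1], rcond=None)
    return coeffs


@dataclass(frozen=True)
class NutrientCoeffs:
    """Log-linear requirement model: intercept + slope * ln(BW)."""

    nutrient: str
    klass: str  # "mineral" or "vitamin"
    intercept: float
    slope: float
    units: str

    def evaluate(self, bw: float) -> float:
        return self.intercept + self.slope * math.log(bw)


def fit_loglinear_coefficients(
    points: Sequence[tuple[float, float]],
    nutrient: str = "",
    klass: str = "mineral",
    units: str = "",
) -> NutrientCoeffs:
    """Least-squares (intercept, slope) of requirement on ln(BW)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points to fit a log-linear requirement")
    x = np.log(pts[:, 0])
    if np.ptp(x) == 0:
        raise ValueError("all body weights identical; log-linear fit is singular")
    design = np.vstack([np.ones_like(x), x]).T
    (intercept, slope), *_ = np.linalg.lstsq(design, pts[:, 1], rcond=None)
    return NutrientCoeffs(nutrient=nutrient, klass=klass, intercept=float(intercept),
                          slope=float(slope), units=units)


def build_micronutrient_table() -> list[NutrientCoeffs]:
    """Fit every mineral/vitamin log-linear model from the built-in points."""
    out = []
    for name, (klass, units, values) in MICRONUTRIENT_POINTS.items():
        points = list(zip(MICRONUTRIENT_REFERENCE_BWS, values))
        out.append(fit_loglinear_coefficients(points, nutrient=name, klass=klass, units=units))
    return out


_COEFF_CSV_HEADER = ["nutrient", "class", "intercept", "slope", "units"]


def write_micronutrient_csv(path: str | Path) -> Path:
    """Write the fitted coefficient table to CSV (the versioned data file)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COEFF_CSV_HEADER)
        for nc in build_micronutrient_table():
            writer.writerow([nc.nutrient, nc.klass, repr(nc.intercept), repr(nc.slope), nc.units])
    return path


def load_micronutrient_table() -> list[NutrientCoeffs]:
    """Load the packaged coefficient CSV, refitting if the file is absent."""
    try:
        text = (resources.files("swinesim") / "data" / "micronutrient_coeffs.csv").read_text()
    except (FileNotFoundError, ModuleNotFoundError):
        return build_micronutrient_table()
    reader = csv.DictReader(io.StringIO(text))
    return [
        NutrientCoeffs(
            nutrient=row["nutrient"], klass=row["class"],
            intercept=float(row["intercept"]), slope=float(row["slope"]),
            units=row["units"],
        )
        for row in reader
    ]
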