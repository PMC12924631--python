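"""Replication statistics, verification against the deterministic reference,
and all file output."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import herd
from .params import AA_RATIOS, HerdConfig, NutrientCoeffs, load_micronutrient_table

__all__ = [
    "TrajectorySummary",
    "VerificationResult",
    "SUMMARY_VARIABLES",
    "summarize",
    "r_squared",
    "deterministic_reference",
    "verify_against_reference",
    "snapshot_requirements",
    "export",
    "plot_trajectories",
]

SUMMARY_VARIABLES = ("bwg", "bw", "pd", "ld", "mei", "fi")
Z_95 = 1.96


@dataclass(frozen=True)
class TrajectorySummary:
    sex: str
    variable: str
    table: pd.DataFrame  # columns: day, n, mean, sd, ci_low, ci_high


@dataclass(frozen=True)
class VerificationResult:
    sex: str
    variable: str
    r_squared: float
    slope: float
    intercept: float
    n: int


def summarize(
    records: pd.DataFrame, variables: tuple[str, ...] = SUMMARY_VARIABLES
) -> pd.DataFrame:
    """Per-day, per-sex mean/SD/95% CI across all pigs and replications.

    The CI is the normal-approximation interval mean +/- 1.96*sd/sqrt(n) with
    n the pig-days contributing to that day's mean; single-observation days
    get sd = 0 and a degenerate interval.
    """
    if records.empty:
        raise ValueError("cannot summarize an empty record set")
    long = records.melt(
        id_vars=["sex", "day"], value_vars=list(variables),
        var_name="variable", value_name="value",
    )
    grouped = long.groupby(["sex", "variable", "day"], sort=True)["value"]
    out = grouped.agg(n="count", mean="mean", sd="std").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    half = Z_95 * out["sd"] / np.sqrt(out["n"])
    out["ci_low"] = out["mean"] - half
    out["ci_high"] = out["mean"] + half
    return out


def r_squared(sim, reference, sex: str = "", variable: str = "") -> VerificationResult:
    """OLS fit of simulated values on the reference series; r^2 is the squared
    Pearson correlation."""
    sim = np.asarray(sim, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if sim.shape != ref.shape:
        raise ValueError("sim and reference series must have equal length")
    if sim.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(sim) == 0 or np.ptp(ref) == 0:
        raise ValueError("zero variance in one of the series")
    fit = stats.linregress(ref, sim)
    return VerificationResult(
        sex=sex, variable=variable, r_squared=float(fit.rvalue**2),
        slope=float(fit.slope), intercept=float(fit.intercept), n=int(sim.size),
    )


def deterministic_reference(config: HerdConfig) -> pd.DataFrame:
    """Noise-free single-pig trajectory per sex under the same configuration.

    This is the deterministic transcription of the model equations and serves
    as the reference series for verification.
    """
    det = dataclasses.replace(
        config, noise_cv=0.0, bw_initial_sd=0.0, n_pigs_per_sex=1, n_replications=1,
    )
    return herd.records_frame(herd.simulate_run(det, replication=0))


def verify_against_reference(
    records: pd.DataFrame,
    config: HerdConfig,
    variables: tuple[str, ...] = ("bwg",),
    reference: pd.DataFrame | None = None,
) -> list[VerificationResult]:
    """Pool all pig-days per sex and regress them on the deterministic
    reference at the same day."""
    if reference is None:
        reference = deterministic_reference(config)
    results = []
    for sex in config.sexes:
        sim_sex = records[records["sex"] == sex]
        ref_sex = reference[reference["sex"] == sex].set_index("day")
        for var in variables:
            merged = sim_sex[["day", var]].join(
                ref_sex[var].rename("reference"), on="day", how="inner"
            ).dropna()
            results.append(
                r_squared(merged[var], merged["reference"], sex=sex, variable=var)
            )
    return results


def snapshot_requirements(
    records: pd.DataFrame,
    day: int,
    micronutrient_coeffs: list[NutrientCoeffs] | None = None,
) -> pd.DataFrame:
    """Day snapshot shaped like the printed requirement tables.

    One row per quantity (BW, SID lysine, each amino acid, STTD P, total Ca,
    then each mineral and vitamin), one column per sex, averaged over all pigs
    and replications present on that day.
    """
    sub = records[records["day"] == day]
    if sub.empty:
        raise ValueError(f"no records on day {day}")
    if micronutrient_coeffs is None:
        micronutrient_coeffs = load_micronutrient_table()
    sexes = [s for s in ("gilt", "barrow", "boar") if s in set(sub["sex"])]
    means = sub.groupby("sex")[["bw", "sid_lysine", "sttd_p", "total_ca"]].mean()
    rows: list[dict] = []

    def add(quantity: str, units: str, values: dict[str, float]) -> None:
        rows.append({"quantity": quantity, "units": units, **values})

    add("BW", "kg", {s: means.loc[s, "bw"] for s in sexes})
    add("SID lysine", "g/d", {s: means.loc[s, "sid_lysine"] for s in sexes})
    for name, ratio in AA_RATIOS.items():
        add(f"SID {name}", "g/d", {s: ratio * means.loc[s, "sid_lysine"] for s in sexes})
    add("STTD P", "g/d", {s: means.loc[s, "sttd_p"] for s in sexes})
    add("Total Ca", "g/d", {s: means.loc[s, "total_ca"] for s in sexes})
    for nc in micronutrient_coeffs:
        add(nc.nutrient, nc.units, {s: nc.evaluate(means.loc[s, "bw"]) for s in sexes})
    return pd.DataFrame(rows, columns=["quantity", "units", *sexes])


def export(
    out_dir: str | Path,
    records: pd.DataFrame | None = None,
    summaries: pd.DataFrame | None = None,
    verification: list[VerificationResult] | None = None,
    snapshot: pd.DataFrame | None = None,
    meta: dict | None = None,
) -> dict[str, Path]:
    """Write CSV/JSON outputs with deterministic ordering; returns the paths.

    Empty frames produce header-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write_csv(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / name
        frame.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path

    if records is not None:
        ordered = records.sort_values(
            ["replication", "pig_id", "day"], kind="mergesort"
        ).reset_index(drop=True)
        write_csv("records.csv", ordered)
    if summaries is not None:
        write_csv("summary.csv", summaries)
    if verification is not None:
        write_csv("verification.csv", pd.DataFrame(
            [dataclasses.asdict(v) for v in verification],
            columns=["sex", "variable", "r_squared", "slope", "intercept", "n"],
        ))
    if snapshot is not None:
        write_csv("requirements_day130.csv", snapshot)
    if meta is not None:
        path = out_dir / "run_meta.json"
        path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
        paths["run_meta.json"] = path
    return paths


def plot_trajectories(
    summaries: pd.DataFrame, out_dir: str | Path,
    variables: tuple[str, ...] = SUMMARY_VARIABLES,
) -> list[Path]:
    """Mean line + SD band + CI band per variable, one PNG per variable."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for var in variables:
        sub = summaries[summaries["variable"] == var]
        if sub.empty:
            continue
        sexes = sorted(sub["sex"].unique())
        fig, axes = plt.subplots(1, len(sexes), figsize=(4 * len(sexes), 3), squeeze=False)
        for ax, sex in zip(axes[0], sexes):
            s = sub[sub["sex"] == sex]
            ax.fill_between(s["day"], s["mean"] - s["sd"], s["mean"] + s["sd"],
                            alpha=0.25, color="tab:green", label="SD")
            ax.fill_between(s["day"], s["ci_low"], s["ci_high"],
                            alpha=0.35, color="tab:red", label="95% CI")
            ax.plot(s["day"], s["mean"], color="tab:blue", lw=1.2, label="mean")
            ax.set_title(f"{var} ({sex})")
            ax.set_xlabel("day")
        axes[0][0].legend(fontsize=7)
        fig.tight_layout()
        path = out_dir / f"trajectory_{var}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
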