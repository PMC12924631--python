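"""Agent scheduler: stocking, the daily update loop, removal at target weight,
and replication runs.

Every pig owns an RNG substream derived from (root seed, replication index,
pig id), so results are independent of update order and of how replications
are scheduled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import energy, growth
from . import requirements as req
from .growth import PigState
from .params import HerdConfig, SexParams

__all__ = [
    "SimulationRun",
    "RECORD_COLUMNS",
    "stock_pigs",
    "step_day",
    "simulate_run",
    "run_replications",
    "records_frame",
]

RECORD_COLUMNS = [
    "replication", "day", "pig_id", "sex", "pen",
    "bw", "bwg", "pd", "ld", "mei", "fi", "m_me",
    "ebw", "pbt", "sid_lysine", "sttd_p", "total_ca",
    "bw_vs_ebw_drift",
]


@dataclass
class SimulationRun:
    """One replication: a pig collection plus its accumulated daily records."""

    config: HerdConfig
    replication_index: int
    pigs: list[PigState]
    params: dict[str, SexParams]
    records: list[tuple] = field(default_factory=list)
    day: int = 0

    @property
    def finished(self) -> bool:
        return self.day >= self.config.run_days or all(p.removed for p in self.pigs)

    @property
    def unfinished_pigs(self) -> list[int]:
        """Pigs still below target weight when the horizon ran out."""
        return [p.pig_id for p in self.pigs if not p.removed]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=RECORD_COLUMNS)


def _pig_rng(seed: int, replication: int, pig_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replication, pig_id)))


def _draw_initial_bw(config: HerdConfig, rng: np.random.Generator) -> float:
    mean, sd = config.bw_initial_mean, config.bw_initial_sd
    if mean - growth.gut_fill(mean) <= 0:
        raise ValueError(f"bw_initial_mean {mean} kg does not exceed its gut fill")
    if sd == 0:
        return mean
    for _ in range(1000):
        bw0 = rng.normal(mean, sd)
        if abs(bw0 - mean) <= 4 * sd and bw0 - growth.gut_fill(bw0) > 0:
            return bw0
    raise ValueError("could not draw a feasible initial body weight in 1000 attempts")


def stock_pigs(
    config: HerdConfig,
    params: dict[str, SexParams] | None = None,
    replication: int = 0,
) -> list[PigState]:
    """Create the herd: ``n_pigs_per_sex`` pigs per configured sex.

    Pigs are assigned round-robin to barns; pens are sex-segregated unless
    ``mixed_pens`` is set.
    """
    if params is None:
        params = config.all_sex_params()
    pigs: list[PigState] = []
    pig_id = 0
    for sex in config.sexes:
        sp = params[sex]
        for _ in range(config.n_pigs_per_sex):
            rng = _pig_rng(config.seed, replication, pig_id)
            bw0 = _draw_initial_bw(config, rng)
            barn = pig_id % config.n_barns
            pen = f"barn{barn}" if config.mixed_pens else f"barn{barn}:{sex}"
            comp = growth.initialize_composition(bw0, sp.pd_max, config.lipid_protein_ratio)
            pigs.append(PigState(
                pig_id=pig_id, sex=sex, pen_id=pen, barn=barn, day=0,
                bw=bw0, bw0=bw0, composition=comp, rng=rng,
            ))
            pig_id += 1
    return pigs


def _advance_pig(pig: PigState, sp: SexParams, config: HerdConfig, replication: int) -> tuple:
    gain = growth.bwg_stochastic(pig.bw, sp.bwg_coeffs, config.noise_cv, pig.rng)
    growth.update_bw(pig, gain)
    bw = pig.bw
    pd_v = growth.pd(bw, sp)
    budget = energy.energy_budget(bw, sp, config)
    ld_v = growth.ld(budget.mei, budget.m_me, pd_v)
    bp_prev = pig.composition.bp
    comp = growth.update_composition(pig, pd_v, ld_v, sp.pd_max)
    if config.gut_fill_uses_current_bw:
        comp.gutf = growth.gut_fill(bw)
    fdmi_kg = config.fdm * budget.fi
    git = req.git_lysine_loss(fdmi_kg * 1000.0)
    integ = req.integument_lysine_loss(bw)
    _, _, sid_total = req.sid_lysine(git, integ, pd_v, bw, sp.pd_max)
    ret = req.max_p_retention(bp_prev, pd_v)
    p_req = req.sttd_p(ret, fdmi_kg, bw, config.sttd_p_retention_multiplies)
    ca = req.total_calcium(p_req)
    return (
        replication, pig.day, pig.pig_id, pig.sex, pig.pen_id,
        bw, gain, pd_v, ld_v, budget.mei, budget.fi, budget.m_me,
        comp.ebw, comp.pbt, sid_total, p_req, ca,
        bw - (comp.ebw + comp.gutf),
    )


def step_day(run: SimulationRun) -> SimulationRun:
    """Advance every live pig by one day, then remove pigs at target weight.

    Removal happens after the day's record is written, so the market-day state
    is always observed.
    """
    if run.finished:
        raise ValueError("simulation run already finished")
    config = run.config
    for pig in run.pigs:
        if pig.removed:
            continue
        run.records.append(_advance_pig(pig, run.params[pig.sex], config, run.replication_index))
        if pig.bw >= config.bw_final:
            pig.removed = True
            pig.removal_day = pig.day
    run.day += 1
    return run


def simulate_run(
    config: HerdConfig,
    replication: int = 0,
    params: dict[str, SexParams] | None = None,
) -> SimulationRun:
    """Run one replication for ``run_days`` days (or until all pigs removed)."""
    if params is None:
        params = config.all_sex_params()
    run = SimulationRun(
        config=config, replication_index=replication,
        pigs=stock_pigs(config, params, replication), params=params,
    )
    while not run.finished:
        step_day(run)
    return run


def run_replications(config: HerdConfig) -> list[SimulationRun]:
    """Independent replications with per-replication RNG substreams."""
    if config.n_replications < 1:
        raise ValueError("n_replications must be >= 1")
    params = config.all_sex_params()
    return [simulate_run(config, rep, params) for rep in range(config.n_replications)]


def records_frame(runs: list[SimulationRun] | SimulationRun) -> pd.DataFrame:
    """Concatenate run records into one frame, deterministically ordered."""
    if isinstance(runs, SimulationRun):
        runs = [runs]
    frames = [run.to_frame() for run in runs if run.records]
    if not frames:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["replication", "pig_id", "day"], kind="mergesort").reset_index(drop=True)
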