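"""Aggregate trajectories into reportable health outcomes.

Covers the quantities a price-increase health impact assessment
reports: smoking prevalences over time, COPD prevalence and incidence
series, cumulative incident cases saved versus the reference,
cohort life expectancies (overall, COPD-free and COPD-disability-
adjusted) and indicative healthcare cost savings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bundle import N_AGES, InputBundle, SMOKING_STATES, SEXES, sex_index
from .engine import COPD, Trajectory, run_simulation
from .scenario import Scenario, reference_scenario

MODES = ("overall", "copd_free", "disability_adjusted")


def smoking_prevalence(traj: Trajectory, year: int, sex: str | None = None) -> dict[str, float]:
    """Percent of the alive population in each smoking state at ``year``.

    Whole-population denominator (all ages, both sexes unless ``sex``
    is given).  The three components sum to 100.
    """
    if not 0 <= year <= traj.horizon:
        raise ValueError(f"year {year} outside 0..{traj.horizon}")
    counts = traj.states[year].counts
    if sex is not None:
        counts = counts[sex_index(sex) : sex_index(sex) + 1]
    alive = counts.sum()
    if alive <= 0:
        raise ValueError("empty population: smoking prevalence undefined")
    by_state = counts.sum(axis=(0, 1, 3))  # (3,)
    return {s: 100.0 * by_state[i] / alive for i, s in enumerate(SMOKING_STATES)}


def copd_prevalence(traj: Trajectory, year: int, sex: str | None = None) -> float:
    """Percent of the alive population (all ages) with COPD at ``year``."""
    if not 0 <= year <= traj.horizon:
        raise ValueError(f"year {year} outside 0..{traj.horizon}")
    counts = traj.states[year].counts
    if sex is not None:
        counts = counts[sex_index(sex) : sex_index(sex) + 1]
    alive = counts.sum()
    if alive <= 0:
        raise ValueError("empty population: COPD prevalence undefined")
    return 100.0 * counts[..., COPD].sum() / alive


def copd_incidence_rate(traj: Trajectory, year: int, sex: str | None = None) -> float:
    """COPD incidence during ``year``, in cases per 1000 person-years.

    Person-years are the mid-year alive population (start-of-year alive
    minus half the deaths of that year).  Not defined for the final
    simulated year: the last state has no following event year.
    """
    if not 0 <= year <= traj.horizon - 1:
        raise ValueError(
            f"COPD incidence is defined for years 0..{traj.horizon - 1}; "
            f"the final year has no event tally"
        )
    sl = slice(None) if sex is None else slice(sex_index(sex), sex_index(sex) + 1)
    alive = traj.alive(year)[sl].sum()
    deaths = traj.deaths[year][sl].sum()
    cases = traj.incident_cases[year][sl].sum()
    py = alive - 0.5 * deaths
    if py <= 0:
        raise ValueError("empty population: incidence rate undefined")
    return 1000.0 * cases / py


def cumulative_cases_saved(reference: Trajectory, intervention: Trajectory) -> float:
    """Total incident COPD cases averted over the horizon versus reference."""
    if reference.horizon != intervention.horizon:
        raise ValueError("trajectories have different horizons")
    return float(reference.incident_cases.sum() - intervention.incident_cases.sum())


# ---------------------------------------------------------------------------
# cohort life expectancy

def _cohort_bundle(bundle: InputBundle, age: int, sex: str) -> InputBundle:
    cb = bundle.copy()
    counts = np.zeros((2, N_AGES))
    counts[sex_index(sex), age] = bundle.demographics.counts[sex_index(sex), age]
    if counts.sum() <= 0:
        counts[sex_index(sex), age] = 1.0  # unit cohort if the cell is empty
    cb.demographics.counts = counts
    cb.demographics.newborns = np.zeros_like(cb.demographics.newborns)
    return cb


def _mode_weights(mode: str, disability_weight: float) -> np.ndarray:
    """Weight per COPD state (no, yes) for person-year accounting."""
    if mode == "overall":
        return np.array([1.0, 1.0])
    if mode == "copd_free":
        return np.array([1.0, 0.0])
    if mode == "disability_adjusted":
        return np.array([1.0, 1.0 - disability_weight])
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def cohort_life_expectancy(
    bundle: InputBundle,
    scenario: Scenario | None,
    age: int,
    sex: str,
    mode: str = "overall",
) -> float:
    """Expected (weighted) lifetime of a closed cohort aged ``age`` at baseline.

    The (age, sex) slice of the bundle is followed, with no newborns,
    through annual cycles up to the 95th birthday.  Weighted person-years
    use a half-cycle correction (trapezoid of start/end weighted
    occupancy, so deaths contribute half a year).  Weights per year
    lived: 1 (``overall``), 1 for COPD-free years only (``copd_free``),
    or 1 - DW for years lived with COPD (``disability_adjusted``).
    Survivors reaching age 95 receive a terminal tail of 1/m(95, sex)
    remaining years (zero when m(95) = 0), weighted by their final COPD
    state.
    """
    if not 0 <= age <= N_AGES - 1:
        raise ValueError(f"age {age} outside 0..{N_AGES - 1}")
    if scenario is None:
        scenario = reference_scenario()
    cb = _cohort_bundle(bundle, age, sex)
    cycles = (N_AGES - 1) - age  # ages a..94 are lived in-simulation
    traj = run_simulation(cb, scenario, horizon=cycles, validate=False)

    w = _mode_weights(mode, bundle.disease.disability_weight)
    n0 = traj.states[0].total()
    weighted = np.array([float((st.counts * w).sum()) for st in traj.states])
    years = float(np.sum(0.5 * (weighted[:-1] + weighted[1:]))) / n0

    m95 = bundle.mortality.all_cause[sex_index(sex), N_AGES - 1]
    tail = 0.0
    if m95 > 0:
        final = traj.states[-1].counts  # cohort now sits at age 95
        tail = float((final * w).sum()) / n0 / m95
    return age + years + tail


def le_gain(
    bundle: InputBundle,
    scenario: Scenario,
    age: int,
    sex: str,
    mode: str = "overall",
) -> float:
    """Life-expectancy gain of ``scenario`` over the 0% reference, in years."""
    ref = Scenario(price_increase_percent=0.0, schedule=scenario.schedule, label="reference")
    return cohort_life_expectancy(bundle, scenario, age, sex, mode) - cohort_life_expectancy(
        bundle, ref, age, sex, mode
    )


def cost_savings(
    cases_saved: float,
    annual_cost: float,
    duration: float,
    productivity_cost: float = 0.0,
) -> float:
    """Healthcare (plus optional productivity) costs averted, in euros.

    Each prevented case is assumed to avoid ``annual_cost`` (plus
    ``productivity_cost``) euros per year for ``duration`` years of
    disease, undiscounted.
    """
    for name, v in (
        ("cases_saved", cases_saved), ("annual_cost", annual_cost),
        ("duration", duration), ("productivity_cost", productivity_cost),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    return cases_saved * (annual_cost + productivity_cost) * duration


# ---------------------------------------------------------------------------
# multi-scenario comparison report

@dataclass
class OutcomeReport:
    """Tidy scenario-comparison tables for one bundle.

    ``smoking``: % per (year, scenario, state); ``copd_prev``: % per
    (year, scenario); ``copd_inc``: cases/1000 PY per (year 0..T-1,
    scenario); ``cases_saved``: cumulative persons per scenario versus
    reference; ``le_table``: optional years per (age, sex, scenario,
    mode).
    """

    smoking: pd.DataFrame
    copd_prev: pd.DataFrame
    copd_inc: pd.DataFrame
    cases_saved: pd.DataFrame
    le_table: pd.DataFrame | None = None
    base_year: int = 2018

    def to_csv(self, directory) -> list:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        tables = {
            "smoking_prevalence_pct.csv": self.smoking,
            "copd_prevalence_pct.csv": self.copd_prev,
            "copd_incidence_per_1000py.csv": self.copd_inc,
            "cumulative_cases_saved.csv": self.cases_saved,
        }
        if self.le_table is not None:
            tables["life_expectancy_years.csv"] = self.le_table
        for name, df in tables.items():
            path = directory / name
            df.to_csv(path, index=False)
            written.append(path)
        return written

    def summary(self, years=(0, 10, 20, 40)) -> str:
        """Human-readable text summary at selected report years."""
        lines = []
        T = int(self.smoking["year"].max())
        years = [y for y in years if y <= T]
        lines.append("Smoking prevalence (%, overall population)")
        piv = self.smoking.pivot_table(
            index=["state", "scenario"], columns="year", values="percent"
        )[years]
        lines.append(piv.round(1).to_string())
        lines.append("")
        lines.append("COPD prevalence (%)")
        piv = self.copd_prev.pivot_table(index="scenario", columns="year", values="percent")[years]
        lines.append(piv.round(2).to_string())
        lines.append("")
        inc_years = [min(y, T - 1) for y in years]
        lines.append("COPD incidence (cases/1,000 person-years)")
        piv = self.copd_inc.pivot_table(index="scenario", columns="year", values="rate")
        piv = piv[sorted(set(inc_years))]
        lines.append(piv.round(2).to_string())
        lines.append("")
        lines.append("Cumulative COPD incident cases saved vs reference")
        lines.append(self.cases_saved.round(0).to_string(index=False))
        return "\n".join(lines)


def compare_scenarios(
    bundle: InputBundle,
    scenarios: list[Scenario],
    le_ages: tuple[int, ...] = (),
) -> OutcomeReport:
    """Run the reference plus each scenario and tabulate the outcomes.

    The reference (0%) scenario is always included first.  If
    ``le_ages`` is nonempty, a cohort life-expectancy table for those
    baseline ages (both sexes, all three modes) is added.
    """
    ref = reference_scenario()
    all_scen = [ref] + [s for s in scenarios if s.price_increase_percent > 0]
    trajs = {s.label: run_simulation(bundle, s) for s in all_scen}
    T = bundle.horizon_years

    smoking_rows, prev_rows, inc_rows, saved_rows = [], [], [], []
    for s in all_scen:
        traj = trajs[s.label]
        for year in range(T + 1):
            sp = smoking_prevalence(traj, year)
            for state, pct in sp.items():
                smoking_rows.append(
                    {"year": year, "scenario": s.label, "state": state, "percent": pct}
                )
            prev_rows.append(
                {"year": year, "scenario": s.label, "percent": copd_prevalence(traj, year)}
            )
            if year < T:
                inc_rows.append(
                    {"year": year, "scenario": s.label, "rate": copd_incidence_rate(traj, year)}
                )
        saved_rows.append({
            "scenario": s.label,
            "cases_saved": cumulative_cases_saved(trajs[ref.label], traj),
        })

    le_df = None
    if le_ages:
        le_rows = []
        for s in all_scen:
            for age in le_ages:
                for sex in SEXES:
                    for mode in MODES:
                        le = cohort_life_expectancy(bundle, s, age, sex, mode)
                        le_rows.append({
                            "age": age, "sex": sex, "scenario": s.label,
                            "mode": mode, "life_expectancy": le,
                        })
        le_df = pd.DataFrame(le_rows)

    return OutcomeReport(
        smoking=pd.DataFrame(smoking_rows),
        copd_prev=pd.DataFrame(prev_rows),
        copd_inc=pd.DataFrame(inc_rows),
        cases_saved=pd.DataFrame(saved_rows),
        le_table=le_df,
        base_year=bundle.base_year,
    )
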