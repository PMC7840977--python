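"""Dynamic Markov multi-state projection engine.

The population is tracked as expected counts over the joint state
space (sex, age 0..95, smoking state never/current/former, COPD
yes/no).  Each annual cycle applies, in fixed order:

1. smoking transitions (initiation, cessation, restart),
2. COPD incidence among disease-free individuals aged >= 40, using
   post-transition smoking states,
3. mortality by smoking state (identical for COPD yes/no),
4. ageing by one year — survivors of age 95 leave the modelled range —
   and newborn entry at age 0 as never-smokers without COPD.

COPD is absorbing (no remission).  State-specific COPD incidence and
mortality are obtained from the population-average inputs by the
standard attributable-risk decomposition and are frozen from the
reference (pre-intervention) smoking distribution, so interventions
act purely through smoking-state occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bundle import (
    MIN_AGE_COPD,
    N_AGES,
    InputBundle,
    RegionTransitions,
    assert_valid,
)
from .scenario import Scenario, apply_intervention, reference_scenario

# smoking-state axis order: never, current, former
NEVER, CURRENT, FORMER = 0, 1, 2
# COPD axis order
NO_COPD, COPD = 0, 1


class SimulationError(RuntimeError):
    """Internal consistency failure (e.g. negative counts)."""


@dataclass
class PopulationState:
    """Expected persons per (sex, age, smoking state, COPD state)."""

    counts: np.ndarray  # (2, 96, 3, 2)
    year_index: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, N_AGES, 3, 2):
            raise ValueError(f"counts must have shape (2, {N_AGES}, 3, 2)")

    def alive(self) -> np.ndarray:
        """Total alive per (sex, age)."""
        return self.counts.sum(axis=(2, 3))

    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class StateRates:
    """Frozen state-specific annual probabilities per (sex, age, smoking)."""

    incidence_by_smoking: np.ndarray  # (2, 96, 3)
    mortality_by_smoking: np.ndarray  # (2, 96, 3)


@dataclass
class Trajectory:
    """Year-by-year simulation output.

    ``states[t]`` is the population at the start of year t (t = 0..T);
    ``incident_cases[t]`` and ``deaths[t]`` are events during year t
    (t = 0..T-1), tallied at the age held during that year.
    """

    states: list[PopulationState]
    incident_cases: np.ndarray  # (T, 2, 96)
    deaths: np.ndarray          # (T, 2, 96)
    base_year: int = 2018

    @property
    def horizon(self) -> int:
        return len(self.states) - 1

    def alive(self, year: int) -> np.ndarray:
        return self.states[year].alive()


# ---------------------------------------------------------------------------
# attributable-risk rate decomposition

def _decompose(total, p_never, p_current, p_former, rr_current, rr_former):
    """Vectorised closed-form decomposition; returns (never, current, former)."""
    denom = p_never + p_current * rr_current + p_former * rr_former
    with np.errstate(divide="ignore", invalid="ignore"):
        base = np.where(denom > 0, total / np.where(denom > 0, denom, 1.0), 0.0)
    r_never = np.clip(base, 0.0, 1.0)
    r_current = np.clip(base * rr_current, 0.0, 1.0)
    r_former = np.clip(base * rr_former, 0.0, 1.0)
    return r_never, r_current, r_former


def decompose_incidence(
    total: float,
    p_never: float,
    p_current: float,
    p_former: float,
    rr_current: float,
    rr_former: float,
) -> tuple[float, float, float]:
    """Split a population-average incidence into state-specific values.

    Solves ``sum_s p_s * i_s = total`` with ``i_current = RR_c * i_never``
    and ``i_former = RR_f * i_never``, i.e.::

        i_never = total / (p_never + p_current*RR_c + p_former*RR_f)

    Each result is clamped to [0, 1]; an empty denominator yields zeros.
    Returns ``(i_never, i_current, i_former)``.
    """
    out = _decompose(
        np.float64(total), np.float64(p_never), np.float64(p_current),
        np.float64(p_former), np.float64(rr_current), np.float64(rr_former),
    )
    return tuple(float(v) for v in out)


def decompose_mortality(
    total: float,
    p_never: float,
    p_current: float,
    p_former: float,
    rr_current: float,
    rr_former: float,
) -> tuple[float, float, float]:
    """Same closed form as :func:`decompose_incidence`, for death probabilities."""
    return decompose_incidence(total, p_never, p_current, p_former, rr_current, rr_former)


def build_state_rates(bundle: InputBundle) -> StateRates:
    """Derive frozen state-specific rates from the reference baseline.

    For every (sex, age) the bundle's *unadjusted* smoking distribution
    weights the decomposition, so the weighted average of the derived
    rates reproduces the input incidence and mortality exactly.  The
    result is reused unchanged in intervention runs.
    """
    s = bundle.smoking
    dis = bundle.disease
    mort = bundle.mortality

    inc = np.zeros((2, N_AGES, 3))
    inc[:, :, NEVER], inc[:, :, CURRENT], inc[:, :, FORMER] = _decompose(
        dis.copd_incidence, s.p_never, s.p_current, s.p_former,
        dis.rr_copd_current, dis.rr_copd_former,
    )

    mor = np.zeros((2, N_AGES, 3))
    rr_c = mort.rr_mort_current[:, np.newaxis]
    rr_f = mort.rr_mort_former[:, np.newaxis]
    mor[:, :, NEVER], mor[:, :, CURRENT], mor[:, :, FORMER] = _decompose(
        mort.all_cause, s.p_never, s.p_current, s.p_former, rr_c, rr_f
    )
    return StateRates(incidence_by_smoking=inc, mortality_by_smoking=mor)


# ---------------------------------------------------------------------------
# annual cycle

def initial_state(bundle: InputBundle) -> PopulationState:
    """Build the year-0 state from population, smoking and COPD prevalences.

    COPD prevalence is applied independently of smoking state within
    each (sex, age) cell.
    """
    n = bundle.demographics.counts  # (2, 96)
    smoking = bundle.smoking.as_stack()  # (2, 96, 3)
    copd = bundle.disease.copd_prevalence  # (2, 96)
    counts = np.zeros((2, N_AGES, 3, 2))
    counts[:, :, :, NO_COPD] = n[:, :, None] * smoking * (1.0 - copd)[:, :, None]
    counts[:, :, :, COPD] = n[:, :, None] * smoking * copd[:, :, None]
    return PopulationState(counts=counts, year_index=0)


def step_year(
    state: PopulationState,
    rates: StateRates,
    transitions: RegionTransitions,
    newborns: np.ndarray,
) -> tuple[PopulationState, np.ndarray, np.ndarray]:
    """Advance the population one annual cycle.

    Returns ``(new_state, incident_cases, deaths)`` where the tallies
    are (2, 96) arrays indexed by the age held *during* the year.
    """
    c = state.counts
    init = transitions.initiation[:, :, None]  # broadcast over copd axis
    cess = transitions.cessation[:, :, None]
    rest = transitions.restart[:, :, None]

    # 1. smoking transitions: flows drawn from start-of-year occupancy
    start = c[:, :, NEVER, :] * init
    quit_ = c[:, :, CURRENT, :] * cess
    relapse = c[:, :, FORMER, :] * rest
    c1 = c.copy()
    c1[:, :, NEVER, :] -= start
    c1[:, :, CURRENT, :] += start + relapse - quit_
    c1[:, :, FORMER, :] += quit_ - relapse

    # 2. COPD incidence among disease-free, post-transition smoking states
    inc_flow = c1[:, :, :, NO_COPD] * rates.incidence_by_smoking
    c2 = c1.copy()
    c2[:, :, :, NO_COPD] -= inc_flow
    c2[:, :, :, COPD] += inc_flow
    incident_cases = inc_flow.sum(axis=2)

    # 3. mortality by smoking state (COPD-independent)
    death_cells = c2 * rates.mortality_by_smoking[:, :, :, None]
    c3 = c2 - death_cells
    deaths = death_cells.sum(axis=(2, 3))

    if c3.min() < -1e-9 * max(1.0, c.sum()):
        raise SimulationError(f"negative counts after mortality: min={c3.min():g}")
    np.clip(c3, 0.0, None, out=c3)

    # 4. ageing + newborn entry; survivors of age 95 exit the range
    c4 = np.zeros_like(c3)
    c4[:, 1:, :, :] = c3[:, :-1, :, :]
    c4[:, 0, NEVER, NO_COPD] = newborns
    return (
        PopulationState(counts=c4, year_index=state.year_index + 1),
        incident_cases,
        deaths,
    )


def run_simulation(
    bundle: InputBundle,
    scenario: Scenario | None = None,
    horizon: int | None = None,
    validate: bool = True,
) -> Trajectory:
    """Project the population over the simulation horizon.

    The intervention (possibly the 0% reference) is applied once before
    year 0; state-specific rates are built from the unadjusted bundle
    and frozen.  Deterministic: identical inputs give identical output.
    """
    if scenario is None:
        scenario = reference_scenario()
    if validate:
        assert_valid(bundle)
    T = bundle.horizon_years if horizon is None else int(horizon)

    adjusted = apply_intervention(bundle, scenario)
    rates = build_state_rates(bundle)  # frozen from the reference baseline
    trans = adjusted.transitions.for_region(adjusted.region)
    newborns = adjusted.demographics.newborns

    state = initial_state(adjusted)
    states = [state]
    cases = np.zeros((T, 2, N_AGES))
    deaths = np.zeros((T, 2, N_AGES))
    for t in range(T):
        nb = newborns[:, t] if t < newborns.shape[1] else np.zeros(2)
        state, cases[t], deaths[t] = step_year(state, rates, trans, nb)
        states.append(state)
    return Trajectory(
        states=states, incident_cases=cases, deaths=deaths, base_year=bundle.base_year
    )
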