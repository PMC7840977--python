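"""One-time tobacco price increase scenarios.

A scenario applies a single price rise at the start of the simulation.
Age-banded price elasticities translate the price change into relative
shifts of the baseline smoking-state prevalences and of the annual
initiation/cessation/restart probabilities: never- and former-smoker
prevalences rise by |elasticity| * price%, current smoking is the
complement, initiation and restart fall and cessation rises by the
same relative amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bundle import (
    MIN_AGE_INITIATION,
    N_AGES,
    InputBundle,
    TransitionRates,
)


@dataclass(frozen=True)
class ElasticitySchedule:
    """Ordered age bands (age_low, age_high, elasticity <= 0).

    Bands must partition ages 11..95 with inclusive edges and no
    overlap; ages below 11 are outside the schedule and never adjusted
    (smoking cannot exist there).
    """

    bands: tuple[tuple[int, int, float], ...]

    def __post_init__(self):
        covered = np.zeros(N_AGES, dtype=bool)
        for lo, hi, eps in self.bands:
            if eps > 0:
                raise ValueError(f"elasticity must be <= 0, got {eps} for band {lo}-{hi}")
            if not (MIN_AGE_INITIATION <= lo <= hi <= N_AGES - 1):
                raise ValueError(f"band {lo}-{hi} outside {MIN_AGE_INITIATION}..{N_AGES - 1}")
            if covered[lo : hi + 1].any():
                raise ValueError(f"band {lo}-{hi} overlaps a previous band")
            covered[lo : hi + 1] = True
        if not covered[MIN_AGE_INITIATION:].all():
            missing = int(np.flatnonzero(~covered[MIN_AGE_INITIATION:])[0]) + MIN_AGE_INITIATION
            raise ValueError(f"schedule does not cover age {missing}")

    def elasticity(self, age: int) -> float:
        """Elasticity at a single age (0.0 below age 11)."""
        for lo, hi, eps in self.bands:
            if lo <= age <= hi:
                return eps
        return 0.0

    def per_age(self) -> np.ndarray:
        """Dense (96,) elasticity vector; zero where no band applies."""
        out = np.zeros(N_AGES)
        for lo, hi, eps in self.bands:
            out[lo : hi + 1] = eps
        return out


def default_schedule() -> ElasticitySchedule:
    """Main-analysis elasticities: -1.5 below 19, -0.75 at 19-29, -0.5 at 30+.

    Adolescents are assumed the most price-responsive (lower disposable
    income), adults the least.
    """
    return ElasticitySchedule(bands=((11, 18, -1.5), (19, 29, -0.75), (30, 95, -0.5)))


def sensitivity_schedule() -> ElasticitySchedule:
    """Sensitivity analysis: a uniform elasticity of -0.5 at every age."""
    return ElasticitySchedule(bands=((11, 95, -0.5),))


SCHEDULES = {
    "default": default_schedule,
    "uniform_0.5": sensitivity_schedule,
}


@dataclass(frozen=True)
class Scenario:
    """A one-time price increase plus the elasticity schedule to use."""

    price_increase_percent: float = 0.0
    schedule: ElasticitySchedule = field(default_factory=default_schedule)
    label: str = ""

    def __post_init__(self):
        if self.price_increase_percent < 0:
            raise ValueError("price_increase_percent must be >= 0")
        if not self.label:
            object.__setattr__(self, "label", f"{self.price_increase_percent:g}%")


def reference_scenario() -> Scenario:
    """The business-as-usual scenario: no price change at all."""
    return Scenario(price_increase_percent=0.0, label="reference")


def adjust_prevalence(
    p: tuple[float, float, float], elasticity: float, price_pct: float
) -> tuple[float, float, float]:
    """Shift one (never, current, former) triple for a price increase.

    Never and former prevalences are multiplied by
    ``1 + |elasticity| * price_pct / 100``; current smoking becomes the
    complement to 1.  If the scaled never+former would exceed 1, both
    are rescaled proportionally (preserving their ratio) and current
    smoking is set to zero.
    """
    if price_pct < 0:
        raise ValueError("price_pct must be >= 0")
    p_never, p_current, p_former = p
    f = 1.0 + abs(elasticity) * price_pct / 100.0
    if f == 1.0:
        return (p_never, p_current, p_former)
    n, fm = p_never * f, p_former * f
    if n + fm > 1.0:
        scale = 1.0 / (n + fm)
        n, fm = n * scale, fm * scale
        c = 0.0
    else:
        c = 1.0 - n - fm
    return (n, c, fm)


def _adjust_prevalence_arrays(p_never, p_current, p_former, factor):
    """Vectorised form of adjust_prevalence over (sex, age) arrays."""
    n = p_never * factor
    fm = p_former * factor
    tot = n + fm
    over = tot > 1.0
    scale = np.where(over, 1.0 / np.where(tot > 0, tot, 1.0), 1.0)
    n = n * scale
    fm = fm * scale
    # clip guards against -1e-17 style float residue in the complement
    c = np.clip(np.where(over, 0.0, 1.0 - n - fm), 0.0, None)
    # a unit factor (zero elasticity / ineligible age) is an exact no-op
    unit = np.broadcast_to(factor == 1.0, n.shape)
    n = np.where(unit, p_never, n)
    c = np.where(unit, p_current, c)
    fm = np.where(unit, p_former, fm)
    return n, c, fm


def adjust_rates(
    rates: TransitionRates, schedule: ElasticitySchedule, price_pct: float
) -> TransitionRates:
    """Scale transition probabilities for a price increase.

    With f = |elasticity(age)| * price_pct / 100: initiation and restart
    shrink by a factor (1 - f), cessation grows by (1 + f); results are
    clamped to [0, 1].  Structural zeros (no cessation below 16, no
    restart below 22) are preserved automatically since 0 scales to 0.
    """
    if price_pct < 0:
        raise ValueError("price_pct must be >= 0")
    f = np.abs(schedule.per_age()) * price_pct / 100.0  # (96,)
    down = np.clip(1.0 - f, 0.0, None)
    up = 1.0 + f
    return TransitionRates(
        initiation=np.clip(rates.initiation * down, 0.0, 1.0),
        cessation=np.clip(rates.cessation * up, 0.0, 1.0),
        restart=np.clip(rates.restart * down, 0.0, 1.0),
    )


def apply_intervention(bundle: InputBundle, scenario: Scenario) -> InputBundle:
    """Return a new bundle with the price shock applied once, before year 0.

    Baseline smoking prevalences at all ages >= 11 and the transition
    probabilities are adjusted; everything else (population, COPD,
    mortality, relative risks) is untouched.  A 0% price increase
    returns an exact copy.
    """
    out = bundle.copy()
    price = scenario.price_increase_percent
    if price == 0:
        return out
    factor = 1.0 + np.abs(scenario.schedule.per_age()) * price / 100.0  # (96,)
    s = out.smoking
    n, c, fm = _adjust_prevalence_arrays(
        s.p_never, s.p_current, s.p_former, factor[np.newaxis, :]
    )
    s.p_never, s.p_current, s.p_former = n, c, fm
    out.transitions = adjust_rates(bundle.transitions, scenario.schedule, price)
    return out
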