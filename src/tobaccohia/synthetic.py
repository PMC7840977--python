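"""Reproducible country-like synthetic input bundles.

Real national inputs (population registers, cohort-derived smoking
transition probabilities, COPD surveillance) are not redistributable,
so this module generates bundles with the statistical structure the
simulation assumes:

* a smooth age pyramid consistent with Gompertz-like mortality and a
  birth-trend skew parameter;
* never/current/former smoking prevalences obtained by age-marching a
  birth cohort through the generated initiation/cessation/restart
  probabilities, so baseline prevalences are internally consistent
  with the transition rates (reference-scenario drift then reflects
  demography, not inconsistent inputs);
* initiation concentrated in adolescence, cessation rising with age,
  restart declining with age; current smoking unimodal with its peak
  in middle age;
* COPD prevalence and incidence zero before age 40 and rising with
  age, calibrated to realistic overall levels (~1% prevalence,
  ~1.5 cases/1000 person-years);
* relative risks of smoking on COPD by sex and age band within
  [8.13, 19.83] and on total mortality of 2.07 (males) / 1.74
  (females).

All randomness flows from a single seeded generator; a fixed seed
yields a byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bundle import (
    AGES,
    MIN_AGE_CESSATION,
    MIN_AGE_COPD,
    MIN_AGE_INITIATION,
    MIN_AGE_RESTART,
    N_AGES,
    Demographics,
    DiseaseInputs,
    InputBundle,
    MortalityInputs,
    SmokingPrevalence,
    TransitionRates,
    sex_index,
)

RR_COPD_MIN, RR_COPD_MAX = 8.13, 19.83

#: COPD relative-risk age bands (age_low, age_high)
RR_AGE_BANDS = ((40, 59), (60, 79), (80, 95))


class SyntheticParamError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the synthetic country generator.

    ``pyramid_shape`` is the historical annual birth-growth rate: a
    positive value skews the pyramid young, a negative value old.
    ``peak_current_prevalence`` is the male mid-life peak of current
    smoking (females are generated at 85% of it).
    ``rr_copd_by_ageband`` holds per-sex current-smoker relative risks
    for the bands 40-59 / 60-79 / 80-95 and must stay within
    [8.13, 19.83]; former-smoker RRs default to 1 + 0.5*(RR - 1).
    """

    seed: int = 1
    total_population: float = 1_000_000.0
    pyramid_shape: float = 0.002
    peak_current_prevalence: float = 0.20
    initiation_peak_age: float = 16.0
    gompertz_alpha: tuple[float, float] = (3.2e-5, 1.7e-5)   # male, female
    gompertz_beta: tuple[float, float] = (0.095, 0.098)
    copd_incidence_at_80: float = 0.01
    overall_copd_prevalence: float = 0.01
    rr_copd_by_ageband: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (14.5, 11.0, 8.6),   # males: 40-59, 60-79, 80-95
        (17.5, 12.5, 9.2),   # females
    )
    rr_mort: tuple[float, float] = (2.07, 1.74)  # male, female
    region: str = "north"
    base_year: int = 2018
    horizon_years: int = 40
    disability_weight: float = 0.2
    jitter: float = 0.04   # lognormal sd applied to scalar levels

    def validate(self) -> None:
        if self.total_population <= 0:
            raise SyntheticParamError("total_population must be positive")
        if not (0 < self.peak_current_prevalence < 0.6):
            raise SyntheticParamError("peak_current_prevalence must be in (0, 0.6)")
        if not (0 <= self.copd_incidence_at_80 <= 1):
            raise SyntheticParamError("copd_incidence_at_80 must be a probability")
        for sx in range(2):
            for v in self.rr_copd_by_ageband[sx]:
                if not (RR_COPD_MIN <= v <= RR_COPD_MAX):
                    raise SyntheticParamError(
                        f"rr_copd_by_ageband value {v} outside [{RR_COPD_MIN}, {RR_COPD_MAX}]"
                    )
        for v in self.rr_mort:
            if v < 1:
                raise SyntheticParamError("rr_mort must be >= 1")


#: qualitative country-style presets (illustrative, not calibrated)
PROFILES = {
    "italy-like": dict(region="south", peak_current_prevalence=0.24,
                       pyramid_shape=-0.004, total_population=1_000_000.0),
    "england-like": dict(region="north", peak_current_prevalence=0.20,
                         pyramid_shape=0.003, total_population=1_000_000.0),
    "sweden-like": dict(region="north", peak_current_prevalence=0.13,
                        pyramid_shape=0.002, total_population=200_000.0),
}


def params_for_profile(profile: str, seed: int = 1) -> SyntheticParams:
    if profile not in PROFILES:
        raise SyntheticParamError(
            f"unknown profile {profile!r}; choose from {sorted(PROFILES)}"
        )
    return SyntheticParams(seed=seed, **PROFILES[profile])


# ---------------------------------------------------------------------------
# component curves

def _mortality_curve(alpha: float, beta: float) -> np.ndarray:
    """Gompertz adult mortality with small infant/background components."""
    m = alpha * np.exp(beta * AGES)
    m = m + 3.5e-3 * np.exp(-AGES / 1.5) + 4e-4
    return np.minimum(m, 0.7)


def _transition_curves(rng_levels, initiation_peak_age: float):
    """Base (northern) initiation/cessation/restart per age, one sex."""
    i_lvl, c_lvl, r_lvl = rng_levels
    a = AGES.astype(float)

    init = i_lvl * np.exp(-0.5 * ((a - initiation_peak_age) / 3.5) ** 2)
    # slow late-uptake tail fading out by age ~58
    tail = 0.12 * i_lvl * np.clip(1.0 - (a - 18.0) / 40.0, 0.0, 1.0)
    init = init + np.where(a > 20, tail, 0.0)
    init[:MIN_AGE_INITIATION] = 0.0

    cess = c_lvl * (1.0 + np.clip(a - 48.0, 0.0, None) * 0.12)
    cess = np.minimum(cess, 0.15)
    cess[:MIN_AGE_CESSATION] = 0.0

    rest = r_lvl * np.exp(-(a - MIN_AGE_RESTART) / 25.0)
    rest[:MIN_AGE_RESTART] = 0.0
    return init, cess, rest


def _march_prevalence(init, cess, rest):
    """Cohort-march smoking states through the annual transition rates."""
    p = np.zeros((N_AGES, 3))  # never, current, former
    p[0, 0] = 1.0
    for a in range(N_AGES - 1):
        n, c, f = p[a]
        start = init[a] * n
        quit_ = cess[a] * c
        relapse = rest[a] * f
        p[a + 1, 0] = n - start
        p[a + 1, 1] = c + start + relapse - quit_
        p[a + 1, 2] = f + quit_ - relapse
        p[a + 1] /= p[a + 1].sum()
    return p


def _calibrate_initiation(init, cess, rest, target_peak: float):
    """Scale initiation so the mid-life current-smoking peak hits target."""
    scale = 1.0
    for _ in range(4):
        p = _march_prevalence(init * scale, cess, rest)
        peak = p[:, 1].max()
        if peak <= 0:
            break
        scale *= target_peak / peak
    scale = min(scale, 0.95 / max(init.max(), 1e-12))
    return init * scale, _march_prevalence(init * scale, cess, rest)


def period_life_expectancy(all_cause: np.ndarray) -> float:
    """Plain life expectancy at birth from one sex's mortality curve.

    Half-cycle-corrected person-years over ages 0..94 plus a 1/m(95)
    tail for survivors, matching the engine's accounting conventions.
    """
    survivors = np.concatenate([[1.0], np.cumprod(1.0 - all_cause[:-1])])
    py = 0.5 * (survivors[:-1] * (1.0 - all_cause[:-1]) + survivors[:-1])
    le = float(py.sum())
    m95 = all_cause[-1]
    if m95 > 0:
        le += survivors[-1] / m95  # geometric tail at the top age
    return le


# ---------------------------------------------------------------------------
# bundle assembly

def generate_bundle(params: SyntheticParams | None = None) -> InputBundle:
    """Generate a complete, validated synthetic country bundle.

    Deterministic in ``params.seed``.  The returned bundle satisfies
    every data-model invariant; current smoking is unimodal in age with
    its maximum in middle age, COPD incidence is zero below 40 and
    nondecreasing thereafter, and adult mortality is nondecreasing.
    """
    params = params or SyntheticParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    jit = lambda: float(np.exp(rng.normal(0.0, params.jitter)))

    # mortality (males first, then females)
    all_cause = np.zeros((2, N_AGES))
    for sx in range(2):
        alpha = params.gompertz_alpha[sx] * jit()
        all_cause[sx] = _mortality_curve(alpha, params.gompertz_beta[sx])

    # transitions: north base, south = higher uptake, lower quitting
    init = np.zeros((2, 2, N_AGES))
    cess = np.zeros((2, 2, N_AGES))
    rest = np.zeros((2, 2, N_AGES))
    prevalence = np.zeros((2, N_AGES, 3))
    region_idx = 0 if params.region == "north" else 1
    for sx in range(2):
        sex_factor = 1.0 if sx == 0 else 0.85
        levels = (0.055 * jit(), 0.004 * jit(), 0.05 * jit())
        i_n, c_n, r_n = _transition_curves(levels, params.initiation_peak_age)
        i_s = np.minimum(i_n * 1.15, 1.0)
        c_s = c_n * 0.85
        r_s = np.minimum(r_n * 1.10, 1.0)
        target = params.peak_current_prevalence * sex_factor
        if region_idx == 0:
            i_n, p = _calibrate_initiation(i_n, c_n, r_n, target)
            i_s = np.minimum(i_n * 1.15, 1.0)
        else:
            i_s, p = _calibrate_initiation(i_s, c_s, r_s, target)
            i_n = i_s / 1.15
        init[0, sx], cess[0, sx], rest[0, sx] = i_n, c_n, r_n
        init[1, sx], cess[1, sx], rest[1, sx] = i_s, c_s, r_s
        prevalence[sx] = p

    # population pyramid: survival curve skewed by the birth trend
    counts = np.zeros((2, N_AGES))
    birth_sex_ratio = (0.512, 0.488)
    for sx in range(2):
        survivors = np.concatenate([[1.0], np.cumprod(1.0 - all_cause[sx, :-1])])
        counts[sx] = birth_sex_ratio[sx] * survivors * (1.0 + params.pyramid_shape) ** (-AGES)
    counts *= params.total_population / counts.sum()

    horizon = params.horizon_years
    newborns = np.zeros((2, max(horizon, 1)))
    birth_cohort = counts[:, 0]
    for t in range(newborns.shape[1]):
        newborns[:, t] = birth_cohort

    # COPD: prevalence calibrated to the overall target, incidence from
    # the level at age 80 with an exponential age slope
    copd_prev = np.zeros((2, N_AGES))
    copd_inc = np.zeros((2, N_AGES))
    adult = AGES >= MIN_AGE_COPD
    prev_shape = np.where(adult, np.clip(AGES - (MIN_AGE_COPD - 1), 0, None) ** 1.1, 0.0)
    pop_w = counts.sum(axis=0) / counts.sum()
    prev_target = params.overall_copd_prevalence * jit()
    prev_scale = prev_target / float((pop_w * prev_shape).sum())
    i80 = params.copd_incidence_at_80 * jit()
    # exponential rise with age, plateauing in very old age
    inc_shape = np.where(adult, np.minimum(np.exp(0.09 * (AGES - 80.0)), 1.2), 0.0)
    for sx, sex_mult in ((0, 1.1), (1, 0.9)):
        copd_prev[sx] = np.minimum(prev_scale * prev_shape * sex_mult, 0.6)
        copd_inc[sx] = np.minimum(i80 * inc_shape * sex_mult, 1.0)

    # relative risks
    rr_copd_c = np.ones((2, N_AGES))
    for sx in range(2):
        for (lo, hi), base in zip(RR_AGE_BANDS, params.rr_copd_by_ageband[sx]):
            v = float(np.clip(base * jit(), RR_COPD_MIN, RR_COPD_MAX))
            rr_copd_c[sx, lo : hi + 1] = v
    rr_copd_f = np.where(rr_copd_c > 1, 1.0 + 0.5 * (rr_copd_c - 1.0), 1.0)
    rr_mort_c = np.asarray(params.rr_mort, dtype=float)
    rr_mort_f = 1.0 + 0.5 * (rr_mort_c - 1.0)

    bundle = InputBundle(
        demographics=Demographics(counts=counts, newborns=newborns),
        smoking=SmokingPrevalence(
            p_never=prevalence[:, :, 0],
            p_current=prevalence[:, :, 1],
            p_former=prevalence[:, :, 2],
        ),
        transitions=TransitionRates(initiation=init, cessation=cess, restart=rest),
        disease=DiseaseInputs(
            copd_prevalence=copd_prev,
            copd_incidence=copd_inc,
            rr_copd_current=rr_copd_c,
            rr_copd_former=rr_copd_f,
            disability_weight=params.disability_weight,
        ),
        mortality=MortalityInputs(
            all_cause=all_cause, rr_mort_current=rr_mort_c, rr_mort_former=rr_mort_f
        ),
        region=params.region,
        horizon_years=horizon,
        base_year=params.base_year,
    )
    return bundle


def generate_cohort_bundle(
    age: int, sex: str, params: SyntheticParams | None = None
) -> InputBundle:
    """A bundle whose population is a single (age, sex) cohort, no newborns.

    All rate tables match :func:`generate_bundle` for the same params,
    so cohort runs use exactly the population-level inputs.
    """
    if not 0 <= age <= N_AGES - 1:
        raise SyntheticParamError(f"age {age} outside 0..{N_AGES - 1}")
    bundle = generate_bundle(params)
    sx = sex_index(sex)
    counts = np.zeros((2, N_AGES))
    counts[sx, age] = bundle.demographics.counts[sx, age]
    if counts[sx, age] <= 0:
        counts[sx, age] = 1.0
    bundle.demographics.counts = counts
    bundle.demographics.newborns = np.zeros_like(bundle.demographics.newborns)
    return bundle
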