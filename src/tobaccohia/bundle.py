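"""Input data model for country-like simulation bundles.

A bundle collects everything the projection engine needs for one
population: the age/sex population pyramid and projected newborns,
never/current/former smoking prevalences, annual smoking transition
probabilities (initiation, cessation, restart) by European region,
COPD prevalence and incidence, all-cause mortality, and the relative
risks of smoking on COPD and on total mortality.

All age-structured quantities are stored as dense numpy arrays over
sex x single year of age 0..95.  Bundles round-trip losslessly through
a directory of CSV tables plus a YAML run configuration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SEXES = ("male", "female")
REGIONS = ("north", "south")
SMOKING_STATES = ("never", "current", "former")
COPD_STATES = ("no", "yes")

N_AGES = 96
AGES = np.arange(N_AGES)

#: youngest ages at which each behaviour / disease is possible
MIN_AGE_INITIATION = 11
MIN_AGE_CESSATION = 16
MIN_AGE_RESTART = 22
MIN_AGE_COPD = 40

_SUM_TOL = 1e-9


class BundleValidationError(ValueError):
    """Raised when a bundle violates a structural invariant."""


def sex_index(sex: str) -> int:
    try:
        return SEXES.index(sex)
    except ValueError:
        raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}") from None


def region_index(region: str) -> int:
    try:
        return REGIONS.index(region)
    except ValueError:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}") from None


def _as_sex_age(name: str, arr) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    if out.shape != (2, N_AGES):
        raise ValueError(f"{name} must have shape (2, {N_AGES}), got {out.shape}")
    return out


@dataclass
class Demographics:
    """Population counts by (sex, age 0..95) and projected newborns.

    ``newborns[s, t]`` is the number of age-0 entrants of sex ``s``
    during simulated year ``t`` (calendar-year offsets 1..T).
    """

    counts: np.ndarray       # (2, 96) persons
    newborns: np.ndarray     # (2, T) persons

    def __post_init__(self):
        self.counts = _as_sex_age("counts", self.counts)
        self.newborns = np.atleast_2d(np.asarray(self.newborns, dtype=float))


@dataclass
class SmokingPrevalence:
    """Never/current/former smoking proportions per (sex, age)."""

    p_never: np.ndarray
    p_current: np.ndarray
    p_former: np.ndarray

    def __post_init__(self):
        for f in ("p_never", "p_current", "p_former"):
            setattr(self, f, _as_sex_age(f, getattr(self, f)))

    def as_stack(self) -> np.ndarray:
        """(2, 96, 3) array ordered as SMOKING_STATES."""
        return np.stack([self.p_never, self.p_current, self.p_former], axis=-1)


@dataclass
class TransitionRates:
    """Annual smoking transition probabilities per (region, sex, age).

    Arrays are indexed ``[region, sex, age]`` following REGIONS/SEXES.
    Values are annual probabilities in [0, 1], not instantaneous rates.
    """

    initiation: np.ndarray   # never -> current
    cessation: np.ndarray    # current -> former
    restart: np.ndarray      # former -> current

    def __post_init__(self):
        for f in ("initiation", "cessation", "restart"):
            arr = np.asarray(getattr(self, f), dtype=float)
            if arr.shape != (2, 2, N_AGES):
                raise ValueError(
                    f"{f} must have shape (2, 2, {N_AGES}) for (region, sex, age), got {arr.shape}"
                )
            setattr(self, f, arr)

    def for_region(self, region: str) -> "RegionTransitions":
        r = region_index(region)
        return RegionTransitions(
            initiation=self.initiation[r],
            cessation=self.cessation[r],
            restart=self.restart[r],
        )


@dataclass
class RegionTransitions:
    """One region's transition probabilities, per (sex, age)."""

    initiation: np.ndarray
    cessation: np.ndarray
    restart: np.ndarray


@dataclass
class DiseaseInputs:
    """COPD prevalence/incidence and smoking relative risks on COPD.

    Relative risks are stored per single year of age (age-group inputs
    are expanded at load time so the same value applies to every age in
    the group).  ``disability_weight`` is the weight applied to a year
    lived with COPD when computing disability-adjusted life expectancy.
    """

    copd_prevalence: np.ndarray
    copd_incidence: np.ndarray
    rr_copd_current: np.ndarray
    rr_copd_former: np.ndarray
    disability_weight: float = 0.2

    def __post_init__(self):
        for f in ("copd_prevalence", "copd_incidence", "rr_copd_current", "rr_copd_former"):
            setattr(self, f, _as_sex_age(f, getattr(self, f)))
        self.disability_weight = float(self.disability_weight)


@dataclass
class MortalityInputs:
    """All-cause annual death probabilities and smoking RRs on mortality."""

    all_cause: np.ndarray          # (2, 96) probability
    rr_mort_current: np.ndarray    # (2,) per sex
    rr_mort_former: np.ndarray     # (2,) per sex

    def __post_init__(self):
        self.all_cause = _as_sex_age("all_cause", self.all_cause)
        self.rr_mort_current = np.asarray(self.rr_mort_current, dtype=float).reshape(2)
        self.rr_mort_former = np.asarray(self.rr_mort_former, dtype=float).reshape(2)


@dataclass
class InputBundle:
    """Complete validated parameter set for one simulated population."""

    demographics: Demographics
    smoking: SmokingPrevalence
    transitions: TransitionRates
    disease: DiseaseInputs
    mortality: MortalityInputs
    region: str = "north"
    horizon_years: int = 40
    base_year: int = 2018

    def copy(self) -> "InputBundle":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# validation

def _check_range(report, table, arr, lo, hi, label):
    bad = np.argwhere((arr < lo) | (arr > hi) | ~np.isfinite(arr))
    for idx in bad[:20]:
        sex = SEXES[idx[0]] if arr.shape[0] == 2 and arr.ndim >= 2 else "?"
        age = idx[-1]
        report.append(f"{table}: {label} out of [{lo}, {hi}] at (sex={sex}, age={age})")


def validate_bundle(bundle: InputBundle) -> list[str]:
    """Return a list of invariant violations; an empty list means valid.

    Never mutates the bundle.  Every structural invariant of the data
    model is checked: value ranges, sum-to-one of smoking states, the
    age eligibility floors (no smoking before 11, no quitting before 16,
    no restarting before 22, no COPD before 40) and relative-risk
    ordering current >= former >= 1.
    """
    rep: list[str] = []
    d, s, t, dis, mort = (
        bundle.demographics, bundle.smoking, bundle.transitions,
        bundle.disease, bundle.mortality,
    )

    if bundle.region not in REGIONS:
        rep.append(f"config: unknown region {bundle.region!r}")
    if bundle.horizon_years < 0:
        rep.append("config: horizon_years must be >= 0")
    if not (0.0 <= dis.disability_weight <= 1.0):
        rep.append("config: disability_weight outside [0, 1]")

    if np.any(d.counts < 0):
        _check_range(rep, "population", d.counts, 0, np.inf, "count")
    if np.any(d.newborns < 0):
        rep.append("newborns: negative count")
    if d.newborns.shape[1] < bundle.horizon_years:
        rep.append(
            f"newborns: series covers {d.newborns.shape[1]} years "
            f"but horizon is {bundle.horizon_years}"
        )

    stack = s.as_stack()
    _check_range(rep, "smoking_prevalence", stack, 0, 1, "proportion")
    bad_sum = np.argwhere(np.abs(stack.sum(axis=-1) - 1.0) > _SUM_TOL)
    for sx, age in bad_sum[:20]:
        rep.append(
            f"smoking_prevalence: states sum to {stack[sx, age].sum():.6f} != 1 "
            f"at (sex={SEXES[sx]}, age={age})"
        )
    if np.any(s.p_current[:, :MIN_AGE_INITIATION] != 0):
        rep.append(f"smoking_prevalence: current smoking before age {MIN_AGE_INITIATION}")
    if np.any(s.p_former[:, :MIN_AGE_CESSATION] != 0):
        rep.append(f"smoking_prevalence: former smoking before age {MIN_AGE_CESSATION}")

    for name, arr, floor in (
        ("initiation", t.initiation, MIN_AGE_INITIATION),
        ("cessation", t.cessation, MIN_AGE_CESSATION),
        ("restart", t.restart, MIN_AGE_RESTART),
    ):
        _check_range(rep, "transitions", arr, 0, 1, name)
        if np.any(arr[:, :, :floor] != 0):
            rep.append(f"transitions: {name} before age {floor}")

    _check_range(rep, "copd", dis.copd_prevalence, 0, 1, "prevalence")
    _check_range(rep, "copd", dis.copd_incidence, 0, 1, "incidence")
    if np.any(dis.copd_prevalence[:, :MIN_AGE_COPD] != 0) or np.any(
        dis.copd_incidence[:, :MIN_AGE_COPD] != 0
    ):
        rep.append(f"copd: COPD before age {MIN_AGE_COPD}")
    if np.any(dis.rr_copd_former < 1) or np.any(dis.rr_copd_current < dis.rr_copd_former):
        rep.append("relative_risks: require rr_copd_current >= rr_copd_former >= 1")

    _check_range(rep, "mortality", mort.all_cause, 0, 1, "all_cause")
    if np.any(mort.rr_mort_former < 1) or np.any(mort.rr_mort_current < mort.rr_mort_former):
        rep.append("relative_risks: require rr_mort_current >= rr_mort_former >= 1")

    return rep


def assert_valid(bundle: InputBundle) -> None:
    rep = validate_bundle(bundle)
    if rep:
        raise BundleValidationError("; ".join(rep))


# ---------------------------------------------------------------------------
# CSV / YAML round-trip

_FILES = (
    "population.csv", "newborns.csv", "smoking_prevalence.csv", "transitions.csv",
    "copd.csv", "mortality.csv", "relative_risks.csv", "config.yaml",
)

_FLOAT_FMT = "%.17g"


def _pivot_sex_age(df: pd.DataFrame, table: str, value_cols: list[str]) -> list[np.ndarray]:
    """Turn a long (sex, age, values...) table into dense (2, 96) arrays."""
    arrays = [np.full((2, N_AGES), np.nan) for _ in value_cols]
    for _, row in df.iterrows():
        sx = sex_index(str(row["sex"]))
        age = int(row["age"])
        if not 0 <= age < N_AGES:
            raise BundleValidationError(f"{table}: age {age} outside 0..{N_AGES - 1}")
        for arr, col in zip(arrays, value_cols):
            arr[sx, age] = row[col]
    for arr, col in zip(arrays, value_cols):
        missing = np.argwhere(np.isnan(arr))
        if missing.size:
            sx, age = missing[0]
            raise BundleValidationError(
                f"{table}: missing {col} row for (sex={SEXES[sx]}, age={age})"
            )
    return arrays


def load_bundle(directory: str | Path) -> InputBundle:
    """Read a bundle directory (seven CSV tables + config.yaml).

    Age-group rows in relative_risks.csv (``age_low``..``age_high``)
    are expanded to single years of age, the same value applied to all
    ages in the group.  The returned bundle has been validated; any
    violation raises :class:`BundleValidationError` naming the table
    and cell.
    """
    directory = Path(directory)
    for fname in _FILES:
        if not (directory / fname).exists():
            raise FileNotFoundError(f"bundle file missing: {directory / fname}")

    with open(directory / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)

    pop = pd.read_csv(directory / "population.csv")
    (counts,) = _pivot_sex_age(pop, "population", ["count"])

    nb = pd.read_csv(directory / "newborns.csv")
    horizon = int(cfg["horizon_years"])
    n_years = max(horizon, int(nb["year_offset"].max()) if len(nb) else 0)
    newborns = np.zeros((2, n_years))
    for _, row in nb.iterrows():
        off = int(row["year_offset"])
        if off < 1:
            raise BundleValidationError("newborns: year_offset must be >= 1")
        newborns[sex_index(str(row["sex"])), off - 1] = row["count"]

    smk = pd.read_csv(directory / "smoking_prevalence.csv")
    p_never, p_current, p_former = _pivot_sex_age(
        smk, "smoking_prevalence", ["never", "current", "former"]
    )

    tr = pd.read_csv(directory / "transitions.csv")
    init = np.full((2, 2, N_AGES), np.nan)
    cess = np.full((2, 2, N_AGES), np.nan)
    rest = np.full((2, 2, N_AGES), np.nan)
    for _, row in tr.iterrows():
        r = region_index(str(row["region"]))
        sx = sex_index(str(row["sex"]))
        age = int(row["age"])
        init[r, sx, age] = row["initiation"]
        cess[r, sx, age] = row["cessation"]
        rest[r, sx, age] = row["restart"]
    if np.isnan(init).any() or np.isnan(cess).any() or np.isnan(rest).any():
        raise BundleValidationError("transitions: incomplete (region, sex, age) coverage")

    cp = pd.read_csv(directory / "copd.csv")
    copd_prev, copd_inc = _pivot_sex_age(cp, "copd", ["prevalence", "incidence"])

    mt = pd.read_csv(directory / "mortality.csv")
    (all_cause,) = _pivot_sex_age(mt, "mortality", ["all_cause"])

    rr = pd.read_csv(directory / "relative_risks.csv")
    rr_copd_c = np.ones((2, N_AGES))
    rr_copd_f = np.ones((2, N_AGES))
    rr_mort_c = np.ones(2)
    rr_mort_f = np.ones(2)
    for _, row in rr.iterrows():
        sx = sex_index(str(row["sex"]))
        lo, hi = int(row["age_low"]), int(row["age_high"])
        if not (0 <= lo <= hi < N_AGES):
            raise BundleValidationError(f"relative_risks: bad age band {lo}-{hi}")
        outcome = str(row["outcome"])
        if outcome == "copd":
            rr_copd_c[sx, lo : hi + 1] = row["rr_current"]
            rr_copd_f[sx, lo : hi + 1] = row["rr_former"]
        elif outcome == "mortality":
            rr_mort_c[sx] = row["rr_current"]
            rr_mort_f[sx] = row["rr_former"]
        else:
            raise BundleValidationError(f"relative_risks: unknown outcome {outcome!r}")

    bundle = InputBundle(
        demographics=Demographics(counts=counts, newborns=newborns),
        smoking=SmokingPrevalence(p_never=p_never, p_current=p_current, p_former=p_former),
        transitions=TransitionRates(initiation=init, cessation=cess, restart=rest),
        disease=DiseaseInputs(
            copd_prevalence=copd_prev,
            copd_incidence=copd_inc,
            rr_copd_current=rr_copd_c,
            rr_copd_former=rr_copd_f,
            disability_weight=float(cfg.get("disability_weight", 0.2)),
        ),
        mortality=MortalityInputs(
            all_cause=all_cause, rr_mort_current=rr_mort_c, rr_mort_former=rr_mort_f
        ),
        region=str(cfg["region"]),
        horizon_years=horizon,
        base_year=int(cfg["base_year"]),
    )
    assert_valid(bundle)
    return bundle


def _long(df_cols: dict) -> pd.DataFrame:
    return pd.DataFrame(df_cols)


def write_bundle(bundle: InputBundle, directory: str | Path) -> list[Path]:
    """Write a bundle to a directory; inverse of :func:`load_bundle`.

    Writes are deterministic (identical bundles produce identical file
    bytes) and floats carry 17 significant digits so the round trip is
    exact to well below 1e-12.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    sex_col = np.repeat(SEXES, N_AGES)
    age_col = np.tile(AGES, 2)

    def _write(name: str, df: pd.DataFrame):
        path = directory / name
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written.append(path)

    d = bundle.demographics
    _write("population.csv", _long(
        {"sex": sex_col, "age": age_col, "count": d.counts.ravel()}
    ))
    n_years = d.newborns.shape[1]
    _write("newborns.csv", _long({
        "sex": np.repeat(SEXES, n_years),
        "year_offset": np.tile(np.arange(1, n_years + 1), 2),
        "count": d.newborns.ravel(),
    }))
    s = bundle.smoking
    _write("smoking_prevalence.csv", _long({
        "sex": sex_col, "age": age_col,
        "never": s.p_never.ravel(), "current": s.p_current.ravel(),
        "former": s.p_former.ravel(),
    }))
    t = bundle.transitions
    _write("transitions.csv", _long({
        "region": np.repeat(REGIONS, 2 * N_AGES),
        "sex": np.tile(sex_col, 2),
        "age": np.tile(AGES, 4),
        "initiation": t.initiation.ravel(),
        "cessation": t.cessation.ravel(),
        "restart": t.restart.ravel(),
    }))
    dis = bundle.disease
    _write("copd.csv", _long({
        "sex": sex_col, "age": age_col,
        "prevalence": dis.copd_prevalence.ravel(),
        "incidence": dis.copd_incidence.ravel(),
    }))
    m = bundle.mortality
    _write("mortality.csv", _long(
        {"sex": sex_col, "age": age_col, "all_cause": m.all_cause.ravel()}
    ))
    rr_rows = {
        "outcome": list(np.repeat("copd", 2 * N_AGES)) + ["mortality", "mortality"],
        "sex": list(sex_col) + list(SEXES),
        "age_low": list(age_col) + [0, 0],
        "age_high": list(age_col) + [N_AGES - 1, N_AGES - 1],
        "rr_current": list(dis.rr_copd_current.ravel()) + list(m.rr_mort_current),
        "rr_former": list(dis.rr_copd_former.ravel()) + list(m.rr_mort_former),
    }
    _write("relative_risks.csv", _long(rr_rows))

    cfg = {
        "base_year": int(bundle.base_year),
        "horizon_years": int(bundle.horizon_years),
        "region": bundle.region,
        "disability_weight": float(bundle.disease.disability_weight),
    }
    cfg_path = directory / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    written.append(cfg_path)
    return written


def bundles_allclose(a: InputBundle, b: InputBundle, tol: float = 1e-12) -> bool:
    """Field-by-field numeric comparison of two bundles."""
    pairs = [
        (a.demographics.counts, b.demographics.counts),
        (a.demographics.newborns, b.demographics.newborns),
        (a.smoking.as_stack(), b.smoking.as_stack()),
        (a.transitions.initiation, b.transitions.initiation),
        (a.transitions.cessation, b.transitions.cessation),
        (a.transitions.restart, b.transitions.restart),
        (a.disease.copd_prevalence, b.disease.copd_prevalence),
        (a.disease.copd_incidence, b.disease.copd_incidence),
        (a.disease.rr_copd_current, b.disease.rr_copd_current),
        (a.disease.rr_copd_former, b.disease.rr_copd_former),
        (a.mortality.all_cause, b.mortality.all_cause),
        (a.mortality.rr_mort_current, b.mortality.rr_mort_current),
        (a.mortality.rr_mort_former, b.mortality.rr_mort_former),
    ]
    if (a.region, a.horizon_years, a.base_year) != (b.region, b.horizon_years, b.base_year):
        return False
    if abs(a.disease.disability_weight - b.disease.disability_weight) > tol:
        return False
    return all(x.shape == y.shape and np.allclose(x, y, rtol=0, atol=tol) for x, y in pairs)
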