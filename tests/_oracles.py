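"""Independent oracles used by the tests.

Everything here is built by explicit enumeration over the state space,
deliberately avoiding the vectorised code paths in the package.
"""

import numpy as np

from tobaccohia.bundle import N_AGES
from tobaccohia.engine import build_state_rates


def state_index(sex, age, smoke, copd):
    """Flat index into the (2, 96, 3, 2) state space."""
    return ((sex * N_AGES + age) * 3 + smoke) * 2 + copd


N_STATES = 2 * N_AGES * 3 * 2


def build_one_year_matrix(bundle):
    """Dense one-year transition matrix assembled cell by cell.

    Composes, per source cell, the annual cycle: smoking transition ->
    COPD incidence (disease-free only) -> survival -> age + 1.  Age-95
    survivors map nowhere (they exit); newborn entry is excluded, so
    this is the pure linear part of the dynamics.
    """
    rates = build_state_rates(bundle)
    trans = bundle.transitions.for_region(bundle.region)
    M = np.zeros((N_STATES, N_STATES))
    for sex in range(2):
        for age in range(N_AGES - 1):
            iota = trans.initiation[sex, age]
            kappa = trans.cessation[sex, age]
            rho = trans.restart[sex, age]
            # smoking transition probabilities smoke_from -> smoke_to
            P = np.array([
                [1 - iota, iota, 0.0],
                [0.0, 1 - kappa, kappa],
                [0.0, rho, 1 - rho],
            ])
            for smoke_from in range(3):
                for copd_from in range(2):
                    src = state_index(sex, age, smoke_from, copd_from)
                    for smoke_to in range(3):
                        p_move = P[smoke_from, smoke_to]
                        if p_move == 0.0:
                            continue
                        inc = rates.incidence_by_smoking[sex, age, smoke_to]
                        surv = 1.0 - rates.mortality_by_smoking[sex, age, smoke_to]
                        if copd_from == 0:
                            dst_no = state_index(sex, age + 1, smoke_to, 0)
                            dst_yes = state_index(sex, age + 1, smoke_to, 1)
                            M[dst_no, src] += p_move * (1 - inc) * surv
                            M[dst_yes, src] += p_move * inc * surv
                        else:
                            dst = state_index(sex, age + 1, smoke_to, 1)
                            M[dst, src] += p_move * surv
    return M


def state_vector(state):
    return state.counts.ravel().copy()


def enumerate_cohort_le(age, q, cycles, tail_m):
    """Half-cycle-corrected survival enumeration for a constant hazard cohort.

    One person aged ``age`` faces death probability ``q`` each year for
    ``cycles`` years; survivors then receive a 1/``tail_m`` tail.
    """
    alive = 1.0
    years = 0.0
    for _ in range(cycles):
        nxt = alive * (1.0 - q)
        years += 0.5 * (alive + nxt)
        alive = nxt
    tail = alive / tail_m if tail_m > 0 else 0.0
    return age + years + tail
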