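"""Yearly-cycle cohort state-transition model of breast-cancer progression.

States are DISEASE_FREE, RECURRENCE (an absorbing morbidity state covering
recurrent and metastatic disease), DEAD_BC and DEAD_OTHER.  During the
disease window (the first 10 years by default) the cohort faces yearly
breast-cancer mortality and recurrence probabilities, optionally inflated on
the hazard scale for omitted adjuvant therapy, in competition with
age-specific all-cause mortality from a life table.  After the window only
all-cause mortality applies, run to the terminal age of the life table for a
life-long horizon.

Competing risks within a cycle are resolved by converting each yearly
probability to a constant hazard, combining hazards, and allocating exits
proportionally to the cause-specific hazards; this avoids any dependence on
the order in which events are applied.  Breast-cancer mortality acts from
both alive states at the same (modified) rate.  Life years accrue as alive
occupancy at the end of each cycle lived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

OCCUPANCY_TOL = 1e-10


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual all-cause death probabilities.

    Rows are (age, q) with strictly increasing ages and q = 1 at the terminal
    age; ages are yearly and contiguous lookups use the row at the attained
    age.
    """

    rows: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("life table is empty")
        ages = [r[0] for r in self.rows]
        if ages != sorted(set(ages)):
            raise ValueError("life table ages must be strictly increasing")
        for age, q in self.rows:
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"life table q at age {age} outside [0, 1]: {q}")
        if self.rows[-1][1] != 1.0:
            raise ValueError("terminal life-table age must have q = 1")

    @property
    def min_age(self) -> int:
        return self.rows[0][0]

    @property
    def terminal_age(self) -> int:
        return self.rows[-1][0]

    def q_at(self, age: float) -> float:
        """Annual death probability for the year starting at ``age``."""
        if age < self.min_age:
            raise ValueError(f"age {age} below life table start {self.min_age}")
        if age >= self.terminal_age:
            return 1.0
        q = None
        for a, qa in self.rows:
            if a <= age:
                q = qa
            else:
                break
        return q


def modified_probability(p: float, hr_product: float) -> float:
    """Apply a hazard-ratio product to a yearly probability.

    The probability is converted to a constant hazard, scaled, and converted
    back: ``1 - (1 - p) ** hr``, capped at 1.  ``p = 1`` stays 1 for any
    hazard ratio.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if hr_product < 0.0:
        raise ValueError(f"hazard-ratio product must be non-negative, got {hr_product}")
    if p >= 1.0:
        return 1.0
    return min(1.0, -math.expm1(hr_product * math.log1p(-p)))


def modified_rates(
    yearly_bc_mortality: float, yearly_recurrence: float, hr_product: float
) -> tuple[float, float]:
    """Yearly breast-cancer mortality and recurrence after hazard modification.

    The same hazard-ratio product (multiplicative over omitted therapies)
    applies to both transitions.
    """
    return (
        modified_probability(yearly_bc_mortality, hr_product),
        modified_probability(yearly_recurrence, hr_product),
    )


def _hazard(p: float) -> float:
    return math.inf if p >= 1.0 else -math.log1p(-p)


def _compete(hazards: tuple[float, ...]) -> tuple[float, tuple[float, ...]]:
    """Total exit probability and cause shares for competing constant hazards."""
    if any(math.isinf(h) for h in hazards):
        infs = [1.0 if math.isinf(h) else 0.0 for h in hazards]
        k = sum(infs)
        return 1.0, tuple(v / k for v in infs)
    total = sum(hazards)
    if total == 0.0:
        return 0.0, tuple(0.0 for _ in hazards)
    p_any = -math.expm1(-total)
    return p_any, tuple(h / total for h in hazards)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy of one patient stratum.

    Arrays are indexed by cycle t = 0..T; cycle t covers ages
    ``start_age + t - 1`` to ``start_age + t``.  ``new_recurrence[t]`` is the
    occupancy entering RECURRENCE during cycle t (used for one-off recurrence
    costs).
    """

    start_age: int
    disease_free: np.ndarray
    recurrence: np.ndarray
    dead_bc: np.ndarray
    dead_other: np.ndarray
    new_recurrence: np.ndarray

    @property
    def horizon(self) -> int:
        return len(self.disease_free) - 1

    @property
    def alive(self) -> np.ndarray:
        return self.disease_free + self.recurrence

    def life_years(self, discount_rate: float = 0.0) -> float:
        """(Discounted) expected life years: alive occupancy per cycle lived."""
        t = np.arange(1, self.horizon + 1)
        w = (1.0 + discount_rate) ** (-t.astype(float))
        return float(np.sum(self.alive[1:] * w))


def run_cohort(
    disease,
    life: LifeTable,
    start_age: int,
    horizon: int | None = None,
    hr_product: float = 1.0,
) -> CohortTrace:
    """Run the cohort model for one stratum.

    ``disease`` is a :class:`~nils_cea.config.DiseaseBlock` (or any object
    with ``yearly_bc_mortality``, ``yearly_recurrence`` and
    ``bc_window_years``).  ``hr_product`` is the combined hazard ratio for the
    stratum's omitted therapies (1 for fully treated strata).  The default
    horizon runs to the life table's terminal age.
    """
    if start_age < life.min_age or start_age >= life.terminal_age:
        raise ValueError(
            f"start_age {start_age} outside life table range "
            f"[{life.min_age}, {life.terminal_age})"
        )
    if horizon is None:
        horizon = life.terminal_age - start_age
    if horizon < 0:
        raise ValueError(f"negative horizon {horizon}")

    p_mort, p_rec = modified_rates(
        disease.yearly_bc_mortality, disease.yearly_recurrence, hr_product
    )
    window = disease.bc_window_years

    T = horizon
    df = np.zeros(T + 1)
    rec = np.zeros(T + 1)
    dbc = np.zeros(T + 1)
    doth = np.zeros(T + 1)
    new_rec = np.zeros(T + 1)
    df[0] = 1.0

    for t in range(1, T + 1):
        age = start_age + t - 1
        q = life.q_at(age)
        h_ac = _hazard(q)
        if t <= window:
            h_bc, h_rc = _hazard(p_mort), _hazard(p_rec)
        else:
            h_bc, h_rc = 0.0, 0.0

        p_exit_df, (s_bc, s_rc, s_ac) = _compete((h_bc, h_rc, h_ac))
        p_exit_rec, (r_bc, r_ac) = _compete((h_bc, h_ac))

        leave_df = df[t - 1] * p_exit_df
        leave_rec = rec[t - 1] * p_exit_rec
        new_rec[t] = leave_df * s_rc
        df[t] = df[t - 1] - leave_df
        rec[t] = rec[t - 1] - leave_rec + new_rec[t]
        dbc[t] = dbc[t - 1] + leave_df * s_bc + leave_rec * r_bc
        doth[t] = doth[t - 1] + leave_df * s_ac + leave_rec * r_ac

    return CohortTrace(
        start_age=start_age,
        disease_free=df,
        recurrence=rec,
        dead_bc=dbc,
        dead_other=doth,
        new_recurrence=new_rec,
    )


def bc_deaths_at_horizon(trace: CohortTrace, horizon: int) -> float:
    """Cumulative breast-cancer death probability at the given cycle."""
    if not 0 <= horizon <= trace.horizon:
        raise ValueError(f"horizon {horizon} outside trace (0..{trace.horizon})")
    return float(trace.dead_bc[horizon])
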