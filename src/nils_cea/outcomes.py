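"""Discounted cost and QALY accumulation over a cohort trace.

Costs and health effects are discounted at an annual rate (default 3%) with
payoffs counted at the end of each cycle lived; one-off costs incurred at
model entry (surgery, complications, therapy initiation) fall at cycle 0 and
are undiscounted.  Utilities are age-adjusted population baselines minus
condition decrements (chemotherapy year, recurrence, lymphedema), clamped
below at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (
    AxillaryExtent,
    ComplicationsBlock,
    CostsBlock,
    EconomicsBlock,
    SurgerySubgroup,
    UtilitiesBlock,
)
from .progression import CohortTrace
from .treatments import TreatmentBundle, complication_cost_for_extent

EXTENDED_ENDOCRINE_CYCLES = range(6, 11)  # "beyond 5 years": cycles 6-10


def discount_factor(t: int, rate: float) -> float:
    """Present-value weight of a payoff at the end of cycle ``t``: (1+r)^-t."""
    if t < 0:
        raise ValueError(f"cycle index must be non-negative, got {t}")
    if rate < 0.0:
        raise ValueError(f"discount rate must be non-negative, got {rate}")
    return (1.0 + rate) ** (-float(t))


def _weights(trace: CohortTrace, rate: float) -> np.ndarray:
    t = np.arange(trace.horizon + 1, dtype=float)
    return (1.0 + rate) ** (-t)


def accumulate_costs(
    trace: CohortTrace,
    bundle: TreatmentBundle,
    subgroup: SurgerySubgroup,
    costs: CostsBlock,
    complications: ComplicationsBlock,
    settings: EconomicsBlock,
) -> float:
    """Expected discounted lifetime cost per patient of one stratum (EUR).

    Cycle 0 carries breast surgery, axillary surgery, expected complication
    costs and adjuvant therapy initiation (radiotherapy, chemotherapy and
    HER2 therapy priced as one-off courses).  Recurring costs are extended
    endocrine therapy in cycles 6-10 for the diagnosed-positive ER+ share
    (while alive) and recurrence care: a one-off cost on entering RECURRENCE
    plus a yearly metastatic-care cost while in that state.
    """
    w = _weights(trace, settings.discount_rate_annual)
    extent = bundle.axillary_extent

    upfront = (
        costs.surgery_bcs if subgroup is SurgerySubgroup.BCS else costs.surgery_mastectomy
    )
    if extent is not AxillaryExtent.NONE:
        upfront += costs.slnb
    if extent is AxillaryExtent.SLNB_PLUS_ALND:
        upfront += costs.alnd
    upfront += complication_cost_for_extent(extent, complications)
    if bundle.radiotherapy:
        upfront += costs.radiotherapy
    upfront += bundle.chemotherapy_prob * costs.chemotherapy
    upfront += bundle.her2_therapy_prob * costs.her2_therapy

    total = upfront
    alive = trace.alive
    for t in EXTENDED_ENDOCRINE_CYCLES:
        if t <= trace.horizon:
            total += (
                bundle.extended_endocrine_prob
                * costs.extended_endocrine_per_year
                * alive[t]
                * w[t]
            )
    total += costs.recurrence_onset * float(np.sum(trace.new_recurrence * w))
    total += costs.metastatic_per_year * float(np.sum(trace.recurrence * w))
    return float(total)


def accumulate_qalys(
    trace: CohortTrace,
    bundle: TreatmentBundle,
    p_lymphedema: float,
    utils: UtilitiesBlock,
    settings: EconomicsBlock,
    lymphedema_decrement: float | None = None,
) -> float:
    """Expected discounted QALYs per patient of one stratum.

    Per cycle, each alive sub-profile (disease-free or recurrent, with or
    without lymphedema, with or without the year-1 chemotherapy decrement)
    contributes occupancy x max(0, baseline utility at the attained age minus
    applicable decrements) x discount factor.  Lymphedema is assigned at
    surgery (independently of later disease events) and its decrement applies
    life-long; ``lymphedema_decrement`` overrides the configured value, which
    underpins the break-even threshold analysis.
    """
    if not 0.0 <= p_lymphedema <= 1.0:
        raise ValueError(f"p_lymphedema {p_lymphedema} outside [0, 1]")
    d_lym = utils.decrement_lymphedema if lymphedema_decrement is None else lymphedema_decrement
    if d_lym < 0.0:
        raise ValueError(f"lymphedema decrement must be non-negative, got {d_lym}")

    w = _weights(trace, settings.discount_rate_annual)
    total = 0.0
    for t in range(1, trace.horizon + 1):
        age = trace.start_age + t - 1
        base = utils.at_age(age)
        chemo_dec = utils.decrement_chemotherapy if t == 1 else 0.0
        cycle = 0.0
        for occ, state_dec in (
            (trace.disease_free[t], 0.0),
            (trace.recurrence[t], utils.decrement_recurrence),
        ):
            if occ == 0.0:
                continue
            for lymph_w, lymph_dec in ((1.0 - p_lymphedema, 0.0), (p_lymphedema, d_lym)):
                if lymph_w == 0.0:
                    continue
                for chemo_w, c_dec in (
                    (1.0 - bundle.chemotherapy_prob, 0.0),
                    (bundle.chemotherapy_prob, chemo_dec),
                ):
                    if chemo_w == 0.0:
                        continue
                    u = max(0.0, base - state_dec - lymph_dec - c_dec)
                    cycle += occ * lymph_w * chemo_w * u
        total += cycle * w[t]
    return float(total)


@dataclass(frozen=True)
class StrategyResult:
    """Aggregate outcomes of one diagnostic strategy, per ``cohort_size`` patients.

    Costs, QALYs and life years are discounted; breast-cancer deaths are the
    cumulative expectation at the end of the 10-year disease window (constant
    thereafter).
    """

    label: str
    population: str
    cohort_size: int
    total_cost: float
    total_qalys: float
    total_life_years: float
    bc_deaths: float
    slnb_count: float
    alnd_count: float
    lymphedema_cases: float

    def __post_init__(self) -> None:
        if self.total_qalys > self.total_life_years + 1e-9:
            raise ValueError("QALYs cannot exceed life years (utilities are at most 1)")
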