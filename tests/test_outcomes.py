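"""Discounted cost and QALY accumulation."""

import numpy as np
import pytest

from nils_cea import accumulate_costs, accumulate_qalys, discount_factor, run_cohort
from nils_cea.config import (
    AxillaryExtent,
    ComplicationsBlock,
    CostsBlock,
    DiseaseBlock,
    EconomicsBlock,
    ExtentMap,
    SurgerySubgroup,
    UtilitiesBlock,
)
from nils_cea.progression import LifeTable
from nils_cea.treatments import TreatmentBundle

ZERO_COSTS = CostsBlock(
    surgery_bcs=0, surgery_mastectomy=0, slnb=0, alnd=0, radiotherapy=0,
    chemotherapy=0, her2_therapy=0, extended_endocrine_per_year=0,
    recurrence_onset=0, metastatic_per_year=0,
)
ZERO_COMPLICATIONS = ComplicationsBlock(
    lymphedema=ExtentMap(none=0, slnb_only=0, slnb_plus_alnd=0),
    seroma=ExtentMap(none=0, slnb_only=0, slnb_plus_alnd=0),
    infection=ExtentMap(none=0, slnb_only=0, slnb_plus_alnd=0),
    cost_lymphedema=0, cost_seroma=0, cost_infection=0,
)


def bundle(extent=AxillaryExtent.NONE, chemo=0.0, endo=0.0, her2=0.0, rt=False):
    return TreatmentBundle(
        alnd=extent is AxillaryExtent.SLNB_PLUS_ALND,
        radiotherapy=rt,
        chemotherapy_prob=chemo,
        extended_endocrine_prob=endo,
        her2_therapy_prob=her2,
        axillary_extent=extent,
    )


def flat_life_table(q: float, terminal: int = 100) -> LifeTable:
    return LifeTable(rows=tuple((a, q) for a in range(terminal)) + ((terminal, 1.0),))


@pytest.fixture(scope="module")
def base_trace():
    disease = DiseaseBlock(yearly_bc_mortality=0.02, yearly_recurrence=0.04)
    return run_cohort(disease, flat_life_table(0.01), start_age=60)


@pytest.mark.parametrize(
    "t, rate, expected",
    [(0, 0.03, 1.0), (1, 0.03, 1.0 / 1.03), (5, 0.0, 1.0), (2, 0.03, 1.03**-2)],
)
def test_discount_factor(t, rate, expected):
    assert discount_factor(t, rate) == pytest.approx(expected, rel=1e-12)


def test_discount_factor_rejects_invalid():
    with pytest.raises(ValueError):
        discount_factor(-1, 0.03)
    with pytest.raises(ValueError):
        discount_factor(1, -0.01)


def test_zero_cost_parameters_give_zero(base_trace):
    econ = EconomicsBlock()
    c = accumulate_costs(
        base_trace, bundle(AxillaryExtent.SLNB_PLUS_ALND, chemo=1, her2=1, rt=True),
        SurgerySubgroup.BCS, ZERO_COSTS, ZERO_COMPLICATIONS, econ,
    )
    assert c == 0.0


def test_single_upfront_cost_undiscounted(base_trace):
    """A lone cycle-0 cost enters at face value regardless of the discount rate."""
    costs = ZERO_COSTS.model_copy(update={"surgery_bcs": 4321.0})
    c = accumulate_costs(
        base_trace, bundle(), SurgerySubgroup.BCS, costs, ZERO_COMPLICATIONS,
        EconomicsBlock(discount_rate_annual=0.03),
    )
    assert c == pytest.approx(4321.0, abs=1e-12)


def test_recurring_metastatic_cost_matches_hand_sum(base_trace):
    """Per-year cost while in the recurrent state equals the explicit
    occupancy-weighted discounted sum."""
    costs = ZERO_COSTS.model_copy(update={"metastatic_per_year": 1000.0})
    econ = EconomicsBlock(discount_rate_annual=0.03)
    c = accumulate_costs(
        base_trace, bundle(), SurgerySubgroup.BCS, costs, ZERO_COMPLICATIONS, econ
    )
    t = np.arange(base_trace.horizon + 1)
    hand = float(np.sum(1000.0 * base_trace.recurrence * 1.03 ** (-t.astype(float))))
    assert c == pytest.approx(hand, rel=1e-12)


def test_extended_endocrine_window(base_trace):
    """Extended endocrine therapy is billed in cycles 6-10 only, for the
    diagnosed-positive share, weighted by survival."""
    costs = ZERO_COSTS.model_copy(update={"extended_endocrine_per_year": 100.0})
    econ = EconomicsBlock(discount_rate_annual=0.0)
    c = accumulate_costs(
        base_trace, bundle(AxillaryExtent.SLNB_PLUS_ALND, endo=0.5),
        SurgerySubgroup.BCS, costs, ZERO_COMPLICATIONS, econ,
    )
    hand = 0.5 * 100.0 * float(np.sum(base_trace.alive[6:11]))
    assert c == pytest.approx(hand, rel=1e-12)


def test_full_utility_no_discounting_recovers_life_years():
    """Baseline utility 1, no decrements, no discounting, no disease: QALYs
    equal terminal minus start age."""
    disease = DiseaseBlock(yearly_bc_mortality=0.0, yearly_recurrence=0.0)
    trace = run_cohort(disease, flat_life_table(0.0), start_age=60)
    utils = UtilitiesBlock(
        age_to_utility={0: 1.0}, decrement_chemotherapy=0.0,
        decrement_recurrence=0.0, decrement_lymphedema=0.0,
    )
    q = accumulate_qalys(trace, bundle(), 0.0, utils, EconomicsBlock(discount_rate_annual=0.0))
    assert q == pytest.approx(40.0, abs=1e-10)


def test_lymphedema_decrement_linearity(base_trace, cfg):
    """QALYs are exactly affine in the lymphedema decrement (negative slope),
    the property underpinning the break-even analysis."""
    econ = EconomicsBlock()
    b = bundle(AxillaryExtent.SLNB_PLUS_ALND, chemo=0.4)
    p_lymph = 0.223
    d_grid = [0.0, 0.05, 0.1, 0.2, 0.3]
    q = [
        accumulate_qalys(base_trace, b, p_lymph, cfg.utilities, econ, lymphedema_decrement=d)
        for d in d_grid
    ]
    slope = (q[1] - q[0]) / d_grid[1]
    assert slope < 0.0
    for d, qi in zip(d_grid, q):
        assert qi == pytest.approx(q[0] + slope * d, abs=1e-9)
    # slope equals -1 x discounted lymphedema-affected alive person-years
    t = np.arange(base_trace.horizon + 1)
    person_years = float(np.sum(base_trace.alive[1:] * 1.03 ** (-t[1:].astype(float))))
    assert slope == pytest.approx(-p_lymph * person_years, rel=1e-9)


def test_qalys_never_exceed_life_years(base_trace, cfg):
    econ = EconomicsBlock()
    q = accumulate_qalys(
        base_trace, bundle(AxillaryExtent.SLNB_ONLY, chemo=0.5), 0.063, cfg.utilities, econ
    )
    assert q <= base_trace.life_years(econ.discount_rate_annual)


def test_discounting_never_increases_totals(base_trace, cfg):
    """Discounted payoff streams are bounded by their undiscounted sums."""
    b = bundle(AxillaryExtent.SLNB_ONLY, chemo=0.5, endo=0.3, her2=0.1, rt=True)
    disc = EconomicsBlock(discount_rate_annual=0.03)
    undisc = EconomicsBlock(discount_rate_annual=0.0)
    c_disc = accumulate_costs(base_trace, b, SurgerySubgroup.BCS, cfg.costs,
                              cfg.complications, disc)
    c_undisc = accumulate_costs(base_trace, b, SurgerySubgroup.BCS, cfg.costs,
                                cfg.complications, undisc)
    assert c_disc <= c_undisc
    q_disc = accumulate_qalys(base_trace, b, 0.063, cfg.utilities, disc)
    q_undisc = accumulate_qalys(base_trace, b, 0.063, cfg.utilities, undisc)
    assert q_disc <= q_undisc
    assert base_trace.life_years(0.03) <= base_trace.life_years(0.0)


def test_zero_discount_rate_regression(base_trace, cfg):
    """Setting the rate to 0 reproduces plain (undiscounted) sums."""
    econ0 = EconomicsBlock(discount_rate_annual=0.0)
    assert base_trace.life_years(0.0) == pytest.approx(
        float(np.sum(base_trace.alive[1:])), rel=1e-12
    )
    costs = ZERO_COSTS.model_copy(update={"metastatic_per_year": 1.0})
    c = accumulate_costs(base_trace, bundle(), SurgerySubgroup.BCS, costs,
                         ZERO_COMPLICATIONS, econ0)
    assert c == pytest.approx(float(np.sum(base_trace.recurrence)), rel=1e-12)


def test_utility_clamped_at_zero(base_trace):
    """Decrements larger than baseline floor the utility at 0, not below."""
    utils = UtilitiesBlock(
        age_to_utility={0: 0.2}, decrement_chemotherapy=0.0,
        decrement_recurrence=0.9, decrement_lymphedema=0.9,
    )
    q = accumulate_qalys(base_trace, bundle(), 1.0, utils, EconomicsBlock())
    assert q == 0.0
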