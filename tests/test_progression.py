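"""Cohort state-transition model: rate modification, traces, competing risks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nils_cea import bc_deaths_at_horizon, modified_rates, run_cohort
from nils_cea.config import DiseaseBlock
from nils_cea.progression import LifeTable, modified_probability

probs = st.floats(min_value=0.0, max_value=0.99, allow_nan=False)
hrs = st.floats(min_value=1.0, max_value=5.0, allow_nan=False)


def flat_life_table(q: float, terminal: int = 100) -> LifeTable:
    rows = tuple((age, q) for age in range(terminal)) + ((terminal, 1.0),)
    return LifeTable(rows=rows)


class TestModifiedRates:
    def test_identity_without_omissions(self):
        assert modified_rates(0.02, 0.05, 1.0) == (0.02, 0.05)

    def test_single_hazard_ratio_closed_form(self):
        """HR 1.5 on p=0.02: matches both (1-p)^HR and explicit rate conversion."""
        p_mod = modified_probability(0.02, 1.5)
        assert p_mod == pytest.approx(1.0 - 0.98**1.5, rel=1e-12)
        rate_based = 1.0 - math.exp(-1.5 * (-math.log(1.0 - 0.02)))
        assert p_mod == pytest.approx(rate_based, rel=1e-12)
        assert p_mod == pytest.approx(0.02985, abs=1e-5)

    @given(hr=hrs)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_boundary_probabilities(self, hr):
        assert modified_probability(0.0, hr) == 0.0
        assert modified_probability(1.0, hr) == 1.0

    @given(p=probs, hr=hrs)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_hazard_ratio_never_decreases_probability(self, p, hr):
        assert modified_probability(p, hr) >= p - 1e-15


def test_deterministic_survival_to_terminal_age():
    """With all rates zero and q jumping to 1 at the terminal age, everyone
    lives exactly terminal - start years."""
    disease = DiseaseBlock(yearly_bc_mortality=0.0, yearly_recurrence=0.0)
    life = flat_life_table(0.0, terminal=100)
    trace = run_cohort(disease, life, start_age=60, horizon=41)
    assert trace.life_years(0.0) == pytest.approx(40.0, abs=1e-12)
    assert trace.dead_other[-1] == pytest.approx(1.0, abs=1e-12)
    assert bc_deaths_at_horizon(trace, trace.horizon) == 0.0


def test_immediate_death_is_absorbing():
    """q = 1 in the first cycle: no life years, the whole cohort dead thereafter."""
    disease = DiseaseBlock(yearly_bc_mortality=0.0, yearly_recurrence=0.0)
    rows = tuple((age, 1.0) for age in range(60, 101))
    trace = run_cohort(disease, LifeTable(rows=rows), start_age=60)
    assert trace.life_years(0.0) == 0.0
    assert np.all(trace.dead_other[1:] == 1.0)
    assert np.all(trace.alive[1:] == 0.0)


def test_single_cycle_bc_mortality():
    """One cycle with only a 10% breast-cancer mortality leaves 0.1 dead of disease."""
    disease = DiseaseBlock(yearly_bc_mortality=0.1, yearly_recurrence=0.0)
    life = flat_life_table(0.0)
    trace = run_cohort(disease, life, start_age=60, horizon=1)
    assert bc_deaths_at_horizon(trace, 1) == pytest.approx(0.1, abs=1e-12)


def test_competing_risk_allocation_matches_microsimulation():
    """Proportional-hazard cause allocation agrees with a seeded individual
    simulation using the same convention (4 SE at 10^6 draws)."""
    p_bc, q_other = 0.1, 0.1
    disease = DiseaseBlock(yearly_bc_mortality=p_bc, yearly_recurrence=0.0)
    life = flat_life_table(q_other)
    horizon = 10
    trace = run_cohort(disease, life, start_age=60, horizon=horizon)
    expected = bc_deaths_at_horizon(trace, horizon)

    n = 1_000_000
    rng = np.random.default_rng(4242)
    h_bc, h_ac = -math.log1p(-p_bc), -math.log1p(-q_other)
    p_any = -math.expm1(-(h_bc + h_ac))
    share_bc = h_bc / (h_bc + h_ac)
    alive = np.ones(n, dtype=bool)
    dead_bc = np.zeros(n, dtype=bool)
    for _ in range(horizon):
        u = rng.random(n)
        died = alive & (u < p_any)
        dead_bc |= died & (u < p_any * share_bc)
        alive &= ~died
    obs = dead_bc.mean()
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(obs - expected) < 4 * se


@given(p_m=probs, p_r=probs, q=probs, hr=hrs)
@settings(max_examples=60, derandomize=True, deadline=None)
def test_occupancy_conservation(p_m, p_r, q, hr):
    """States partition the cohort at every cycle, dead states absorbing."""
    disease = DiseaseBlock(yearly_bc_mortality=p_m, yearly_recurrence=p_r)
    trace = run_cohort(disease, flat_life_table(q), start_age=60, hr_product=hr)
    total = trace.disease_free + trace.recurrence + trace.dead_bc + trace.dead_other
    assert np.max(np.abs(total - 1.0)) < 1e-10
    assert np.all(trace.disease_free >= -1e-15) and np.all(trace.recurrence >= -1e-15)
    assert np.all(np.diff(trace.dead_bc) >= -1e-15)
    assert np.all(np.diff(trace.dead_other) >= -1e-15)


@given(p_m=probs, p_r=probs, q=probs, hr=hrs)
@settings(max_examples=60, derandomize=True, deadline=None)
def test_omitted_therapy_monotonicity(p_m, p_r, q, hr):
    """A hazard ratio above 1 never reduces cumulative disease deaths or
    recurrences."""
    disease = DiseaseBlock(yearly_bc_mortality=p_m, yearly_recurrence=p_r)
    life = flat_life_table(q)
    base = run_cohort(disease, life, start_age=60)
    worse = run_cohort(disease, life, start_age=60, hr_product=hr)
    assert worse.dead_bc[-1] >= base.dead_bc[-1] - 1e-12
    assert np.sum(worse.new_recurrence) >= np.sum(base.new_recurrence) - 1e-12


def test_life_years_decrease_with_mortality():
    life_lo = flat_life_table(0.01)
    life_hi = flat_life_table(0.05)
    disease = DiseaseBlock(yearly_bc_mortality=0.01, yearly_recurrence=0.01)
    assert run_cohort(disease, life_hi, 60).life_years(0.0) < run_cohort(
        disease, life_lo, 60
    ).life_years(0.0)


def test_false_negative_stratum_has_excess_deaths(cfg):
    """At base-case rates, an untreated (hazard-modified) stratum accumulates
    strictly more 10-year disease deaths than a fully treated one."""
    life = LifeTable(rows=cfg.life_table)
    hr = (
        cfg.disease.hr_omitted_radiotherapy
        * cfg.disease.hr_omitted_chemotherapy
        * cfg.disease.hr_omitted_extended_endocrine
    )
    fn = run_cohort(cfg.disease, life, cfg.population.start_age, hr_product=hr)
    tn = run_cohort(cfg.disease, life, cfg.population.start_age)
    assert bc_deaths_at_horizon(fn, 10) > bc_deaths_at_horizon(tn, 10)


def test_bc_transitions_stop_after_window(cfg):
    """Disease-specific deaths are flat once the 10-year window closes."""
    life = LifeTable(rows=cfg.life_table)
    trace = run_cohort(cfg.disease, life, cfg.population.start_age)
    assert np.all(np.diff(trace.dead_bc[cfg.disease.bc_window_years:]) == 0.0)


def test_start_age_outside_life_table_rejected(cfg):
    life = LifeTable(rows=cfg.life_table)
    with pytest.raises(ValueError):
        run_cohort(cfg.disease, life, start_age=150)
    with pytest.raises(ValueError):
        run_cohort(cfg.disease, life, start_age=60, horizon=-1)
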