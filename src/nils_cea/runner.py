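"""Orchestration: strategy runs, incremental comparison, scenario suite, threshold.

A strategy run enumerates the patient strata implied by the diagnostic
pathway (true status x diagnostic outcome x axillary extent), crossed with
the breast-surgery subgroup mix and, for false negatives, the omitted-therapy
combinations; runs the progression model per stratum; and aggregates
discounted costs, QALYs, life years, breast-cancer deaths and surgery and
complication counts per cohort.  The pooled population is a weighted mix of
the two subgroup models; subgroup analyses set the weight to 1 or 0.

Everything here is deterministic cohort expectation: two runs with the same
configuration produce identical results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .config import AxillaryExtent, ModelConfig, SurgerySubgroup
from .diagnostics import DiagnosticStrategy
from .outcomes import StrategyResult, accumulate_costs, accumulate_qalys
from .progression import LifeTable, bc_deaths_at_horizon, run_cohort
from .treatments import (
    TreatmentBundle,
    assign_treatment,
    expected_lymphedema_cases,
    omission_branches,
)

POPULATIONS = ("pooled", "bcs", "mastectomy")
WEIGHT_TOL = 1e-10


@dataclass(frozen=True)
class PatientStratum:
    """Joint label of one cohort stratum with its weight and treatment bundle."""

    weight: float
    true_node_positive: bool
    diagnosed_positive: bool
    subgroup: SurgerySubgroup
    axillary_extent: AxillaryExtent
    omitted_therapies: frozenset[str]
    hr_product: float
    bundle: TreatmentBundle


def soc_strategy(cfg: ModelConfig) -> DiagnosticStrategy:
    """The standard-of-care arm: SLNB staging for every patient."""
    return DiagnosticStrategy(label="SOC", slnb=cfg.diagnostics.slnb)


def nils_strategy(cfg: ModelConfig, scenario: str) -> DiagnosticStrategy:
    """The triage arm at one configured NILS operating point."""
    if scenario not in cfg.diagnostics.scenarios:
        raise ValueError(
            f"unknown scenario {scenario!r}; configured: {sorted(cfg.diagnostics.scenarios)}"
        )
    return DiagnosticStrategy(
        label="NILS_TRIAGE",
        slnb=cfg.diagnostics.slnb,
        nils=cfg.diagnostics.scenarios[scenario],
    )


def _subgroup_mix(population: str, bcs_share: float) -> list[tuple[SurgerySubgroup, float]]:
    if population == "pooled":
        return [(SurgerySubgroup.BCS, bcs_share), (SurgerySubgroup.MASTECTOMY, 1.0 - bcs_share)]
    if population == "bcs":
        return [(SurgerySubgroup.BCS, 1.0)]
    if population == "mastectomy":
        return [(SurgerySubgroup.MASTECTOMY, 1.0)]
    raise ValueError(f"unknown population {population!r}; expected one of {POPULATIONS}")


def enumerate_strata(
    strategy: DiagnosticStrategy, cfg: ModelConfig, population: str = "pooled"
) -> list[PatientStratum]:
    """All strata of one strategy arm, with weights summing to 1."""
    fractions = strategy.classify(cfg.diagnostics.prevalence)
    strata: list[PatientStratum] = []
    for subgroup, sg_weight in _subgroup_mix(population, cfg.population.bcs_share):
        for pf in fractions.strata:
            is_false_negative = pf.true_positive and not pf.diagnosed_positive
            if is_false_negative:
                branches = omission_branches(subgroup, cfg.treatment, cfg.disease)
            else:
                branches = [(frozenset(), 1.0, 1.0)]
            bundle = assign_treatment(
                pf.diagnosed_positive, subgroup, cfg.treatment, pf.extent
            )
            for omitted, b_weight, hr in branches:
                weight = sg_weight * pf.weight * b_weight
                if weight == 0.0:
                    continue
                strata.append(
                    PatientStratum(
                        weight=weight,
                        true_node_positive=pf.true_positive,
                        diagnosed_positive=pf.diagnosed_positive,
                        subgroup=subgroup,
                        axillary_extent=pf.extent,
                        omitted_therapies=omitted,
                        hr_product=hr,
                        bundle=bundle,
                    )
                )
    total = sum(s.weight for s in strata)
    if abs(total - 1.0) > WEIGHT_TOL:
        raise ValueError(f"stratum weights sum to {total}, expected 1")
    return strata


def run_strategy(
    strategy: DiagnosticStrategy,
    cfg: ModelConfig,
    population: str = "pooled",
    lymphedema_decrement: Optional[float] = None,
) -> StrategyResult:
    """Expected cohort outcomes of one strategy arm.

    ``lymphedema_decrement`` overrides the configured life-long utility
    decrement (used by the with/without-decrement analyses and the break-even
    threshold search).
    """
    life = LifeTable(rows=cfg.life_table)
    n = cfg.economics.cohort_size
    rate = cfg.economics.discount_rate_annual
    start_age = cfg.population.start_age
    window = cfg.disease.bc_window_years

    strata = enumerate_strata(strategy, cfg, population)
    traces: dict[float, object] = {}
    total_cost = total_qalys = total_ly = total_deaths = 0.0
    for s in strata:
        trace = traces.get(s.hr_product)
        if trace is None:
            trace = run_cohort(cfg.disease, life, start_age, hr_product=s.hr_product)
            traces[s.hr_product] = trace
        cost_pp = accumulate_costs(
            trace, s.bundle, s.subgroup, cfg.costs, cfg.complications, cfg.economics
        )
        qaly_pp = accumulate_qalys(
            trace,
            s.bundle,
            cfg.complications.lymphedema.at(s.axillary_extent),
            cfg.utilities,
            cfg.economics,
            lymphedema_decrement=lymphedema_decrement,
        )
        total_cost += s.weight * cost_pp
        total_qalys += s.weight * qaly_pp
        total_ly += s.weight * trace.life_years(rate)
        total_deaths += s.weight * bc_deaths_at_horizon(trace, min(window, trace.horizon))

    fractions = strategy.classify(cfg.diagnostics.prevalence)
    return StrategyResult(
        label=strategy.label,
        population=population,
        cohort_size=n,
        total_cost=n * total_cost,
        total_qalys=n * total_qalys,
        total_life_years=n * total_ly,
        bc_deaths=n * total_deaths,
        slnb_count=n * fractions.f_slnb_performed,
        alnd_count=n * fractions.f_alnd_performed,
        lymphedema_cases=expected_lymphedema_cases(fractions, cfg.complications, n),
    )


@dataclass(frozen=True)
class IncrementalResult:
    """Triage-minus-SOC deltas per cohort; dominant means cost saving and QALY gaining."""

    delta_cost: float
    delta_qalys: float
    delta_life_years: float
    delta_bc_deaths: float
    slnb_omitted_count: float
    delta_lymphedema_cases: float
    dominant: bool


def compare(soc: StrategyResult, nils: StrategyResult) -> IncrementalResult:
    """Incremental (triage minus standard-of-care) outcomes."""
    if soc.cohort_size != nils.cohort_size or soc.population != nils.population:
        raise ValueError("cannot compare strategy results with different settings")
    delta_cost = nils.total_cost - soc.total_cost
    delta_qalys = nils.total_qalys - soc.total_qalys
    omitted = soc.slnb_count - nils.slnb_count
    if not -WEIGHT_TOL <= omitted <= soc.cohort_size + WEIGHT_TOL:
        raise ValueError(f"SLNB omission count {omitted} outside [0, cohort size]")
    return IncrementalResult(
        delta_cost=delta_cost,
        delta_qalys=delta_qalys,
        delta_life_years=nils.total_life_years - soc.total_life_years,
        delta_bc_deaths=nils.bc_deaths - soc.bc_deaths,
        slnb_omitted_count=omitted,
        delta_lymphedema_cases=nils.lymphedema_cases - soc.lymphedema_cases,
        dominant=(delta_cost < 0.0) and (delta_qalys > 0.0),
    )


def run_scenario_suite(cfg: ModelConfig) -> pd.DataFrame:
    """Full deterministic result table.

    Rows cover every configured NILS scenario x population (pooled and the
    two surgery subgroups) x lymphedema-decrement setting (the configured
    value and 0); columns carry the per-arm absolutes and the incremental
    deltas.
    """
    decrements = [cfg.utilities.decrement_lymphedema, 0.0]
    rows = []
    soc_cache: dict[tuple[str, float], StrategyResult] = {}
    for scenario in sorted(cfg.diagnostics.scenarios):
        nils = nils_strategy(cfg, scenario)
        for population in POPULATIONS:
            for d in decrements:
                soc_res = soc_cache.get((population, d))
                if soc_res is None:
                    soc_res = run_strategy(
                        soc_strategy(cfg), cfg, population, lymphedema_decrement=d
                    )
                    soc_cache[(population, d)] = soc_res
                nils_res = run_strategy(nils, cfg, population, lymphedema_decrement=d)
                inc = compare(soc_res, nils_res)
                rows.append(
                    {
                        "scenario": scenario,
                        "population": population,
                        "lymphedema_decrement": d,
                        "soc_cost": soc_res.total_cost,
                        "nils_cost": nils_res.total_cost,
                        "delta_cost": inc.delta_cost,
                        "soc_qalys": soc_res.total_qalys,
                        "nils_qalys": nils_res.total_qalys,
                        "delta_qalys": inc.delta_qalys,
                        "soc_life_years": soc_res.total_life_years,
                        "nils_life_years": nils_res.total_life_years,
                        "delta_life_years": inc.delta_life_years,
                        "soc_bc_deaths": soc_res.bc_deaths,
                        "nils_bc_deaths": nils_res.bc_deaths,
                        "delta_bc_deaths": inc.delta_bc_deaths,
                        "soc_slnb_count": soc_res.slnb_count,
                        "nils_slnb_count": nils_res.slnb_count,
                        "slnb_omitted_count": inc.slnb_omitted_count,
                        "soc_alnd_count": soc_res.alnd_count,
                        "nils_alnd_count": nils_res.alnd_count,
                        "soc_lymphedema_cases": soc_res.lymphedema_cases,
                        "nils_lymphedema_cases": nils_res.lymphedema_cases,
                        "delta_lymphedema_cases": inc.delta_lymphedema_cases,
                        "dominant": inc.dominant,
                    }
                )
    return pd.DataFrame(rows)


def delta_qalys_at_decrement(
    cfg: ModelConfig, scenario: str, decrement: float, population: str = "pooled"
) -> float:
    """Incremental QALYs (triage minus SOC) at one lymphedema decrement value."""
    soc = run_strategy(soc_strategy(cfg), cfg, population, lymphedema_decrement=decrement)
    nils = run_strategy(nils_strategy(cfg, scenario), cfg, population, lymphedema_decrement=decrement)
    return nils.total_qalys - soc.total_qalys


@dataclass(frozen=True)
class ThresholdResult:
    """Break-even lymphedema decrement: minimal value giving QALY gains in all scenarios."""

    threshold: Optional[float]  # None when unattainable in [0, 1]
    per_scenario: dict[str, Optional[float]]

    @property
    def attainable(self) -> bool:
        return self.threshold is not None


_AFFINE_PROBE = 0.1  # slope probe point; well inside the unclamped-utility region


def lymphedema_threshold(
    cfg: ModelConfig, scenarios: Optional[list[str]] = None, population: str = "pooled"
) -> ThresholdResult:
    """Analytic break-even lymphedema QoL decrement.

    Incremental QALYs are affine and increasing in the decrement (the triage
    arm always has fewer lymphedema-affected person-years), so the
    per-scenario break-even point solves a linear equation from two
    evaluations; the overall threshold is the largest per-scenario root,
    floored at 0.  Returns an unattainable result if some scenario has no
    root in [0, 1].
    """
    scenarios = sorted(cfg.diagnostics.scenarios) if scenarios is None else scenarios
    roots: dict[str, Optional[float]] = {}
    for sc in scenarios:
        a = delta_qalys_at_decrement(cfg, sc, 0.0, population)
        slope = (delta_qalys_at_decrement(cfg, sc, _AFFINE_PROBE, population) - a) / _AFFINE_PROBE
        if a >= 0.0:
            roots[sc] = 0.0
        elif slope <= 0.0:
            roots[sc] = None
        else:
            r = -a / slope
            roots[sc] = r if r <= 1.0 else None
    if any(r is None for r in roots.values()):
        return ThresholdResult(threshold=None, per_scenario=roots)
    return ThresholdResult(threshold=max(roots.values()), per_scenario=roots)


def lymphedema_threshold_bisect(
    cfg: ModelConfig,
    scenarios: Optional[list[str]] = None,
    population: str = "pooled",
    tol: float = 1e-6,
) -> Optional[float]:
    """Bisection cross-check of :func:`lymphedema_threshold`."""
    scenarios = sorted(cfg.diagnostics.scenarios) if scenarios is None else scenarios

    def worst(d: float) -> float:
        return min(delta_qalys_at_decrement(cfg, sc, d, population) for sc in scenarios)

    lo, hi = 0.0, 1.0
    if worst(lo) >= 0.0:
        return 0.0
    if worst(hi) < 0.0:
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if worst(mid) >= 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
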