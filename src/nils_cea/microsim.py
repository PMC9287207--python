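"""Individual-level Monte Carlo oracle for the cohort-expectation model.

Simulates patients one by one through the same diagnostic pathway, treatment
assignment, complication draws and yearly progression conventions as the
deterministic cohort model, so the sample means estimate exactly the
quantities the cohort model computes in expectation.  Used to validate the
cohort pipeline (agreement within sampling error), never as the primary
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig, SurgerySubgroup
from .diagnostics import DiagnosticStrategy
from .progression import LifeTable

# state codes
_DF, _REC, _DEAD_BC, _DEAD_OTHER = 0, 1, 2, 3


@dataclass(frozen=True)
class MicrosimEstimate:
    mean: float
    se: float


@dataclass(frozen=True)
class MicrosimResult:
    """Per-patient means (with standard errors) from one simulated arm."""

    n: int
    estimates: dict[str, MicrosimEstimate]

    def mean(self, key: str) -> float:
        return self.estimates[key].mean

    def se(self, key: str) -> float:
        return self.estimates[key].se

    def per_cohort(self, key: str, cohort_size: int) -> float:
        return self.estimates[key].mean * cohort_size


def _estimate(values: np.ndarray) -> MicrosimEstimate:
    n = len(values)
    return MicrosimEstimate(
        mean=float(np.mean(values)), se=float(np.std(values, ddof=1) / np.sqrt(n))
    )


def simulate_strategy(
    strategy: DiagnosticStrategy,
    cfg: ModelConfig,
    n_patients: int,
    seed: int,
    population: str = "pooled",
    lymphedema_decrement: float | None = None,
) -> MicrosimResult:
    """Simulate one strategy arm for ``n_patients`` seeded individuals.

    Returns per-patient discounted cost, QALYs and life years, breast-cancer
    death and lymphedema indicators and surgery counts, each with its
    standard error.
    """
    rng = np.random.default_rng(seed)
    n = int(n_patients)
    dx, tr, comp, dis = cfg.diagnostics, cfg.treatment, cfg.complications, cfg.disease
    life = LifeTable(rows=cfg.life_table)
    start_age = cfg.population.start_age
    rate = cfg.economics.discount_rate_annual
    d_lym = (
        cfg.utilities.decrement_lymphedema
        if lymphedema_decrement is None
        else lymphedema_decrement
    )

    true_pos = rng.random(n) < dx.prevalence
    if strategy.label == "SOC":
        slnb_done = np.ones(n, dtype=bool)
    else:
        u = rng.random(n)
        slnb_done = np.where(true_pos, u < strategy.nils.sensitivity,
                             u < 1.0 - strategy.nils.specificity)
    u = rng.random(n)
    slnb_pos = np.where(true_pos, u < strategy.slnb.sensitivity,
                        u < 1.0 - strategy.slnb.specificity)
    diag_pos = slnb_done & slnb_pos
    extent = slnb_done.astype(int) + diag_pos.astype(int)  # 0 none, 1 slnb, 2 slnb+alnd

    if population == "pooled":
        bcs = rng.random(n) < cfg.population.bcs_share
    elif population == "bcs":
        bcs = np.ones(n, dtype=bool)
    elif population == "mastectomy":
        bcs = np.zeros(n, dtype=bool)
    else:
        raise ValueError(f"unknown population {population!r}")

    radiotherapy = bcs | diag_pos
    u_chemo = rng.random(n)
    p_chemo = np.where(diag_pos, tr.chemotherapy_prob_node_positive,
                       tr.chemotherapy_prob_node_negative)
    chemo = u_chemo < p_chemo
    u_endo = rng.random(n)
    endo = diag_pos & (u_endo < tr.extended_endocrine_prob_node_positive)
    her2 = rng.random(n) < tr.her2_therapy_prob

    fn = true_pos & ~diag_pos
    omit_rt = fn & ~bcs
    omit_chemo = fn & (u_chemo < tr.chemotherapy_prob_node_positive) & (
        u_chemo >= tr.chemotherapy_prob_node_negative
    )
    omit_endo = fn & (u_endo < tr.extended_endocrine_prob_node_positive)
    hr = np.ones(n)
    hr[omit_rt] *= dis.hr_omitted_radiotherapy
    hr[omit_chemo] *= dis.hr_omitted_chemotherapy
    hr[omit_endo] *= dis.hr_omitted_extended_endocrine

    p_lymph = np.array([comp.lymphedema.none, comp.lymphedema.slnb_only,
                        comp.lymphedema.slnb_plus_alnd])[extent]
    p_ser = np.array([comp.seroma.none, comp.seroma.slnb_only,
                      comp.seroma.slnb_plus_alnd])[extent]
    p_inf = np.array([comp.infection.none, comp.infection.slnb_only,
                      comp.infection.slnb_plus_alnd])[extent]
    lymph = rng.random(n) < p_lymph
    seroma = rng.random(n) < p_ser
    infect = rng.random(n) < p_inf

    c = cfg.costs
    cost = np.where(bcs, c.surgery_bcs, c.surgery_mastectomy).astype(float)
    cost += c.slnb * slnb_done + c.alnd * diag_pos
    cost += c.radiotherapy * radiotherapy + c.chemotherapy * chemo + c.her2_therapy * her2
    cost += (comp.cost_lymphedema * lymph + comp.cost_seroma * seroma
             + comp.cost_infection * infect)

    # per-patient modified yearly transition hazards (constant over the window)
    p_mort = 1.0 - (1.0 - dis.yearly_bc_mortality) ** hr
    p_rec = 1.0 - (1.0 - dis.yearly_recurrence) ** hr
    h_bc = -np.log1p(-p_mort)
    h_rc = -np.log1p(-p_rec)

    T = life.terminal_age - start_age
    state = np.full(n, _DF, dtype=np.int8)
    qalys = np.zeros(n)
    ly = np.zeros(n)
    utils = cfg.utilities

    for t in range(1, T + 1):
        age = start_age + t - 1
        q = life.q_at(age)
        disc = (1.0 + rate) ** (-t)
        in_df = state == _DF
        in_rec = state == _REC
        u = rng.random(n)
        if q >= 1.0:
            # terminal cycle: all-cause hazard dominates every finite hazard
            state[in_df | in_rec] = _DEAD_OTHER
        else:
            h_ac = -np.log1p(-q)
            in_window = t <= dis.bc_window_years
            hb = h_bc if in_window else np.zeros(n)
            hc = h_rc if in_window else np.zeros(n)
            h_tot = hb + hc + h_ac
            p_any = -np.expm1(-h_tot)
            with np.errstate(invalid="ignore", divide="ignore"):
                c1 = np.where(h_tot > 0, p_any * hb / h_tot, 0.0)
                c2 = np.where(h_tot > 0, c1 + p_any * hc / h_tot, 0.0)
            # disease-free exits: breast-cancer death, recurrence, other death
            df_bc = in_df & (u < c1)
            df_rc = in_df & (u >= c1) & (u < c2)
            df_ac = in_df & (u >= c2) & (u < p_any)
            state[df_bc] = _DEAD_BC
            state[df_rc] = _REC
            state[df_ac] = _DEAD_OTHER
            # recurrent-state exits: breast-cancer death or other death
            h_tot_r = hb + h_ac
            p_any_r = -np.expm1(-h_tot_r)
            with np.errstate(invalid="ignore", divide="ignore"):
                r1 = np.where(h_tot_r > 0, p_any_r * hb / h_tot_r, 0.0)
            rec_bc = in_rec & (u < r1)
            rec_ac = in_rec & (u >= r1) & (u < p_any_r)
            state[rec_bc] = _DEAD_BC
            state[rec_ac] = _DEAD_OTHER
            new_rec = df_rc
            cost += disc * c.recurrence_onset * new_rec

        alive = (state == _DF) | (state == _REC)
        ly += disc * alive
        base = utils.at_age(age)
        u_t = (base
               - utils.decrement_recurrence * (state == _REC)
               - d_lym * lymph
               - (utils.decrement_chemotherapy if t == 1 else 0.0) * chemo)
        qalys += disc * np.maximum(0.0, u_t) * alive
        cost += disc * c.metastatic_per_year * (state == _REC)
        if 6 <= t <= 10:
            cost += disc * c.extended_endocrine_per_year * endo * alive

    bc_dead = state == _DEAD_BC
    return MicrosimResult(
        n=n,
        estimates={
            "cost": _estimate(cost),
            "qalys": _estimate(qalys),
            "life_years": _estimate(ly),
            "bc_deaths": _estimate(bc_dead.astype(float)),
            "lymphedema_cases": _estimate(lymph.astype(float)),
            "slnb_count": _estimate(slnb_done.astype(float)),
            "alnd_count": _estimate(diag_pos.astype(float)),
        },
    )
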