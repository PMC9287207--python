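"""Configuration schema, validation and result serialization.

The model is driven by a single :class:`ModelConfig` object covering the
diagnostic pathway, treatment assignment, complications, disease progression,
costs, utilities, economic settings, population structure and the background
life table.  The canonical on-disk format is JSON; an equivalent YAML reader
is provided.  All probabilities are validated into [0, 1], costs must be
non-negative and hazard ratios at least 1; unknown keys are rejected with the
offending key path in the error message.
"""

from __future__ import annotations

import enum
import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Annotated

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

SCHEMA_VERSION = 1

Prob = Annotated[float, Field(ge=0.0, le=1.0)]
NonNeg = Annotated[float, Field(ge=0.0)]
HazardRatio = Annotated[float, Field(ge=1.0)]


class ConfigError(ValueError):
    """Raised when a configuration file fails parsing or validation."""


class AxillaryExtent(str, enum.Enum):
    """Extent of axillary surgery actually performed on a patient."""

    NONE = "none"
    SLNB_ONLY = "slnb_only"
    SLNB_PLUS_ALND = "slnb_plus_alnd"


class SurgerySubgroup(str, enum.Enum):
    """Breast surgery procedure defining the subgroup analyses."""

    BCS = "bcs"
    MASTECTOMY = "mastectomy"


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class TestPerformance(_Block):
    """Sensitivity/specificity pair of a diagnostic procedure."""

    __test__ = False  # not a test case despite the name

    sensitivity: Prob
    specificity: Prob


class DiagnosticsBlock(_Block):
    """Prevalence and test operating points for the diagnostic pathway.

    ``prevalence`` is the proportion of clinically node-negative (cN0)
    patients with pathologically node-positive disease (micro- or
    macrometastases; isolated tumor cells count as node-negative).
    ``scenarios`` holds the NILS prediction-model operating points evaluated;
    when omitted, the three published scenarios are used.
    """

    prevalence: Prob = 0.32
    slnb: TestPerformance = TestPerformance(sensitivity=0.923, specificity=1.0)
    scenarios: dict[str, TestPerformance] = Field(
        default_factory=lambda: {
            "1": TestPerformance(sensitivity=0.99, specificity=0.11),
            "2": TestPerformance(sensitivity=0.95, specificity=0.25),
            "3": TestPerformance(sensitivity=0.90, specificity=0.37),
        }
    )


class TreatmentBlock(_Block):
    """Adjuvant-treatment uptake shares by diagnosed nodal status.

    Radiotherapy after breast-conserving surgery and HER2-targeted therapy are
    given regardless of nodal status; ALND, radiotherapy after mastectomy,
    adjuvant chemotherapy shares and extended endocrine therapy (beyond year
    5, ER+ disease) depend on the diagnosed status.  The extended-endocrine
    share is the joint probability of being ER+ *and* receiving the extension.
    """

    chemotherapy_prob_node_positive: Prob = 0.65
    chemotherapy_prob_node_negative: Prob = 0.25
    extended_endocrine_prob_node_positive: Prob = 0.50
    her2_therapy_prob: Prob = 0.13


class ExtentMap(_Block):
    """A probability (or cost) keyed by axillary surgical extent."""

    none: NonNeg
    slnb_only: NonNeg
    slnb_plus_alnd: NonNeg

    def at(self, extent: AxillaryExtent) -> float:
        return {
            AxillaryExtent.NONE: self.none,
            AxillaryExtent.SLNB_ONLY: self.slnb_only,
            AxillaryExtent.SLNB_PLUS_ALND: self.slnb_plus_alnd,
        }[extent]


class ComplicationsBlock(_Block):
    """Surgical complication risks by axillary extent and their one-off costs (EUR)."""

    lymphedema: ExtentMap = ExtentMap(none=0.004, slnb_only=0.063, slnb_plus_alnd=0.223)
    seroma: ExtentMap = ExtentMap(none=0.0, slnb_only=0.05, slnb_plus_alnd=0.15)
    infection: ExtentMap = ExtentMap(none=0.0, slnb_only=0.02, slnb_plus_alnd=0.06)
    cost_lymphedema: NonNeg = 2500.0
    cost_seroma: NonNeg = 300.0
    cost_infection: NonNeg = 800.0

    @model_validator(mode="after")
    def _probabilities_valid(self) -> "ComplicationsBlock":
        for name in ("lymphedema", "seroma", "infection"):
            m: ExtentMap = getattr(self, name)
            for field in ("none", "slnb_only", "slnb_plus_alnd"):
                v = getattr(m, field)
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"complications.{name}.{field}: probability {v} outside [0, 1]")
        m = self.lymphedema
        if not m.none <= m.slnb_only <= m.slnb_plus_alnd:
            raise ValueError(
                "complications.lymphedema risks must be non-decreasing in surgical extent"
            )
        return self


class DiseaseBlock(_Block):
    """Breast-cancer progression rates and hazard modifiers for omitted therapy.

    Yearly probabilities apply during the disease window (default the first
    10 years); the hazard ratios multiply both the breast-cancer mortality
    and the recurrence hazard for false-negative patients who miss the
    corresponding adjuvant therapy.
    """

    yearly_bc_mortality: Prob = 0.010481
    yearly_recurrence: Prob = 0.016120
    bc_window_years: int = Field(default=10, ge=0)
    hr_omitted_radiotherapy: HazardRatio = 1.60
    hr_omitted_chemotherapy: HazardRatio = 1.30
    hr_omitted_extended_endocrine: HazardRatio = 1.15


class CostsBlock(_Block):
    """One-off and per-year health-care costs in EUR (undiscounted)."""

    surgery_bcs: NonNeg = 4000.0
    surgery_mastectomy: NonNeg = 5500.0
    slnb: NonNeg = 1800.0
    alnd: NonNeg = 3200.0
    radiotherapy: NonNeg = 4000.0
    chemotherapy: NonNeg = 12000.0
    her2_therapy: NonNeg = 35000.0
    extended_endocrine_per_year: NonNeg = 400.0
    recurrence_onset: NonNeg = 20000.0
    metastatic_per_year: NonNeg = 15000.0


class UtilitiesBlock(_Block):
    """Age-adjusted baseline utilities and condition decrements.

    ``age_to_utility`` is a step function: the utility for an attained age is
    the value at the largest breakpoint not exceeding it.  Decrements are
    subtracted from baseline while the condition applies (chemotherapy during
    the treatment year, recurrence while in the recurrent/metastatic state,
    lymphedema life-long); the result is clamped below at 0.
    """

    age_to_utility: dict[int, float] = Field(
        default_factory=lambda: {
            0: 0.90,
            30: 0.88,
            40: 0.86,
            50: 0.84,
            60: 0.81,
            70: 0.78,
            80: 0.74,
            90: 0.69,
        }
    )
    decrement_chemotherapy: NonNeg = 0.10
    decrement_recurrence: NonNeg = 0.15
    decrement_lymphedema: NonNeg = 0.10

    @model_validator(mode="after")
    def _utilities_valid(self) -> "UtilitiesBlock":
        if not self.age_to_utility:
            raise ValueError("utilities.age_to_utility: at least one breakpoint required")
        for age, u in self.age_to_utility.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utilities.age_to_utility[{age}]: utility {u} outside [0, 1]")
        return self

    def at_age(self, age: float) -> float:
        ages = sorted(self.age_to_utility)
        if age < ages[0]:
            raise ValueError(f"age {age} below first utility breakpoint {ages[0]}")
        best = ages[0]
        for a in ages:
            if a <= age:
                best = a
        return self.age_to_utility[best]


class EconomicsBlock(_Block):
    """Discounting and cohort settings."""

    discount_rate_annual: NonNeg = 0.03
    cohort_size: int = Field(default=1000, gt=0)
    cycle_length_years: int = Field(default=1, ge=1, le=1)


class PopulationBlock(_Block):
    """Cohort entry age and breast-surgery mix."""

    start_age: int = Field(default=60, ge=0)
    bcs_share: Prob = 0.65


class ModelConfig(_Block):
    """Complete, validated parameter set for one model run."""

    schema_version: int = SCHEMA_VERSION
    diagnostics: DiagnosticsBlock = DiagnosticsBlock()
    treatment: TreatmentBlock = TreatmentBlock()
    complications: ComplicationsBlock = ComplicationsBlock()
    disease: DiseaseBlock = DiseaseBlock()
    costs: CostsBlock = CostsBlock()
    utilities: UtilitiesBlock = UtilitiesBlock()
    economics: EconomicsBlock = EconomicsBlock()
    population: PopulationBlock = PopulationBlock()
    life_table: tuple[tuple[int, float], ...] = ()

    @model_validator(mode="after")
    def _life_table_valid(self) -> "ModelConfig":
        rows = self.life_table
        if not rows:
            return self
        ages = [r[0] for r in rows]
        if ages != sorted(set(ages)):
            raise ValueError("life_table: ages must be strictly increasing")
        for age, q in rows:
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"life_table age {age}: q {q} outside [0, 1]")
        if rows[-1][1] != 1.0:
            raise ValueError("life_table: terminal age must have q = 1")
        if self.population.start_age < ages[0] or self.population.start_age >= ages[-1]:
            raise ValueError(
                f"population.start_age {self.population.start_age} outside life table "
                f"range [{ages[0]}, {ages[-1]})"
            )
        return self


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"])
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a model configuration from JSON or YAML.

    Omitted optional blocks are filled from defaults; an omitted life table
    is filled with the synthetic Gompertz table.  Validation failures raise
    :class:`ConfigError` naming the offending key path.
    """
    path = Path(path)
    try:
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
    except (OSError, ValueError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    if not data.get("life_table"):
        from .synthetic import synthetic_life_table

        data = dict(data)
        data["life_table"] = synthetic_life_table().rows
    try:
        return ModelConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    """Write a configuration to JSON (canonical) or YAML, by file suffix."""
    path = Path(path)
    data = cfg.model_dump(mode="json")
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def load_life_table_tsv(path: str | Path) -> tuple[tuple[int, float], ...]:
    """Read a two-column (age, annual death probability) delimited text file."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        age_s, q_s = line.split("\t") if "\t" in line else line.split()
        rows.append((int(age_s), float(q_s)))
    return tuple(rows)


def save_life_table_tsv(rows, path: str | Path) -> None:
    lines = ["# age\tq_annual"] + [f"{age}\t{q!r}" for age, q in rows]
    Path(path).write_text("\n".join(lines) + "\n")


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero-up, as used for displayed patient counts."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


_DISPLAY_ROUNDING = {
    "delta_cost": 0,
    "soc_cost": 0,
    "nils_cost": 0,
    "delta_qalys": 1,
    "soc_qalys": 1,
    "nils_qalys": 1,
    "delta_life_years": 1,
    "soc_life_years": 1,
    "nils_life_years": 1,
    "delta_bc_deaths": 1,
    "soc_bc_deaths": 1,
    "nils_bc_deaths": 1,
    "slnb_omitted_count": 0,
    "delta_lymphedema_cases": 1,
    "soc_lymphedema_cases": 1,
    "nils_lymphedema_cases": 1,
    "soc_slnb_count": 0,
    "nils_slnb_count": 0,
    "soc_alnd_count": 1,
    "nils_alnd_count": 1,
}


def _rounded_for_display(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col, nd in _DISPLAY_ROUNDING.items():
        if col in out.columns:
            out[col] = [round_half_up(v, nd) for v in out[col]]
            if nd == 0:
                out[col] = out[col].astype(int)
    return out


def write_results(suite: pd.DataFrame, out_dir: str | Path, fmt: str = "csv") -> list[Path]:
    """Serialize a scenario-suite result table.

    Writes one table per reported view (pooled incremental summary, pooled
    cost/life-year/QALY breakdown, subgroup incremental summary) plus a
    machine-readable JSON summary with unrounded values.  CSV numbers are
    rounded for display (EUR to integers, QALYs and life years to one
    decimal); JSON retains full precision.
    """
    if fmt not in ("csv", "json"):
        raise ValueError(f"unknown format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary = out_dir / "summary.json"
    records = suite.to_dict(orient="records")
    summary.write_text(json.dumps(records, indent=2, sort_keys=True) + "\n")
    written.append(summary)

    if fmt == "json":
        return written

    pooled = suite[suite["population"] == "pooled"]
    sub = suite[suite["population"] != "pooled"]

    incremental_cols = [
        "scenario",
        "population",
        "lymphedema_decrement",
        "delta_cost",
        "delta_qalys",
        "delta_life_years",
        "delta_bc_deaths",
        "slnb_omitted_count",
        "delta_lymphedema_cases",
        "dominant",
    ]
    breakdown_cols = [
        "scenario",
        "lymphedema_decrement",
        "soc_cost",
        "nils_cost",
        "delta_cost",
        "soc_life_years",
        "nils_life_years",
        "delta_life_years",
        "soc_qalys",
        "nils_qalys",
        "delta_qalys",
    ]
    for name, frame, cols in (
        ("incremental_pooled", pooled, incremental_cols),
        ("breakdown_pooled", pooled, breakdown_cols),
        ("incremental_subgroups", sub, incremental_cols),
    ):
        p = out_dir / f"{name}.csv"
        _rounded_for_display(frame[cols]).to_csv(p, index=False)
        written.append(p)
    return written
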