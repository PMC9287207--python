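"""Probabilistic flow of a cN0 cohort through the two diagnostic strategies.

Standard of care (SOC) stages every patient with sentinel lymph node biopsy
(SLNB).  The triage strategy runs the NILS prediction model first and performs
SLNB only on NILS-positive patients; NILS-negative patients receive no
axillary surgery and are managed as node-negative.  Every positive SLNB is
followed by axillary lymph node dissection (ALND).

NILS and SLNB results are modelled as conditionally independent given the true
nodal status.  The general formulas support SLNB specificity below 1 (false
positives proceed to ALND), although the shipped default fixes it at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .config import AxillaryExtent, TestPerformance

_SUM_TOL = 1e-12


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")


def _check_performance(name: str, perf: TestPerformance) -> None:
    _check_prob(f"{name}.sensitivity", perf.sensitivity)
    _check_prob(f"{name}.specificity", perf.specificity)


@dataclass(frozen=True)
class PathwayFraction:
    """One leaf of the diagnostic decision tree.

    ``weight`` is the cohort fraction reaching this leaf; ``true_positive``
    and ``diagnosed_positive`` give the true and diagnosed nodal status and
    ``extent`` the axillary surgery actually performed on the way.
    """

    true_positive: bool
    diagnosed_positive: bool
    extent: AxillaryExtent
    weight: float


@dataclass(frozen=True)
class DiagnosticOutcomeFractions:
    """Cohort flow through one diagnostic strategy.

    Aggregate fractions are derived from the leaf-level pathway fractions so
    the two views can never disagree.
    """

    strata: tuple[PathwayFraction, ...]

    def __post_init__(self) -> None:
        total = sum(s.weight for s in self.strata)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pathway fractions sum to {total}, expected 1")

    def _sum(self, pred) -> float:
        return sum(s.weight for s in self.strata if pred(s))

    @property
    def f_true_positive(self) -> float:
        return self._sum(lambda s: s.true_positive and s.diagnosed_positive)

    @property
    def f_false_negative(self) -> float:
        return self._sum(lambda s: s.true_positive and not s.diagnosed_positive)

    @property
    def f_false_positive(self) -> float:
        return self._sum(lambda s: not s.true_positive and s.diagnosed_positive)

    @property
    def f_true_negative(self) -> float:
        return self._sum(lambda s: not s.true_positive and not s.diagnosed_positive)

    @property
    def f_slnb_performed(self) -> float:
        return self._sum(lambda s: s.extent is not AxillaryExtent.NONE)

    @property
    def f_slnb_omitted(self) -> float:
        return self._sum(lambda s: s.extent is AxillaryExtent.NONE)

    @property
    def f_alnd_performed(self) -> float:
        return self._sum(lambda s: s.extent is AxillaryExtent.SLNB_PLUS_ALND)

    def to_dict(self) -> dict:
        """Plain-record form, serializable to JSON."""
        return {
            "f_true_positive": self.f_true_positive,
            "f_false_negative": self.f_false_negative,
            "f_false_positive": self.f_false_positive,
            "f_true_negative": self.f_true_negative,
            "f_slnb_performed": self.f_slnb_performed,
            "f_slnb_omitted": self.f_slnb_omitted,
            "f_alnd_performed": self.f_alnd_performed,
            "strata": [
                {
                    "true_positive": s.true_positive,
                    "diagnosed_positive": s.diagnosed_positive,
                    "extent": s.extent.value,
                    "weight": s.weight,
                }
                for s in self.strata
            ],
        }


def classify_soc(prevalence: float, slnb: TestPerformance) -> DiagnosticOutcomeFractions:
    """Cohort fractions when every patient is staged with SLNB.

    True positives (and, when SLNB specificity is below 1, false positives)
    proceed to ALND; everyone else stops after the SLNB.
    """
    _check_prob("prevalence", prevalence)
    _check_performance("slnb", slnb)
    p, sens, spec = prevalence, slnb.sensitivity, slnb.specificity
    strata = (
        PathwayFraction(True, True, AxillaryExtent.SLNB_PLUS_ALND, p * sens),
        PathwayFraction(True, False, AxillaryExtent.SLNB_ONLY, p * (1.0 - sens)),
        PathwayFraction(False, True, AxillaryExtent.SLNB_PLUS_ALND, (1.0 - p) * (1.0 - spec)),
        PathwayFraction(False, False, AxillaryExtent.SLNB_ONLY, (1.0 - p) * spec),
    )
    return DiagnosticOutcomeFractions(strata=strata)


def classify_nils(
    prevalence: float, nils: TestPerformance, slnb: TestPerformance
) -> DiagnosticOutcomeFractions:
    """Cohort fractions under NILS triage: SLNB only after a positive NILS result.

    A NILS-negative patient is diagnosed node-negative with no axillary
    surgery; NILS-positive patients follow the SOC pathway.
    """
    _check_prob("prevalence", prevalence)
    _check_performance("nils", nils)
    _check_performance("slnb", slnb)
    p = prevalence
    sn, cn = nils.sensitivity, nils.specificity
    ss, cs = slnb.sensitivity, slnb.specificity
    strata = (
        # true node-positive
        PathwayFraction(True, True, AxillaryExtent.SLNB_PLUS_ALND, p * sn * ss),
        PathwayFraction(True, False, AxillaryExtent.SLNB_ONLY, p * sn * (1.0 - ss)),
        PathwayFraction(True, False, AxillaryExtent.NONE, p * (1.0 - sn)),
        # true node-negative
        PathwayFraction(
            False, True, AxillaryExtent.SLNB_PLUS_ALND, (1.0 - p) * (1.0 - cn) * (1.0 - cs)
        ),
        PathwayFraction(False, False, AxillaryExtent.SLNB_ONLY, (1.0 - p) * (1.0 - cn) * cs),
        PathwayFraction(False, False, AxillaryExtent.NONE, (1.0 - p) * cn),
    )
    return DiagnosticOutcomeFractions(strata=strata)


def slnb_omitted_fraction(prevalence: float, nils: TestPerformance) -> float:
    """Closed-form share of the cohort spared an SLNB under NILS triage.

    Equals ``prev * (1 - sens_nils) + (1 - prev) * spec_nils`` — the
    NILS-negative share of the cohort.
    """
    _check_prob("prevalence", prevalence)
    _check_performance("nils", nils)
    return prevalence * (1.0 - nils.sensitivity) + (1.0 - prevalence) * nils.specificity


@dataclass(frozen=True)
class DiagnosticStrategy:
    """A named staging strategy: SOC (SLNB for all) or NILS triage."""

    label: str  # "SOC" or "NILS_TRIAGE"
    slnb: TestPerformance
    nils: Optional[TestPerformance] = None

    def __post_init__(self) -> None:
        if self.label not in ("SOC", "NILS_TRIAGE"):
            raise ValueError(f"unknown strategy label {self.label!r}")
        if self.label == "NILS_TRIAGE" and self.nils is None:
            raise ValueError("NILS_TRIAGE strategy requires NILS operating point")

    def classify(self, prevalence: float) -> DiagnosticOutcomeFractions:
        if self.label == "SOC":
            return classify_soc(prevalence, self.slnb)
        return classify_nils(prevalence, self.nils, self.slnb)
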