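"""Treatment assignment and complication burden per diagnostic outcome.

Treatment rules: every patient diagnosed node-positive undergoes ALND after
the SLNB; radiotherapy is given after breast-conserving surgery regardless of
nodal status but after mastectomy only for diagnosed node-positive disease;
HER2-targeted therapy is independent of nodal status; chemotherapy uptake and
extended endocrine therapy (beyond year 5, ER+ disease) take their
diagnosed-positive values only for diagnosed-positive patients.

False-negative patients (true node-positive, diagnosed negative) receive the
diagnosed-negative bundle — this is precisely how adjuvant therapies are
omitted; the survival consequences are handled by hazard modifiers in the
progression module.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .config import (
    AxillaryExtent,
    ComplicationsBlock,
    DiseaseBlock,
    SurgerySubgroup,
    TreatmentBlock,
)
from .diagnostics import DiagnosticOutcomeFractions

OMITTABLE_THERAPIES = ("radiotherapy", "chemotherapy", "extended_endocrine")


@dataclass(frozen=True)
class TreatmentBundle:
    """Treatments received by one diagnostic/surgical stratum.

    Chemotherapy, extended endocrine and HER2 therapy are cohort shares (the
    receptor-status mix is not modelled individually), the rest booleans.
    """

    alnd: bool
    radiotherapy: bool
    chemotherapy_prob: float
    extended_endocrine_prob: float
    her2_therapy_prob: float
    axillary_extent: AxillaryExtent


def assign_treatment(
    diagnosed_positive: bool,
    subgroup: SurgerySubgroup,
    params: TreatmentBlock,
    axillary_extent: AxillaryExtent | None = None,
) -> TreatmentBundle:
    """Treatment bundle for a diagnosed status and breast-surgery subgroup.

    ``axillary_extent`` records the surgery performed on the diagnostic
    pathway; diagnosed-positive patients always end at SLNB plus ALND, so it
    may be omitted for them.  Pure function: identical inputs give identical
    bundles.
    """
    if not isinstance(subgroup, SurgerySubgroup):
        raise ValueError(f"unknown subgroup {subgroup!r}")
    if diagnosed_positive:
        if axillary_extent is None:
            axillary_extent = AxillaryExtent.SLNB_PLUS_ALND
        if axillary_extent is not AxillaryExtent.SLNB_PLUS_ALND:
            raise ValueError("diagnosed node-positive patients undergo SLNB plus ALND")
    elif axillary_extent is None:
        raise ValueError("axillary extent required for diagnosed node-negative patients")
    return TreatmentBundle(
        alnd=diagnosed_positive,
        radiotherapy=(subgroup is SurgerySubgroup.BCS) or diagnosed_positive,
        chemotherapy_prob=(
            params.chemotherapy_prob_node_positive
            if diagnosed_positive
            else params.chemotherapy_prob_node_negative
        ),
        extended_endocrine_prob=(
            params.extended_endocrine_prob_node_positive if diagnosed_positive else 0.0
        ),
        her2_therapy_prob=params.her2_therapy_prob,
        axillary_extent=axillary_extent,
    )


def omission_probabilities(subgroup: SurgerySubgroup, params: TreatmentBlock) -> dict[str, float]:
    """Probability that a false-negative patient misses each therapy.

    Relative to the bundle the same patient would have received if correctly
    diagnosed: radiotherapy is missed by every false negative treated with
    mastectomy (never after breast-conserving surgery, where it is given
    regardless); chemotherapy by the excess diagnosed-positive uptake (uptake
    is assumed nested: anyone treated when diagnosed negative would also be
    treated when diagnosed positive); extended endocrine therapy by the full
    diagnosed-positive share.
    """
    return {
        "radiotherapy": 1.0 if subgroup is SurgerySubgroup.MASTECTOMY else 0.0,
        "chemotherapy": max(
            0.0,
            params.chemotherapy_prob_node_positive - params.chemotherapy_prob_node_negative,
        ),
        "extended_endocrine": params.extended_endocrine_prob_node_positive,
    }


def omission_branches(
    subgroup: SurgerySubgroup, params: TreatmentBlock, disease: DiseaseBlock
) -> list[tuple[frozenset[str], float, float]]:
    """Enumerate omitted-therapy combinations for a false-negative stratum.

    Returns ``(omitted_set, weight, hazard_ratio_product)`` triples, treating
    the three omission events as independent; weights sum to 1.  The hazard
    ratios combine multiplicatively on the hazard scale.
    """
    probs = omission_probabilities(subgroup, params)
    hrs = {
        "radiotherapy": disease.hr_omitted_radiotherapy,
        "chemotherapy": disease.hr_omitted_chemotherapy,
        "extended_endocrine": disease.hr_omitted_extended_endocrine,
    }
    branches = []
    for flags in product((False, True), repeat=len(OMITTABLE_THERAPIES)):
        weight = 1.0
        hr = 1.0
        omitted = []
        for therapy, flag in zip(OMITTABLE_THERAPIES, flags):
            p = probs[therapy]
            weight *= p if flag else (1.0 - p)
            if flag:
                omitted.append(therapy)
                hr *= hrs[therapy]
        if weight > 0.0:
            branches.append((frozenset(omitted), weight, hr))
    return branches


def expected_lymphedema_cases(
    fractions: DiagnosticOutcomeFractions, risks: ComplicationsBlock, cohort_size: float
) -> float:
    """Expected lymphedema cases: occupancy x extent-specific risk x cohort size."""
    return cohort_size * sum(
        s.weight * risks.lymphedema.at(s.extent) for s in fractions.strata
    )


def complication_cost(
    fractions: DiagnosticOutcomeFractions, risks: ComplicationsBlock
) -> float:
    """Expected one-off complication cost per patient (applied at cycle 0)."""
    return sum(
        s.weight * complication_cost_for_extent(s.extent, risks) for s in fractions.strata
    )


def complication_cost_for_extent(extent: AxillaryExtent, risks: ComplicationsBlock) -> float:
    """Expected one-off complication cost for one axillary extent."""
    return (
        risks.lymphedema.at(extent) * risks.cost_lymphedema
        + risks.seroma.at(extent) * risks.cost_seroma
        + risks.infection.at(extent) * risks.cost_infection
    )
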