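"""Patient-level ADA status classification.

A patient is *assessable* when they have a pretreatment sample and at
least one postdose sample. Assessable patients fall into exactly one of:

* **positive** — at least one sample (pre or post) is tier-2 confirmed
  positive;
* **inconclusive** — all samples negative AND the drug concentration in
  the last postdose sample is above the vendor's drug tolerance level
  (the assay could have missed antibodies);
* **negative** — all samples negative and the last postdose concentration
  is at or below the DTL.

*Evaluable* patients (the incidence denominator) are the negative plus
positive patients. Positive patients are split into treatment-emergent
(TE: baseline-negative with any postdose positive, or baseline-positive
with a postdose titer at least ``te_fold_threshold`` times baseline) and
non-treatment-emergent, and each into NAb-positive / NAb-negative by the
neutralizing-antibody assay on their confirmed-positive samples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .assay import (
    AssayConfig,
    NabResult,
    SampleAdaOutcome,
    SampleRecord,
    evaluate_sample,
    is_above_dtl,
)

__all__ = [
    "Regimen",
    "Indication",
    "Setting",
    "AdaCategory",
    "TeFlag",
    "NabFlag",
    "AeEvent",
    "TumorAssessment",
    "PatientRecord",
    "AdaPatientStatus",
    "NotAssessableError",
    "is_assessable",
    "classify_patient",
    "classify_te",
    "classify_nab",
    "classify_cohort",
]

#: Canonical dose-regimen labels.
REGIMENS = ("2 mg/kg Q3W", "10 mg/kg Q2W", "10 mg/kg Q3W", "200 mg Q3W")
INDICATIONS = ("melanoma", "NSCLC", "HNSCC", "CRC", "HL", "UC")
SETTINGS = ("nonadjuvant", "adjuvant")

# Kept as plain tuples rather than enums: these vocabularies travel through
# CSV files and user configs, where string round-tripping matters more than
# enum identity.
Regimen = str
Indication = str
Setting = str


class AdaCategory(str, enum.Enum):
    INCONCLUSIVE = "inconclusive"
    NEGATIVE = "negative"
    POSITIVE = "positive"


class TeFlag(str, enum.Enum):
    TE_POSITIVE = "te_positive"
    NON_TE_POSITIVE = "non_te_positive"
    NOT_APPLICABLE = "not_applicable"


class NabFlag(str, enum.Enum):
    NAB_POSITIVE = "nab_positive"
    NAB_NEGATIVE = "nab_negative"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class AeEvent:
    """One adverse event: a MedDRA-style preferred term plus relatedness."""

    preferred_term: str
    drug_related: bool
    onset_day: float = 0.0


@dataclass(frozen=True)
class TumorAssessment:
    """Sum of target-lesion diameters at one imaging visit (mm)."""

    time_days: float
    sum_of_diameters_mm: float


@dataclass
class PatientRecord:
    """One treated subject with their time-ordered immunogenicity samples."""

    patient_id: str
    regimen: Regimen
    indication: Indication
    setting: Setting = "nonadjuvant"
    body_weight_kg: float = 75.0
    samples: List[SampleRecord] = field(default_factory=list)
    ae_events: List[AeEvent] = field(default_factory=list)
    tumor_assessments: List[TumorAssessment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.regimen not in REGIMENS:
            raise ValueError(f"{self.patient_id}: unknown regimen {self.regimen!r}")
        if self.indication not in INDICATIONS:
            raise ValueError(
                f"{self.patient_id}: unknown indication {self.indication!r}"
            )
        if self.setting not in SETTINGS:
            raise ValueError(f"{self.patient_id}: unknown setting {self.setting!r}")
        if self.body_weight_kg <= 0:
            raise ValueError(f"{self.patient_id}: body weight must be positive")
        if self.setting == "adjuvant" and (
            self.indication != "melanoma" or self.regimen != "200 mg Q3W"
        ):
            raise ValueError(
                f"{self.patient_id}: the adjuvant setting is restricted to "
                "melanoma at 200 mg Q3W"
            )
        times = [s.time_days for s in self.samples]
        if times != sorted(times):
            raise ValueError(f"{self.patient_id}: samples must be time-ordered")
        if sum(s.is_pretreatment for s in self.samples) > 1:
            raise ValueError(
                f"{self.patient_id}: at most one pretreatment sample is allowed"
            )

    @property
    def pretreatment_sample(self) -> Optional[SampleRecord]:
        for s in self.samples:
            if s.is_pretreatment:
                return s
        return None

    @property
    def postdose_samples(self) -> List[SampleRecord]:
        return [s for s in self.samples if not s.is_pretreatment]


@dataclass(frozen=True)
class AdaPatientStatus:
    """Patient-level classification output.

    For non-assessable patients the category and sub-flags are ``None``
    (a single "not assessable" terminal state). TE and NAb flags are
    meaningful only for ADA-positive patients and are ``NOT_APPLICABLE``
    otherwise.
    """

    assessable: bool
    category: Optional[AdaCategory] = None
    te: Optional[TeFlag] = None
    nab: Optional[NabFlag] = None

    def __post_init__(self) -> None:
        if not self.assessable:
            if any(x is not None for x in (self.category, self.te, self.nab)):
                raise ValueError("non-assessable status must carry no category")
            return
        if self.category is None or self.te is None or self.nab is None:
            raise ValueError("assessable status must be fully specified")
        positive = self.category is AdaCategory.POSITIVE
        if positive == (self.te is TeFlag.NOT_APPLICABLE):
            raise ValueError("TE flag applies exactly to ADA-positive patients")
        if positive == (self.nab is NabFlag.NOT_APPLICABLE):
            raise ValueError("NAb flag applies exactly to ADA-positive patients")


NOT_ASSESSABLE = AdaPatientStatus(assessable=False)


class NotAssessableError(ValueError):
    """Raised when classification is requested for a non-assessable patient."""


def is_assessable(patient: PatientRecord) -> bool:
    """A patient needs a pretreatment sample and >= 1 postdose sample."""
    return patient.pretreatment_sample is not None and len(patient.postdose_samples) > 0


def non_assessable_reason(patient: PatientRecord) -> str:
    reasons = []
    if patient.pretreatment_sample is None:
        reasons.append("no pretreatment sample")
    if not patient.postdose_samples:
        reasons.append("no postdose sample")
    return "; ".join(reasons) if reasons else "assessable"


def classify_te(
    pre_outcome: Optional[SampleAdaOutcome],
    post_outcomes: Sequence[SampleAdaOutcome],
    config: AssayConfig,
) -> TeFlag:
    """Treatment-emergent vs non-treatment-emergent sub-classification.

    Baseline negative with >= 1 postdose positive is TE. Baseline positive
    is TE only when the maximum postdose titer reaches
    ``te_fold_threshold`` × the baseline titer (inclusive); otherwise —
    including when every postdose sample is negative — the positivity is
    pre-existing, i.e. non-TE. A confirmed-positive sample missing its
    titer contributes the minimum reportable titer, so titer ratios are
    always defined.
    """
    pre_positive = pre_outcome is not None and pre_outcome.confirmed_positive
    post_positive = [o for o in post_outcomes if o.confirmed_positive]
    if not pre_positive and not post_positive:
        raise ValueError("TE classification requires at least one positive sample")
    if not pre_positive:
        return TeFlag.TE_POSITIVE
    if not post_positive:
        return TeFlag.NON_TE_POSITIVE
    floor = config.titer_base_dilution
    baseline_titer = pre_outcome.titer if pre_outcome.titer is not None else floor
    max_post = max(o.titer if o.titer is not None else floor for o in post_positive)
    if max_post >= config.te_fold_threshold * baseline_titer:
        return TeFlag.TE_POSITIVE
    return TeFlag.NON_TE_POSITIVE


def classify_nab(patient: PatientRecord, config: AssayConfig) -> NabFlag:
    """NAb status of an ADA-positive patient.

    NAb-positive iff any confirmed-positive sample has a positive
    neutralizing-antibody result. Confirmed positives that were never NAb
    tested count as NAb-negative at patient level, so the NAb split
    exhausts each positive category.
    """
    for sample in patient.samples:
        outcome = evaluate_sample(sample, config)
        if outcome.confirmed_positive and sample.nab_result is NabResult.POSITIVE:
            return NabFlag.NAB_POSITIVE
    return NabFlag.NAB_NEGATIVE


def _last_postdose_with_conc(patient: PatientRecord) -> Optional[SampleRecord]:
    """Latest postdose sample carrying a drug concentration (follow-up included)."""
    candidates = [s for s in patient.postdose_samples if s.drug_conc_ug_ml is not None]
    if not candidates:
        return None
    return max(candidates, key=lambda s: s.time_days)


def classify_patient(patient: PatientRecord, config: AssayConfig) -> AdaPatientStatus:
    """Classify one assessable patient.

    Positivity takes precedence: any confirmed-positive sample makes the
    patient ADA-positive regardless of terminal drug concentration. With
    all samples negative, the drug concentration of the last postdose
    sample decides between inconclusive (above the vendor's DTL) and
    negative.
    """
    if not is_assessable(patient):
        raise NotAssessableError(
            f"{patient.patient_id}: {non_assessable_reason(patient)}"
        )
    pre_sample = patient.pretreatment_sample
    pre_outcome = evaluate_sample(pre_sample, config) if pre_sample else None
    post_outcomes = [evaluate_sample(s, config) for s in patient.postdose_samples]

    any_positive = (pre_outcome is not None and pre_outcome.confirmed_positive) or any(
        o.confirmed_positive for o in post_outcomes
    )
    if any_positive:
        return AdaPatientStatus(
            assessable=True,
            category=AdaCategory.POSITIVE,
            te=classify_te(pre_outcome, post_outcomes, config),
            nab=classify_nab(patient, config),
        )
    last = _last_postdose_with_conc(patient)
    if last is not None and is_above_dtl(last.drug_conc_ug_ml, last.vendor, config):
        category = AdaCategory.INCONCLUSIVE
    else:
        category = AdaCategory.NEGATIVE
    return AdaPatientStatus(
        assessable=True,
        category=category,
        te=TeFlag.NOT_APPLICABLE,
        nab=NabFlag.NOT_APPLICABLE,
    )


def classify_cohort(
    patients: Sequence[PatientRecord], config: AssayConfig
) -> Dict[str, AdaPatientStatus]:
    """Classify a cohort; non-assessable patients keep an explicit marker.

    Returns a mapping patient_id -> :class:`AdaPatientStatus` covering every
    patient; entries with ``assessable=False`` form the non-assessable
    listing. Duplicate patient ids are an input error.
    """
    seen = set()
    statuses: Dict[str, AdaPatientStatus] = {}
    for patient in patients:
        if patient.patient_id in seen:
            raise ValueError(f"duplicate patient_id {patient.patient_id!r}")
        seen.add(patient.patient_id)
        if is_assessable(patient):
            statuses[patient.patient_id] = classify_patient(patient, config)
        else:
            statuses[patient.patient_id] = NOT_ASSESSABLE
    return statuses
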