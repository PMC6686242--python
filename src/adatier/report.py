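"""Incidence, safety, exposure and tumor-size summaries.

Reproduces the reporting surfaces of a clinical immunogenicity analysis:
stratified incidence tables (by treatment regimen, by indication, or
pooled), adverse-event summaries by ADA category, per-visit drug-exposure
summaries, and best-percent-change tumor summaries. Percentages follow
clinical-table conventions: the denominator is always the stratum's
*evaluable* count, values are rounded half-up to one decimal, integers
drop the trailing ``.0``, and zero-count cells are left blank.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import (
    AdaCategory,
    AdaPatientStatus,
    NabFlag,
    PatientRecord,
    TeFlag,
)
from .simulate import regimen_interval_days

__all__ = [
    "INFUSION_REACTION_PREFERRED_TERMS",
    "StratumCounts",
    "IncidenceTable",
    "AeSummary",
    "format_percent",
    "percent_value",
    "incidence_table",
    "classify_infusion_reaction",
    "ae_summary",
    "exposure_by_group",
    "tumor_change_by_group",
]

#: The eight MedDRA preferred terms whose occurrence defines an
#: infusion-related reaction in the safety summary.
INFUSION_REACTION_PREFERRED_TERMS = frozenset(
    {
        "hypersensitivity",
        "drug hypersensitivity",
        "anaphylactic reaction",
        "anaphylactoid reaction",
        "cytokine release syndrome",
        "serum sickness",
        "serum sickness-like reaction",
        "infusion-related reaction",
    }
)


def percent_value(numerator: int, denominator: int) -> Optional[float]:
    """100·n/d rounded half-up to one decimal; None when the cell is blank."""
    if denominator < 0:
        raise ValueError("denominator must be non-negative")
    if numerator == 0 or denominator == 0:
        return None
    quantized = (Decimal(100 * numerator) / Decimal(denominator)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(quantized)


def format_percent(numerator: int, denominator: int) -> str:
    """Render a table percentage.

    Half-up rounding at one decimal (so 9/2000 → ``"0.5"``); a rounded
    integer drops the decimal (27/36 → ``"75"``); a zero numerator gives a
    blank cell; a positive numerator over a zero denominator yields the
    error token ``"NA"``.
    """
    if numerator == 0:
        return ""
    if denominator == 0:
        return "NA"
    value = percent_value(numerator, denominator)
    text = f"{value:.1f}"
    if text.endswith(".0"):
        text = text[:-2]
    return text


# ---------------------------------------------------------------------------
# Incidence tables


@dataclass
class StratumCounts:
    assessable: int = 0
    inconclusive: int = 0
    negative: int = 0
    non_te_nab_negative: int = 0
    non_te_nab_positive: int = 0
    te_nab_negative: int = 0
    te_nab_positive: int = 0

    @property
    def non_te_positive(self) -> int:
        return self.non_te_nab_negative + self.non_te_nab_positive

    @property
    def te_positive(self) -> int:
        return self.te_nab_negative + self.te_nab_positive

    @property
    def positive(self) -> int:
        return self.non_te_positive + self.te_positive

    @property
    def evaluable(self) -> int:
        return self.negative + self.positive

    def add(self, status: AdaPatientStatus) -> None:
        if not status.assessable:
            return
        self.assessable += 1
        if status.category is AdaCategory.INCONCLUSIVE:
            self.inconclusive += 1
        elif status.category is AdaCategory.NEGATIVE:
            self.negative += 1
        elif status.te is TeFlag.TE_POSITIVE:
            if status.nab is NabFlag.NAB_POSITIVE:
                self.te_nab_positive += 1
            else:
                self.te_nab_negative += 1
        else:
            if status.nab is NabFlag.NAB_POSITIVE:
                self.non_te_nab_positive += 1
            else:
                self.non_te_nab_negative += 1


_MEASURES: List[Tuple[str, str]] = [
    ("assessable", "Assessable patients"),
    ("inconclusive", "Inconclusive patients"),
    ("evaluable", "Evaluable patients"),
    ("negative", "Negative"),
    ("non_te_positive", "Non-treatment-emergent positive"),
    ("non_te_nab_negative", "  Neutralizing negative"),
    ("non_te_nab_positive", "  Neutralizing positive"),
    ("te_positive", "Treatment-emergent positive"),
    ("te_nab_negative", "  Neutralizing negative"),
    ("te_nab_positive", "  Neutralizing positive"),
]

#: Measures whose percentage is reported (denominator: stratum evaluable).
_PERCENT_MEASURES = {
    "negative",
    "non_te_positive",
    "non_te_nab_negative",
    "non_te_nab_positive",
    "te_positive",
    "te_nab_negative",
    "te_nab_positive",
}

TREATMENT_STRATA = ("2 mg/kg Q3W", "10 mg/kg Q3W/Q2W", "200 mg Q3W")
INDICATION_STRATA = ("melanoma", "NSCLC", "HNSCC", "CRC", "HL", "UC")
ALL_LABEL = "All treatments"


@dataclass
class IncidenceTable:
    """Stratified immunogenicity incidence counts plus formatted cells."""

    stratify_by: Optional[str]
    strata: List[str]
    counts: Dict[str, StratumCounts]

    def count(self, stratum: str, measure: str) -> int:
        return getattr(self.counts[stratum], measure)

    def percent(self, stratum: str, measure: str) -> Optional[float]:
        return percent_value(
            self.count(stratum, measure), self.counts[stratum].evaluable
        )

    def cell(self, stratum: str, measure: str) -> str:
        n = self.count(stratum, measure)
        if measure not in _PERCENT_MEASURES:
            return str(n)
        pct = format_percent(n, self.counts[stratum].evaluable)
        return f"{n} ({pct}%)" if pct else str(n)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            stratum: [self.cell(stratum, key) for key, _ in _MEASURES]
            for stratum in self.strata
        }
        return pd.DataFrame(data, index=[label for _, label in _MEASURES])

    def to_text(self) -> str:
        df = self.to_dataframe()
        return df.to_string()


def _stratum_of(patient: PatientRecord, stratify_by: Optional[str]) -> str:
    if stratify_by is None:
        return ALL_LABEL
    if stratify_by == "treatment":
        if patient.regimen in ("10 mg/kg Q2W", "10 mg/kg Q3W"):
            return "10 mg/kg Q3W/Q2W"
        return patient.regimen
    if stratify_by == "indication":
        return patient.indication
    raise ValueError(f"unknown stratification {stratify_by!r}")


def incidence_table(
    statuses: Mapping[str, AdaPatientStatus],
    patients: Sequence[PatientRecord],
    stratify_by: Optional[str] = None,
) -> IncidenceTable:
    """Build an incidence table from classification output.

    ``stratify_by`` is ``"treatment"`` (regimen columns — the two
    10 mg/kg schedules share one column — plus an all-treatments total),
    ``"indication"`` (tumor-type columns), or ``None`` (single pooled
    column). Non-assessable patients are excluded; every patient carrying
    an assessable status must appear in ``patients``.
    """
    meta = {p.patient_id: p for p in patients}
    missing = [pid for pid in statuses if pid not in meta]
    if missing:
        raise ValueError(f"patients missing metadata: {missing[:5]}")
    if stratify_by == "treatment":
        strata = [*TREATMENT_STRATA, ALL_LABEL]
    elif stratify_by == "indication":
        strata = list(INDICATION_STRATA)
    elif stratify_by is None:
        strata = [ALL_LABEL]
    else:
        raise ValueError(f"unknown stratification {stratify_by!r}")
    counts = {s: StratumCounts() for s in strata}
    for pid, status in statuses.items():
        if not status.assessable:
            continue
        stratum = _stratum_of(meta[pid], stratify_by)
        counts[stratum].add(status)
        if stratify_by == "treatment":
            counts[ALL_LABEL].add(status)
    return IncidenceTable(stratify_by=stratify_by, strata=strata, counts=counts)


# ---------------------------------------------------------------------------
# Adverse-event summary


def classify_infusion_reaction(preferred_term: str) -> bool:
    """Case-insensitive exact match against the eight defining terms."""
    return preferred_term.strip().lower() in INFUSION_REACTION_PREFERRED_TERMS


AE_COLUMNS = (
    "ADA-negative",
    "Non-TE NAb negative",
    "Non-TE NAb positive",
    "TE NAb negative",
    "TE NAb positive",
    "Total",
)


def _ae_column(status: AdaPatientStatus) -> Optional[str]:
    if not status.assessable or status.category is not AdaCategory.POSITIVE:
        if status.assessable and status.category is AdaCategory.NEGATIVE:
            return "ADA-negative"
        return None
    te = "TE" if status.te is TeFlag.TE_POSITIVE else "Non-TE"
    nab = "positive" if status.nab is NabFlag.NAB_POSITIVE else "negative"
    return f"{te} NAb {nab}"


@dataclass
class AeSummary:
    """Counts of patients with ≥1 drug-related AE / infusion reaction."""

    n_patients: Dict[str, int]
    drug_related: Dict[str, int]
    infusion_reaction: Dict[str, int]

    def percent(self, row: str, column: str) -> Optional[float]:
        counts = getattr(self, row)
        return percent_value(counts[column], self.n_patients[column])

    def cell(self, row: str, column: str) -> str:
        counts = getattr(self, row)
        pct = format_percent(counts[column], self.n_patients[column])
        return f"{counts[column]} ({pct})" if pct else str(counts[column])

    def to_dataframe(self) -> pd.DataFrame:
        rows = {
            "Patients in population": {
                c: str(self.n_patients[c]) for c in AE_COLUMNS
            },
            "Patients with drug-related AE, n (%)": {
                c: self.cell("drug_related", c) for c in AE_COLUMNS
            },
            "Patients with infusion-related reaction, n (%)": {
                c: self.cell("infusion_reaction", c) for c in AE_COLUMNS
            },
        }
        return pd.DataFrame(rows).T[list(AE_COLUMNS)]


def ae_summary(
    statuses: Mapping[str, AdaPatientStatus],
    patients: Sequence[PatientRecord],
) -> AeSummary:
    """Adverse events by ADA category over the evaluable population."""
    meta = {p.patient_id: p for p in patients}
    n = {c: 0 for c in AE_COLUMNS}
    drug = {c: 0 for c in AE_COLUMNS}
    infusion = {c: 0 for c in AE_COLUMNS}
    for pid, status in statuses.items():
        column = _ae_column(status)
        if column is None:
            continue
        patient = meta.get(pid)
        if patient is None:
            raise ValueError(f"patient {pid!r} missing metadata")
        has_drug = any(ae.drug_related for ae in patient.ae_events)
        has_infusion = any(
            classify_infusion_reaction(ae.preferred_term) for ae in patient.ae_events
        )
        for col in (column, "Total"):
            n[col] += 1
            drug[col] += has_drug
            infusion[col] += has_infusion
    return AeSummary(n_patients=n, drug_related=drug, infusion_reaction=infusion)


# ---------------------------------------------------------------------------
# Exposure summaries


def _ada_group(status: AdaPatientStatus) -> Optional[str]:
    if not status.assessable:
        return None
    if status.category is AdaCategory.NEGATIVE:
        return "negative"
    if status.category is AdaCategory.POSITIVE:
        return (
            "TE positive"
            if status.te is TeFlag.TE_POSITIVE
            else "non-TE positive"
        )
    return None  # inconclusive patients are excluded from exposure plots


_CYCLE_LABEL = re.compile(r"^C(\d+) predose$")


def nominal_visit_time(visit_label: str, regimen: str) -> Optional[float]:
    """Scheduled day of a predose visit; None for visits without a fixed day."""
    m = _CYCLE_LABEL.match(visit_label)
    if not m:
        return None
    cycle = int(m.group(1))
    return (cycle - 1) * regimen_interval_days(regimen)


def exposure_by_group(
    patients: Sequence[PatientRecord],
    statuses: Mapping[str, AdaPatientStatus],
    stat: str = "geometric",
) -> pd.DataFrame:
    """Per-regimen, per-visit, per-ADA-group drug concentration summary.

    Samples drawn later than twice their scheduled visit time are
    excluded. Zero concentrations are excluded from the mean (they cannot
    enter a geometric mean) and reported in ``n_zero``. ``stat`` selects
    geometric (default; concentrations are near log-normal) or
    ``"arithmetic"`` central tendency.
    """
    if stat not in ("geometric", "arithmetic"):
        raise ValueError("stat must be 'geometric' or 'arithmetic'")
    rows = []
    for patient in patients:
        status = statuses.get(patient.patient_id)
        if status is None:
            continue
        group = _ada_group(status)
        if group is None:
            continue
        for sample in patient.samples:
            scheduled = nominal_visit_time(sample.visit_label, patient.regimen)
            if (
                scheduled is not None
                and scheduled > 0
                and sample.time_days > 2.0 * scheduled
            ):
                continue
            rows.append(
                {
                    "regimen": patient.regimen,
                    "ada_group": group,
                    "visit_label": sample.visit_label,
                    "conc": sample.drug_conc_ug_ml,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=[
                "regimen",
                "ada_group",
                "visit_label",
                "n",
                "n_zero",
                "mean_conc",
                "min_conc",
                "max_conc",
            ]
        )
    df = pd.DataFrame(rows)
    out = []
    for (regimen, group, visit), sub in df.groupby(
        ["regimen", "ada_group", "visit_label"], sort=True
    ):
        positive = sub.loc[sub["conc"] > 0, "conc"].to_numpy()
        if len(positive):
            if stat == "geometric":
                mean = float(np.exp(np.mean(np.log(positive))))
            else:
                mean = float(np.mean(positive))
            lo, hi = float(positive.min()), float(positive.max())
        else:
            mean = lo = hi = np.nan
        out.append(
            {
                "regimen": regimen,
                "ada_group": group,
                "visit_label": visit,
                "n": int(len(positive)),
                "n_zero": int((sub["conc"] == 0).sum()),
                "mean_conc": mean,
                "min_conc": lo,
                "max_conc": hi,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Tumor-size change


@dataclass
class TumorChangeResult:
    per_patient: pd.DataFrame  # patient_id, ada_group, regimen, best_change_pct
    series: pd.DataFrame  # patient_id, time_days, change_pct
    summary: pd.DataFrame  # grouped median / IQR of best change
    excluded: List[Tuple[str, str]]  # (patient_id, reason)


def tumor_change_by_group(
    patients: Sequence[PatientRecord],
    statuses: Mapping[str, AdaPatientStatus],
) -> TumorChangeResult:
    """Percent change in tumor size from baseline, by ADA group.

    Baseline is the latest assessment at or before day 0; percent change
    is 100·(post − baseline)/baseline. The per-patient best (most
    negative) change and the full longitudinal series are both reported,
    with descriptive group summaries (median, IQR). Applies to the
    nonadjuvant setting only — adjuvant patients have no measurable
    disease after resection and are excluded with a warning.
    """
    per_patient_rows, series_rows, excluded = [], [], []
    any_nonadjuvant = False
    for patient in patients:
        status = statuses.get(patient.patient_id)
        group = _ada_group(status) if status is not None else None
        if patient.setting == "adjuvant":
            excluded.append((patient.patient_id, "adjuvant setting"))
            continue
        any_nonadjuvant = True
        if group is None:
            excluded.append((patient.patient_id, "not evaluable"))
            continue
        baseline_candidates = [
            a for a in patient.tumor_assessments if a.time_days <= 0
        ]
        if not baseline_candidates:
            excluded.append((patient.patient_id, "missing baseline assessment"))
            continue
        baseline = max(baseline_candidates, key=lambda a: a.time_days)
        post = [a for a in patient.tumor_assessments if a.time_days > 0]
        if not post:
            excluded.append((patient.patient_id, "no post-baseline assessment"))
            continue
        changes = []
        for a in post:
            change = (
                100.0
                * (a.sum_of_diameters_mm - baseline.sum_of_diameters_mm)
                / baseline.sum_of_diameters_mm
            )
            changes.append(change)
            series_rows.append(
                {
                    "patient_id": patient.patient_id,
                    "time_days": a.time_days,
                    "change_pct": change,
                }
            )
        per_patient_rows.append(
            {
                "patient_id": patient.patient_id,
                "ada_group": group,
                "regimen": patient.regimen,
                "best_change_pct": min(changes),
            }
        )
    if not any_nonadjuvant and patients:
        warnings.warn(
            "tumor-size change applies to the nonadjuvant setting only; "
            "all patients were adjuvant",
            stacklevel=2,
        )
    per_patient = pd.DataFrame(
        per_patient_rows,
        columns=["patient_id", "ada_group", "regimen", "best_change_pct"],
    )
    series = pd.DataFrame(
        series_rows, columns=["patient_id", "time_days", "change_pct"]
    )
    if len(per_patient):
        summary = (
            per_patient.groupby(["regimen", "ada_group"])["best_change_pct"]
            .agg(
                n="count",
                median="median",
                q1=lambda s: s.quantile(0.25),
                q3=lambda s: s.quantile(0.75),
            )
            .reset_index()
        )
    else:
        summary = pd.DataFrame(
            columns=["regimen", "ada_group", "n", "median", "q1", "q3"]
        )
    return TumorChangeResult(
        per_patient=per_patient, series=series, summary=summary, excluded=excluded
    )
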