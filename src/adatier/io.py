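"""CSV and YAML input/output.

All tables are UTF-8 comma-separated files with a header row; day-number
times are canonical; an empty field encodes a missing value. Files
written by a simulation run carry the seed in a leading ``# seed=N``
comment line, which the readers skip. Every CSV written by this module
round-trips through the corresponding reader with no loss.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .assay import AssayConfig, NabResult, SampleRecord
from .classify import (
    AdaCategory,
    AdaPatientStatus,
    AeEvent,
    NabFlag,
    PatientRecord,
    TeFlag,
    TumorAssessment,
    is_assessable,
    non_assessable_reason,
)
from .simulate import CohortConfig, ImmunogenicityParams, PkParams

__all__ = [
    "SAMPLE_COLUMNS",
    "write_samples_csv",
    "read_samples_csv",
    "write_patients_csv",
    "read_patients_csv",
    "write_ae_csv",
    "read_ae_csv",
    "write_tumor_csv",
    "read_tumor_csv",
    "write_truth_csv",
    "write_status_csv",
    "read_status_csv",
    "write_non_assessable_csv",
    "assemble_patients",
    "load_assay_config",
    "dump_assay_config",
    "load_cohort_config",
]

PathLike = Union[str, Path]

SAMPLE_COLUMNS = [
    "patient_id",
    "visit_label",
    "time_days",
    "screen_signal",
    "confirm_inhibition",
    "titer",
    "drug_conc_ug_ml",
    "nab_result",
    "vendor",
    "is_pretreatment",
]

PATIENT_COLUMNS = [
    "patient_id",
    "regimen",
    "indication",
    "setting",
    "body_weight_kg",
]

AE_COLUMNS = ["patient_id", "preferred_term", "drug_related", "onset_day"]
TUMOR_COLUMNS = ["patient_id", "time_days", "sum_of_diameters_mm"]
STATUS_COLUMNS = ["patient_id", "assessable", "category", "te", "nab"]


def _write_df(df: pd.DataFrame, path: PathLike, seed: Optional[int]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def _read_df(path: PathLike, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        comment="#",
        dtype={"patient_id": str},
        keep_default_na=True,
        float_precision="round_trip",
    )
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1"):
        return True
    if text in ("false", "0"):
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


# ---------------------------------------------------------------------------
# Samples


def write_samples_csv(
    patients: Sequence[PatientRecord], path: PathLike, seed: Optional[int] = None
) -> None:
    rows = []
    for p in patients:
        for s in p.samples:
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "visit_label": s.visit_label,
                    "time_days": s.time_days,
                    "screen_signal": s.screen_signal,
                    "confirm_inhibition": (
                        "" if s.confirm_inhibition is None else s.confirm_inhibition
                    ),
                    "titer": "" if s.titer is None else s.titer,
                    "drug_conc_ug_ml": s.drug_conc_ug_ml,
                    "nab_result": s.nab_result.value,
                    "vendor": s.vendor,
                    "is_pretreatment": s.is_pretreatment,
                }
            )
    df = pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
    _write_df(df, path, seed)


def read_samples_csv(path: PathLike) -> Dict[str, List[SampleRecord]]:
    """Read samples grouped by patient id, time-ordered."""
    df = _read_df(path, SAMPLE_COLUMNS)
    grouped: Dict[str, List[SampleRecord]] = {}
    errors: List[str] = []
    for i, row in df.iterrows():
        try:
            record = SampleRecord(
                patient_id=str(row["patient_id"]),
                visit_label=str(row["visit_label"]),
                time_days=float(row["time_days"]),
                screen_signal=float(row["screen_signal"]),
                confirm_inhibition=(
                    None
                    if pd.isna(row["confirm_inhibition"])
                    else float(row["confirm_inhibition"])
                ),
                titer=None if pd.isna(row["titer"]) else float(row["titer"]),
                drug_conc_ug_ml=float(row["drug_conc_ug_ml"]),
                nab_result=NabResult(str(row["nab_result"])),
                vendor=int(row["vendor"]),
                is_pretreatment=_bool(row["is_pretreatment"]),
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i + 2}: {exc}")
            continue
        grouped.setdefault(record.patient_id, []).append(record)
    if errors:
        raise ValueError(
            "malformed sample rows:\n" + "\n".join(errors[:20])
        )
    for records in grouped.values():
        records.sort(key=lambda s: s.time_days)
    return grouped


# ---------------------------------------------------------------------------
# Patients / AEs / tumor


def write_patients_csv(
    patients: Sequence[PatientRecord], path: PathLike, seed: Optional[int] = None
) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "regimen": p.regimen,
            "indication": p.indication,
            "setting": p.setting,
            "body_weight_kg": p.body_weight_kg,
        }
        for p in patients
    ]
    _write_df(pd.DataFrame(rows, columns=PATIENT_COLUMNS), path, seed)


def read_patients_csv(path: PathLike) -> pd.DataFrame:
    df = _read_df(path, PATIENT_COLUMNS)
    ids = df["patient_id"]
    duplicates = ids[ids.duplicated()].unique().tolist()
    if duplicates:
        raise ValueError(f"duplicate patient_id values: {duplicates[:10]}")
    return df


def write_ae_csv(
    patients: Sequence[PatientRecord], path: PathLike, seed: Optional[int] = None
) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "preferred_term": ae.preferred_term,
            "drug_related": ae.drug_related,
            "onset_day": ae.onset_day,
        }
        for p in patients
        for ae in p.ae_events
    ]
    _write_df(pd.DataFrame(rows, columns=AE_COLUMNS), path, seed)


def read_ae_csv(path: PathLike) -> Dict[str, List[AeEvent]]:
    df = _read_df(path, AE_COLUMNS)
    grouped: Dict[str, List[AeEvent]] = {}
    for _, row in df.iterrows():
        grouped.setdefault(str(row["patient_id"]), []).append(
            AeEvent(
                preferred_term=str(row["preferred_term"]),
                drug_related=_bool(row["drug_related"]),
                onset_day=float(row["onset_day"]),
            )
        )
    return grouped


def write_tumor_csv(
    patients: Sequence[PatientRecord], path: PathLike, seed: Optional[int] = None
) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "time_days": a.time_days,
            "sum_of_diameters_mm": a.sum_of_diameters_mm,
        }
        for p in patients
        for a in p.tumor_assessments
    ]
    _write_df(pd.DataFrame(rows, columns=TUMOR_COLUMNS), path, seed)


def read_tumor_csv(path: PathLike) -> Dict[str, List[TumorAssessment]]:
    df = _read_df(path, TUMOR_COLUMNS)
    grouped: Dict[str, List[TumorAssessment]] = {}
    for _, row in df.iterrows():
        grouped.setdefault(str(row["patient_id"]), []).append(
            TumorAssessment(
                time_days=float(row["time_days"]),
                sum_of_diameters_mm=float(row["sum_of_diameters_mm"]),
            )
        )
    for assessments in grouped.values():
        assessments.sort(key=lambda a: a.time_days)
    return grouped


def write_truth_csv(
    truth: pd.DataFrame, path: PathLike, seed: Optional[int] = None
) -> None:
    _write_df(truth, path, seed)


# ---------------------------------------------------------------------------
# Classification output


def write_status_csv(
    statuses: Mapping[str, AdaPatientStatus],
    path: PathLike,
    seed: Optional[int] = None,
) -> None:
    rows = []
    for pid, status in statuses.items():
        rows.append(
            {
                "patient_id": pid,
                "assessable": status.assessable,
                "category": status.category.value if status.category else "",
                "te": status.te.value if status.te else "",
                "nab": status.nab.value if status.nab else "",
            }
        )
    _write_df(pd.DataFrame(rows, columns=STATUS_COLUMNS), path, seed)


def read_status_csv(path: PathLike) -> Dict[str, AdaPatientStatus]:
    df = _read_df(path, STATUS_COLUMNS)
    statuses: Dict[str, AdaPatientStatus] = {}
    for _, row in df.iterrows():
        assessable = _bool(row["assessable"])
        if not assessable:
            statuses[str(row["patient_id"])] = AdaPatientStatus(assessable=False)
            continue
        statuses[str(row["patient_id"])] = AdaPatientStatus(
            assessable=True,
            category=AdaCategory(str(row["category"])),
            te=TeFlag(str(row["te"])),
            nab=NabFlag(str(row["nab"])),
        )
    return statuses


def write_non_assessable_csv(
    patients: Sequence[PatientRecord], path: PathLike
) -> None:
    rows = [
        {"patient_id": p.patient_id, "reason": non_assessable_reason(p)}
        for p in patients
        if not is_assessable(p)
    ]
    _write_df(pd.DataFrame(rows, columns=["patient_id", "reason"]), path, None)


# ---------------------------------------------------------------------------
# Record assembly


def assemble_patients(
    patients_df: pd.DataFrame,
    samples: Mapping[str, List[SampleRecord]],
    ae_events: Optional[Mapping[str, List[AeEvent]]] = None,
    tumor: Optional[Mapping[str, List[TumorAssessment]]] = None,
) -> List[PatientRecord]:
    """Join the per-patient metadata with samples, AEs and tumor data."""
    out: List[PatientRecord] = []
    for _, row in patients_df.iterrows():
        pid = str(row["patient_id"])
        out.append(
            PatientRecord(
                patient_id=pid,
                regimen=str(row["regimen"]),
                indication=str(row["indication"]),
                setting=str(row["setting"]),
                body_weight_kg=float(row["body_weight_kg"]),
                samples=list(samples.get(pid, [])),
                ae_events=list((ae_events or {}).get(pid, [])),
                tumor_assessments=list((tumor or {}).get(pid, [])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# YAML configuration


def load_assay_config(path: PathLike) -> AssayConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if "dtl_by_vendor" in data:
        data["dtl_by_vendor"] = {
            int(k): float(v) for k, v in data["dtl_by_vendor"].items()
        }
    return AssayConfig(**data)


def dump_assay_config(config: AssayConfig, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def load_cohort_config(path: PathLike) -> CohortConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if "pk" in data:
        data["pk"] = PkParams(**data["pk"])
    if "imm" in data:
        data["imm"] = ImmunogenicityParams(**data["imm"])
    if "assay" in data:
        assay = data["assay"]
        if "dtl_by_vendor" in assay:
            assay["dtl_by_vendor"] = {
                int(k): float(v) for k, v in assay["dtl_by_vendor"].items()
            }
        data["assay"] = AssayConfig(**assay)
    if "vendor_mix" in data:
        data["vendor_mix"] = {int(k): float(v) for k, v in data["vendor_mix"].items()}
    return CohortConfig(**data)
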