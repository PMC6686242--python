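"""Synthetic cohort generation for the immunogenicity pipeline.

Real immunogenicity datasets from checkpoint-inhibitor programs are not
public, so this module generates cohorts with the statistical structure
the analysis assumes:

* the clinical sampling schedule — baseline, predose draws at cycles 2,
  4, 8 (then every 8 cycles), end of treatment, and follow-up at 1, 3 and
  6 months;
* regimen-specific trough drug concentrations from a one-compartment IV
  bolus superposition model with log-normal between-patient variability;
* latent patient-level ADA truth — pre-existing positivity, treatment-
  emergent seroconversion during dosing, geometric titer growth;
* assay observations in which circulating drug suppresses the true ADA
  signal through a rational half-saturation interference curve (the
  mechanism that produces inconclusive patients);
* adverse events and tumor-size trajectories for the safety and efficacy
  summaries.

Cohorts are fully reproducible: one master seed, with per-patient
substreams derived from (seed, patient index) so that changing the cohort
size never reshuffles existing patients.

:func:`fixture_from_counts` goes the other way: it deterministically
constructs minimal patients whose classification reproduces a requested
status partition exactly — the bridge between a published contingency
table and an executable end-to-end check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .assay import AssayConfig, ConfigError, NabResult, SampleRecord, assign_titer
from .classify import (
    INDICATIONS,
    REGIMENS,
    AeEvent,
    PatientRecord,
    TumorAssessment,
)

__all__ = [
    "PkParams",
    "ImmunogenicityParams",
    "CohortConfig",
    "PatientTruth",
    "schedule_samples",
    "simulate_pk_trough",
    "interference_factor",
    "simulate_assay_observation",
    "simulate_patient_truth",
    "generate_cohort",
    "fixture_from_counts",
    "FIXTURE_STATUSES",
]

#: (dose in mg/kg or None, flat dose in mg or None, dosing interval in days)
REGIMEN_SPECS: Dict[str, Tuple[Optional[float], Optional[float], float]] = {
    "2 mg/kg Q3W": (2.0, None, 21.0),
    "10 mg/kg Q2W": (10.0, None, 14.0),
    "10 mg/kg Q3W": (10.0, None, 21.0),
    "200 mg Q3W": (None, 200.0, 21.0),
}


def regimen_interval_days(regimen: str) -> float:
    try:
        return REGIMEN_SPECS[regimen][2]
    except KeyError:
        raise ConfigError(f"unknown regimen {regimen!r}") from None


@dataclass(frozen=True)
class PkParams:
    """One-compartment PK parameters (population typical values).

    Defaults (clearance 0.2 L/day, volume 6 L, ~21-day half-life) mimic
    published population PK of IgG4 monoclonal antibodies such as
    pembrolizumab; they are configuration, not estimates from data.
    ``iiv_log_sd`` is the standard deviation of the log-normal
    between-patient variability applied to both CL and V.
    """

    clearance_l_per_day: float = 0.2
    volume_l: float = 6.0
    iiv_log_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.clearance_l_per_day <= 0 or self.volume_l <= 0:
            raise ConfigError("clearance and volume must be positive")
        if self.iiv_log_sd < 0:
            raise ConfigError("iiv_log_sd must be non-negative")
        if not math.isfinite(math.log(2) * self.volume_l / self.clearance_l_per_day):
            raise ConfigError("half-life must be finite")


@dataclass(frozen=True)
class ImmunogenicityParams:
    """Latent ADA dynamics and assay-observation parameters.

    ``p_te`` and ``p_preexisting`` anchor the simulated incidence to the
    observed clinical rates (1.8% treatment-emergent, 1.1% pre-existing);
    ``p_nab_given_te`` = 0.25 reflects 9 neutralizing among 36
    treatment-emergent positives, ``p_nab_given_preexisting`` ≈ 0.095
    reflects 2 of 21. ``interference_scale`` is the drug concentration
    (µg/mL) at which the true ADA signal is half-suppressed.
    """

    p_te: float = 0.018
    p_preexisting: float = 0.011
    p_nab_given_te: float = 0.25
    p_nab_given_preexisting: float = 2.0 / 21.0
    onset_max_cycles: float = 4.0
    titer_growth_fold: float = 2.0
    titer_growth_log_sd: float = 0.25
    titer_cap: float = 512.0
    interference_scale: float = 150.0
    background_signal_frac: float = 0.5
    noise_log_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "p_te",
            "p_preexisting",
            "p_nab_given_te",
            "p_nab_given_preexisting",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.interference_scale <= 0:
            raise ConfigError("interference_scale must be positive")
        if not 0.0 < self.background_signal_frac < 1.0:
            raise ConfigError("background_signal_frac must lie in (0, 1)")
        if self.noise_log_sd < 0 or self.titer_growth_log_sd < 0:
            raise ConfigError("log-sd parameters must be non-negative")


def _default_regimen_mix() -> Dict[str, float]:
    # Proportions follow the relative sizes of the four regimen groups in
    # the pooled nonadjuvant analysis population.
    return {
        "200 mg Q3W": 0.41,
        "2 mg/kg Q3W": 0.30,
        "10 mg/kg Q3W": 0.23,
        "10 mg/kg Q2W": 0.06,
    }


def _default_indication_mix() -> Dict[str, float]:
    # Evaluable-patient shares of the six tumor types in the pooled cohort.
    return {
        "melanoma": 0.201,
        "NSCLC": 0.3955,
        "HNSCC": 0.031,
        "CRC": 0.027,
        "HL": 0.091,
        "UC": 0.2545,
    }


@dataclass
class CohortConfig:
    """Everything needed to simulate one cohort reproducibly."""

    n_patients: int = 2000
    seed: int = 0
    setting: str = "nonadjuvant"
    regimen_mix: Dict[str, float] = field(default_factory=_default_regimen_mix)
    indication_mix: Dict[str, float] = field(default_factory=_default_indication_mix)
    vendor_mix: Dict[int, float] = field(default_factory=lambda: {1: 0.5, 2: 0.5})
    pk: PkParams = field(default_factory=PkParams)
    imm: ImmunogenicityParams = field(default_factory=ImmunogenicityParams)
    assay: AssayConfig = field(default_factory=AssayConfig)
    p_drug_related_ae: float = 0.689
    p_infusion_reaction: float = 0.022
    eot_mean_days: float = 180.0
    eot_min_days: float = 21.0
    eot_max_days: float = 730.0
    p_missing_followup: float = 0.5
    weight_median_kg: float = 75.0
    weight_log_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        if self.setting not in ("nonadjuvant", "adjuvant"):
            raise ConfigError(f"unknown setting {self.setting!r}")
        for name, mix in (
            ("regimen_mix", self.regimen_mix),
            ("indication_mix", self.indication_mix),
            ("vendor_mix", self.vendor_mix),
        ):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} probabilities must sum to 1 (got {total})")
            if any(p < 0 for p in mix.values()):
                raise ConfigError(f"{name} contains a negative probability")
        for regimen in self.regimen_mix:
            if regimen not in REGIMENS:
                raise ConfigError(f"unknown regimen {regimen!r} in regimen_mix")
        for indication in self.indication_mix:
            if indication not in INDICATIONS:
                raise ConfigError(f"unknown indication {indication!r}")
        for p in (
            self.p_drug_related_ae,
            self.p_infusion_reaction,
            self.p_missing_followup,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("event probabilities must lie in [0, 1]")
        if not 0 < self.eot_min_days <= self.eot_max_days:
            raise ConfigError("end-of-treatment bounds are inconsistent")


# ---------------------------------------------------------------------------
# Visit schedule


def schedule_samples(
    regimen: str, treatment_duration_days: float
) -> List[Tuple[str, float]]:
    """Immunogenicity sampling schedule for one patient.

    Baseline just before the first dose; predose draws at cycles 2, 4 and
    8 and every 8 cycles thereafter (predose at cycle *n* falls on day
    (n − 1) × interval, kept while it precedes the end of treatment); an
    end-of-treatment draw; and follow-up draws 30, 90 and 180 days after
    treatment ends.
    """
    if treatment_duration_days <= 0:
        raise ValueError("treatment duration must be positive")
    interval = regimen_interval_days(regimen)
    visits: List[Tuple[str, float]] = [("baseline", -0.5)]
    cycle = 2
    while True:
        t = (cycle - 1) * interval
        if t >= treatment_duration_days:
            break
        visits.append((f"C{cycle} predose", t))
        cycle = cycle * 2 if cycle < 8 else cycle + 8
    visits.append(("EOT", treatment_duration_days))
    for label, offset in (("FU 1 mo", 30.0), ("FU 3 mo", 90.0), ("FU 6 mo", 180.0)):
        visits.append((label, treatment_duration_days + offset))
    return visits


# ---------------------------------------------------------------------------
# Pharmacokinetics


def simulate_pk_trough(
    regimen: str,
    weight_kg: float,
    times: Sequence[float],
    params: PkParams,
    rng: np.random.Generator,
    treatment_duration_days: float = math.inf,
) -> np.ndarray:
    """Drug concentrations (µg/mL) by one-compartment IV superposition.

    ``C(t) = Σ over doses given strictly before t of (D/V)·exp(−(CL/V)(t−t_d))``
    with doses every interval until ``treatment_duration_days``. Dose is
    flat (mg) or weight-based (mg/kg × weight). CL and V are drawn once
    per call from log-normal distributions around the typical values
    (mg/L ≡ µg/mL). Times at or before the first dose return 0.
    """
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    per_kg, flat, interval = REGIMEN_SPECS.get(regimen, (None, None, None))
    if interval is None:
        raise ConfigError(f"unknown regimen {regimen!r}")
    dose_mg = flat if flat is not None else per_kg * weight_kg
    cl = params.clearance_l_per_day * math.exp(rng.normal(0.0, params.iiv_log_sd))
    v = params.volume_l * math.exp(rng.normal(0.0, params.iiv_log_sd))
    k = cl / v
    times_arr = np.asarray(times, dtype=float)
    horizon = float(np.max(times_arr, initial=0.0))
    last_dose = min(treatment_duration_days, horizon)
    n_doses = max(0, math.ceil(last_dose / interval)) if last_dose > 0 else 0
    conc = np.zeros_like(times_arr)
    for d in range(n_doses + 1):
        t_d = d * interval
        if t_d >= treatment_duration_days:
            break
        mask = times_arr > t_d
        conc[mask] += (dose_mg / v) * np.exp(-k * (times_arr[mask] - t_d))
    return conc


# ---------------------------------------------------------------------------
# Assay observation


def interference_factor(drug_conc_ug_ml: float, interference_scale: float) -> float:
    """Fraction of the true ADA signal surviving drug interference.

    Rational half-suppression: 1 / (1 + conc/scale); exactly 0.5 at
    ``conc == interference_scale`` and → 0 as conc → ∞.
    """
    if drug_conc_ug_ml < 0:
        raise ValueError("drug concentration must be non-negative")
    return 1.0 / (1.0 + drug_conc_ug_ml / interference_scale)


def simulate_assay_observation(
    true_titer: float,
    drug_conc_ug_ml: float,
    imm: ImmunogenicityParams,
    assay: AssayConfig,
    rng: np.random.Generator,
) -> Dict[str, Optional[float]]:
    """Observed tier-1/2/3 readouts for one sample.

    The screening signal is a noisy background plus a term proportional to
    the *effective* titer (true titer × interference factor); a truly
    positive sample with circulating drug far above ``interference_scale``
    therefore screens negative. Tier 2 and 3 are only simulated along the
    cascade the laboratory would actually run.
    """
    if true_titer < 0:
        raise ValueError("true titer must be non-negative")
    cut = assay.screen_cut_point
    effective = true_titer * interference_factor(
        drug_conc_ug_ml, imm.interference_scale
    )
    background = cut * imm.background_signal_frac
    if imm.noise_log_sd > 0:
        background *= math.exp(rng.normal(0.0, imm.noise_log_sd))
    signal = background + cut * effective
    out: Dict[str, Optional[float]] = {
        "screen_signal": signal,
        "confirm_inhibition": None,
        "titer": None,
        "confirmed": False,
    }
    if signal < cut:
        return out
    # Drug-specific inhibition saturates with the surviving ADA signal; a
    # noise-driven reactive (effective ~ 0) fails confirmation.
    inhibition = min(0.99, effective / (effective + 0.5))
    out["confirm_inhibition"] = inhibition
    if inhibition < assay.confirm_threshold:
        return out
    out["confirmed"] = True
    series = []
    dilution = assay.titer_base_dilution
    while dilution <= max(effective, assay.titer_base_dilution):
        series.append((dilution, effective >= dilution))
        dilution *= assay.titer_dilution_factor
    out["titer"] = assign_titer(series)
    return out


# ---------------------------------------------------------------------------
# Latent truth


@dataclass(frozen=True)
class PatientTruth:
    """Latent ADA trajectory of one simulated patient."""

    status: str  # "negative" | "te_positive" | "non_te_positive"
    preexisting: bool
    is_te: bool
    onset_day: Optional[float]
    baseline_titer: float
    onset_titer: float
    growth_fold_per_cycle: float
    interval_days: float
    titer_cap: float
    nab_positive: bool

    def true_titer(self, time_days: float) -> float:
        titer = self.baseline_titer
        if self.is_te and self.onset_day is not None and time_days >= self.onset_day:
            cycles = (time_days - self.onset_day) / self.interval_days
            titer = min(
                self.titer_cap,
                self.onset_titer * self.growth_fold_per_cycle**cycles,
            )
        return titer


def simulate_patient_truth(
    imm: ImmunogenicityParams,
    interval_days: float,
    treatment_duration_days: float,
    rng: np.random.Generator,
) -> PatientTruth:
    """Draw one patient's latent ADA status and titer dynamics.

    Pre-existing positivity (probability ``p_preexisting``) gives a
    constant baseline titer. Treatment-emergent seroconversion
    (probability ``p_te``, independent) begins at a time drawn uniformly
    over the first ``onset_max_cycles`` cycles but no later than the end
    of treatment — ADA develops while the patient is exposed to drug —
    with the titer stepping to at least twice baseline at onset and then
    growing geometrically per cycle.
    """
    preexisting = bool(rng.random() < imm.p_preexisting)
    is_te = bool(rng.random() < imm.p_te)
    baseline_titer = float(rng.choice([1.0, 2.0, 4.0, 8.0])) if preexisting else 0.0
    onset_day: Optional[float] = None
    onset_titer = 0.0
    growth = 1.0
    if is_te:
        onset_day = float(
            rng.uniform(
                0.0, min(imm.onset_max_cycles * interval_days, treatment_duration_days)
            )
        )
        seed_titer = float(rng.choice([2.0, 4.0, 8.0]))
        onset_titer = max(seed_titer, 2.0 * baseline_titer)
        growth = math.exp(
            rng.normal(math.log(imm.titer_growth_fold), imm.titer_growth_log_sd)
        )
        growth = max(1.0, growth)
    if is_te:
        status = "te_positive"
    elif preexisting:
        status = "non_te_positive"
    else:
        status = "negative"
    if status == "te_positive":
        nab = bool(rng.random() < imm.p_nab_given_te)
    elif status == "non_te_positive":
        nab = bool(rng.random() < imm.p_nab_given_preexisting)
    else:
        nab = False
    return PatientTruth(
        status=status,
        preexisting=preexisting,
        is_te=is_te,
        onset_day=onset_day,
        baseline_titer=baseline_titer,
        onset_titer=onset_titer,
        growth_fold_per_cycle=growth,
        interval_days=interval_days,
        titer_cap=imm.titer_cap,
        nab_positive=nab,
    )


# ---------------------------------------------------------------------------
# Cohort generation

INFUSION_REACTION_TERM = "infusion-related reaction"
GENERIC_DRUG_RELATED_TERMS = ("fatigue", "pruritus", "rash", "diarrhoea")


def _choice(rng: np.random.Generator, mix: Mapping) -> object:
    keys = list(mix.keys())
    probs = np.asarray([mix[k] for k in keys], dtype=float)
    idx = int(rng.choice(len(keys), p=probs / probs.sum()))
    return keys[idx]


def _simulate_one_patient(
    config: CohortConfig, index: int
) -> Tuple[PatientRecord, Dict[str, object]]:
    rng = np.random.default_rng([config.seed, index])
    patient_id = f"SIM{index:05d}"
    if config.setting == "adjuvant":
        regimen, indication = "200 mg Q3W", "melanoma"
    else:
        regimen = _choice(rng, config.regimen_mix)
        indication = _choice(rng, config.indication_mix)
    interval = regimen_interval_days(regimen)
    weight = config.weight_median_kg * math.exp(
        rng.normal(0.0, config.weight_log_sd)
    )
    vendor = _choice(rng, config.vendor_mix)
    duration = float(
        np.clip(
            rng.exponential(config.eot_mean_days),
            config.eot_min_days,
            config.eot_max_days,
        )
    )
    visits = schedule_samples(regimen, duration)
    if rng.random() < config.p_missing_followup:
        # Lost to follow-up (or still on treatment at data cutoff): the
        # end-of-treatment draw is the last sample, typically at high
        # drug concentration — the source of inconclusive patients.
        visits = [v for v in visits if not v[0].startswith("FU")]
    times = [t for _, t in visits]
    concs = simulate_pk_trough(
        regimen, weight, times, config.pk, rng, treatment_duration_days=duration
    )
    truth = simulate_patient_truth(config.imm, interval, duration, rng)
    samples: List[SampleRecord] = []
    for (label, t), conc in zip(visits, concs):
        obs = simulate_assay_observation(
            truth.true_titer(t), float(conc), config.imm, config.assay, rng
        )
        if obs["confirmed"]:
            nab_result = (
                NabResult.POSITIVE if truth.nab_positive else NabResult.NEGATIVE
            )
        else:
            nab_result = NabResult.NOT_TESTED
        samples.append(
            SampleRecord(
                patient_id=patient_id,
                visit_label=label,
                time_days=t,
                screen_signal=obs["screen_signal"],
                confirm_inhibition=obs["confirm_inhibition"],
                titer=obs["titer"],
                drug_conc_ug_ml=float(conc),
                nab_result=nab_result,
                vendor=vendor,
                is_pretreatment=t <= 0,
            )
        )
    ae_events: List[AeEvent] = []
    if rng.random() < config.p_drug_related_ae:
        term = GENERIC_DRUG_RELATED_TERMS[
            int(rng.integers(len(GENERIC_DRUG_RELATED_TERMS)))
        ]
        ae_events.append(AeEvent(term, True, float(rng.uniform(0.0, duration))))
    if rng.random() < config.p_infusion_reaction:
        ae_events.append(
            AeEvent(INFUSION_REACTION_TERM, True, float(rng.uniform(0.0, duration)))
        )
    tumor: List[TumorAssessment] = []
    if config.setting == "nonadjuvant":
        sld0 = 60.0 * math.exp(rng.normal(0.0, 0.4))
        growth_rate = rng.normal(-0.0015, 0.0035)
        tumor.append(TumorAssessment(-7.0, sld0))
        t = 63.0
        while t <= duration + 30.0:
            sld = max(5.0, sld0 * math.exp(growth_rate * t))
            tumor.append(TumorAssessment(t, sld))
            t += 63.0
    patient = PatientRecord(
        patient_id=patient_id,
        regimen=regimen,
        indication=indication,
        setting=config.setting,
        body_weight_kg=weight,
        samples=samples,
        ae_events=ae_events,
        tumor_assessments=tumor,
    )
    truth_row = {
        "patient_id": patient_id,
        "true_status": truth.status,
        "is_te": truth.is_te,
        "preexisting": truth.preexisting,
        "onset_day": truth.onset_day,
        "baseline_titer": truth.baseline_titer,
        "nab_positive": truth.nab_positive,
        "regimen": regimen,
        "indication": indication,
        "vendor": vendor,
        "treatment_duration_days": duration,
        "last_sample_conc_ug_ml": float(concs[-1]) if len(concs) else 0.0,
    }
    return patient, truth_row


def generate_cohort(
    config: CohortConfig,
) -> Tuple[List[PatientRecord], pd.DataFrame]:
    """Simulate a cohort; returns (patients, latent-truth table).

    Fully reproducible from ``config.seed``; per-patient substreams are
    keyed by (seed, index) so patient *i* is identical in any cohort of
    size > *i* generated with the same configuration.
    """
    patients: List[PatientRecord] = []
    truth_rows: List[Dict[str, object]] = []
    for i in range(config.n_patients):
        patient, row = _simulate_one_patient(config, i)
        patients.append(patient)
        truth_rows.append(row)
    columns = [
        "patient_id",
        "true_status",
        "is_te",
        "preexisting",
        "onset_day",
        "baseline_titer",
        "nab_positive",
        "regimen",
        "indication",
        "vendor",
        "treatment_duration_days",
        "last_sample_conc_ug_ml",
    ]
    truth = pd.DataFrame(truth_rows, columns=columns)
    return patients, truth


# ---------------------------------------------------------------------------
# Deterministic fixtures from contingency counts

FIXTURE_STATUSES = (
    "negative",
    "inconclusive",
    "non_te_nab_negative",
    "non_te_nab_positive",
    "te_nab_negative",
    "te_nab_positive",
)

_STATUS_ALIASES = {
    "non_te_positive": "non_te_nab_negative",
    "te_positive": "te_nab_negative",
}

CountSpecValue = Union[int, Mapping[str, int]]


def _normalize_spec(
    count_spec: Mapping[str, CountSpecValue],
) -> Dict[str, Dict[str, int]]:
    normalized: Dict[str, Dict[str, int]] = {
        status: {"n": 0, "drug_related_ae": 0, "infusion_reaction": 0}
        for status in FIXTURE_STATUSES
    }
    for raw_key, value in count_spec.items():
        key = _STATUS_ALIASES.get(raw_key, raw_key)
        if key not in normalized:
            raise ValueError(f"unknown status {raw_key!r} in count spec")
        if isinstance(value, Mapping):
            entry = {
                "n": int(value.get("n", value.get("count", 0))),
                "drug_related_ae": int(value.get("drug_related_ae", 0)),
                "infusion_reaction": int(value.get("infusion_reaction", 0)),
            }
        else:
            entry = {"n": int(value), "drug_related_ae": 0, "infusion_reaction": 0}
        if entry["n"] < 0:
            raise ValueError(f"negative count for {raw_key!r}")
        if entry["drug_related_ae"] < 0 or entry["infusion_reaction"] < 0:
            raise ValueError(f"negative AE count for {raw_key!r}")
        if max(entry["drug_related_ae"], entry["infusion_reaction"]) > entry["n"]:
            raise ValueError(
                f"AE count exceeds patient count for status {raw_key!r}"
            )
        for k in entry:
            normalized[key][k] += entry[k]
    return normalized


def fixture_from_counts(
    count_spec: Mapping[str, CountSpecValue],
    *,
    regimen: str = "200 mg Q3W",
    indication: str = "melanoma",
    setting: str = "nonadjuvant",
    assay: Optional[AssayConfig] = None,
    vendor: int = 2,
    id_prefix: str = "P",
) -> List[PatientRecord]:
    """Build a minimal cohort that classifies to the requested counts.

    ``count_spec`` maps status names (``negative``, ``inconclusive``,
    ``non_te_nab_negative``, ``non_te_nab_positive``, ``te_nab_negative``,
    ``te_nab_positive``; ``te_positive``/``non_te_positive`` are accepted
    as NAb-negative shorthands) to either a patient count or a mapping
    ``{"n": ..., "drug_related_ae": ..., "infusion_reaction": ...}``
    assigning numbers of patients carrying a drug-related adverse event
    and an infusion-related-reaction preferred term.

    Each patient gets exactly two samples (baseline and one postdose
    draw) engineered so that :func:`adatier.classify.classify_patient`
    with the same assay configuration reproduces the requested status —
    the round trip ``fixture_from_counts ∘ classify_cohort`` is the
    identity on any feasible spec.
    """
    assay = assay or AssayConfig()
    spec = _normalize_spec(count_spec)
    dtl = assay.dtl(vendor)
    cut = assay.screen_cut_point
    strong_inhibition = max(assay.confirm_threshold, 0.9)
    base = assay.titer_base_dilution
    factor = assay.titer_dilution_factor

    def negative_sample(pid: str, t: float, label: str, conc: float) -> SampleRecord:
        return SampleRecord(
            patient_id=pid,
            visit_label=label,
            time_days=t,
            screen_signal=0.0,
            drug_conc_ug_ml=conc,
            vendor=vendor,
            is_pretreatment=t <= 0,
        )

    def positive_sample(
        pid: str, t: float, label: str, titer: float, nab: NabResult, conc: float
    ) -> SampleRecord:
        return SampleRecord(
            patient_id=pid,
            visit_label=label,
            time_days=t,
            screen_signal=2.0 * cut,
            confirm_inhibition=strong_inhibition,
            titer=titer,
            drug_conc_ug_ml=conc,
            nab_result=nab,
            vendor=vendor,
            is_pretreatment=t <= 0,
        )

    patients: List[PatientRecord] = []
    idx = 0
    for status in FIXTURE_STATUSES:
        entry = spec[status]
        for j in range(entry["n"]):
            pid = f"{id_prefix}{idx:05d}"
            idx += 1
            if status == "negative":
                samples = [
                    negative_sample(pid, -0.5, "baseline", 0.0),
                    negative_sample(pid, 21.0, "C2 predose", 0.5 * dtl),
                ]
            elif status == "inconclusive":
                samples = [
                    negative_sample(pid, -0.5, "baseline", 0.0),
                    negative_sample(pid, 21.0, "C2 predose", 2.0 * dtl),
                ]
            elif status.startswith("te_"):
                nab = (
                    NabResult.POSITIVE
                    if status.endswith("nab_positive")
                    else NabResult.NEGATIVE
                )
                samples = [
                    negative_sample(pid, -0.5, "baseline", 0.0),
                    positive_sample(
                        pid, 21.0, "C2 predose", base * factor, nab, 10.0
                    ),
                ]
            else:  # pre-existing (non-TE) positivity at baseline only
                nab = (
                    NabResult.POSITIVE
                    if status.endswith("nab_positive")
                    else NabResult.NEGATIVE
                )
                samples = [
                    positive_sample(
                        pid, -0.5, "baseline", base * factor**2, nab, 0.0
                    ),
                    negative_sample(pid, 21.0, "C2 predose", 0.5 * dtl),
                ]
            ae_events: List[AeEvent] = []
            if j < entry["drug_related_ae"]:
                ae_events.append(AeEvent("fatigue", True, 1.0))
            if j < entry["infusion_reaction"]:
                ae_events.append(AeEvent(INFUSION_REACTION_TERM, False, 0.0))
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    regimen=regimen,
                    indication=indication,
                    setting=setting,
                    samples=samples,
                    ae_events=ae_events,
                )
            )
    return patients
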