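"""Sample-level anti-drug-antibody (ADA) assay logic.

Implements the three-tier testing cascade used for immunogenicity
assessment of therapeutic monoclonal antibodies:

* **Tier 1 (screening)** — the raw electrochemiluminescence response is
  compared against a screening cut point; samples at or above it are
  *reactive*.
* **Tier 2 (confirmation)** — reactive samples are re-assayed in the
  presence of excess drug; a fractional signal inhibition at or above the
  confirmatory threshold confirms that the signal is drug-specific.
* **Tier 3 (titer)** — confirmed-positive samples are serially diluted;
  the titer is the reciprocal of the highest dilution still reactive.

Circulating drug competes with assay reagents for the antibody, so above a
vendor-specific **drug tolerance level (DTL)** a negative result is not
informative; :func:`is_above_dtl` carries that comparison.

Threshold conventions: the tier-1 and tier-2 cut points are inclusive
(a signal exactly at the cut point is reactive/positive, as is customary
for validated cut points), while the DTL comparison is strict — a
concentration exactly at the DTL does not invalidate a negative result.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "Tier1Result",
    "Tier2Result",
    "NabResult",
    "SampleRecord",
    "AssayConfig",
    "SampleAdaOutcome",
    "ConfigError",
    "evaluate_tier1",
    "evaluate_tier2",
    "assign_titer",
    "evaluate_sample",
    "is_above_dtl",
]


class ConfigError(ValueError):
    """Raised when assay configuration is inconsistent with the data."""


class Tier1Result(str, enum.Enum):
    REACTIVE = "reactive"
    NON_REACTIVE = "non_reactive"


class Tier2Result(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_RUN = "not_run"


class NabResult(str, enum.Enum):
    """Neutralizing-antibody assay outcome for a sample.

    NAb assays are run only on tier-2 confirmed ADA-positive samples, so
    ``NOT_TESTED`` is the only legal value for unconfirmed samples.
    """

    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_TESTED = "not_tested"


@dataclass(frozen=True)
class AssayConfig:
    """Cut points, titer scheme, drug tolerance levels and the TE threshold.

    Parameters
    ----------
    screen_cut_point
        Tier-1 screening cut point in assay response units. The study
        assay is validated externally; the value here is configuration,
        not derived from data.
    confirm_threshold
        Minimum fractional signal inhibition (0–1) for tier-2 positivity.
    titer_base_dilution
        First dilution of the tier-3 series; also the minimum reportable
        titer.
    titer_dilution_factor
        Geometric step of the dilution series (> 1).
    dtl_by_vendor
        Drug tolerance level in µg/mL per assay vendor. The study used
        25 µg/mL at vendor 1 and 124 µg/mL after the assay was optimized
        at vendor 2.
    te_fold_threshold
        Minimum postdose/baseline titer ratio for a baseline-positive
        patient to count as treatment-emergent. Default 2 (the stringent
        choice); the conventional alternatives are 4 or 9.
    """

    screen_cut_point: float = 1.5
    confirm_threshold: float = 0.2
    titer_base_dilution: float = 1.0
    titer_dilution_factor: float = 2.0
    dtl_by_vendor: dict = field(default_factory=lambda: {1: 25.0, 2: 124.0})
    te_fold_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.screen_cut_point <= 0:
            raise ConfigError("screen_cut_point must be positive")
        if not 0.0 < self.confirm_threshold < 1.0:
            raise ConfigError("confirm_threshold must be in (0, 1)")
        if self.titer_base_dilution <= 0:
            raise ConfigError("titer_base_dilution must be positive")
        if self.titer_dilution_factor <= 1:
            raise ConfigError("titer_dilution_factor must exceed 1")
        if self.te_fold_threshold <= 1:
            raise ConfigError("te_fold_threshold must exceed 1")
        for vendor, dtl in self.dtl_by_vendor.items():
            if dtl <= 0:
                raise ConfigError(f"DTL for vendor {vendor!r} must be positive")

    def dtl(self, vendor) -> float:
        try:
            return self.dtl_by_vendor[vendor]
        except KeyError:
            raise ConfigError(
                f"no drug tolerance level configured for vendor {vendor!r}"
            ) from None


@dataclass
class SampleRecord:
    """One immunogenicity blood sample.

    ``confirm_inhibition`` and ``titer`` are ``None`` when the respective
    tier was not run (tier 2 is only run on tier-1 reactive samples, tier 3
    only on tier-2 positives). ``time_days`` is days since the first dose;
    the baseline draw falls in [-1, 0].
    """

    patient_id: str
    visit_label: str
    time_days: float
    screen_signal: float
    confirm_inhibition: Optional[float] = None
    titer: Optional[float] = None
    drug_conc_ug_ml: float = 0.0
    nab_result: NabResult = NabResult.NOT_TESTED
    vendor: int = 2
    is_pretreatment: bool = False

    def __post_init__(self) -> None:
        self.nab_result = NabResult(self.nab_result)
        if self.screen_signal < 0:
            raise ValueError(f"{self.patient_id}: screen_signal must be >= 0")
        if self.drug_conc_ug_ml < 0:
            raise ValueError(f"{self.patient_id}: drug_conc_ug_ml must be >= 0")
        if self.confirm_inhibition is not None and not (
            0.0 <= self.confirm_inhibition <= 1.0
        ):
            raise ValueError(f"{self.patient_id}: confirm_inhibition outside [0, 1]")
        if self.titer is not None:
            if self.titer <= 0:
                raise ValueError(f"{self.patient_id}: titer must be positive")
            if self.confirm_inhibition is None:
                raise ValueError(
                    f"{self.patient_id}: titer reported without a confirmatory result"
                )
        if self.is_pretreatment != (self.time_days <= 0):
            raise ValueError(
                f"{self.patient_id}: is_pretreatment must mirror time_days <= 0"
            )


@dataclass(frozen=True)
class SampleAdaOutcome:
    """Result of running a sample through the tier cascade."""

    tier1: Tier1Result
    tier2: Tier2Result
    titer: Optional[float]
    confirmed_positive: bool

    def __post_init__(self) -> None:
        if self.confirmed_positive != (self.tier2 is Tier2Result.POSITIVE):
            raise ValueError("confirmed_positive must mirror tier2 positivity")
        if self.tier1 is Tier1Result.NON_REACTIVE and self.tier2 is not Tier2Result.NOT_RUN:
            raise ValueError("tier 2 must not run on a tier-1 non-reactive sample")


def evaluate_tier1(signal: float, config: AssayConfig) -> Tier1Result:
    """Screen a raw assay signal against the tier-1 cut point (inclusive)."""
    if signal < 0:
        raise ValueError("screening signal must be non-negative")
    if signal >= config.screen_cut_point:
        return Tier1Result.REACTIVE
    return Tier1Result.NON_REACTIVE


def evaluate_tier2(inhibition: float, config: AssayConfig) -> Tier2Result:
    """Confirm a tier-1 reactive sample by drug competition (inclusive cut)."""
    if not 0.0 <= inhibition <= 1.0:
        raise ValueError("fractional inhibition must lie in [0, 1]")
    if inhibition >= config.confirm_threshold:
        return Tier2Result.POSITIVE
    return Tier2Result.NEGATIVE


def assign_titer(
    dilution_outcomes: Sequence[tuple[float, bool]],
) -> Optional[float]:
    """Read a titer off a serial-dilution series.

    Parameters
    ----------
    dilution_outcomes
        Ordered ``(dilution_factor, reactive)`` pairs with strictly
        increasing dilution factors, starting at the base dilution.

    Returns
    -------
    The reciprocal of the highest reactive dilution (which for
    reciprocal-dilution factors is the factor itself), ``None`` if no
    dilution is reactive. A series reactive only at the base dilution
    reports the base dilution — the minimum reportable titer.
    """
    if len(dilution_outcomes) == 0:
        raise ValueError("dilution series must not be empty")
    previous = -math.inf
    highest: Optional[float] = None
    for dilution, reactive in dilution_outcomes:
        if dilution <= previous:
            raise ValueError("dilution factors must be strictly increasing")
        previous = dilution
        if reactive:
            highest = dilution
    return highest


def evaluate_sample(sample: SampleRecord, config: AssayConfig) -> SampleAdaOutcome:
    """Run one sample through tiers 1 → 2 → 3 in order.

    Tier 2 is never evaluated on a tier-1 non-reactive sample, and the
    titer is carried only for tier-2 positives. The function is pure:
    identical inputs always give identical outcomes.
    """
    tier1 = evaluate_tier1(sample.screen_signal, config)
    if tier1 is Tier1Result.NON_REACTIVE:
        return SampleAdaOutcome(tier1, Tier2Result.NOT_RUN, None, False)
    if sample.confirm_inhibition is None:
        raise ValueError(
            f"{sample.patient_id}: tier-1 reactive sample lacks a confirmatory result"
        )
    tier2 = evaluate_tier2(sample.confirm_inhibition, config)
    if tier2 is Tier2Result.NEGATIVE:
        return SampleAdaOutcome(tier1, tier2, None, False)
    return SampleAdaOutcome(tier1, tier2, sample.titer, True)


def is_above_dtl(conc_ug_ml: float, vendor, config: AssayConfig) -> bool:
    """True iff a drug concentration is strictly above the vendor's DTL."""
    if conc_ug_ml < 0:
        raise ValueError("drug concentration must be non-negative")
    return conc_ug_ml > config.dtl(vendor)
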