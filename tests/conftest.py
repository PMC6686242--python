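import pytest
from hypothesis import settings

from adatier.assay import AssayConfig, NabResult, SampleRecord

settings.register_profile("default", derandomize=True, max_examples=200)
settings.load_profile("default")


@pytest.fixture
def assay() -> AssayConfig:
    return AssayConfig()


def negative_sample(pid, t, conc=0.0, vendor=2, label=None):
    return SampleRecord(
        patient_id=pid,
        visit_label=label or ("baseline" if t <= 0 else "C2 predose"),
        time_days=t,
        screen_signal=0.0,
        drug_conc_ug_ml=conc,
        vendor=vendor,
        is_pretreatment=t <= 0,
    )


def positive_sample(
    pid, t, titer=4.0, nab=NabResult.NOT_TESTED, conc=0.0, vendor=2, label=None
):
    return SampleRecord(
        patient_id=pid,
        visit_label=label or ("baseline" if t <= 0 else "C2 predose"),
        time_days=t,
        screen_signal=3.0,
        confirm_inhibition=0.9,
        titer=titer,
        drug_conc_ug_ml=conc,
        nab_result=nab,
        vendor=vendor,
        is_pretreatment=t <= 0,
    )
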