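import pytest

from schizodoc.clinical import RawPatientRecord
from schizodoc.intervals import AttrValue, Domain


@pytest.fixture
def patient_2() -> RawPatientRecord:
    """The 28-year-old woman: genetic relation unknown, voided lucidity and
    differential, one second-order symptom present."""
    p = AttrValue.point
    return RawPatientRecord(
        record_id="patient_2", age=28, sex="female", relation=None,
        drugs=p(0), alcohol=p(1), somnolence=p(1), consciousness=p(2),
        neurological=p(0), infectious=p(1), toxic_metabolic=p(1),
        thinking_alterations=p(0), passivity=p(0), hallucinations=p(0), delusions=p(0),
        delusional_intuition=p(0), perplexity=p(1),
        emotional_impoverishment=p(0), dysthymias=p(0),
    )


@pytest.fixture
def male_22() -> RawPatientRecord:
    """The 22-year-old man: fully lucid, toxic/metabolic status undetectable,
    first-order score 5, weak emotional impoverishment."""
    p = AttrValue.point
    return RawPatientRecord(
        record_id="male_22", age=22, sex="male", relation="general_population",
        drugs=p(1), alcohol=p(1), somnolence=p(1), consciousness=p(2),
        neurological=p(1), infectious=p(1), toxic_metabolic=AttrValue.unknown(),
        thinking_alterations=p(3), passivity=p(0), hallucinations=p(0), delusions=p(2),
        delusional_intuition=p(0), perplexity=p(0),
        emotional_impoverishment=AttrValue.interval(0.25, 0.75), dysthymias=p(0),
    )


@pytest.fixture
def toy_a1():
    """Three-argument toy predicate: unknown on [5,10], [10,20] on [5,30], 15 on [10,20]."""
    return [
        (AttrValue.unknown(), Domain(5, 10)),
        (AttrValue.interval(10, 20), Domain(5, 30)),
        (AttrValue.point(15), Domain(10, 20)),
    ]


@pytest.fixture
def toy_a2():
    """[45,54] on [30,60], [10,12] on [6,14], unknown on [2000,6000]."""
    return [
        (AttrValue.interval(45, 54), Domain(30, 60)),
        (AttrValue.interval(10, 12), Domain(6, 14)),
        (AttrValue.unknown(), Domain(2000, 6000)),
    ]
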