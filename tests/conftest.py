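import pytest
from hypothesis import HealthCheck, settings

from cvdscreen.encounter import Demographics, MedicalHistory, RiskFactorProfile
from cvdscreen.fixtures import fixture_charts

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def charts():
    """(LI, HI) synthetic fixture charts, built in memory."""
    return fixture_charts()


@pytest.fixture(scope="session")
def fig_profile():
    """The worked on-screen example: young male smoker with diabetes,
    BP 160/89 mmHg, total cholesterol 176 mg/dL."""
    return RiskFactorProfile(
        demographics=Demographics(patient_id="fig", age=33, gender="male"),
        history=MedicalHistory(past_diabetes=True),
        sbp=160.0,
        dbp=89.0,
        tc=176.0,
        smoker=True,
    )


def make_profile(**kw):
    """Convenience profile builder with sensible defaults."""
    demo = Demographics(
        patient_id=kw.pop("patient_id", "p1"),
        age=kw.pop("age", 55),
        gender=kw.pop("gender", "male"),
    )
    hist = MedicalHistory(
        past_mi_angina=kw.pop("past_mi_angina", None),
        past_stroke=kw.pop("past_stroke", None),
        past_pvd=kw.pop("past_pvd", None),
        past_diabetes=kw.pop("past_diabetes", None),
        hypertension_history=kw.pop("hypertension_history", None),
    )
    defaults = dict(sbp=120.0, dbp=80.0)
    defaults.update(kw)
    return RiskFactorProfile(demographics=demo, history=hist, **defaults)


@pytest.fixture
def profile_factory():
    return make_profile
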