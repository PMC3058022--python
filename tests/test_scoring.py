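"""Scoring-engine tests: oracle equivalence, bounds, monotonicity, derivatives."""

import pytest
from hypothesis import given, settings, strategies as st

from icubench.cohort import reduce_daily_worst
from icubench.scoring import (
    SYSTEMS,
    derive_summary,
    saps2_probability,
    score_panel,
    score_sofa,
    summarize_scores,
    score_cohort,
)

from conftest import make_panel, make_stay
from oracle_panels import ALL_CASES

MAX_TOTAL = {"SOFA": 24, "APACHE2": 71, "SAPS2": 163, "CASUS": 40}


@pytest.mark.parametrize(
    "system,label,panel_kwargs,stay_kwargs,expected",
    ALL_CASES,
    ids=[f"{c[0]}-{c[1]}" for c in ALL_CASES],
)
def test_hand_scored_oracle(system, label, panel_kwargs, stay_kwargs, expected):
    """Engine totals reproduce manual application of the point tables exactly."""
    sp = score_panel(make_panel(**panel_kwargs), make_stay(**stay_kwargs), system)
    assert sp.total == expected
    assert sp.total == sum(sp.components.values())


def test_sofa_components_and_range():
    sp = score_sofa(make_panel(pao2=40, fio2=1.0, platelets=10, bilirubin=15,
                               map=40, catecholamine_dose_class=3, gcs=3,
                               creatinine=6.0, urine_output=100,
                               flags={"mech_ventilation": True}))
    assert set(sp.components) == {
        "respiration", "coagulation", "liver", "cardiovascular", "cns", "renal"
    }
    assert all(v == 4 for v in sp.components.values())


def test_apache2_gcs_rule():
    """Dropping GCS from 15 to 10 adds exactly 5 acute-physiology points."""
    stay = make_stay(age=40)
    base = score_panel(make_panel(), stay, "APACHE2")
    low = score_panel(make_panel(gcs=10), stay, "APACHE2")
    assert low.components["acute_physiology"] - base.components["acute_physiology"] == 5
    assert low.total - base.total == 5


def test_saps2_oxygenation_requires_ventilation():
    """Identical panels with/without ventilation differ only in the oxygenation item."""
    stay = make_stay(age=35)
    off = score_panel(make_panel(pao2=95, fio2=0.5), stay, "SAPS2")
    on = score_panel(
        make_panel(pao2=95, fio2=0.5, flags={"mech_ventilation": True}), stay, "SAPS2"
    )
    diff = {
        k: on.components[k] - off.components[k]
        for k in on.components
        if on.components[k] != off.components[k]
    }
    assert diff == {"oxygenation": 9}


def test_casus_assist_device_isolation():
    base = score_panel(make_panel(), make_stay(), "CASUS")
    iabp = score_panel(make_panel(flags={"iabp": True}), make_stay(), "CASUS")
    assert iabp.total - base.total == 3
    assert iabp.components["mechanical_assist"] == 3


def test_saps2_probability_transform_monotone_and_bounded():
    probs = [saps2_probability(s) for s in (0, 20, 40, 80, 120, 163)]
    assert all(0 < p < 1 for p in probs)
    assert probs == sorted(probs)
    # published transform at 0 points: logit = -7.7631 -> p ~ 4.2e-4
    assert probs[0] == pytest.approx(0.000424, abs=1e-4)


def test_bidirectional_worst_matches_brute_force():
    """Engine output equals the max over scoring every raw reading of the day."""
    readings = [128.0, 139.0, 152.0]
    obs = [("sodium", v) for v in readings] + [("gcs", 15)]
    panel = reduce_daily_worst(obs, stay_id="S1", day=1)
    stay = make_stay(age=35)
    for system in ("SAPS2", "APACHE2"):
        combined = score_panel(panel, stay, system).total
        singles = [
            score_panel(
                reduce_daily_worst([("sodium", v), ("gcs", 15)], stay_id="S1", day=1),
                stay,
                system,
            ).total
            for v in readings
        ]
        assert combined == max(singles)


severity = st.floats(min_value=0.0, max_value=14.0, allow_nan=False)


@st.composite
def random_panels(draw):
    """Physiologically plausible random panels spanning all band strata."""
    def pair(lo, hi):
        a = draw(st.floats(min_value=lo, max_value=hi, allow_nan=False))
        b = draw(st.floats(min_value=lo, max_value=hi, allow_nan=False))
        return (min(a, b), max(a, b))

    return make_panel(
        map=pair(30, 130), sbp=pair(50, 220), heart_rate=pair(30, 220),
        cvp=pair(0, 35), lactate=pair(0.3, 25), pao2=pair(30, 500),
        fio2=pair(0.21, 1.0), paco2=pair(20, 90), respiratory_rate=pair(5, 55),
        ph=pair(6.9, 7.75), creatinine=pair(0.3, 12), urea=pair(5, 200),
        bilirubin=pair(0.1, 30), platelets=pair(5, 600), leukocytes=pair(0.3, 60),
        hematocrit=pair(12, 65), sodium=pair(110, 185), potassium=pair(1.8, 9),
        bicarbonate=pair(5, 45), temperature=pair(28, 42.5),
        urine_output=draw(st.floats(min_value=0, max_value=6000)),
        gcs=draw(st.integers(min_value=3, max_value=15)),
        neurologic_state=draw(st.integers(min_value=0, max_value=4)),
        catecholamine_dose_class=draw(st.integers(min_value=0, max_value=3)),
        flags={f: draw(st.booleans()) for f in
               ("mech_ventilation", "iabp", "vad", "dialysis")},
    )


@settings(max_examples=150, deadline=None, derandomize=True)
@given(panel=random_panels(), age=st.integers(min_value=18, max_value=99))
def test_totals_additive_and_within_published_bounds(panel, age):
    stay = make_stay(age=age, admission_category="medical",
                     chronic_health_flags=("copd",))
    for system in SYSTEMS:
        sp = score_panel(panel, stay, system)
        assert sp.total == sum(sp.components.values())
        assert 0 <= sp.total <= MAX_TOTAL[system]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(panel=random_panels(), worse=st.floats(min_value=0.0, max_value=10.0))
def test_worsening_creatinine_never_lowers_totals(panel, worse):
    """Monotonicity: raising the worst creatinine never decreases any total."""
    lo, hi = panel.extremes["creatinine"]
    worse_panel = make_panel(
        creatinine=(lo, min(hi + worse, 15.0)),
        urine_output=panel.urine_output, gcs=panel.gcs,
        neurologic_state=panel.neurologic_state,
        catecholamine_dose_class=panel.catecholamine_dose_class,
        flags=panel.flags,
        **{v: panel.extremes[v] for v in panel.extremes if v != "creatinine"},
    )
    stay = make_stay(age=50)
    for system in SYSTEMS:
        assert (
            score_panel(worse_panel, stay, system).total
            >= score_panel(panel, stay, system).total
        )


@pytest.mark.parametrize(
    "totals,mean,mx",
    [([4, 6, 2], 4.0, 6), ([5], 5.0, 5), ([0, 0, 0, 0], 0.0, 0)],
)
def test_derive_summary_definitions(totals, mean, mx):
    s = derive_summary(totals, stay_id="S1", system="SOFA")
    assert s.mean_score == pytest.approx(mean)
    assert s.max_score == mx
    assert s.iculos == len(totals)
    assert min(totals) <= s.mean_score <= s.max_score


def test_derive_summary_empty_errors():
    with pytest.raises(ValueError):
        derive_summary([])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=40), min_size=1, max_size=30))
def test_mean_never_exceeds_max(totals):
    s = derive_summary(totals)
    assert s.mean_score <= s.max_score
    if len(set(totals)) == 1:
        assert s.mean_score == s.max_score
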