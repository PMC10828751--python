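"""Unit and property tests for the six component scorers and the estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from pewrisk import (
    ComponentScores,
    HashmiScorer,
    InvalidInputError,
    MissingDataError,
    PatientSnapshot,
    aggregate_quarters,
    classify,
    compute_score,
    score_albumin,
    score_bmi,
    score_comorbidity,
    score_ferritin,
    score_frame,
    score_functional,
    score_vintage,
)
from conftest import make_patient_row


@pytest.mark.parametrize(
    "value,expected",
    [(22.0, 0), (19.0, 1), (15.9, 3), (20.0, 0), (18.0, 1), (16.0, 2), (17.9, 2)],
)
def test_bmi_bands(value, expected):
    assert score_bmi(value) == expected


@pytest.mark.parametrize(
    "value,expected",
    [(36.0, 0), (30.0, 2), (27.9, 3), (35.0, 0), (32.0, 1), (28.0, 2), (31.5, 2)],
)
def test_albumin_bands(value, expected):
    """The printed >=35 / 32-35 overlap resolves to the less-severe band; the
    31/32 gap is closed by extending the 28-31 band up to (but not including) 32."""
    assert score_albumin(value) == expected


@pytest.mark.parametrize(
    "value,expected",
    [(500, 0), (750, 1), (1001, 3), (700.5, 1), (700, 0), (800, 1), (1000, 2)],
)
def test_ferritin_bands(value, expected):
    assert score_ferritin(value) == expected


@pytest.mark.parametrize(
    "value,expected",
    [(0.5, 0), (2.0, 1), (5.0, 3), (4.0, 2), (3.0, 2), (1.0, 1), (0.0, 0)],
)
def test_vintage_bands(value, expected):
    """The 3-4 year band is closed at both ends: exactly 3 and exactly 4 score 2."""
    assert score_vintage(value) == expected


@pytest.mark.parametrize(
    "level,expected",
    [
        ("normal", 0),
        ("occasional_difficulty", 1),
        ("dependent_difficulty", 2),
        ("bed_chair_bound", 3),
    ],
)
def test_functional_levels(level, expected):
    assert score_functional(level) == expected


@pytest.mark.parametrize(
    "count,expected", [(0, 0), (1, 0), (2, 1), (3, 2), (4, 3), (5, 3)]
)
def test_comorbidity_counts(count, expected):
    """Zero comorbidities sits below the least-severe band and scores 0."""
    assert score_comorbidity(count) == expected


@pytest.mark.parametrize(
    "fn,bad",
    [
        (score_bmi, -1.0),
        (score_bmi, 0.0),
        (score_bmi, float("nan")),
        (score_albumin, 0.0),
        (score_ferritin, -5.0),
        (score_vintage, -0.1),
        (score_comorbidity, -1),
    ],
)
def test_invalid_numeric_inputs_raise(fn, bad):
    with pytest.raises(InvalidInputError):
        fn(bad)


def test_unknown_functional_level_raises():
    with pytest.raises(InvalidInputError):
        score_functional("walking")


def _snapshot(**kw):
    base = dict(
        patient_id="P1",
        sex="male",
        age=60.0,
        bmi=22.0,
        functional_capacity="normal",
        vintage=0.5,
        albumin=40.0,
        ferritin=200.0,
        comorbidities=frozenset({"DM"}),
    )
    base.update(kw)
    return PatientSnapshot(**base)


def test_compute_score_best_and_worst():
    assert compute_score(_snapshot()).total == 0
    worst = _snapshot(
        bmi=15.0,
        functional_capacity="bed_chair_bound",
        vintage=6.0,
        albumin=25.0,
        ferritin=1200.0,
        comorbidities=frozenset({"DM", "HTN", "IHD", "CVD"}),
    )
    # four listed conditions cap the set; a fifth would be out of dictionary
    assert compute_score(worst).total == 15 + score_comorbidity(4)


def test_compute_score_mixed_equals_component_sum():
    snap = _snapshot(
        bmi=21.0,
        functional_capacity="dependent_difficulty",
        vintage=5.0,
        albumin=33.0,
        ferritin=650.0,
        comorbidities=frozenset({"DM", "HTN", "IHD"}),
    )
    scores = compute_score(snap)
    assert scores.as_tuple() == (0, 2, 3, 1, 0, 2)
    assert scores.total == 8


def test_compute_score_missing_field_names_it():
    with pytest.raises(MissingDataError, match="albumin"):
        compute_score(_snapshot(albumin=float("nan")))


def test_snapshot_rejects_unknown_comorbidity():
    with pytest.raises(InvalidInputError):
        _snapshot(comorbidities=frozenset({"COPD"}))


def test_classify_step_function_exhaustive():
    for total in range(19):
        res = classify(total)
        assert res.category == ("high" if total >= 6 else "low")
    assert classify(5).category == "low"
    assert classify(6).category == "high"
    assert classify(13).category == "high"


@pytest.mark.parametrize("bad_total", [-1, 19])
def test_classify_rejects_out_of_range(bad_total):
    with pytest.raises(InvalidInputError):
        classify(bad_total)


def test_classify_custom_threshold():
    assert classify(3, threshold=3).category == "high"
    assert classify(2, threshold=3).category == "low"


def test_aggregate_quarters_policies():
    s4 = ComponentScores(1, 1, 1, 1, 0, 0)
    s7 = ComponentScores(2, 2, 1, 1, 1, 0)
    assert aggregate_quarters([s4]).total == 4
    assert aggregate_quarters([s4, s7], policy="maximum").total == 7
    assert aggregate_quarters([s4, s7], policy="baseline").total == 4
    assert aggregate_quarters([s7, s4], policy="latest").total == 4
    # maximum is per component, so it can exceed both quarterly totals
    a = ComponentScores(3, 0, 0, 0, 0, 0)
    b = ComponentScores(0, 3, 0, 0, 0, 0)
    assert aggregate_quarters([a, b], policy="maximum").total == 6
    assert aggregate_quarters([a, b], policy="mean_rounded").as_tuple() == (2, 2, 0, 0, 0, 0)


def test_aggregate_quarters_empty_raises():
    with pytest.raises(InvalidInputError):
        aggregate_quarters([])


# --- property tests -------------------------------------------------------

snapshot_strategy = st.builds(
    _snapshot,
    bmi=st.floats(min_value=8.0, max_value=60.0),
    functional_capacity=st.sampled_from(
        ["normal", "occasional_difficulty", "dependent_difficulty", "bed_chair_bound"]
    ),
    vintage=st.floats(min_value=0.0, max_value=40.0),
    albumin=st.floats(min_value=10.0, max_value=60.0),
    ferritin=st.floats(min_value=0.0, max_value=5000.0),
    comorbidities=st.sets(st.sampled_from(["DM", "HTN", "IHD", "CVD"])).map(frozenset),
)


@given(snapshot_strategy)
def test_components_in_range_and_total_is_sum(snap):
    scores = compute_score(snap)
    assert all(0 <= c <= 3 for c in scores.as_tuple())
    assert 0 <= scores.total <= 18
    assert scores.total == sum(scores.as_tuple())


@given(snapshot_strategy, st.floats(min_value=0.1, max_value=10.0))
def test_monotone_in_severity(snap, delta):
    """Worsening any single input never decreases the total score."""
    base = compute_score(snap).total
    levels = ["normal", "occasional_difficulty", "dependent_difficulty", "bed_chair_bound"]
    worse = [
        _snapshot(**{**_fields(snap), "bmi": max(snap.bmi - delta, 1e-3)}),
        _snapshot(**{**_fields(snap), "albumin": max(snap.albumin - delta, 1e-3)}),
        _snapshot(**{**_fields(snap), "ferritin": snap.ferritin + 100 * delta}),
        _snapshot(**{**_fields(snap), "vintage": snap.vintage + delta}),
        _snapshot(**{**_fields(snap), "functional_capacity": levels[
            min(levels.index(snap.functional_capacity) + 1, 3)
        ]}),
        _snapshot(**{**_fields(snap), "comorbidities": frozenset({"DM", "HTN", "IHD", "CVD"})})
        if len(snap.comorbidities) < 4 else None,
    ]
    for w in worse:
        if w is not None:
            assert compute_score(w).total >= base


def _fields(snap):
    return dict(
        patient_id=snap.patient_id,
        sex=snap.sex,
        age=snap.age,
        bmi=snap.bmi,
        functional_capacity=snap.functional_capacity,
        vintage=snap.vintage,
        albumin=snap.albumin,
        ferritin=snap.ferritin,
        comorbidities=snap.comorbidities,
    )


@given(st.floats(min_value=1e-6, max_value=1e4, allow_nan=False))
def test_band_partition_continuous(x):
    """Every finite positive input maps to exactly one score in 0..3."""
    for fn in (score_bmi, score_albumin, score_ferritin, score_vintage):
        s = fn(x)
        assert s in (0, 1, 2, 3)


@pytest.mark.parametrize(
    "fn,edges",
    [
        (score_bmi, (16.0, 18.0, 20.0)),
        (score_albumin, (28.0, 32.0, 35.0)),
        (score_ferritin, (700.0, 800.0, 1000.0)),
        (score_vintage, (1.0, 3.0, 4.0)),
    ],
)
def test_band_edges_single_valued(fn, edges):
    for e in edges:
        for x in (e - 1e-9, e, e + 1e-9):
            assert fn(x) in (0, 1, 2, 3)


# --- DataFrame layer and estimator ----------------------------------------

def test_score_frame_matches_scalar_scorers(synthetic_cohort):
    df = synthetic_cohort.data
    scores = score_frame(df)
    idx = 17
    row = df.iloc[idx]
    assert scores.loc[idx, "bmi_score"] == score_bmi(row["bmi"])
    assert scores.loc[idx, "albumin_score"] == score_albumin(row["albumin_gL"])
    assert (scores["total"] == scores[
        ["bmi_score", "functional_score", "vintage_score",
         "albumin_score", "ferritin_score", "comorbidity_score"]
    ].sum(axis=1)).all()


def test_score_frame_missing_column_raises(synthetic_cohort):
    with pytest.raises(MissingDataError, match="albumin_gL"):
        score_frame(synthetic_cohort.data.drop(columns=["albumin_gL"]))


def test_score_frame_nan_raises(synthetic_cohort):
    df = synthetic_cohort.data.copy()
    df.loc[3, "bmi"] = np.nan
    with pytest.raises(MissingDataError):
        score_frame(df)


def test_estimator_fit_transform_predict(synthetic_cohort):
    df = synthetic_cohort.data
    scorer = HashmiScorer().fit(df)
    scores = scorer.transform(df)
    assert scorer.threshold_ == 6
    assert len(scores) == len(df)
    pred = scorer.predict(df)
    assert set(pred) <= {"low", "high"}
    assert ((scores["total"] >= 6) == (pred == "high")).all()


def test_estimator_is_sklearn_compatible(synthetic_cohort):
    scorer = HashmiScorer(threshold=8)
    assert clone(scorer).get_params()["threshold"] == 8
    scorer.set_params(threshold=4).fit(synthetic_cohort.data)
    assert scorer.threshold_ == 4


def test_estimator_quarterly_aggregation():
    # one patient, two quarters; maximum policy takes the component-wise worst
    rows = [
        make_patient_row(patient_id="P1", quarter=0),
        make_patient_row(patient_id="P1", quarter=1, albumin_gL=25.0, ferritin_ugL=1200.0),
        make_patient_row(patient_id="P2", quarter=0, bmi=15.0),
        make_patient_row(patient_id="P2", quarter=1),
    ]
    df = pd.DataFrame(rows)
    out = HashmiScorer(aggregation="maximum").fit(df).transform(df)
    assert len(out) == 2
    assert out.set_index("patient_id").loc["P1", "total"] == 6  # albumin 3 + ferritin 3
    assert out.set_index("patient_id").loc["P2", "total"] == 3
    base = HashmiScorer(aggregation="baseline").fit(df).transform(df)
    assert base.set_index("patient_id").loc["P1", "total"] == 0


def test_estimator_unfitted_raises(synthetic_cohort):
    with pytest.raises(RuntimeError):
        HashmiScorer().transform(synthetic_cohort.data)
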