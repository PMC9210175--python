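"""Disability-severity and affect-severity classification rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inclusion_monitor.wg_classifiers import (
    FUNCTIONING_DOMAINS,
    AffectClassification,
    AffectFrequency,
    AffectIntensity,
    AffectLevel,
    AffectSeverity,
    ClassificationUndefinedError,
    DisabilitySeverity,
    FunctioningLevel,
    SeverityCutoffs,
    affect_level,
    affect_partition,
    affect_severity_frame,
    classify_affect_severity,
    classify_disability_severity,
    default_affect_grid,
    disability_severity_frame,
    severity_partition,
)
from oracles import oracle_disability

NO, SOME, ALOT, CANNOT = (
    FunctioningLevel.NO_DIFFICULTY,
    FunctioningLevel.SOME_DIFFICULTY,
    FunctioningLevel.A_LOT_OF_DIFFICULTY,
    FunctioningLevel.CANNOT_DO_AT_ALL,
)


@pytest.mark.parametrize(
    "levels, expected",
    [
        ([NO] * 6, DisabilitySeverity.NONE),
        ([SOME] + [NO] * 5, DisabilitySeverity.NONE),
        ([SOME] * 3 + [NO] * 3, DisabilitySeverity.MILD),
        ([SOME] * 2 + [NO] * 4, DisabilitySeverity.MILD),
        ([SOME] * 4 + [NO] * 2, DisabilitySeverity.MILD),
        ([SOME] * 5 + [NO], DisabilitySeverity.MODERATE),
        ([SOME] * 6, DisabilitySeverity.MODERATE),
        ([ALOT] + [NO] * 5, DisabilitySeverity.MODERATE),
        ([CANNOT] + [NO] * 5, DisabilitySeverity.MODERATE),
        ([ALOT] + [SOME] * 5, DisabilitySeverity.MODERATE),
    ],
)
def test_disability_severity_rule(levels, expected):
    assert classify_disability_severity(levels) == expected
    # string codes and mapping input are equivalent
    as_map = dict(zip(FUNCTIONING_DOMAINS, levels))
    assert classify_disability_severity(as_map) == expected


def test_disability_totality_and_partition_counts():
    """Every one of the 4^6 patterns gets exactly one severity, matching the
    independent oracle; the partition sizes sum to 4096."""
    counts = {s: 0 for s in DisabilitySeverity}
    for pattern in itertools.product(range(4), repeat=6):
        sev = classify_disability_severity(pattern)
        assert int(sev) == oracle_disability(pattern)
        counts[sev] += 1
    assert sum(counts.values()) == 4 ** 6
    # combinatorial cross-check: none = C(6,0)+C(6,1), mild = C(6,2..4)
    assert counts[DisabilitySeverity.NONE] == 7
    assert counts[DisabilitySeverity.MILD] == 50
    assert counts[DisabilitySeverity.MODERATE] == 4096 - 57


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    levels=st.lists(st.integers(0, 3), min_size=6, max_size=6),
    pos=st.integers(0, 5),
)
def test_disability_monotone_in_each_response(levels, pos):
    """Raising one response a step never lowers the severity."""
    if levels[pos] == 3:
        return
    raised = list(levels)
    raised[pos] += 1
    assert classify_disability_severity(raised) >= classify_disability_severity(levels)


def test_wg_recommended_variant_differs_only_on_many_some():
    wg = SeverityCutoffs(many_some_is_moderate=False)
    assert classify_disability_severity([SOME] * 5 + [NO], wg) == DisabilitySeverity.MILD
    assert classify_disability_severity([SOME] * 6, wg) == DisabilitySeverity.MILD
    for pattern in itertools.product(range(4), repeat=6):
        some = sum(1 for v in pattern if v == 1)
        default = classify_disability_severity(pattern)
        variant = classify_disability_severity(pattern, wg)
        if some >= 5 and max(pattern) < 2:
            assert (default, variant) == (DisabilitySeverity.MODERATE, DisabilitySeverity.MILD)
        else:
            assert default == variant


def test_missing_functioning_response_raises_with_domains():
    levels = {d: NO for d in FUNCTIONING_DOMAINS}
    levels["walking"] = None
    with pytest.raises(ClassificationUndefinedError) as err:
        classify_disability_severity(levels)
    assert "walking" in err.value.missing


# ---------------------------------------------------------------------------
# Affect composite


def test_affect_trivial_extremes():
    never = ("never", None)
    assert classify_affect_severity(never, never).severity == AffectSeverity.NONE
    worst = classify_affect_severity(never, ("daily", "a_lot"))
    assert worst.severity == AffectSeverity.MODERATE
    assert worst.internal_level == AffectLevel.SEVERE


def test_affect_default_grid_lookup():
    # weekly + a_little -> mild, monthly + a_little -> none: collapses to none
    res = classify_affect_severity(("weekly", "a_little"), ("monthly", "a_little"))
    assert res.severity == AffectSeverity.NONE
    assert res.internal_level == AffectLevel.MILD


def test_affect_collapse_consistent_on_every_cell():
    """value = moderate iff the internal composite is moderate or severe."""
    grid = default_affect_grid()
    cells = [(AffectFrequency.NEVER, None)] + [
        (f, i) for f in AffectFrequency if f != AffectFrequency.NEVER for i in AffectIntensity
    ]
    for anx, dep in itertools.product(cells, repeat=2):
        res = classify_affect_severity(anx, dep, grid=grid)
        assert (res.severity == AffectSeverity.MODERATE) == (
            res.internal_level >= AffectLevel.MODERATE
        )


def test_affect_monotone_in_frequency_and_intensity():
    grid = default_affect_grid()
    for f in AffectFrequency:
        if f == AffectFrequency.NEVER:
            continue
        for i in AffectIntensity:
            here = affect_level(f, i, grid)
            if f < AffectFrequency.DAILY:
                up_f = AffectFrequency(int(f) + 1)
                assert affect_level(up_f, i, grid) >= here
            if i < AffectIntensity.A_LOT:
                up_i = AffectIntensity(int(i) + 1)
                assert affect_level(f, up_i, grid) >= here


def test_affect_missing_fields_raise():
    with pytest.raises(ClassificationUndefinedError):
        classify_affect_severity((None, None), ("never", None))
    with pytest.raises(ClassificationUndefinedError):
        classify_affect_severity(("weekly", None), ("never", None))


def test_inconsistent_affect_classification_rejected():
    with pytest.raises(ValueError):
        AffectClassification(AffectSeverity.NONE, AffectLevel.SEVERE)


# ---------------------------------------------------------------------------
# Vectorised frame helpers agree with the scalar rules


def test_frame_helpers_match_scalar_paths(small_population):
    _, records = small_population
    sub = records.head(300)
    dis = disability_severity_frame(sub)
    aff = affect_severity_frame(sub)
    for idx, row in sub.iterrows():
        levels = [row[f"wg_{d}"] for d in FUNCTIONING_DOMAINS]
        assert int(dis[idx]) == int(classify_disability_severity(levels))
        anx = (row["anxiety_frequency"], row["anxiety_intensity"] or None)
        dep = (row["depression_frequency"], row["depression_intensity"] or None)
        assert int(aff[idx]) == int(classify_affect_severity(anx, dep).severity)


def test_frame_helper_flags_missing_as_na():
    frame = pd.DataFrame(
        {f"wg_{d}": ["no_difficulty", "some_difficulty"] for d in FUNCTIONING_DOMAINS}
    )
    frame.loc[1, "wg_seeing"] = np.nan
    out = disability_severity_frame(frame)
    assert int(out[0]) == int(DisabilitySeverity.NONE)
    assert pd.isna(out[1])


def test_partitions_cover_and_respect_class():
    part = severity_partition()
    assert sum(len(v) for v in part.values()) == 4 ** 6
    for label, patterns in part.items():
        for pattern in patterns[:: max(1, len(patterns) // 50)]:
            assert classify_disability_severity(pattern).label == label
    aff = affect_partition()
    assert sum(len(v) for v in aff.values()) == 13 ** 2
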