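"""Pipeline orchestration, gaps, severity patterns and prioritisation."""

import math

import numpy as np
import pandas as pd
import pytest

from inclusion_monitor.reporting import (
    AnalysisConfig,
    classify_severity_pattern,
    compute_gaps,
    prioritise_domains,
    run_pipeline,
)
from inclusion_monitor.indicator_engine import DOMAINS
from inclusion_monitor.synthetic_data import default_scenario, generate_population


@pytest.fixture(scope="module")
def bundle(small_population):
    scenario, records = small_population
    return run_pipeline(records, margins=scenario.implied_margins(), seed=424242)


def test_bundle_shapes_match_reporting_structure(bundle):
    """9 domains x 6 disability groups, 32 indicators x 6 groups, 9 domains x
    4 affect groups, three percentage rows per block member."""
    dom = bundle.domain_table
    assert dom["unit_id"].nunique() == 9
    assert dom["group"].nunique() == 6
    assert len(dom) == 9 * 6 * 3
    ind = bundle.indicator_table
    assert ind["unit_id"].nunique() == 32
    assert len(ind) == 32 * 6 * 3
    aff = bundle.affect_table
    assert aff["unit_id"].nunique() == 9
    assert aff["group"].nunique() == 4
    assert len(aff) == 9 * 4 * 3


def test_every_percentage_row_sums_to_100(bundle):
    for table in (bundle.domain_table, bundle.indicator_table, bundle.affect_table):
        sums = table.groupby(["unit_id", "group"])["weighted_pct"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)


def test_adjusted_p_valid_or_not_available(bundle):
    for table in (bundle.domain_table, bundle.indicator_table, bundle.affect_table):
        ps = table["adjusted_p"]
        ok = ps.isna() | ((ps >= 0) & (ps <= 1))
        assert ok.all()


def test_metadata_records_run_details(bundle):
    meta = bundle.metadata
    assert meta["n_records"] == 2000
    assert meta["raking"]["converged"]
    assert meta["families"] == {"domains_m": 9, "indicators_m": 32, "affect_m": 9}
    assert isinstance(meta["config_hash"], str) and len(meta["config_hash"]) == 16


def test_rankings_are_permutations_of_the_nine_domains(bundle):
    for approach, grp in bundle.rankings.groupby("approach"):
        assert sorted(grp["domain_id"]) == sorted(DOMAINS)
        assert list(grp["rank"]) == list(range(1, 10))


def test_pipeline_outputs_are_deterministic(tmp_path, small_population):
    scenario, records = small_population
    margins = scenario.implied_margins()
    for sub in ("a", "b"):
        run_pipeline(records, margins=margins, seed=1).write(tmp_path / sub)
    for name in (
        "domains_by_disability.csv",
        "indicators_by_disability.csv",
        "domains_by_affect.csv",
        "gender_gaps.csv",
        "severity_patterns.csv",
        "priority_rankings.csv",
        "run_metadata.json",
    ):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


# ---------------------------------------------------------------------------
# Gap summaries


def _gap_table(male, female, unit="personal_safety", category="included"):
    rows = []
    for group, val in (("none_male", male), ("none_female", female)):
        rows.append(
            {"unit_id": unit, "group": group, "category": category,
             "weighted_pct": val, "raw_p": 0.01, "adjusted_p": 0.09}
        )
    return pd.DataFrame(rows)


def test_female_inclusion_gap_example():
    """Inclusion 24.7% (men) vs 13.7% (women): an 11.0-point gap with women
    worse off."""
    gaps = compute_gaps(_gap_table(24.7, 13.7), metric="inclusion_pct")
    row = gaps.iloc[0]
    assert row["gap"] == pytest.approx(11.0)
    assert row["worse_off"] == "female"


def test_equal_values_have_no_worse_gender():
    gaps = compute_gaps(_gap_table(30.0, 30.0), metric="inclusion_pct")
    assert gaps.iloc[0]["gap"] == 0.0
    assert gaps.iloc[0]["worse_off"] == ""


def test_exclusion_gap_direction_flips():
    gaps = compute_gaps(_gap_table(20.0, 10.0, category="excluded"), metric="exclusion_pct")
    assert gaps.iloc[0]["worse_off"] == "male"


def test_single_gender_entry_skipped():
    table = _gap_table(24.7, 13.7).iloc[:1]
    gaps = compute_gaps(table, metric="inclusion_pct")
    assert gaps.empty


# ---------------------------------------------------------------------------
# Severity patterns


@pytest.mark.parametrize(
    "exclusions, p, expected",
    [
        ((5, 15, 30), 0.001, "monotone_worsening"),
        ((5, 22, 23), 0.001, "mild_equals_moderate_worse"),
        ((5, 15, 30), 1.0, "no_significant_difference"),
        ((5, 15, 30), float("nan"), "no_significant_difference"),
        ((5, 30, 15), 0.001, "mild_worst"),
        ((30, 5, 15), 0.001, "none_worst"),
    ],
)
def test_severity_pattern_labels(exclusions, p, expected):
    by_class = dict(zip(("none", "mild", "moderate"), exclusions))
    assert classify_severity_pattern(by_class, p, alpha=0.05, band=2.0) == expected


def test_pattern_requires_all_classes():
    with pytest.raises(ValueError):
        classify_severity_pattern({"none": 5, "mild": 10}, 0.01)


def test_bundle_patterns_have_one_label_per_indicator(bundle):
    assert len(bundle.patterns) == 32
    assert bundle.patterns["pattern"].isin(
        ["monotone_worsening", "mild_equals_moderate_worse", "no_significant_difference",
         "mild_worst", "none_worst"]
    ).all()


# ---------------------------------------------------------------------------
# Prioritisation


def _summary(incl, inb=None):
    domains = list(DOMAINS)
    incl = pd.Series(incl, index=domains[: len(incl)])
    df = pd.DataFrame({"included": incl})
    df["in_between"] = inb if inb is not None else (100 - incl) / 2
    df["excluded"] = 100 - df["included"] - df["in_between"]
    df.index.name = "unit_id"
    return df


def test_farthest_from_inclusion_on_calibrated_scenario():
    """On the default calibrated scenario the two lowest-inclusion domains
    for respondents with disabilities are personal safety and social
    relationships, so the farthest-from-inclusion approach ranks them first."""
    scenario = default_scenario(n_respondents=6000, seed=2024)
    records = generate_population(scenario)
    bundle = run_pipeline(records, margins=scenario.implied_margins())
    ranking = bundle.rankings
    far = ranking[ranking["approach"] == "farthest_from_inclusion"]
    assert set(far.head(2)["domain_id"]) == {"personal_safety", "social_relationships"}


def test_all_domains_identical_flags_ties():
    summary = _summary([40.0] * 9, inb=30.0)
    pr = prioritise_domains(summary, "farthest_from_inclusion")
    assert pr.ranking["tied"].all()
    # deterministic alphabetical order on ties
    assert list(pr.ranking["domain_id"]) == sorted(DOMAINS)


def test_largest_disability_gap_puts_constructed_gap_first():
    with_dis = _summary([50.0] * 9, inb=25.0)
    without = _summary([55.0] * 9, inb=25.0)
    with_dis.loc["education", "included"] = 30.0  # 30-point gap by construction
    without.loc["education", "included"] = 60.0
    pr = prioritise_domains(with_dis, "largest_disability_gap", comparison=without)
    assert pr.ranking.iloc[0]["domain_id"] == "education"
    assert pr.ranking.iloc[0]["score"] == pytest.approx(30.0)


def test_closest_to_inclusion_respects_ceiling():
    incl = [85.0, 75.0, 70.0, 60.0, 50.0, 40.0, 30.0, 20.0, 10.0]
    summary = _summary(incl, inb=5.0)
    pr = prioritise_domains(summary, "closest_to_inclusion", ceiling=80.0)
    first = pr.ranking.iloc[0]
    assert first["score"] == 75.0 and not first["above_ceiling"]
    # the >= ceiling domain is appended last and flagged
    last = pr.ranking.iloc[-1]
    assert last["score"] == 85.0 and last["above_ceiling"]


def test_unknown_approach_rejected():
    with pytest.raises(ValueError):
        prioritise_domains(_summary([50.0] * 9), "no_such_approach")
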