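"""Synthetic-microdata generator: determinism, round-trip fidelity, recovery."""

import numpy as np
import pandas as pd
import pytest

from inclusion_monitor.indicator_engine import ALL_INDICATORS, BINARY_INDICATORS, InclusionCategory
from inclusion_monitor.synthetic_data import (
    ScenarioError,
    SyntheticScenario,
    default_scenario,
    effect_scenario,
    generate_population,
    null_scenario,
)
from inclusion_monitor.wg_classifiers import (
    DISABILITY_LABELS,
    disability_severity_frame,
    affect_severity_frame,
)


def test_same_seed_gives_identical_populations():
    sc = default_scenario(n_respondents=500, seed=31)
    a = generate_population(sc)
    b = generate_population(sc)
    pd.testing.assert_frame_equal(a, b)
    c = generate_population(sc, seed=32)
    assert not a.equals(c)


def test_generated_records_respect_scenario_structure(small_population):
    scenario, records = small_population
    assert len(records) == scenario.n_respondents
    assert (records["age"] >= 16).all()
    assert set(records["stratum"]) <= {"urban", "rural"}
    assert records["selection_prob"].between(0, 1, inclusive="neither").all()
    # selection probability is the stratum's two-stage product
    urban = records[records["stratum"] == "urban"]
    assert np.allclose(urban["selection_prob"], scenario.urban_design.selection_prob)


def test_patterns_classify_back_to_assigned_class(small_population):
    """Round trip: generated functioning/affect patterns recover the drawn
    severity class with probability 1."""
    _, records = small_population
    dis = disability_severity_frame(records)
    aff = affect_severity_frame(records)
    dis_label = pd.Series(np.asarray(DISABILITY_LABELS, dtype=object)[dis.astype(int)],
                          index=records.index)
    assert (dis_label == records["true_disability_class"]).all()
    aff_label = pd.Series(np.asarray(["none", "moderate"], dtype=object)[aff.astype(int)],
                          index=records.index)
    assert (aff_label == records["true_affect_class"]).all()


def test_prevalence_recovery_at_ten_thousand():
    """Scenario with 80/10/10 disability prevalences: classifier-recovered
    prevalences land within 3 binomial standard errors (fixed seed)."""
    joint = np.array([[0.64, 0.16], [0.08, 0.02], [0.08, 0.02]])
    sc = default_scenario(n_respondents=10_000, seed=909, joint_severity=joint)
    records = generate_population(sc)
    dis = disability_severity_frame(records)
    n = len(records)
    for code, target in enumerate((0.80, 0.10, 0.10)):
        got = (dis == code).mean()
        se = np.sqrt(target * (1 - target) / n)
        assert abs(got - target) < 3 * se, (code, got, target)


def test_zero_refusal_means_no_in_between_on_binary_indicators(configs):
    sc = default_scenario(n_respondents=1500, seed=55, refusal_rate=0.0)
    records = generate_population(sc)
    from inclusion_monitor.indicator_engine import build_indicator_matrix

    matrix = build_indicator_matrix(records, configs)
    for ind in BINARY_INDICATORS:
        assert not (matrix[ind] == int(InclusionCategory.IN_BETWEEN)).any()


def test_null_scenario_equalises_and_is_idempotent():
    base = default_scenario(n_respondents=100)
    nul = null_scenario(base)
    for ind in ALL_INDICATORS:
        vals = {nul.indicator_probs[ind][cls] for cls in DISABILITY_LABELS}
        assert len(vals) == 1
    again = null_scenario(nul)
    assert again.indicator_probs == nul.indicator_probs
    # everything else unchanged
    assert again.n_respondents == base.n_respondents
    assert np.allclose(again.joint_severity, base.joint_severity)


def test_effect_scenario_shifts_only_target_domain():
    base = default_scenario(n_respondents=100)
    eff = effect_scenario(base, "education", shift=0.3)
    from inclusion_monitor.indicator_engine import DOMAINS

    for ind in ALL_INDICATORS:
        for cls in DISABILITY_LABELS:
            b = base.indicator_probs[ind][cls]
            e = eff.indicator_probs[ind][cls]
            if ind in DOMAINS["education"] and cls == "moderate":
                assert e[0] == pytest.approx(max(b[0] - 0.3, 0.0))
            else:
                assert e == b
    with pytest.raises(ScenarioError):
        effect_scenario(base, "not_a_domain")


def test_infeasible_scenarios_rejected():
    with pytest.raises(ScenarioError):
        default_scenario(joint_severity=np.array([[0.9, -0.1], [0.1, 0.05], [0.05, 0.0]]))
    with pytest.raises(ScenarioError):
        default_scenario(refusal_rate=1.5)
    sc = default_scenario(n_respondents=10)
    sc.indicator_probs["food_security"]["mild"] = (0.9, 0.3)  # sums past 1
    with pytest.raises(ScenarioError):
        generate_population(sc)


def test_self_weighting_design_reproduces_unweighted_proportions(configs):
    """With equal selection probabilities the weighted pipeline equals the
    unweighted one exactly."""
    from inclusion_monitor.indicator_engine import build_indicator_matrix
    from inclusion_monitor.survey_weights import base_weights, weighted_proportions
    from inclusion_monitor.synthetic_data import StratumDesign

    design = StratumDesign(50, 5, 100, 20)
    sc = default_scenario(
        n_respondents=800, seed=21, urban_design=design, rural_design=design
    )
    records = generate_population(sc)
    matrix = build_indicator_matrix(records, configs)
    cats = matrix["food_security"]
    groups = records["gender"]
    wv = base_weights(records["selection_prob"])
    weighted = weighted_proportions(cats, wv, groups)
    unweighted = weighted_proportions(cats, pd.Series(np.ones(len(records))), groups)
    pd.testing.assert_frame_equal(weighted, unweighted)


def test_demographic_margins_recovered(small_population):
    scenario, records = small_population
    implied = {m.dimension: m.targets for m in scenario.implied_margins()}
    n = len(records)
    for dim, targets in implied.items():
        shares = records[dim].value_counts(normalize=True)
        for level, target in targets.items():
            se = max(np.sqrt(target * (1 - target) / n), 1e-6)
            assert abs(shares.get(level, 0.0) - target) < 4 * se, (dim, level)
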