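"""Synthetic survey microdata with the structure the pipeline assumes.

The real microdata (a national multidimensional-deprivation survey of 8499
adults) are not publicly deposited, so every pipeline stage is exercised on
synthetic populations instead.  The generator emulates:

* a stratified two-stage design — nine provinces x urban/rural strata,
  enumeration areas, dwellings sampled with known probabilities;
* severity structure — a joint disability x affect severity table whose
  margins default to roughly 80/10/10% none/mild/moderate disability and
  80/20% none/moderate affect, with the strong female and older-age skew in
  the mild and moderate classes;
* functioning and affect response patterns drawn uniformly from each
  assigned class's valid pattern set, so generated responses classify back
  to the assigned class with probability 1;
* per-severity-class category probabilities for every indicator, mapped to
  raw response codes through the inverse of the indicator configuration,
  plus a small refusal rate.

Indicator responses are independent across indicators given the severity
class; real deprivations co-occur, so domain-level exclusion is rarer here
than dependence would make it.  Class-conditional probabilities are
calibrated so that the domain-level ordering matches the study's qualitative
shape (personal safety and social relationships worst, healthcare best).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .indicator_engine import (
    ALL_INDICATORS,
    DOMAINS,
    REFUSAL_CODE,
    InclusionCategory,
    IndicatorConfig,
    configs_by_id,
    default_indicator_configs,
)
from .survey_weights import MarginSpec
from .wg_classifiers import (
    AFFECT_LABELS,
    DISABILITY_LABELS,
    FUNCTIONING_CODE_NAMES,
    FUNCTIONING_COLUMN_PREFIX,
    FUNCTIONING_DOMAINS,
    AffectFrequency,
    AffectIntensity,
    DEFAULT_CUTOFFS,
    SeverityCutoffs,
    affect_partition,
    severity_partition,
)

__all__ = [
    "ScenarioError",
    "StratumDesign",
    "SyntheticScenario",
    "default_scenario",
    "null_scenario",
    "effect_scenario",
    "generate_population",
]

AGE_BINS: Tuple[str, ...] = ("16-24", "25-64", "65+")
AGE_BOUNDS: Mapping[str, Tuple[int, int]] = {"16-24": (16, 24), "25-64": (25, 64), "65+": (65, 90)}
GENDERS: Tuple[str, ...] = ("male", "female")
POPULATION_GROUPS: Tuple[str, ...] = ("black_african", "coloured", "indian_asian", "white")

FREQUENCY_NAMES = tuple(f.name.lower() for f in AffectFrequency)
INTENSITY_NAMES = tuple(i.name.lower() for i in AffectIntensity)


class ScenarioError(ValueError):
    """Raised for an internally inconsistent generative scenario."""


@dataclass(frozen=True)
class StratumDesign:
    """Two-stage sampling fractions for one stratum type."""

    ea_frame: int
    eas_sampled: int
    dwelling_frame: int
    dwellings_sampled: int

    @property
    def selection_prob(self) -> float:
        return (self.eas_sampled / self.ea_frame) * (
            self.dwellings_sampled / self.dwelling_frame
        )


# Joint severity table, disability (rows) x affect (columns), unweighted
# sample shares ~ 66.6/13.7, 6.8/2.7, 6.8/3.5 (normalised at validation).
_DEFAULT_JOINT = np.array(
    [
        [0.666, 0.137],
        [0.068, 0.027],
        [0.068, 0.035],
    ]
)

_DEFAULT_AGE = {
    "none": (0.290, 0.661, 0.049),
    "mild": (0.109, 0.562, 0.329),
    "moderate": (0.088, 0.584, 0.328),
}
_DEFAULT_GENDER = {
    "none": (0.497, 0.503),
    "mild": (0.347, 0.653),
    "moderate": (0.306, 0.694),
}
_DEFAULT_POPGROUP = {
    "none": (0.774, 0.089, 0.027, 0.110),
    "mild": (0.800, 0.101, 0.039, 0.060),
    "moderate": (0.803, 0.109, 0.032, 0.056),
}

# Per-indicator (included, in_between) probability by disability class;
# excluded takes the remainder.  Binary indicators have zero substantive
# in-between mass (in between then arises only from refusals).
_DEFAULT_INDICATOR_PROBS: Mapping[str, Mapping[str, Tuple[float, float]]] = {
    "unpaid_care_work_humiliation": {"none": (0.973, 0.0), "mild": (0.971, 0.0), "moderate": (0.965, 0.0)},
    "unpaid_care_work_value": {"none": (0.887, 0.0), "mild": (0.894, 0.0), "moderate": (0.881, 0.0)},
    "reciprocate_support": {"none": (0.400, 0.0), "mild": (0.330, 0.0), "moderate": (0.310, 0.0)},
    "community_event_inclusion": {"none": (0.510, 0.385), "mild": (0.565, 0.293), "moderate": (0.501, 0.294)},
    "food_security": {"none": (0.550, 0.400), "mild": (0.420, 0.500), "moderate": (0.380, 0.520)},
    "drinking_water": {"none": (0.840, 0.140), "mild": (0.740, 0.230), "moderate": (0.700, 0.270)},
    "domestic_water": {"none": (0.850, 0.148), "mild": (0.740, 0.255), "moderate": (0.710, 0.285)},
    "cooking_energy": {"none": (0.750, 0.220), "mild": (0.640, 0.310), "moderate": (0.570, 0.380)},
    "lighting_energy": {"none": (0.820, 0.160), "mild": (0.690, 0.280), "moderate": (0.630, 0.350)},
    "heating_energy": {"none": (0.650, 0.300), "mild": (0.550, 0.380), "moderate": (0.460, 0.460)},
    "home_toilet_facilities": {"none": (0.970, 0.0), "mild": (0.940, 0.0), "moderate": (0.950, 0.0)},
    "toilet_modifications": {"none": (0.980, 0.0), "mild": (0.900, 0.0), "moderate": (0.920, 0.0)},
    "clothing_footwear_ownership": {"none": (0.960, 0.0), "mild": (0.920, 0.0), "moderate": (0.900, 0.0)},
    "clothing_footwear_quality": {"none": (0.760, 0.200), "mild": (0.600, 0.340), "moderate": (0.550, 0.380)},
    "bedding_ownership": {"none": (0.950, 0.0), "mild": (0.900, 0.0), "moderate": (0.880, 0.0)},
    "eviction_concern": {"none": (0.960, 0.0), "mild": (0.950, 0.0), "moderate": (0.940, 0.0)},
    "labour_force_status": {"none": (0.658, 0.260), "mild": (0.717, 0.155), "moderate": (0.642, 0.128)},
    "public_transport": {"none": (0.448, 0.354), "mild": (0.289, 0.383), "moderate": (0.332, 0.373)},
    "support_availability": {"none": (0.910, 0.0), "mild": (0.807, 0.0), "moderate": (0.776, 0.0)},
    "grant_receipt": {"none": (0.974, 0.0), "mild": (0.412, 0.0), "moderate": (0.469, 0.0)},
    "identity_document": {"none": (0.895, 0.0), "mild": (0.941, 0.0), "moderate": (0.962, 0.0)},
    "birth_certificate": {"none": (0.662, 0.0), "mild": (0.482, 0.0), "moderate": (0.450, 0.0)},
    "local_decision_making": {"none": (0.242, 0.483), "mild": (0.385, 0.347), "moderate": (0.312, 0.418)},
    "voting_inclusion": {"none": (0.529, 0.222), "mild": (0.661, 0.136), "moderate": (0.629, 0.126)},
    "schooling": {"none": (0.521, 0.363), "mild": (0.320, 0.500), "moderate": (0.280, 0.450)},
    "basic_literacy": {"none": (0.737, 0.222), "mild": (0.520, 0.360), "moderate": (0.450, 0.370)},
    "basic_numeracy": {"none": (0.657, 0.252), "mild": (0.440, 0.420), "moderate": (0.380, 0.420)},
    "healthcare_access_quality": {"none": (0.922, 0.067), "mild": (0.857, 0.113), "moderate": (0.841, 0.143)},
    "fuel_collection_hazards": {"none": (0.974, 0.0), "mild": (0.968, 0.0), "moderate": (0.962, 0.0)},
    "water_collection_hazards": {"none": (0.977, 0.0), "mild": (0.981, 0.0), "moderate": (0.965, 0.0)},
    "safety_at_home": {"none": (0.213, 0.722), "mild": (0.154, 0.764), "moderate": (0.213, 0.672)},
    "safety_in_neighbourhood": {"none": (0.072, 0.723), "mild": (0.046, 0.700), "moderate": (0.071, 0.566)},
}


def _check_probs(vec: Sequence[float], what: str) -> np.ndarray:
    arr = np.asarray(vec, dtype=float)
    if (arr < 0).any():
        raise ScenarioError(f"{what}: negative probability")
    if abs(arr.sum() - 1.0) > 1e-6:
        raise ScenarioError(f"{what}: probabilities sum to {arr.sum():.8f}, expected 1")
    return arr


@dataclass
class SyntheticScenario:
    """Generative parameters for one synthetic survey population."""

    n_respondents: int = 8499
    seed: int = 2019
    joint_severity: np.ndarray = field(default_factory=lambda: _DEFAULT_JOINT.copy())
    age_by_disability: Dict[str, Tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_AGE)
    )
    gender_by_disability: Dict[str, Tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_GENDER)
    )
    popgroup_by_disability: Dict[str, Tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_POPGROUP)
    )
    indicator_probs: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_INDICATOR_PROBS.items()}
    )
    refusal_rate: float = 0.005
    provinces: int = 9
    urban_share: float = 0.65
    urban_design: StratumDesign = StratumDesign(60, 5, 120, 30)
    rural_design: StratumDesign = StratumDesign(40, 4, 80, 25)
    cutoffs: SeverityCutoffs = DEFAULT_CUTOFFS

    def validate(self) -> None:
        joint = np.asarray(self.joint_severity, dtype=float)
        if joint.shape != (len(DISABILITY_LABELS), len(AFFECT_LABELS)):
            raise ScenarioError("joint_severity must be 3 x 2 (disability x affect)")
        if (joint < 0).any():
            raise ScenarioError("joint_severity has a negative cell")
        if joint.sum() <= 0:
            raise ScenarioError("joint_severity sums to zero")
        for cls in DISABILITY_LABELS:
            _check_probs(self.age_by_disability[cls], f"age margins for {cls}")
            _check_probs(self.gender_by_disability[cls], f"gender margins for {cls}")
            _check_probs(self.popgroup_by_disability[cls], f"population-group margins for {cls}")
        if not 0.0 <= self.refusal_rate < 1.0:
            raise ScenarioError("refusal_rate must lie in [0, 1)")
        if not 0.0 < self.urban_share < 1.0:
            raise ScenarioError("urban_share must lie in (0, 1)")
        for ind in ALL_INDICATORS:
            if ind not in self.indicator_probs:
                raise ScenarioError(f"indicator_probs missing {ind!r}")
            for cls in DISABILITY_LABELS:
                inc, inb = self.indicator_probs[ind][cls]
                if inc < 0 or inb < 0 or inc + inb > 1 + 1e-9:
                    raise ScenarioError(f"{ind}/{cls}: invalid category probabilities")

    # -- derived quantities ------------------------------------------------

    @property
    def joint_normalised(self) -> np.ndarray:
        joint = np.asarray(self.joint_severity, dtype=float)
        return joint / joint.sum()

    @property
    def disability_margin(self) -> np.ndarray:
        return self.joint_normalised.sum(axis=1)

    @property
    def affect_margin(self) -> np.ndarray:
        return self.joint_normalised.sum(axis=0)

    def implied_margins(self) -> List[MarginSpec]:
        """Population margins implied by the class-conditional demographics.

        These stand in for external census margins when raking synthetic
        data; real analyses supply their own :class:`MarginSpec` values.
        """
        d = self.disability_margin

        def mix(table: Mapping[str, Tuple[float, ...]], levels: Tuple[str, ...]) -> Dict[str, float]:
            arr = sum(
                d[i] * np.asarray(table[cls], dtype=float)
                for i, cls in enumerate(DISABILITY_LABELS)
            )
            arr = arr / arr.sum()
            return dict(zip(levels, arr.tolist()))

        return [
            MarginSpec("age_group", mix(self.age_by_disability, AGE_BINS)),
            MarginSpec("gender", mix(self.gender_by_disability, GENDERS)),
            MarginSpec("population_group", mix(self.popgroup_by_disability, POPULATION_GROUPS)),
        ]

    def category_probabilities(self, indicator_id: str, cls: str) -> Tuple[float, float, float]:
        """(included, in_between, excluded) after the refusal overlay."""
        inc, inb = self.indicator_probs[indicator_id][cls]
        exc = 1.0 - inc - inb
        r = self.refusal_rate
        return (inc * (1 - r), inb * (1 - r) + r, exc * (1 - r))


def default_scenario(**overrides) -> SyntheticScenario:
    """The calibrated default scenario (validated)."""
    sc = SyntheticScenario(**overrides)
    sc.validate()
    return sc


def null_scenario(base: SyntheticScenario) -> SyntheticScenario:
    """Equalise every indicator's category probabilities across severity
    classes (all classes get the no-disability values); everything else is
    unchanged.  Idempotent."""
    probs = {
        ind: {cls: tuple(table["none"]) for cls in DISABILITY_LABELS}
        for ind, table in base.indicator_probs.items()
    }
    return dataclasses.replace(base, indicator_probs=probs)


def effect_scenario(
    base: SyntheticScenario,
    domain_id: str,
    shift: float = 0.30,
    target_class: str = "moderate",
) -> SyntheticScenario:
    """Inject a large single-domain group difference for power studies.

    Moves ``shift`` of inclusion probability to exclusion for every
    indicator of ``domain_id`` in ``target_class``.
    """
    if domain_id not in DOMAINS:
        raise ScenarioError(f"unknown domain {domain_id!r}")
    probs = {ind: dict(table) for ind, table in base.indicator_probs.items()}
    for ind in DOMAINS[domain_id]:
        inc, inb = probs[ind][target_class]
        moved = min(shift, inc)
        probs[ind][target_class] = (inc - moved, inb)
    return dataclasses.replace(base, indicator_probs=probs)


# ---------------------------------------------------------------------------
# Generation


def _draw_conditional(
    rng: np.random.Generator,
    cls_idx: np.ndarray,
    tables: Mapping[str, Sequence[float]],
    levels: Sequence[str],
) -> np.ndarray:
    """Draw a categorical level per respondent from class-conditional margins."""
    out = np.empty(len(cls_idx), dtype=object)
    for i, cls in enumerate(DISABILITY_LABELS):
        mask = cls_idx == i
        if not mask.any():
            continue
        p = _check_probs(tables[cls], f"margins for {cls}")
        draws = rng.choice(len(levels), size=int(mask.sum()), p=p)
        out[mask] = np.asarray(levels, dtype=object)[draws]
    return out


def generate_population(
    scenario: SyntheticScenario, seed: Optional[int] = None,
    configs: Optional[Sequence[IndicatorConfig]] = None,
) -> pd.DataFrame:
    """Generate one synthetic survey microdata frame.

    Deterministic given the seed (``seed`` overrides ``scenario.seed``).
    Columns: respondent and design fields, demographics, the true generative
    classes (``true_disability_class``, ``true_affect_class``), six
    string-coded functioning responses (``wg_*``), four affect responses and
    32 raw indicator responses (``ind_*``).
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = scenario.n_respondents
    cfg_map = configs_by_id(configs or default_indicator_configs())

    # --- design: province x urban/rural stratum, EA, selection probability
    province = rng.integers(1, scenario.provinces + 1, size=n)
    urban = rng.random(n) < scenario.urban_share
    stratum = np.where(urban, "urban", "rural")
    designs = {"urban": scenario.urban_design, "rural": scenario.rural_design}
    ea_index = np.empty(n, dtype=np.int64)
    selection_prob = np.empty(n, dtype=float)
    for name, design in designs.items():
        mask = stratum == name
        ea_index[mask] = rng.integers(1, design.eas_sampled + 1, size=int(mask.sum()))
        selection_prob[mask] = design.selection_prob
    ea_id = np.char.add(
        np.char.add(np.char.add("p", province.astype(str)), "_"),
        np.char.add(np.char.add(stratum.astype(str), "_ea"), ea_index.astype(str)),
    )

    # --- severity classes from the joint table
    joint = scenario.joint_normalised
    cell = rng.choice(joint.size, size=n, p=joint.ravel())
    dis_idx, aff_idx = np.divmod(cell, joint.shape[1])
    dis_labels = np.asarray(DISABILITY_LABELS, dtype=object)[dis_idx]
    aff_labels = np.asarray(AFFECT_LABELS, dtype=object)[aff_idx]

    # --- demographics conditional on disability class
    age_bin = _draw_conditional(rng, dis_idx, scenario.age_by_disability, AGE_BINS)
    gender = _draw_conditional(rng, dis_idx, scenario.gender_by_disability, GENDERS)
    popgroup = _draw_conditional(rng, dis_idx, scenario.popgroup_by_disability, POPULATION_GROUPS)
    age = np.empty(n, dtype=np.int64)
    for b in AGE_BINS:
        mask = age_bin == b
        lo, hi = AGE_BOUNDS[b]
        age[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))

    # --- functioning patterns sampled uniformly within the assigned class
    partition = severity_partition(scenario.cutoffs)
    functioning = np.empty((n, len(FUNCTIONING_DOMAINS)), dtype=np.int8)
    for i, cls in enumerate(DISABILITY_LABELS):
        mask = dis_idx == i
        if not mask.any():
            continue
        pool = partition[cls]
        picks = rng.integers(0, len(pool), size=int(mask.sum()))
        functioning[mask] = pool[picks]

    # --- affect patterns sampled uniformly within the assigned class
    aff_pool = affect_partition()
    affect = np.empty((n, 4), dtype=np.int8)
    for i, cls in enumerate(AFFECT_LABELS):
        mask = aff_idx == i
        if not mask.any():
            continue
        pool = aff_pool[cls]
        picks = rng.integers(0, len(pool), size=int(mask.sum()))
        affect[mask] = pool[picks]

    # --- indicator responses from class-conditional category probabilities
    indicator_cols: Dict[str, np.ndarray] = {}
    for ind in ALL_INDICATORS:
        cfg = cfg_map[ind]
        codes = np.array(
            [
                cfg.code_for(InclusionCategory.INCLUDED),
                cfg.code_for(InclusionCategory.IN_BETWEEN),
                cfg.code_for(InclusionCategory.EXCLUDED),
            ],
            dtype=object,
        )
        cat = np.empty(n, dtype=np.int8)
        u = rng.random(n)
        for i, cls in enumerate(DISABILITY_LABELS):
            mask = dis_idx == i
            if not mask.any():
                continue
            p = np.asarray(scenario.category_probabilities(ind, cls))
            cat[mask] = np.searchsorted(np.cumsum(p)[:-1], u[mask], side="right")
        indicator_cols[ind] = codes[cat]

    func_names = np.asarray(FUNCTIONING_CODE_NAMES, dtype=object)
    freq_names = np.asarray(FREQUENCY_NAMES, dtype=object)
    inten_names = np.asarray(INTENSITY_NAMES + ("",), dtype=object)  # -1 -> ""

    frame = {
        "respondent_id": np.arange(1, n + 1),
        "province": np.char.add("province_", province.astype(str)),
        "stratum": stratum,
        "ea_id": ea_id,
        "selection_prob": selection_prob,
        "age": age,
        "age_group": age_bin,
        "gender": gender,
        "population_group": popgroup,
        "true_disability_class": dis_labels,
        "true_affect_class": aff_labels,
    }
    for j, dom in enumerate(FUNCTIONING_DOMAINS):
        frame[f"{FUNCTIONING_COLUMN_PREFIX}{dom}"] = func_names[functioning[:, j]]
    frame["anxiety_frequency"] = freq_names[affect[:, 0]]
    frame["anxiety_intensity"] = inten_names[affect[:, 1]]
    frame["depression_frequency"] = freq_names[affect[:, 2]]
    frame["depression_intensity"] = inten_names[affect[:, 3]]
    for ind in ALL_INDICATORS:
        frame[f"ind_{ind}"] = indicator_cols[ind]
    return pd.DataFrame(frame)
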