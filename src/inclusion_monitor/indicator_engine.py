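"""Trichotomous indicator scoring.

Each of the 32 inclusion indicators maps a respondent's raw survey response
to one of three ordered categories, excluded < in between < included.
Fourteen indicators are binary (every substantive response is included or
excluded; "in between" arises only from refusals), the remaining eighteen
are nuanced (at least one substantive response sits in between, e.g. mild to
moderate food insecurity).

The mapping is declarative configuration, not code: the shipped default
response maps are plausible reconstructions from the indicator names, since
the instrument-level cut-off definitions are not public.  Users analysing a
real instrument supply their own maps (see ``indicator_configs_from_json``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InclusionCategory",
    "CATEGORY_LABELS",
    "DOMAINS",
    "BINARY_INDICATORS",
    "ALL_INDICATORS",
    "INDICATOR_COLUMN_PREFIX",
    "REFUSAL_CODE",
    "ConfigurationError",
    "IndicatorConfig",
    "classify_indicator",
    "default_indicator_configs",
    "configs_by_id",
    "build_indicator_matrix",
    "indicator_configs_to_json",
    "indicator_configs_from_json",
]


class InclusionCategory(IntEnum):
    """Ordered trichotomy used at indicator and domain level."""

    EXCLUDED = 0
    IN_BETWEEN = 1
    INCLUDED = 2

    @property
    def label(self) -> str:
        return CATEGORY_LABELS[self.value]


CATEGORY_LABELS: Tuple[str, ...] = ("excluded", "in_between", "included")

#: The nine inclusion domains and their indicators (after the instrument's
#: merges: one grant-receipt indicator, one healthcare indicator).
DOMAINS: Mapping[str, Tuple[str, ...]] = {
    "social_relationships": (
        "unpaid_care_work_humiliation",
        "unpaid_care_work_value",
        "reciprocate_support",
        "community_event_inclusion",
    ),
    "living_conditions": (
        "food_security",
        "drinking_water",
        "domestic_water",
        "cooking_energy",
        "lighting_energy",
        "heating_energy",
        "home_toilet_facilities",
        "toilet_modifications",
        "clothing_footwear_ownership",
        "clothing_footwear_quality",
        "bedding_ownership",
        "eviction_concern",
    ),
    "economic_opportunities": (
        "labour_force_status",
        "public_transport",
    ),
    "support_systems": (
        "support_availability",
        "grant_receipt",
    ),
    "institutional_status": (
        "identity_document",
        "birth_certificate",
    ),
    "voice": (
        "local_decision_making",
        "voting_inclusion",
    ),
    "education": (
        "schooling",
        "basic_literacy",
        "basic_numeracy",
    ),
    "healthcare_access": ("healthcare_access_quality",),
    "personal_safety": (
        "fuel_collection_hazards",
        "water_collection_hazards",
        "safety_at_home",
        "safety_in_neighbourhood",
    ),
}

ALL_INDICATORS: Tuple[str, ...] = tuple(
    ind for inds in DOMAINS.values() for ind in inds
)

#: The 14 indicators with binary substantive outcomes.  Which indicators are
#: binary is part of the reconstructed configuration (see module docstring).
BINARY_INDICATORS = frozenset(
    {
        "unpaid_care_work_humiliation",
        "unpaid_care_work_value",
        "reciprocate_support",
        "home_toilet_facilities",
        "toilet_modifications",
        "clothing_footwear_ownership",
        "bedding_ownership",
        "eviction_concern",
        "support_availability",
        "grant_receipt",
        "identity_document",
        "birth_certificate",
        "fuel_collection_hazards",
        "water_collection_hazards",
    }
)

INDICATOR_COLUMN_PREFIX = "ind_"
REFUSAL_CODE = "refused"


class ConfigurationError(ValueError):
    """Raised for inconsistent indicator configuration or unmapped codes."""


@dataclass(frozen=True)
class IndicatorConfig:
    """Declarative per-indicator classification rule.

    ``response_map`` sends substantive response codes to categories;
    ``refusal_codes`` always map to in between, whatever the mode.  Item
    missingness (an absent response) is deliberately distinct from refusal:
    missing responses drop the respondent from that indicator's denominator.
    """

    indicator_id: str
    domain_id: str
    mode: str  # "binary" | "nuanced"
    response_map: Mapping[str, InclusionCategory]
    refusal_codes: frozenset = frozenset({REFUSAL_CODE})

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "nuanced"):
            raise ConfigurationError(f"{self.indicator_id}: unknown mode {self.mode!r}")
        overlap = set(self.response_map) & set(self.refusal_codes)
        if overlap:
            raise ConfigurationError(
                f"{self.indicator_id}: codes {sorted(overlap)} are both mapped and refusal"
            )
        cats = set(self.response_map.values())
        if self.mode == "binary" and InclusionCategory.IN_BETWEEN in cats:
            raise ConfigurationError(
                f"{self.indicator_id}: binary indicator maps a substantive code to in_between"
            )
        if self.mode == "nuanced" and InclusionCategory.IN_BETWEEN not in cats:
            raise ConfigurationError(
                f"{self.indicator_id}: nuanced indicator has no in_between code"
            )

    def classify(self, code: str) -> InclusionCategory:
        if code in self.refusal_codes:
            return InclusionCategory.IN_BETWEEN
        try:
            return self.response_map[code]
        except KeyError:
            raise ConfigurationError(
                f"indicator {self.indicator_id!r}: unmapped response code {code!r}"
            ) from None

    def code_for(self, category: InclusionCategory) -> str:
        """A representative raw code for a category (generator inverse map).

        For a binary indicator in between is reachable only through refusal,
        so the refusal code is returned for it.
        """
        for code, cat in self.response_map.items():
            if cat == category:
                return code
        if category == InclusionCategory.IN_BETWEEN:
            return next(iter(sorted(self.refusal_codes)))
        raise ConfigurationError(
            f"indicator {self.indicator_id!r}: no code maps to {category.label}"
        )

    @property
    def full_map(self) -> Dict[str, InclusionCategory]:
        out = dict(self.response_map)
        out.update({c: InclusionCategory.IN_BETWEEN for c in self.refusal_codes})
        return out


def classify_indicator(code: str, config: IndicatorConfig) -> InclusionCategory:
    """Map one raw response code to its inclusion category (pure lookup)."""
    return config.classify(code)


# ---------------------------------------------------------------------------
# Default (reconstructed) response maps

_INC, _INB, _EXC = (
    InclusionCategory.INCLUDED,
    InclusionCategory.IN_BETWEEN,
    InclusionCategory.EXCLUDED,
)

_DEFAULT_MAPS: Mapping[str, Mapping[str, InclusionCategory]] = {
    "unpaid_care_work_humiliation": {"not_humiliated": _INC, "humiliated": _EXC},
    "unpaid_care_work_value": {"work_valued": _INC, "work_not_valued": _EXC},
    "reciprocate_support": {"can_reciprocate": _INC, "cannot_reciprocate": _EXC},
    "community_event_inclusion": {
        "always_included": _INC,
        "sometimes_included": _INB,
        "never_included": _EXC,
    },
    "food_security": {
        "food_secure": _INC,
        "mild_moderate_food_insecurity": _INB,
        "severe_food_insecurity": _EXC,
    },
    "drinking_water": {"safe_source": _INC, "partially_safe_source": _INB, "unsafe_source": _EXC},
    "domestic_water": {"sufficient": _INC, "partially_sufficient": _INB, "insufficient": _EXC},
    "cooking_energy": {"clean_reliable": _INC, "partially_adequate": _INB, "inadequate": _EXC},
    "lighting_energy": {"clean_reliable": _INC, "partially_adequate": _INB, "inadequate": _EXC},
    "heating_energy": {"clean_reliable": _INC, "partially_adequate": _INB, "inadequate": _EXC},
    "home_toilet_facilities": {"adequate_toilet": _INC, "no_adequate_toilet": _EXC},
    "toilet_modifications": {"modifications_met": _INC, "modifications_unmet": _EXC},
    "clothing_footwear_ownership": {"owns_sufficient": _INC, "lacks_sufficient": _EXC},
    "clothing_footwear_quality": {"good_quality": _INC, "fair_quality": _INB, "poor_quality": _EXC},
    "bedding_ownership": {"owns_bedding": _INC, "lacks_bedding": _EXC},
    "eviction_concern": {"secure": _INC, "concerned": _EXC},
    "labour_force_status": {
        "employed_or_studying": _INC,
        "not_in_labour_force": _INB,
        "unemployed_seeking": _EXC,
    },
    "public_transport": {
        "available_affordable": _INC,
        "available_unaffordable": _INB,
        "unavailable": _EXC,
    },
    "support_availability": {"support_available": _INC, "no_support": _EXC},
    "grant_receipt": {"grant_received_or_not_needed": _INC, "eligible_no_grant": _EXC},
    "identity_document": {"has_document": _INC, "no_document": _EXC},
    "birth_certificate": {"has_certificate": _INC, "no_certificate": _EXC},
    "local_decision_making": {"always_able": _INC, "sometimes_able": _INB, "never_able": _EXC},
    "voting_inclusion": {"voted_or_able": _INC, "partially_able": _INB, "unable_or_prevented": _EXC},
    "schooling": {"completed_secondary": _INC, "some_schooling": _INB, "no_schooling": _EXC},
    "basic_literacy": {"reads_easily": _INC, "reads_with_difficulty": _INB, "cannot_read": _EXC},
    "basic_numeracy": {"counts_easily": _INC, "counts_with_difficulty": _INB, "cannot_count": _EXC},
    "healthcare_access_quality": {
        "accessed_good_quality": _INC,
        "accessed_mixed_quality": _INB,
        "unmet_need": _EXC,
    },
    "fuel_collection_hazards": {"no_hazard_exposure": _INC, "hazard_exposure": _EXC},
    "water_collection_hazards": {"no_hazard_exposure": _INC, "hazard_exposure": _EXC},
    "safety_at_home": {"always_safe": _INC, "sometimes_safe": _INB, "never_safe": _EXC},
    "safety_in_neighbourhood": {"always_safe": _INC, "sometimes_safe": _INB, "never_safe": _EXC},
}


def default_indicator_configs() -> List[IndicatorConfig]:
    """The shipped 32-indicator configuration (14 binary, 18 nuanced)."""
    configs = []
    for domain_id, indicators in DOMAINS.items():
        for ind in indicators:
            configs.append(
                IndicatorConfig(
                    indicator_id=ind,
                    domain_id=domain_id,
                    mode="binary" if ind in BINARY_INDICATORS else "nuanced",
                    response_map=dict(_DEFAULT_MAPS[ind]),
                )
            )
    return configs


def configs_by_id(configs: Iterable[IndicatorConfig]) -> Dict[str, IndicatorConfig]:
    out = {}
    for cfg in configs:
        if cfg.indicator_id in out:
            raise ConfigurationError(f"duplicate indicator id {cfg.indicator_id!r}")
        out[cfg.indicator_id] = cfg
    return out


def build_indicator_matrix(
    records: pd.DataFrame,
    configs: Sequence[IndicatorConfig],
    prefix: str = INDICATOR_COLUMN_PREFIX,
) -> pd.DataFrame:
    """Classify every configured indicator for every respondent.

    Returns a frame of nullable Int8 category codes (columns = indicator ids,
    aligned with ``records``).  Absent responses (NaN / empty string) become
    ``NA`` and are excluded from that indicator's denominators downstream;
    a present but unmapped code raises :class:`ConfigurationError`.
    """
    data = {}
    for cfg in configs:
        col = f"{prefix}{cfg.indicator_id}"
        if col not in records.columns:
            raise ConfigurationError(f"records lack column {col!r}")
        raw = records[col]
        present = raw.notna() & (raw != "")
        mapping = {k: int(v) for k, v in cfg.full_map.items()}
        unmapped = set(raw[present].unique()) - set(mapping)
        if unmapped:
            raise ConfigurationError(
                f"indicator {cfg.indicator_id!r}: unmapped response codes {sorted(unmapped)}"
            )
        col_data = raw.map(mapping).astype("Int8")
        n_missing = int((~present).sum())
        if n_missing:
            logger.info("indicator %s: %d missing responses dropped from denominators",
                        cfg.indicator_id, n_missing)
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug("indicator %s: category counts %s", cfg.indicator_id,
                         col_data.value_counts(dropna=False).to_dict())
        data[cfg.indicator_id] = col_data
    return pd.DataFrame(data, index=records.index)


# ---------------------------------------------------------------------------
# JSON round-trip (configuration is data)


def indicator_configs_to_json(configs: Sequence[IndicatorConfig]) -> str:
    payload = [
        {
            "indicator_id": c.indicator_id,
            "domain_id": c.domain_id,
            "mode": c.mode,
            "response_map": {k: v.label for k, v in c.response_map.items()},
            "refusal_codes": sorted(c.refusal_codes),
        }
        for c in configs
    ]
    return json.dumps(payload, indent=2, sort_keys=True)


def indicator_configs_from_json(text: str) -> List[IndicatorConfig]:
    label_to_cat = {c.label: c for c in InclusionCategory}
    out = []
    for item in json.loads(text):
        out.append(
            IndicatorConfig(
                indicator_id=item["indicator_id"],
                domain_id=item["domain_id"],
                mode=item["mode"],
                response_map={
                    k: label_to_cat[v] for k, v in item["response_map"].items()
                },
                refusal_codes=frozenset(item.get("refusal_codes", [REFUSAL_CODE])),
            )
        )
    return out
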