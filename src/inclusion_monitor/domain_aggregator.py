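"""Dual cut-off aggregation of indicator categories into domain categories.

A domain with n indicators is *included* when at least k indicators are
included and none of the remainder falls below in between (i.e. no indicator
is excluded); it is *excluded* symmetrically; everything else is in between.
The k values are fixed per domain size (1, 1, 2, 3 and 8 for n = 1, 2, 3, 4
and 12) and stored as configuration rather than derived from a formula —
the sequence fits no clean closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .indicator_engine import (
    DOMAINS,
    InclusionCategory,
    IndicatorConfig,
)

__all__ = [
    "DEFAULT_K_BY_SIZE",
    "DomainRule",
    "default_domain_rules",
    "aggregate_domain",
    "aggregate_all",
]

#: Required count in the extreme category, by number of indicators in the
#: domain.
DEFAULT_K_BY_SIZE: Mapping[int, int] = {1: 1, 2: 1, 3: 2, 4: 3, 12: 8}


@dataclass(frozen=True)
class DomainRule:
    """k-of-n rule for one domain."""

    domain_id: str
    n_indicators: int
    k_threshold: int

    def __post_init__(self) -> None:
        if not 1 <= self.k_threshold <= self.n_indicators:
            raise ValueError(
                f"{self.domain_id}: k_threshold must lie in [1, n_indicators]"
            )


def default_domain_rules(
    configs: Optional[Sequence[IndicatorConfig]] = None,
) -> List[DomainRule]:
    """Rules for the nine domains, sized from the indicator configuration."""
    if configs is None:
        sizes = {d: len(inds) for d, inds in DOMAINS.items()}
    else:
        sizes = {}
        for cfg in configs:
            sizes[cfg.domain_id] = sizes.get(cfg.domain_id, 0) + 1
    rules = []
    for domain_id, n in sizes.items():
        if n not in DEFAULT_K_BY_SIZE:
            raise ValueError(
                f"{domain_id}: no default threshold for a domain of {n} indicators"
            )
        rules.append(DomainRule(domain_id, n, DEFAULT_K_BY_SIZE[n]))
    return rules


def aggregate_domain(
    categories: Sequence, rule: DomainRule
) -> InclusionCategory:
    """Aggregate one respondent's indicator categories for one domain."""
    cats = [InclusionCategory(int(c)) for c in categories]
    if len(cats) != rule.n_indicators:
        raise ValueError(
            f"{rule.domain_id}: expected {rule.n_indicators} categories, got {len(cats)}"
        )
    n_inc = sum(c == InclusionCategory.INCLUDED for c in cats)
    n_exc = sum(c == InclusionCategory.EXCLUDED for c in cats)
    if n_inc >= rule.k_threshold and n_exc == 0:
        return InclusionCategory.INCLUDED
    if n_exc >= rule.k_threshold and n_inc == 0:
        return InclusionCategory.EXCLUDED
    return InclusionCategory.IN_BETWEEN


def _domain_members(
    configs: Optional[Sequence[IndicatorConfig]],
) -> Mapping[str, Tuple[str, ...]]:
    if configs is None:
        return DOMAINS
    members: Dict[str, list] = {}
    for cfg in configs:
        members.setdefault(cfg.domain_id, []).append(cfg.indicator_id)
    return {d: tuple(v) for d, v in members.items()}


def aggregate_all(
    matrix: pd.DataFrame,
    rules: Iterable[DomainRule],
    configs: Optional[Sequence[IndicatorConfig]] = None,
) -> pd.DataFrame:
    """Domain categories for every respondent (vectorised).

    ``matrix`` holds per-indicator categories (nullable Int8, from
    :func:`~inclusion_monitor.indicator_engine.build_indicator_matrix`).
    A respondent with any missing indicator inside a domain gets ``NA`` for
    that domain and drops out of its denominators.
    """
    members = _domain_members(configs)
    out = {}
    for rule in rules:
        cols = list(members[rule.domain_id])
        if len(cols) != rule.n_indicators:
            raise ValueError(
                f"{rule.domain_id}: rule expects {rule.n_indicators} indicators, "
                f"configuration provides {len(cols)}"
            )
        sub = matrix[cols]
        valid = sub.notna().all(axis=1).to_numpy()
        vals = sub.fillna(-1).to_numpy(dtype=np.int8)
        n_inc = (vals == int(InclusionCategory.INCLUDED)).sum(axis=1)
        n_exc = (vals == int(InclusionCategory.EXCLUDED)).sum(axis=1)
        res = np.full(len(matrix), int(InclusionCategory.IN_BETWEEN), dtype=np.int8)
        res[(n_inc >= rule.k_threshold) & (n_exc == 0)] = int(InclusionCategory.INCLUDED)
        res[(n_exc >= rule.k_threshold) & (n_inc == 0)] = int(InclusionCategory.EXCLUDED)
        col = pd.Series(res, index=matrix.index, dtype="Int8")
        col[~valid] = pd.NA
        n_flagged = int((~valid).sum())
        if n_flagged:
            logger.info("domain %s: %d respondents with missing indicators flagged",
                        rule.domain_id, n_flagged)
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug("domain %s: category tallies %s", rule.domain_id,
                         col.value_counts(dropna=False).to_dict())
        out[rule.domain_id] = col
    return pd.DataFrame(out, index=matrix.index)
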