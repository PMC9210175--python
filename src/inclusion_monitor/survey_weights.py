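"""Design weights, raking (iterative proportional fitting) and weighted shares.

The sample is a stratified two-stage design (province x urban/rural strata,
enumeration areas, then dwellings); base weights are inverse selection
probabilities.  Raking adjusts the base weights one margin dimension at a
time until the weighted marginal shares match external population targets
(age group, gender, population group), the standard survey practice for
maximising generalisability of a sample.  Joint-cell post-stratification is
deliberately out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .indicator_engine import CATEGORY_LABELS

__all__ = [
    "MarginSpec",
    "WeightVector",
    "RakingInfeasibleError",
    "base_weights",
    "rake",
    "weighted_proportions",
]

logger = logging.getLogger(__name__)


class RakingInfeasibleError(ValueError):
    """A margin level has positive target share but zero sample weight."""


@dataclass(frozen=True)
class MarginSpec:
    """Target population shares for one raking dimension."""

    dimension: str
    targets: Mapping[str, float]

    def __post_init__(self) -> None:
        shares = np.asarray(list(self.targets.values()), dtype=float)
        if (shares < 0).any():
            raise ValueError(f"{self.dimension}: negative target share")
        if abs(shares.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"{self.dimension}: target shares sum to {shares.sum():.8f}, expected 1"
            )


@dataclass
class WeightVector:
    """Per-respondent weights plus raking convergence metadata."""

    weights: pd.Series
    iterations: int = 0
    max_margin_error: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if (self.weights <= 0).any():
            raise ValueError("weights must be strictly positive")


def base_weights(selection_prob: Union[pd.Series, np.ndarray, Sequence[float]]) -> WeightVector:
    """Inverse-probability base weights from dwelling selection probabilities."""
    p = pd.Series(selection_prob, dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("selection probabilities must lie in (0, 1]")
    return WeightVector(weights=1.0 / p)


def _margin_error(
    w: pd.Series, sample: pd.DataFrame, margins: Sequence[MarginSpec]
) -> float:
    total = w.sum()
    err = 0.0
    for spec in margins:
        shares = w.groupby(sample[spec.dimension], observed=True).sum() / total
        for level, target in spec.targets.items():
            err = max(err, abs(shares.get(level, 0.0) - target))
    return err


def rake(
    weights: Union[WeightVector, pd.Series],
    sample: pd.DataFrame,
    margins: Sequence[MarginSpec],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> WeightVector:
    """Rake weights to external margins by iterative proportional fitting.

    Cycles over the margin dimensions, within each level multiplying weights
    by (target share x total weight) / (current level weight), until the
    largest absolute margin error drops below ``tol`` or ``max_iter`` cycles
    are exhausted (reported on the returned metadata, never silent).

    Raises
    ------
    RakingInfeasibleError
        If a level with a positive target has no sample weight.
    ValueError
        If a sample level is absent from its margin specification.
    """
    w = (weights.weights if isinstance(weights, WeightVector) else pd.Series(weights)).astype(
        float
    )
    for spec in margins:
        if spec.dimension not in sample.columns:
            raise ValueError(f"sample lacks margin dimension {spec.dimension!r}")
        observed = set(sample[spec.dimension].unique())
        unspecified = observed - set(spec.targets)
        if unspecified:
            raise ValueError(
                f"{spec.dimension}: sample levels {sorted(unspecified)} missing from MarginSpec"
            )
        counts = sample[spec.dimension].value_counts()
        for level, target in spec.targets.items():
            if target > 0 and counts.get(level, 0) == 0:
                raise RakingInfeasibleError(
                    f"{spec.dimension}={level!r} has target {target} but no sample cases"
                )

    err = _margin_error(w, sample, margins)
    if err < tol:
        return WeightVector(weights=w, iterations=0, max_margin_error=err, converged=True)

    iterations = 0
    for _ in range(max_iter):
        for spec in margins:
            levels = sample[spec.dimension]
            total = w.sum()
            level_w = w.groupby(levels, observed=True).sum()
            factors = {
                level: (spec.targets[level] * total / lw) if lw > 0 else 1.0
                for level, lw in level_w.items()
            }
            w = w * levels.map(factors).astype(float)
        iterations += 1
        err = _margin_error(w, sample, margins)
        if err < tol:
            break
    converged = err < tol
    if not converged:
        warnings.warn(
            f"raking did not converge in {max_iter} cycles "
            f"(max margin error {err:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )
    return WeightVector(
        weights=w, iterations=iterations, max_margin_error=err, converged=converged
    )


def weighted_proportions(
    categories: pd.Series,
    weights: Union[WeightVector, pd.Series],
    groups: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Weighted percentage of each inclusion category, by group.

    Rows are groups, columns the three ordered categories; each row sums to
    100 (before rounding) and the result is invariant to a global rescaling
    of the weights.  Respondents with a missing category are dropped from
    the denominators; empty groups are omitted with a logged warning.
    """
    w = weights.weights if isinstance(weights, WeightVector) else pd.Series(weights)
    cats = pd.Series(categories)
    if groups is None:
        groups = pd.Series("all", index=cats.index)
    valid = cats.notna()
    if not valid.all():
        logger.info("weighted_proportions: dropping %d missing categories", (~valid).sum())
    cats, w, groups = cats[valid], w[valid], groups[valid]
    tab = (
        pd.DataFrame({"group": groups, "category": cats.astype(int), "w": w})
        .pivot_table(index="group", columns="category", values="w", aggfunc="sum", fill_value=0.0, observed=False)
        .reindex(columns=range(len(CATEGORY_LABELS)), fill_value=0.0)
    )
    tab.columns = list(CATEGORY_LABELS)
    totals = tab.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("weighted_proportions: omitting empty groups %s", list(tab.index[empty]))
        tab = tab[~empty]
        totals = totals[~empty]
    return tab.div(totals, axis=0) * 100.0
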