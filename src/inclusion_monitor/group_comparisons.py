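"""Weighted contingency tables and Bonferroni-adjusted chi-squared tests.

Group x category tables are built from weighted counts.  Because the weights
are survey weights, a naive Pearson test on the weighted counts would be
anti-conservative; two design-aware flavours are offered:

``pearson_effective_n``
    Rescale the whole weighted table so its total equals the Kish effective
    sample size, (sum w)^2 / (sum w^2), then apply the classical Pearson
    chi-squared test.  With unit weights this reproduces the classical test
    exactly.

``rao_scott``
    First-order design-effect correction: each group's row is rescaled to
    that group's own Kish effective size before the Pearson statistic is
    computed, so groups with more variable weights contribute less evidence.

Rare categories break the asymptotic chi-squared reference: with expected
cell counts below Cochran's rule of thumb (5), the Pearson statistic is
anti-conservative.  Both flavours therefore fall back to a Monte-Carlo
p-value in that regime.  When the respondent-level data are attached to the
table (they always are for tables built by :func:`contingency_table`) the
reference distribution is obtained by permuting group labels over the
observed (category, weight) pairs — an exact conditional null that respects
the weight variability inside rare cells.  Without respondent data the
fallback resamples multinomial tables under row-margin-fixed homogeneity,
the scheme of R's ``chisq.test(simulate.p.value = TRUE)``.  The simulation
seed is derived from the table itself so results are reproducible without
global state.

Families of tests (one per domain or per indicator) are adjusted with the
Bonferroni rule, adjusted p = min(1, m x raw p).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .indicator_engine import CATEGORY_LABELS
from .survey_weights import WeightVector

__all__ = [
    "ComparisonUndefinedError",
    "WeightedTable",
    "ComparisonFamily",
    "kish_effective_n",
    "contingency_table",
    "chisq_test",
    "bonferroni_adjust",
    "run_family",
]

METHODS = ("pearson_effective_n", "rao_scott")


class ComparisonUndefinedError(ValueError):
    """Raised when a comparison has fewer than two non-empty groups."""


def kish_effective_n(weights: Union[pd.Series, np.ndarray]) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / np.square(w).sum())


@dataclass
class WeightedTable:
    """A group x category weighted table plus the design quantities the
    chi-squared flavours need, and its (adjusted) p-value once computed."""

    unit_id: str
    counts: pd.DataFrame  # weighted counts, groups x categories
    neff_total: float
    neff_by_group: pd.Series
    raw_p: float = float("nan")
    adjusted_p: float = float("nan")
    #: respondent-level (group, category, weight) backing the table; used by
    #: the permutation fallback for sparse tables
    respondents: Optional[pd.DataFrame] = None

    @property
    def percentages(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0) * 100.0

    @property
    def group_weights(self) -> pd.Series:
        return self.counts.sum(axis=1)


def contingency_table(
    categories: pd.Series,
    weights: Union[WeightVector, pd.Series],
    groups: pd.Series,
    unit_id: str = "",
    group_order: Optional[Sequence[str]] = None,
) -> WeightedTable:
    """Build the weighted group x category table for one domain/indicator.

    Respondents with a missing category are dropped (with their weights)
    from this table only.  Requires at least two non-empty groups.
    """
    w = weights.weights if isinstance(weights, WeightVector) else pd.Series(weights)
    cats = pd.Series(categories)
    valid = cats.notna() & groups.notna()
    cats, w, groups = cats[valid], w[valid], groups[valid]
    if groups.nunique() < 2:
        raise ComparisonUndefinedError(
            f"{unit_id or 'comparison'}: fewer than two non-empty groups"
        )
    df = pd.DataFrame({"group": groups, "category": cats.astype(int), "w": w})
    counts = (
        df.pivot_table(index="group", columns="category", values="w", aggfunc="sum", fill_value=0.0, observed=False)
        .reindex(columns=range(len(CATEGORY_LABELS)), fill_value=0.0)
    )
    counts.columns = list(CATEGORY_LABELS)
    if group_order is not None:
        order = [g for g in group_order if g in counts.index]
        counts = counts.loc[order]
    sq = df.assign(w2=df["w"] ** 2).groupby("group", observed=True)[["w", "w2"]].sum()
    neff_by_group = (sq["w"] ** 2 / sq["w2"]).reindex(counts.index)
    neff_total = kish_effective_n(w)
    return WeightedTable(
        unit_id=unit_id,
        counts=counts,
        neff_total=neff_total,
        neff_by_group=neff_by_group,
        respondents=df,
    )


#: Cochran's rule of thumb: below this expected cell count the asymptotic
#: chi-squared reference is unreliable and the Monte-Carlo p-value is used.
MIN_EXPECTED_FOR_ASYMPTOTIC = 5.0
MC_REPLICATES = 1000


def _table_seed(table: np.ndarray) -> int:
    digest = hashlib.sha256(np.ascontiguousarray(np.round(table, 6)).tobytes())
    return int(digest.hexdigest()[:8], 16)


def _permutation_p(
    respondents: pd.DataFrame,
    keep_groups: Sequence,
    keep_categories: Sequence[int],
    n_sim: int = MC_REPLICATES,
) -> float:
    """Permutation homogeneity p: shuffle group labels over the observed
    (category, weight) pairs and recompute the weighted Pearson statistic."""
    sub = respondents[
        respondents["group"].isin(keep_groups)
        & respondents["category"].isin(keep_categories)
    ]
    groups, g_idx = np.unique(sub["group"].to_numpy(), return_inverse=True)
    cats, c_idx = np.unique(sub["category"].to_numpy(), return_inverse=True)
    w = sub["w"].to_numpy(dtype=float)
    n, g, k = len(sub), len(groups), len(cats)
    wc = np.zeros((n, k))
    wc[np.arange(n), c_idx] = w
    gmat = np.zeros((g, n))
    gmat[g_idx, np.arange(n)] = 1.0
    observed_table = gmat @ wc
    observed = _pearson_stat(observed_table)
    rng = np.random.default_rng(_table_seed(observed_table))
    group_sizes = np.bincount(g_idx, minlength=g)

    # Permuting labels over respondents is distributionally identical to
    # allocating the pool of distinct (category, weight) combinations to the
    # groups by successive multivariate hypergeometric draws; with few
    # distinct weights that is orders of magnitude cheaper than gathering.
    combos, j_idx = np.unique(
        np.column_stack([c_idx, np.round(w, 9)]), axis=0, return_inverse=True
    )
    n_combo = len(combos)
    if n_combo <= 512:
        pool = np.bincount(j_idx, minlength=n_combo)
        combo_w = np.zeros((n_combo, k))
        combo_w[np.arange(n_combo), combos[:, 0].astype(int)] = combos[:, 1]
        stats_sim = np.empty(n_sim)
        draws = np.empty((g, n_combo), dtype=np.int64)
        for s in range(n_sim):
            remaining = pool.copy()
            for gi in range(g - 1):
                take = rng.multivariate_hypergeometric(remaining, int(group_sizes[gi]))
                draws[gi] = take
                remaining -= take
            draws[g - 1] = remaining
            stats_sim[s] = _pearson_stat(draws @ combo_w)
        return float((1 + (stats_sim >= observed - 1e-12).sum()) / (1 + n_sim))

    exceed = 0
    batch = 200
    done = 0
    while done < n_sim:
        b = min(batch, n_sim - done)
        idx = np.tile(np.arange(n), (b, 1))
        rng.permuted(idx, axis=1, out=idx)
        tables = np.einsum("gn,bnk->bgk", gmat, wc[idx])
        rows = tables.sum(axis=2, keepdims=True)
        cols = tables.sum(axis=1, keepdims=True)
        totals = tables.sum(axis=(1, 2), keepdims=True)
        expected = rows * cols / totals
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(expected > 0, (tables - expected) ** 2 / expected, 0.0)
        stats_b = contrib.sum(axis=(1, 2))
        exceed += int((stats_b >= observed - 1e-12).sum())
        done += b
    return float((1 + exceed) / (1 + n_sim))


def _pearson_stat(table: np.ndarray) -> float:
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(contrib.sum())


def _mc_pearson_p(table: np.ndarray, n_sim: int = MC_REPLICATES) -> float:
    """Monte-Carlo homogeneity p: resample rows as multinomials with pooled
    column probabilities and fixed (rounded) row totals."""
    rng = np.random.default_rng(_table_seed(table))
    col_p = table.sum(axis=0) / table.sum()
    row_totals = np.maximum(np.rint(table.sum(axis=1)).astype(int), 1)
    sims = np.stack(
        [rng.multinomial(n_i, col_p, size=n_sim) for n_i in row_totals], axis=1
    ).astype(float)  # (n_sim, rows, cols)
    rows_sum = sims.sum(axis=2, keepdims=True)
    cols_sum = sims.sum(axis=1, keepdims=True)
    totals = sims.sum(axis=(1, 2), keepdims=True)
    expected = rows_sum * cols_sum / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (sims - expected) ** 2 / expected, 0.0)
    sim_stats = contrib.sum(axis=(1, 2))
    observed = _pearson_stat(table)
    return float((1 + (sim_stats >= observed - 1e-12).sum()) / (1 + n_sim))


def _pearson_p(table: np.ndarray) -> float:
    if table.shape[0] < 2 or table.shape[1] < 2:
        return float("nan")
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def chisq_test(table: WeightedTable, method: str = "pearson_effective_n") -> float:
    """Raw chi-squared p-value for a weighted table.

    All-zero rows and columns are dropped first; a table degenerating below
    2 x 2 (a single non-empty row or column) has no defined test and returns
    NaN, mirroring the not-available entries that arise when a category is
    empty for every group.  Tables with expected counts below Cochran's rule
    use the Monte-Carlo reference distribution (see module docstring).
    """
    if method not in METHODS:
        raise ValueError(f"unknown chi-squared method {method!r}; choose from {METHODS}")
    counts = table.counts.to_numpy(dtype=float)
    row_keep = counts.sum(axis=1) > 0
    col_keep = counts.sum(axis=0) > 0
    trimmed = counts[np.ix_(row_keep, col_keep)]
    if trimmed.shape[0] < 2 or trimmed.shape[1] < 2:
        return float("nan")
    if method == "pearson_effective_n":
        scale = table.neff_total / trimmed.sum()
        scaled = trimmed * scale
    else:  # rao_scott: per-group effective-n rescale (first-order correction)
        neff = table.neff_by_group.to_numpy(dtype=float)[row_keep]
        row_sums = trimmed.sum(axis=1)
        scaled = trimmed * (neff / row_sums)[:, None]
    expected = np.outer(scaled.sum(axis=1), scaled.sum(axis=0)) / scaled.sum()
    if expected.min() < MIN_EXPECTED_FOR_ASYMPTOTIC:
        if table.respondents is not None:
            keep_groups = table.counts.index[row_keep]
            keep_categories = [i for i, keep in enumerate(col_keep) if keep]
            return _permutation_p(table.respondents, keep_groups, keep_categories)
        return _mc_pearson_p(scaled)
    return _pearson_p(scaled)


def bonferroni_adjust(
    p_values: Sequence[float], m: Optional[int] = None
) -> List[float]:
    """Bonferroni adjustment: each p becomes min(1, p x m); NaN passes through.

    ``m`` defaults to the number of p-values and may exceed it (the family
    may be larger than the reported tests).
    """
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < 1:
        raise ValueError("m must be at least 1")
    out = []
    for p in ps:
        if p is None or (isinstance(p, float) and math.isnan(p)):
            out.append(float("nan"))
            continue
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, p * m))
    return out


@dataclass
class ComparisonFamily:
    """One Bonferroni family: a table (with raw and adjusted p) per unit."""

    tables: List[WeightedTable]
    m: int
    method: str
    grouping: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Long-format family table: unit, group, category, weighted %, p's."""
        rows = []
        for t in self.tables:
            pct = t.percentages
            for group in pct.index:
                for category in pct.columns:
                    rows.append(
                        {
                            "unit_id": t.unit_id,
                            "group": group,
                            "category": category,
                            "weighted_pct": pct.loc[group, category],
                            "raw_p": t.raw_p,
                            "adjusted_p": t.adjusted_p,
                        }
                    )
        return pd.DataFrame(rows)

    def p_by_unit(self) -> Dict[str, float]:
        return {t.unit_id: t.adjusted_p for t in self.tables}


def run_family(
    items: Mapping[str, pd.Series],
    weights: Union[WeightVector, pd.Series],
    groups: pd.Series,
    method: str = "pearson_effective_n",
    m: Optional[int] = None,
    grouping: str = "",
    group_order: Optional[Sequence[str]] = None,
) -> ComparisonFamily:
    """Run one chi-squared test per unit (domain or indicator) and adjust.

    ``m`` defaults to the family size (all units, including those whose test
    is undefined — the family never silently shrinks).
    """
    tables = []
    for unit_id, cats in items.items():
        t = contingency_table(cats, weights, groups, unit_id=unit_id, group_order=group_order)
        t.raw_p = chisq_test(t, method=method)
        tables.append(t)
    m_eff = m if m is not None else len(tables)
    adjusted = bonferroni_adjust([t.raw_p for t in tables], m_eff)
    for t, ap in zip(tables, adjusted):
        t.adjusted_p = ap
    return ComparisonFamily(tables=tables, m=m_eff, method=method, grouping=grouping)
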