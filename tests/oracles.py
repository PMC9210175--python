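"""Independent straight-line oracles used by the test suite.

These re-state the classification and aggregation rules, the IPF fixed
point and the Pearson chi-squared formula directly, without touching the
package's implementation paths, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2


def oracle_disability(levels) -> int:
    """0 = none, 1 = mild, 2 = moderate.

    levels: six ints on the 0-3 difficulty scale.
    """
    levels = list(levels)
    some = sum(1 for v in levels if v == 1)
    if any(v >= 2 for v in levels):
        return 2
    if some >= 5:
        return 2
    if 2 <= some <= 4:
        return 1
    return 0


def oracle_domain(categories, k: int) -> int:
    """0 = excluded, 1 = in between, 2 = included.

    Included: at least k of the indicators included and none of the
    remainder below in between.  Excluded symmetrically.  Else in between.
    """
    cats = list(categories)
    n_inc = sum(1 for c in cats if c == 2)
    n_exc = sum(1 for c in cats if c == 0)
    if n_inc >= k and n_exc == 0:
        return 2
    if n_exc >= k and n_inc == 0:
        return 0
    return 1


def oracle_ipf(table: np.ndarray, row_targets, col_targets, iters: int = 10000) -> np.ndarray:
    """Long-run elementwise IPF fixed point of a 2-way table, as shares."""
    t = np.asarray(table, dtype=float).copy()
    row_targets = np.asarray(row_targets, dtype=float)
    col_targets = np.asarray(col_targets, dtype=float)
    for _ in range(iters):
        t *= (row_targets / t.sum(axis=1))[:, None]
        t *= col_targets / t.sum(axis=0)
    return t / t.sum()


def oracle_pearson_p(table: np.ndarray) -> float:
    """Textbook Pearson chi-squared p-value (no continuity correction)."""
    t = np.asarray(table, dtype=float)
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    stat = ((t - expected) ** 2 / expected).sum()
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return float(chi2.sf(stat, df))
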