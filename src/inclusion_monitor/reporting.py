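"""End-to-end pipeline orchestration, output tables and prioritisation.

``run_pipeline`` ties the stages together: severity classification (with
drop-and-count handling of undefined records), indicator scoring, domain
aggregation, base weights and raking, and one Bonferroni family of weighted
chi-squared comparisons per output table:

* domains x (disability severity x gender)   — 9 tests
* indicators x (disability severity x gender) — 32 tests
* domains x (affect severity x gender)        — 9 tests

On top of the tables it computes gender gap summaries (inclusion gaps at
domain level, exclusion gaps at indicator level), classifies each
indicator's severity pattern (monotone worsening, mild ~ moderate worse,
no significant difference, mild worst, none worst), and ranks domains for
three policy-targeting approaches: closest to inclusion, farthest from
inclusion, and largest disability gap.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .domain_aggregator import DomainRule, aggregate_all, default_domain_rules
from .group_comparisons import ComparisonFamily, run_family
from .indicator_engine import (
    CATEGORY_LABELS,
    IndicatorConfig,
    build_indicator_matrix,
    default_indicator_configs,
    indicator_configs_to_json,
)
from .survey_weights import MarginSpec, WeightVector, base_weights, rake
from .synthetic_data import SyntheticScenario, generate_population
from .wg_classifiers import (
    AFFECT_LABELS,
    DEFAULT_CUTOFFS,
    DISABILITY_LABELS,
    SeverityCutoffs,
    affect_severity_frame,
    default_affect_grid,
    disability_severity_frame,
)

__all__ = [
    "AnalysisConfig",
    "ResultBundle",
    "run_pipeline",
    "compute_gaps",
    "classify_severity_pattern",
    "prioritise_domains",
    "PriorityRanking",
    "pooled_percentages",
    "simulate_family_rejections",
]

PATTERN_LABELS = (
    "monotone_worsening",
    "mild_equals_moderate_worse",
    "no_significant_difference",
    "mild_worst",
    "none_worst",
)

APPROACHES = ("closest_to_inclusion", "farthest_from_inclusion", "largest_disability_gap")


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with study defaults."""

    indicator_configs: List[IndicatorConfig] = field(default_factory=default_indicator_configs)
    domain_rules: List[DomainRule] = field(default_factory=default_domain_rules)
    cutoffs: SeverityCutoffs = DEFAULT_CUTOFFS
    affect_grid: Mapping = field(default_factory=default_affect_grid)
    raking_tol: float = 1e-8
    raking_max_iter: int = 100
    test_method: str = "pearson_effective_n"
    m_domains: Optional[int] = None  # default: family size (9)
    m_indicators: Optional[int] = None  # default: family size (32)
    alpha: float = 0.05
    pattern_band: float = 2.0  # percentage points treated as "same" exclusion
    inclusion_ceiling: float = 80.0  # closest-to-inclusion approach ceiling

    def config_hash(self) -> str:
        payload = {
            "indicators": indicator_configs_to_json(self.indicator_configs),
            "rules": [(r.domain_id, r.n_indicators, r.k_threshold) for r in self.domain_rules],
            "cutoffs": dataclasses.astuple(self.cutoffs),
            "grid": sorted((int(f), int(i), int(l)) for (f, i), l in self.affect_grid.items()),
            "raking": [self.raking_tol, self.raking_max_iter],
            "test": [self.test_method, self.m_domains, self.m_indicators, self.alpha],
            "reporting": [self.pattern_band, self.inclusion_ceiling],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


DIS_GROUP_ORDER = tuple(f"{c}_{g}" for c in DISABILITY_LABELS for g in ("male", "female"))
AFF_GROUP_ORDER = tuple(f"{c}_{g}" for c in AFFECT_LABELS for g in ("male", "female"))


@dataclass
class ResultBundle:
    """All pipeline outputs for one run."""

    domain_table: pd.DataFrame
    indicator_table: pd.DataFrame
    affect_table: pd.DataFrame
    gaps: pd.DataFrame
    patterns: pd.DataFrame
    rankings: pd.DataFrame
    metadata: Dict
    domain_family: ComparisonFamily
    indicator_family: ComparisonFamily
    affect_family: ComparisonFamily

    def write(self, outdir: Union[str, Path]) -> None:
        """Write the CSV tables and the JSON run-metadata file."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.domain_table.to_csv(outdir / "domains_by_disability.csv", index=False)
        self.indicator_table.to_csv(outdir / "indicators_by_disability.csv", index=False)
        self.affect_table.to_csv(outdir / "domains_by_affect.csv", index=False)
        self.gaps.to_csv(outdir / "gender_gaps.csv", index=False)
        self.patterns.to_csv(outdir / "severity_patterns.csv", index=False)
        self.rankings.to_csv(outdir / "priority_rankings.csv", index=False)
        (outdir / "run_metadata.json").write_text(
            json.dumps(self.metadata, indent=2, sort_keys=True, default=str)
        )


def _group_labels(classes: pd.Series, gender: pd.Series, labels: Sequence[str]) -> pd.Series:
    lab = pd.Series(pd.NA, index=classes.index, dtype=object)
    ok = classes.notna()
    arr = np.asarray(labels, dtype=object)[classes[ok].astype(int).to_numpy()]
    lab[ok] = np.char.add(np.char.add(arr.astype(str), "_"), gender[ok].astype(str).to_numpy())
    return lab


def run_pipeline(
    records: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
    margins: Optional[Sequence[MarginSpec]] = None,
    seed: Optional[int] = None,
) -> ResultBundle:
    """Run the full analysis on a microdata frame.

    ``margins`` are the external population margins for raking; if ``None``
    the base design weights are used unadjusted (recorded in the metadata).
    ``seed`` is recorded in the run metadata only — the analysis itself is
    deterministic.
    """
    config = config or AnalysisConfig()
    meta: Dict = {
        "n_records": int(len(records)),
        "seed": seed,
        "config_hash": config.config_hash(),
    }

    dis = disability_severity_frame(records, config.cutoffs)
    aff = affect_severity_frame(records, config.affect_grid)
    meta["dropped_disability_undefined"] = int(dis.isna().sum())
    meta["dropped_affect_undefined"] = int(aff.isna().sum())

    matrix = build_indicator_matrix(records, config.indicator_configs)
    meta["missing_indicator_cells"] = int(matrix.isna().to_numpy().sum())
    domains = aggregate_all(matrix, config.domain_rules, config.indicator_configs)

    wv = base_weights(records["selection_prob"])
    if margins:
        sample = records[[m.dimension for m in margins]]
        wv = rake(wv, sample, margins, tol=config.raking_tol, max_iter=config.raking_max_iter)
        meta["raking"] = {
            "iterations": wv.iterations,
            "max_margin_error": wv.max_margin_error,
            "converged": wv.converged,
        }
    else:
        meta["raking"] = None

    gender = records["gender"]
    dis_groups = _group_labels(dis, gender, DISABILITY_LABELS)
    aff_groups = _group_labels(aff, gender, AFFECT_LABELS)

    domain_items = {d: domains[d] for d in domains.columns}
    indicator_items = {c.indicator_id: matrix[c.indicator_id] for c in config.indicator_configs}

    domain_family = run_family(
        domain_items, wv, dis_groups, method=config.test_method,
        m=config.m_domains, grouping="disability_severity_x_gender",
        group_order=DIS_GROUP_ORDER,
    )
    indicator_family = run_family(
        indicator_items, wv, dis_groups, method=config.test_method,
        m=config.m_indicators, grouping="disability_severity_x_gender",
        group_order=DIS_GROUP_ORDER,
    )
    affect_family = run_family(
        domain_items, wv, aff_groups, method=config.test_method,
        m=config.m_domains, grouping="affect_severity_x_gender",
        group_order=AFF_GROUP_ORDER,
    )

    domain_table = domain_family.to_frame()
    indicator_table = indicator_family.to_frame()
    affect_table = affect_family.to_frame()

    gaps = pd.concat(
        [
            compute_gaps(domain_table, metric="inclusion_pct"),
            compute_gaps(indicator_table, metric="exclusion_pct"),
        ],
        ignore_index=True,
    )

    patterns = _severity_patterns(indicator_family, config)
    rankings = _all_rankings(domain_family, config)

    meta["families"] = {
        "domains_m": domain_family.m,
        "indicators_m": indicator_family.m,
        "affect_m": affect_family.m,
    }
    return ResultBundle(
        domain_table=domain_table,
        indicator_table=indicator_table,
        affect_table=affect_table,
        gaps=gaps,
        patterns=patterns,
        rankings=rankings,
        metadata=meta,
        domain_family=domain_family,
        indicator_family=indicator_family,
        affect_family=affect_family,
    )


# ---------------------------------------------------------------------------
# Gap summaries


def _split_group(group: str) -> Tuple[str, str]:
    cls, _, gender = group.rpartition("_")
    return cls, gender


def compute_gaps(table: pd.DataFrame, metric: str = "inclusion_pct") -> pd.DataFrame:
    """Male - female gaps per unit and severity class.

    ``metric`` selects the category compared: ``inclusion_pct`` (lower is
    worse) or ``exclusion_pct`` (higher is worse).  Severity classes missing
    one gender are skipped.  The sign of ``gap`` is male minus female;
    ``worse_off`` names the gender with the worse outcome (empty on ties).
    """
    if metric not in ("inclusion_pct", "exclusion_pct"):
        raise ValueError(f"unknown gap metric {metric!r}")
    category = "included" if metric == "inclusion_pct" else "excluded"
    sub = table[table["category"] == category].copy()
    sub[["severity_class", "gender"]] = sub["group"].map(_split_group).apply(pd.Series)
    rows = []
    for (unit, cls), grp in sub.groupby(["unit_id", "severity_class"], sort=False):
        vals = grp.set_index("gender")["weighted_pct"]
        if "male" not in vals.index or "female" not in vals.index:
            continue
        male, female = float(vals["male"]), float(vals["female"])
        gap = male - female
        if math.isclose(male, female, abs_tol=1e-12):
            worse = ""
        elif metric == "inclusion_pct":
            worse = "female" if female < male else "male"
        else:
            worse = "female" if female > male else "male"
        rows.append(
            {
                "unit_id": unit,
                "severity_class": cls,
                "metric": metric,
                "male": male,
                "female": female,
                "gap": gap,
                "worse_off": worse,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["unit_id", "severity_class", "metric", "male", "female", "gap", "worse_off"],
    )


# ---------------------------------------------------------------------------
# Severity patterns


def classify_severity_pattern(
    exclusion_by_class: Mapping[str, float],
    adjusted_p: float,
    alpha: float = 0.05,
    band: float = 2.0,
) -> str:
    """Label the shape of exclusion rates across the three severity classes.

    Not significant (adjusted p >= alpha, or undefined) dominates; then a
    closeness band: mild and moderate within ``band`` points of each other
    and both above none reads as "mild equals moderate, worse"; then the
    monotone ordering none < mild < moderate; the residual orderings are
    labelled by the class with the highest exclusion.
    """
    try:
        none_, mild, moderate = (
            float(exclusion_by_class[c]) for c in ("none", "mild", "moderate")
        )
    except KeyError as exc:
        raise ValueError(f"missing severity class {exc} in exclusion rates") from None
    if adjusted_p is None or math.isnan(adjusted_p) or adjusted_p >= alpha:
        return "no_significant_difference"
    if abs(mild - moderate) <= band and mild > none_ and moderate > none_:
        return "mild_equals_moderate_worse"
    if none_ < mild < moderate:
        return "monotone_worsening"
    if mild >= none_ and mild >= moderate:
        return "mild_worst"
    return "none_worst"


def pooled_percentages(family: ComparisonFamily, classes: Sequence[str]) -> pd.DataFrame:
    """Category percentages per unit, pooling genders within severity classes
    by their weight mass (one row per unit x class)."""
    rows = []
    for t in family.tables:
        pct = t.percentages
        gw = t.group_weights
        for cls in classes:
            members = [g for g in pct.index if _split_group(g)[0] == cls]
            if not members:
                continue
            wts = gw.loc[members]
            pooled = (pct.loc[members].mul(wts, axis=0)).sum() / wts.sum()
            rows.append({"unit_id": t.unit_id, "severity_class": cls, **pooled.to_dict()})
    return pd.DataFrame(rows)


def _severity_patterns(family: ComparisonFamily, config: AnalysisConfig) -> pd.DataFrame:
    pooled = pooled_percentages(family, DISABILITY_LABELS)
    rows = []
    for t in family.tables:
        sub = pooled[pooled["unit_id"] == t.unit_id].set_index("severity_class")
        excl = sub["excluded"].to_dict()
        label = classify_severity_pattern(
            excl, t.adjusted_p, alpha=config.alpha, band=config.pattern_band
        )
        rows.append(
            {
                "indicator_id": t.unit_id,
                "pattern": label,
                "exclusion_none": excl.get("none", float("nan")),
                "exclusion_mild": excl.get("mild", float("nan")),
                "exclusion_moderate": excl.get("moderate", float("nan")),
                "adjusted_p": t.adjusted_p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Domain prioritisation


@dataclass
class PriorityRanking:
    """Ordered domain list for one targeting approach."""

    approach: str
    ranking: pd.DataFrame  # columns: rank, domain_id, score, tied, above_ceiling

    def domains(self) -> List[str]:
        return list(self.ranking["domain_id"])


def prioritise_domains(
    summary: pd.DataFrame,
    approach: str,
    ceiling: float = 80.0,
    by_exclusion: bool = False,
    comparison: Optional[pd.DataFrame] = None,
) -> PriorityRanking:
    """Rank the nine domains for one policy-targeting approach.

    ``summary`` has one row per domain (index = domain_id) with columns
    ``included``, ``in_between``, ``excluded`` — the pooled percentages for
    the population of interest (e.g. respondents with disabilities).

    * ``closest_to_inclusion`` — highest inclusion first among domains below
      the inclusion ``ceiling`` (preferring large in-between mass on near
      ties); domains already at or above the ceiling are appended last and
      flagged.
    * ``farthest_from_inclusion`` — lowest inclusion first, or highest
      exclusion first when ``by_exclusion`` is set.
    * ``largest_disability_gap`` — largest drop in inclusion relative to
      ``comparison`` (the no-disability summary) first.

    Ties are broken alphabetically and flagged.
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}; choose from {APPROACHES}")
    df = summary.copy()
    df["above_ceiling"] = False
    if approach == "closest_to_inclusion":
        df["above_ceiling"] = df["included"] >= ceiling
        df["score"] = df["included"]
        # stable sort over an alphabetical base => deterministic tie-break
        df = df.sort_index(kind="mergesort").sort_values(
            ["above_ceiling", "score", "in_between"],
            ascending=[True, False, False],
            kind="mergesort",
        )
    elif approach == "farthest_from_inclusion":
        if by_exclusion:
            df["score"] = df["excluded"]
            ascending = False
        else:
            df["score"] = df["included"]
            ascending = True
        df = df.sort_index(kind="mergesort").sort_values(
            "score", ascending=ascending, kind="mergesort"
        )
    else:  # largest_disability_gap
        if comparison is None:
            raise ValueError("largest_disability_gap requires a comparison summary")
        df["score"] = comparison["included"].reindex(df.index) - df["included"]
        df = df.sort_index(kind="mergesort").sort_values(
            "score", ascending=False, kind="mergesort"
        )
    scores = df["score"].round(12)
    tied = scores.duplicated(keep=False)
    ranking = pd.DataFrame(
        {
            "rank": np.arange(1, len(df) + 1),
            "domain_id": df.index,
            "score": df["score"].to_numpy(),
            "tied": tied.to_numpy(),
            "above_ceiling": df["above_ceiling"].to_numpy(),
        }
    )
    return PriorityRanking(approach=approach, ranking=ranking)


def _all_rankings(domain_family: ComparisonFamily, config: AnalysisConfig) -> pd.DataFrame:
    pooled = pooled_percentages(domain_family, DISABILITY_LABELS)
    with_dis = _pool_classes(domain_family, ("mild", "moderate"))
    without = pooled[pooled["severity_class"] == "none"].set_index("unit_id")[
        ["included", "in_between", "excluded"]
    ]
    frames = []
    for approach in APPROACHES:
        pr = prioritise_domains(
            with_dis,
            approach,
            ceiling=config.inclusion_ceiling,
            comparison=without if approach == "largest_disability_gap" else None,
        )
        frame = pr.ranking.copy()
        frame.insert(0, "approach", approach)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _pool_classes(family: ComparisonFamily, classes: Sequence[str]) -> pd.DataFrame:
    """Pool the given severity classes (both genders) by weight mass."""
    rows = {}
    for t in family.tables:
        pct = t.percentages
        gw = t.group_weights
        members = [g for g in pct.index if _split_group(g)[0] in classes]
        wts = gw.loc[members]
        pooled = (pct.loc[members].mul(wts, axis=0)).sum() / wts.sum()
        rows[t.unit_id] = pooled
    out = pd.DataFrame(rows).T
    out.index.name = "unit_id"
    return out[["included", "in_between", "excluded"]]


# ---------------------------------------------------------------------------
# Monte-Carlo simulation (type-I error and power)


def simulate_family_rejections(
    scenario: SyntheticScenario,
    n_reps: int,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    method: str = "pearson_effective_n",
    m: Optional[int] = None,
) -> Dict:
    """Replicate the domain-level comparison family on fresh populations.

    Each replicate generates a population from ``scenario``, classifies it,
    runs the 9-domain family over the six disability x gender groups with
    base design weights, and records which adjusted p-values fall below
    ``alpha``.  Returns the familywise rejection rate and per-domain
    rejection counts — the type-I error under a null scenario, power under
    an effect scenario.
    """
    config = AnalysisConfig(test_method=method, m_domains=m, alpha=alpha)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    per_domain: Dict[str, int] = {}
    family_rejections = 0
    for s in rep_seeds:
        records = generate_population(scenario, seed=int(s))
        dis = disability_severity_frame(records, config.cutoffs)
        matrix = build_indicator_matrix(records, config.indicator_configs)
        domains = aggregate_all(matrix, config.domain_rules, config.indicator_configs)
        wv = base_weights(records["selection_prob"])
        groups = _group_labels(dis, records["gender"], DISABILITY_LABELS)
        family = run_family(
            {d: domains[d] for d in domains.columns},
            wv,
            groups,
            method=method,
            m=m,
            group_order=DIS_GROUP_ORDER,
        )
        rejected = [
            t.unit_id
            for t in family.tables
            if not math.isnan(t.adjusted_p) and t.adjusted_p < alpha
        ]
        if rejected:
            family_rejections += 1
        for d in rejected:
            per_domain[d] = per_domain.get(d, 0) + 1
    return {
        "n_reps": n_reps,
        "alpha": alpha,
        "familywise_rate": family_rejections / n_reps,
        "per_domain_rate": {d: c / n_reps for d, c in sorted(per_domain.items())},
    }
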