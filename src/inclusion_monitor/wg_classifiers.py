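"""Washington Group severity classification.

Disability severity is derived from the WG Short Set (WG-SS): six questions
on core functioning domains (seeing, hearing, walking, cognition, self-care,
communication), each answered on a four-level difficulty scale.  The rule used
here folds severe into moderate and, unlike the WG-recommended reporting
cut-offs, additionally places respondents with five or six "some difficulty"
answers in the moderate class:

* none      -- at most one "some difficulty", nothing above it
* mild      -- two to four "some difficulty", nothing above it
* moderate  -- five or six "some difficulty", or any "a lot of difficulty" /
               "cannot do at all"

Psychosocial ("affect") severity is derived from the WG Extended Set anxiety
and depression items.  Each construct contributes a frequency x intensity
composite on a four-level scale (none/mild/moderate/severe); the respondent
composite is the maximum over the two constructs and is collapsed to a
two-level severity (none/moderate) by merging mild into none.  The exact WG
scoring grid is unpublished, so the grid here is a declared, overridable
default.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "FUNCTIONING_DOMAINS",
    "FUNCTIONING_COLUMN_PREFIX",
    "FunctioningLevel",
    "DisabilitySeverity",
    "AffectFrequency",
    "AffectIntensity",
    "AffectLevel",
    "AffectSeverity",
    "AffectClassification",
    "SeverityCutoffs",
    "DEFAULT_CUTOFFS",
    "ClassificationUndefinedError",
    "classify_disability_severity",
    "classify_affect_severity",
    "affect_level",
    "default_affect_grid",
    "disability_severity_frame",
    "affect_severity_frame",
]

FUNCTIONING_DOMAINS: Tuple[str, ...] = (
    "seeing",
    "hearing",
    "walking",
    "cognition",
    "self_care",
    "communication",
)

#: Column prefix used for functioning responses in microdata frames,
#: e.g. ``wg_seeing``.
FUNCTIONING_COLUMN_PREFIX = "wg_"

AFFECT_CONSTRUCTS: Tuple[str, ...] = ("anxiety", "depression")


class FunctioningLevel(IntEnum):
    """Four-level WG-SS difficulty scale (ordinal)."""

    NO_DIFFICULTY = 0
    SOME_DIFFICULTY = 1
    A_LOT_OF_DIFFICULTY = 2
    CANNOT_DO_AT_ALL = 3


FUNCTIONING_CODES: Mapping[str, FunctioningLevel] = {
    "no_difficulty": FunctioningLevel.NO_DIFFICULTY,
    "some_difficulty": FunctioningLevel.SOME_DIFFICULTY,
    "a_lot_of_difficulty": FunctioningLevel.A_LOT_OF_DIFFICULTY,
    "cannot_do_at_all": FunctioningLevel.CANNOT_DO_AT_ALL,
}

FUNCTIONING_CODE_NAMES: Tuple[str, ...] = tuple(FUNCTIONING_CODES)


class DisabilitySeverity(IntEnum):
    """Three-level disability severity, totally ordered none < mild < moderate."""

    NONE = 0
    MILD = 1
    MODERATE = 2

    @property
    def label(self) -> str:
        return DISABILITY_LABELS[self.value]


DISABILITY_LABELS: Tuple[str, ...] = ("none", "mild", "moderate")


class AffectFrequency(IntEnum):
    NEVER = 0
    A_FEW_TIMES_A_YEAR = 1
    MONTHLY = 2
    WEEKLY = 3
    DAILY = 4


class AffectIntensity(IntEnum):
    A_LITTLE = 0
    IN_BETWEEN = 1
    A_LOT = 2


class AffectLevel(IntEnum):
    """Internal four-level affect composite."""

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3


class AffectSeverity(IntEnum):
    """Collapsed affect severity: mild is merged into none."""

    NONE = 0
    MODERATE = 1


AFFECT_LABELS: Tuple[str, ...] = ("none", "moderate")

FREQUENCY_CODES: Mapping[str, AffectFrequency] = {
    "never": AffectFrequency.NEVER,
    "a_few_times_a_year": AffectFrequency.A_FEW_TIMES_A_YEAR,
    "monthly": AffectFrequency.MONTHLY,
    "weekly": AffectFrequency.WEEKLY,
    "daily": AffectFrequency.DAILY,
}

INTENSITY_CODES: Mapping[str, AffectIntensity] = {
    "a_little": AffectIntensity.A_LITTLE,
    "in_between": AffectIntensity.IN_BETWEEN,
    "a_lot": AffectIntensity.A_LOT,
}


class ClassificationUndefinedError(ValueError):
    """Raised when a severity classification cannot be computed.

    Carries the functioning domains / affect fields whose responses are
    missing or refused so callers can decide to drop or impute.
    """

    def __init__(self, message: str, missing: Iterable[str] = ()):  # noqa: D107
        super().__init__(message)
        self.missing = tuple(missing)


@dataclass(frozen=True)
class SeverityCutoffs:
    """Cut-offs for the disability-severity rule.

    ``many_some_is_moderate`` selects whether five or six "some difficulty"
    answers are classified moderate (the default) or mild (the WG-recommended
    reporting variant, which triggers moderate only on "a lot" / "cannot do").
    """

    none_max_some: int = 1
    mild_max_some: int = 4
    many_some_is_moderate: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.none_max_some <= self.mild_max_some <= len(FUNCTIONING_DOMAINS):
            raise ValueError("cut-offs must satisfy 0 <= none_max_some <= mild_max_some <= 6")


DEFAULT_CUTOFFS = SeverityCutoffs()

LevelLike = Union[FunctioningLevel, int, str, None]


def _coerce_level(value: LevelLike) -> Optional[FunctioningLevel]:
    if value is None:
        return None
    if isinstance(value, str):
        try:
            return FUNCTIONING_CODES[value]
        except KeyError:
            raise ValueError(f"unknown functioning code {value!r}") from None
    if isinstance(value, float) and np.isnan(value):
        return None
    return FunctioningLevel(int(value))


def _coerce_responses(
    responses: Union[Mapping[str, LevelLike], Sequence[LevelLike]],
) -> Mapping[str, Optional[FunctioningLevel]]:
    if isinstance(responses, Mapping):
        unknown = set(responses) - set(FUNCTIONING_DOMAINS)
        if unknown:
            raise ValueError(f"unknown functioning domains: {sorted(unknown)}")
        levels = {d: _coerce_level(responses.get(d)) for d in FUNCTIONING_DOMAINS}
        absent = [d for d in FUNCTIONING_DOMAINS if d not in responses]
        if absent:
            raise ClassificationUndefinedError(
                f"functioning responses absent for domains {absent}", absent
            )
        return levels
    values = list(responses)
    if len(values) != len(FUNCTIONING_DOMAINS):
        raise ValueError(
            f"expected {len(FUNCTIONING_DOMAINS)} functioning responses, got {len(values)}"
        )
    return {d: _coerce_level(v) for d, v in zip(FUNCTIONING_DOMAINS, values)}


def classify_disability_severity(
    responses: Union[Mapping[str, LevelLike], Sequence[LevelLike]],
    cutoffs: SeverityCutoffs = DEFAULT_CUTOFFS,
) -> DisabilitySeverity:
    """Classify disability severity from the six WG-SS functioning responses.

    Parameters
    ----------
    responses
        Either a mapping from functioning domain to level, or a sequence of
        six levels in :data:`FUNCTIONING_DOMAINS` order.  Levels may be
        :class:`FunctioningLevel`, integer codes 0-3, or string codes such as
        ``"some_difficulty"``.
    cutoffs
        Severity cut-offs; the default is the study variant.

    Raises
    ------
    ClassificationUndefinedError
        If any functioning response is missing or refused.  The error lists
        the offending domains; the caller decides whether to drop or impute.
    """
    levels = _coerce_responses(responses)
    missing = [d for d, v in levels.items() if v is None]
    if missing:
        raise ClassificationUndefinedError(
            f"functioning response missing for domains {missing}", missing
        )
    values = [int(levels[d]) for d in FUNCTIONING_DOMAINS]
    some = sum(v == FunctioningLevel.SOME_DIFFICULTY for v in values)
    if any(v >= FunctioningLevel.A_LOT_OF_DIFFICULTY for v in values):
        return DisabilitySeverity.MODERATE
    if cutoffs.many_some_is_moderate and some > cutoffs.mild_max_some:
        return DisabilitySeverity.MODERATE
    if some <= cutoffs.none_max_some:
        return DisabilitySeverity.NONE
    return DisabilitySeverity.MILD


# ---------------------------------------------------------------------------
# Affect composite


def default_affect_grid() -> dict:
    """Default frequency x intensity scoring grid for one affect construct.

    The WG combination rule is unpublished, so this monotone grid is a
    declared stand-in: severe requires daily + a-lot; moderate requires
    daily + in-between or weekly + a-lot; mild covers daily + a-little,
    weekly + a-little / in-between, and monthly + a-lot; everything else is
    none.  Replace via the ``grid`` argument or the analysis configuration.
    """
    F, I, L = AffectFrequency, AffectIntensity, AffectLevel
    grid = {(f, i): L.NONE for f in F for i in I if f != F.NEVER}
    grid[(F.DAILY, I.A_LOT)] = L.SEVERE
    grid[(F.DAILY, I.IN_BETWEEN)] = L.MODERATE
    grid[(F.WEEKLY, I.A_LOT)] = L.MODERATE
    grid[(F.DAILY, I.A_LITTLE)] = L.MILD
    grid[(F.WEEKLY, I.IN_BETWEEN)] = L.MILD
    grid[(F.WEEKLY, I.A_LITTLE)] = L.MILD
    grid[(F.MONTHLY, I.A_LOT)] = L.MILD
    return grid


def _coerce_frequency(value) -> Optional[AffectFrequency]:
    if value is None:
        return None
    if isinstance(value, str):
        try:
            return FREQUENCY_CODES[value]
        except KeyError:
            raise ValueError(f"unknown affect frequency code {value!r}") from None
    if isinstance(value, float) and np.isnan(value):
        return None
    return AffectFrequency(int(value))


def _coerce_intensity(value) -> Optional[AffectIntensity]:
    if value is None or (isinstance(value, str) and value == ""):
        return None
    if isinstance(value, str):
        try:
            return INTENSITY_CODES[value]
        except KeyError:
            raise ValueError(f"unknown affect intensity code {value!r}") from None
    if isinstance(value, float) and np.isnan(value):
        return None
    return AffectIntensity(int(value))


def affect_level(
    frequency,
    intensity=None,
    grid: Optional[Mapping] = None,
    construct: str = "",
) -> AffectLevel:
    """Four-level composite for one construct from its frequency and intensity."""
    freq = _coerce_frequency(frequency)
    if freq is None:
        raise ClassificationUndefinedError(
            f"affect frequency missing for {construct or 'construct'}",
            [f"{construct}_frequency" if construct else "frequency"],
        )
    if freq == AffectFrequency.NEVER:
        return AffectLevel.NONE
    inten = _coerce_intensity(intensity)
    if inten is None:
        raise ClassificationUndefinedError(
            f"affect intensity missing for {construct or 'construct'} "
            "although frequency is not 'never'",
            [f"{construct}_intensity" if construct else "intensity"],
        )
    if grid is None:
        grid = default_affect_grid()
    return AffectLevel(grid[(freq, inten)])


@dataclass(frozen=True)
class AffectClassification:
    """Collapsed affect severity together with the four-level composite."""

    severity: AffectSeverity
    internal_level: AffectLevel

    def __post_init__(self) -> None:
        expected = (
            AffectSeverity.MODERATE
            if self.internal_level >= AffectLevel.MODERATE
            else AffectSeverity.NONE
        )
        if self.severity != expected:
            raise ValueError("severity inconsistent with internal level")


def classify_affect_severity(
    anxiety: Tuple,
    depression: Tuple,
    grid: Optional[Mapping] = None,
) -> AffectClassification:
    """Classify affect severity from anxiety and depression responses.

    Each construct is given as a ``(frequency, intensity)`` pair; intensity
    must be ``None`` exactly when frequency is ``"never"``.  The respondent
    composite is the maximum of the two construct levels; mild and none
    collapse to none, moderate and severe to moderate.
    """
    level = max(
        affect_level(*anxiety, grid=grid, construct="anxiety"),
        affect_level(*depression, grid=grid, construct="depression"),
    )
    severity = (
        AffectSeverity.MODERATE if level >= AffectLevel.MODERATE else AffectSeverity.NONE
    )
    return AffectClassification(severity, level)


# ---------------------------------------------------------------------------
# Vectorised helpers for microdata frames


def _grid_array(grid: Optional[Mapping]) -> np.ndarray:
    if grid is None:
        grid = default_affect_grid()
    arr = np.zeros((len(AffectFrequency), len(AffectIntensity)), dtype=np.int8)
    for (f, i), lvl in grid.items():
        arr[int(f), int(i)] = int(lvl)
    return arr


def disability_severity_frame(
    frame: pd.DataFrame,
    cutoffs: SeverityCutoffs = DEFAULT_CUTOFFS,
    prefix: str = FUNCTIONING_COLUMN_PREFIX,
) -> pd.Series:
    """Row-wise disability severity for a microdata frame.

    Expects string-coded columns ``wg_<domain>``.  Rows with any missing or
    unmapped functioning response get ``NA`` (the pipeline drops and counts
    them rather than imputing).
    """
    cols = [f"{prefix}{d}" for d in FUNCTIONING_DOMAINS]
    levels = np.full((len(frame), len(cols)), -1, dtype=np.int8)
    code_map = {k: int(v) for k, v in FUNCTIONING_CODES.items()}
    for j, col in enumerate(cols):
        levels[:, j] = frame[col].map(code_map).fillna(-1).to_numpy(dtype=np.int8)
    valid = (levels >= 0).all(axis=1)
    some = (levels == int(FunctioningLevel.SOME_DIFFICULTY)).sum(axis=1)
    above = (levels >= int(FunctioningLevel.A_LOT_OF_DIFFICULTY)).any(axis=1)
    sev = np.full(len(frame), int(DisabilitySeverity.MILD), dtype=np.int8)
    sev[some <= cutoffs.none_max_some] = int(DisabilitySeverity.NONE)
    if cutoffs.many_some_is_moderate:
        sev[some > cutoffs.mild_max_some] = int(DisabilitySeverity.MODERATE)
    sev[above] = int(DisabilitySeverity.MODERATE)
    out = pd.Series(sev, index=frame.index, dtype="Int8", name="disability_severity")
    out[~valid] = pd.NA
    return out


def affect_severity_frame(
    frame: pd.DataFrame,
    grid: Optional[Mapping] = None,
) -> pd.Series:
    """Row-wise collapsed affect severity for a microdata frame.

    Expects columns ``anxiety_frequency``, ``anxiety_intensity``,
    ``depression_frequency``, ``depression_intensity``; intensities are blank
    when the matching frequency is ``"never"``.  Undefined rows get ``NA``.
    """
    arr = _grid_array(grid)
    n = len(frame)
    level = np.zeros(n, dtype=np.int8)
    valid = np.ones(n, dtype=bool)
    fmap = {k: int(v) for k, v in FREQUENCY_CODES.items()}
    imap = {k: int(v) for k, v in INTENSITY_CODES.items()}
    for construct in AFFECT_CONSTRUCTS:
        freq = frame[f"{construct}_frequency"].map(fmap).fillna(-1).to_numpy(dtype=np.int8)
        inten_raw = frame[f"{construct}_intensity"]
        inten = inten_raw.map(imap).fillna(-1).to_numpy(dtype=np.int8)
        valid &= freq >= 0
        never = freq == int(AffectFrequency.NEVER)
        valid &= never | (inten >= 0)
        lv = np.zeros(n, dtype=np.int8)
        ok = (freq > 0) & (inten >= 0)
        lv[ok] = arr[freq[ok], inten[ok]]
        level = np.maximum(level, lv)
    sev = (level >= int(AffectLevel.MODERATE)).astype(np.int8)
    out = pd.Series(sev, index=frame.index, dtype="Int8", name="affect_severity")
    out[~valid] = pd.NA
    return out


@functools.lru_cache(maxsize=8)
def severity_partition(cutoffs: SeverityCutoffs = DEFAULT_CUTOFFS) -> Mapping[str, np.ndarray]:
    """Partition of all 4^6 functioning patterns by severity class.

    Returns a mapping from severity label to an ``(n_patterns, 6)`` int8
    array of levels.  Used by the synthetic generator so that generated
    patterns classify back to their assigned class by construction.
    """
    buckets: dict = {label: [] for label in DISABILITY_LABELS}
    for pattern in itertools.product(range(4), repeat=len(FUNCTIONING_DOMAINS)):
        sev = classify_disability_severity(pattern, cutoffs)
        buckets[sev.label].append(pattern)
    return {k: np.asarray(v, dtype=np.int8) for k, v in buckets.items()}


@functools.lru_cache(maxsize=2)
def affect_partition(grid_items: Optional[tuple] = None) -> Mapping[str, np.ndarray]:
    """Partition of all joint anxiety x depression response cells by severity.

    Each row of the returned arrays is ``(anx_freq, anx_int, dep_freq,
    dep_int)`` with -1 marking an absent intensity (frequency "never").
    """
    grid = dict(grid_items) if grid_items is not None else default_affect_grid()
    cells = [(AffectFrequency.NEVER, None)] + [
        (f, i) for f in AffectFrequency if f != AffectFrequency.NEVER for i in AffectIntensity
    ]
    buckets: dict = {label: [] for label in AFFECT_LABELS}
    for (af, ai), (df_, di) in itertools.product(cells, repeat=2):
        cls = classify_affect_severity((af, ai), (df_, di), grid=grid)
        row = (
            int(af),
            -1 if ai is None else int(ai),
            int(df_),
            -1 if di is None else int(di),
        )
        buckets[AFFECT_LABELS[int(cls.severity)]].append(row)
    return {k: np.asarray(v, dtype=np.int8) for k, v in buckets.items()}
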