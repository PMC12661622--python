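"""Composite cognitive scoring and outcome classification.

The composite cognitive score is the unweighted mean of six z-scores —
MoCA plus one task per cognitive domain (inverted Stroop colour-naming
time, category fluency, letter fluency, recognition memory, Hooper visual
organization) — each referenced to control performance at baseline.
Timed ("lower is better") tests are sign-flipped before z-scoring so that
negative always means impairment.

Mild cognitive impairment (MCI) uses the 1.5-SD criterion: performance
below -1.5 SD in two tests of one domain, or one test in each of two
domains, persisting across consecutive assessed sessions. A poor cognitive
outcome is any of death, frailty, dementia, or MCI during follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import ValidationError

#: direction: +1 higher-is-better, -1 lower-is-better (timed tests)
#: The six components of the composite score.
COMPOSITE_TESTS: dict[str, int] = {
    "moca": +1,
    "stroop_colour_time": -1,
    "category_fluency": +1,
    "letter_fluency": +1,
    "recognition_memory": +1,
    "hooper": +1,
}

#: Two tests per cognitive domain (first test of each also feeds the composite).
DOMAIN_TESTS: dict[str, tuple[str, str]] = {
    "attention": ("stroop_colour_time", "digit_span"),
    "executive": ("letter_fluency", "trail_making_b"),
    "memory": ("recognition_memory", "word_recall"),
    "language": ("category_fluency", "naming"),
    "visuospatial": ("hooper", "cube_copy"),
}

TEST_DIRECTIONS: dict[str, int] = {
    **COMPOSITE_TESTS,
    "digit_span": +1,
    "trail_making_b": -1,
    "word_recall": +1,
    "naming": +1,
    "cube_copy": +1,
}

#: Synthetic control-baseline reference statistics (mean, SD) per test, on
#: plausible raw scales; real analyses substitute the observed control stats.
DEFAULT_CONTROL_STATS: dict[str, tuple[float, float]] = {
    "moca": (28.9, 1.3),
    "stroop_colour_time": (62.0, 14.0),
    "category_fluency": (21.0, 5.0),
    "letter_fluency": (44.0, 11.0),
    "recognition_memory": (46.0, 4.0),
    "hooper": (25.0, 2.5),
    "digit_span": (6.5, 1.2),
    "trail_making_b": (75.0, 25.0),
    "word_recall": (8.0, 2.0),
    "naming": (27.0, 2.0),
    "cube_copy": (10.5, 1.5),
}


def zscore_test(
    value: float, test: str, control_stats: Mapping[str, tuple[float, float]]
) -> float:
    """Control-referenced z with impairment always negative."""
    mean, sd = control_stats[test]
    if sd <= 0:
        raise ValidationError(f"control SD for {test} must be > 0")
    direction = TEST_DIRECTIONS.get(test, +1)
    return direction * (value - mean) / sd


@dataclass
class CompositeResult:
    score: float  # NaN when no component is available
    n_components: int
    missing: tuple[str, ...]

    @property
    def complete(self) -> bool:
        return not self.missing


def composite_cognitive_score(
    scores: Mapping[str, float],
    control_stats: Mapping[str, tuple[float, float]] | None = None,
) -> CompositeResult:
    """Mean of the six control-referenced component z-scores.

    Missing components shrink the mean's denominator and are reported; a
    fully missing battery yields NaN with all six flagged.
    """
    stats = control_stats or DEFAULT_CONTROL_STATS
    zs: list[float] = []
    missing: list[str] = []
    for test in COMPOSITE_TESTS:
        v = scores.get(test)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            missing.append(test)
            continue
        zs.append(zscore_test(float(v), test, stats))
    score = sum(zs) / len(zs) if zs else float("nan")
    return CompositeResult(score=score, n_components=len(zs), missing=tuple(missing))


def session_meets_mci_criterion(
    domain_z: Mapping[str, Mapping[str, float]], threshold_sd: float = 1.5
) -> bool:
    """One session's 1.5-SD rule: >=2 impaired tests in one domain, or
    >=1 impaired test in each of >=2 domains. ``domain_z`` maps domain ->
    {test: z}; z below ``-threshold_sd`` counts as impaired."""
    impaired_per_domain = {
        dom: sum(1 for z in tests.values() if z < -threshold_sd)
        for dom, tests in domain_z.items()
    }
    if any(n >= 2 for n in impaired_per_domain.values()):
        return True
    return sum(1 for n in impaired_per_domain.values() if n >= 1) >= 2


def classify_mci(
    sessions_z: pd.DataFrame, threshold_sd: float = 1.5, consecutive: int = 2
) -> bool:
    """Persistent MCI: the criterion met at ``consecutive`` consecutive
    assessed sessions.

    ``sessions_z`` is long-format with columns (session, domain, test, z).
    "Consecutive" counts over the sessions actually assessed, in order.
    """
    required = {"session", "domain", "test", "z"}
    if not required.issubset(sessions_z.columns):
        raise ValidationError(f"sessions_z needs columns {sorted(required)}")
    if sessions_z.empty:
        raise ValidationError("no sessions with any scores")
    meets: list[bool] = []
    for _, sess in sessions_z.groupby("session", sort=True):
        domain_z = {
            dom: dict(zip(d["test"], d["z"])) for dom, d in sess.groupby("domain")
        }
        meets.append(session_meets_mci_criterion(domain_z, threshold_sd))
    run = 0
    for m in meets:
        run = run + 1 if m else 0
        if run >= consecutive:
            return True
    return False


OUTCOME_EVENTS = ("death", "frailty", "dementia", "mci")


@dataclass(frozen=True)
class OutcomeLabel:
    label: str  # "good" | "poor"
    reasons: frozenset[str]

    def __post_init__(self) -> None:
        if (self.label == "poor") != bool(self.reasons):
            raise ValidationError("poor outcome iff at least one reason")


def classify_outcome(events: Mapping[str, bool]) -> OutcomeLabel:
    """Poor outcome iff any of death / frailty / dementia / MCI occurred;
    reasons accumulate (a subject may have several)."""
    reasons = frozenset(e for e in OUTCOME_EVENTS if events.get(e, False))
    return OutcomeLabel(label="poor" if reasons else "good", reasons=reasons)
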