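"""Windowed behavior probability and duration statistics with inclusion filters.

Tracker output (per-animal tracked intervals, collision intervals and behavior
bouts) is summarized over an analysis window anchored at stimulus onset (15 s
for optogenetic or vibration stimuli, 40 s for thermogenetic activation, whose
onset is the moment the plate reaches 35 C). An animal enters the analysis
only if it was tracked for at least 95% of the window and had no collision
overlapping it. The behavior probability is the proportion of valid animals
performing the behavior at least once in the window (a bout counts if it
intersects the window at all); durations are per-animal total bout time
clipped to the window. Probabilities are compared with a chi-square test of
proportions and durations with a two-sided (Welch) t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import stat_tests

__all__ = [
    "WINDOW_OPTOGENETIC_S",
    "WINDOW_THERMOGENETIC_S",
    "MIN_COVERAGE",
    "Interval",
    "Bout",
    "AnimalTrack",
    "AnalysisWindow",
    "BehaviorSummary",
    "valid_animals",
    "behavior_probability",
    "behavior_duration",
    "compare_groups",
    "load_tracks",
]

WINDOW_OPTOGENETIC_S = 15.0  # optogenetic activation or vibration stimulus
WINDOW_THERMOGENETIC_S = 40.0  # thermogenetic activation (slow temperature ramp)
MIN_COVERAGE = 0.95

Interval = tuple[float, float]


@dataclass(frozen=True)
class Bout:
    behavior: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if not self.start_s < self.end_s:
            raise ValueError("bout start must precede end")


@dataclass
class AnimalTrack:
    animal_id: str
    group: str = ""
    tracked_intervals: list[Interval] = field(default_factory=list)
    collision_intervals: list[Interval] = field(default_factory=list)
    bouts: list[Bout] = field(default_factory=list)


@dataclass(frozen=True)
class AnalysisWindow:
    onset_s: float
    length_s: float = WINDOW_OPTOGENETIC_S
    onset_rule: str = "stimulus_onset"  # or "plate_reached_35C"

    def __post_init__(self):
        if self.length_s <= 0:
            raise ValueError("window length must be positive")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.length_s


@dataclass(frozen=True)
class BehaviorSummary:
    behavior: str
    n_valid: int
    n_responding: int
    probability: float
    ci95: tuple[float, float]
    duration_mean: float | None
    duration_se: float | None


def _overlap(a: Interval, b: Interval) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def valid_animals(
    tracks: Iterable[AnimalTrack],
    window: AnalysisWindow,
    min_coverage: float = MIN_COVERAGE,
) -> tuple[list[AnimalTrack], dict[str, str]]:
    """Apply the tracking-coverage and collision inclusion filters.

    An animal is included iff its tracked time overlapping the window is at
    least ``min_coverage`` of the window length and no collision interval
    intersects the window (any overlap, however brief, excludes it). Returns
    the included tracks and an exclusion log mapping animal id to reason.
    """
    win = (window.onset_s, window.end_s)
    included: list[AnimalTrack] = []
    excluded: dict[str, str] = {}
    for track in tracks:
        covered = sum(_overlap(iv, win) for iv in track.tracked_intervals)
        if covered < min_coverage * window.length_s:
            excluded[track.animal_id] = (
                f"coverage {covered / window.length_s:.3f} < {min_coverage}"
            )
            continue
        if any(_overlap(iv, win) > 0 for iv in track.collision_intervals):
            excluded[track.animal_id] = "collision during window"
            continue
        included.append(track)
    return included, excluded


def _responded(track: AnimalTrack, behavior: str, window: AnalysisWindow) -> bool:
    win = (window.onset_s, window.end_s)
    return any(
        b.behavior == behavior and _overlap((b.start_s, b.end_s), win) > 0
        for b in track.bouts
    )


def _animal_duration(track: AnimalTrack, behavior: str, window: AnalysisWindow) -> float:
    win = (window.onset_s, window.end_s)
    return sum(
        _overlap((b.start_s, b.end_s), win)
        for b in track.bouts
        if b.behavior == behavior
    )


def behavior_probability(
    tracks: Iterable[AnimalTrack],
    behavior: str,
    window: AnalysisWindow,
    min_coverage: float = MIN_COVERAGE,
    ci_method: str = "wilson",
) -> BehaviorSummary:
    """Proportion of valid animals performing the behavior in the window.

    Pooled across all trials: every valid animal is one Bernoulli observation.
    The 95% CI is a Wilson score interval by default (Wald available). The
    duration fields summarize per-animal total bout time (clipped to the
    window) over responding animals; the SE is undefined (None) with fewer
    than two responders.
    """
    included, _ = valid_animals(tracks, window, min_coverage)
    if not included:
        raise ValueError("no valid animals in the analysis window")
    responders = [t for t in included if _responded(t, behavior, window)]
    n_valid, n_resp = len(included), len(responders)
    durations = np.array(
        [_animal_duration(t, behavior, window) for t in responders], dtype=float
    )
    return BehaviorSummary(
        behavior=behavior,
        n_valid=n_valid,
        n_responding=n_resp,
        probability=n_resp / n_valid,
        ci95=stat_tests.proportion_ci(n_resp, n_valid, method=ci_method),
        duration_mean=float(durations.mean()) if n_resp else None,
        duration_se=float(durations.std(ddof=1) / np.sqrt(n_resp))
        if n_resp >= 2
        else None,
    )


def behavior_duration(
    tracks: Iterable[AnimalTrack],
    behavior: str,
    window: AnalysisWindow,
    min_coverage: float = MIN_COVERAGE,
) -> tuple[np.ndarray, float, float | None]:
    """Per-animal window-clipped bout durations over valid responding animals.

    Returns ``(durations, mean, se)``; the SE is None (flagged undefined)
    with fewer than two responding animals.
    """
    included, _ = valid_animals(tracks, window, min_coverage)
    durations = np.array(
        [
            _animal_duration(t, behavior, window)
            for t in included
            if _responded(t, behavior, window)
        ],
        dtype=float,
    )
    if durations.size == 0:
        return durations, float("nan"), None
    se = (
        float(durations.std(ddof=1) / np.sqrt(durations.size))
        if durations.size >= 2
        else None
    )
    return durations, float(durations.mean()), se


def compare_groups(
    a,
    b,
    what: str = "probability",
    continuity: bool = False,
) -> stat_tests.TestResult:
    """Compare two cohorts on response probability or duration.

    For ``what="probability"``, ``a``/``b`` are :class:`BehaviorSummary`
    objects and the test is a chi-square on responder/non-responder counts
    (continuity correction off by default). For ``what="duration"``,
    ``a``/``b`` are per-animal duration arrays and the test is a two-sided
    Welch t test.
    """
    if what == "probability":
        table = [
            [a.n_responding, a.n_valid - a.n_responding],
            [b.n_responding, b.n_valid - b.n_responding],
        ]
        return stat_tests.chi_square_proportions(table, continuity=continuity)
    if what == "duration":
        return stat_tests.t_test(a, b, alternative=stat_tests.TWO_SIDED)
    raise ValueError("what must be 'probability' or 'duration'")


def load_tracks(path) -> list[AnimalTrack]:
    """Read tracks from a long-format CSV.

    Columns: animal_id, group, interval_type in {tracked, collision, bout},
    behavior (empty except for bouts), start_s, end_s.
    """
    df = pd.read_csv(path)
    tracks: dict[str, AnimalTrack] = {}
    for r in df.itertuples():
        aid = str(r.animal_id)
        track = tracks.setdefault(
            aid, AnimalTrack(animal_id=aid, group=str(getattr(r, "group", "")))
        )
        iv = (float(r.start_s), float(r.end_s))
        if r.interval_type == "tracked":
            track.tracked_intervals.append(iv)
        elif r.interval_type == "collision":
            track.collision_intervals.append(iv)
        elif r.interval_type == "bout":
            track.bouts.append(Bout(str(r.behavior), *iv))
        else:
            raise ValueError(f"unknown interval_type {r.interval_type!r}")
    return list(tracks.values())
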