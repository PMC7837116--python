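"""dF/F0 computation and response scoring for stimulus-locked calcium trials.

A trial is a uniformly sampled fluorescence trace (nominally 6.61 frames/s)
with one stimulus epoch. The baseline F0 is the median of the whole trace;
dF/F0 = (F_t - F0)/F0. The peak response is the maximum dF/F0 in the 4.5 s
window immediately after stimulation offset minus the recent baseline (mean
dF/F0 over the 3 s preceding stimulation onset). A trial counts as
non-responding -- and is discarded from per-animal averages -- when the mean
dF/F0 of that post-stimulation window stays within +-k standard deviations of
the recent baseline (k = 1.5 for mechanosensory stimulation, 0.5 for
nociceptive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import stat_tests

__all__ = [
    "PEAK_WINDOW_S",
    "BASELINE_WINDOW_S",
    "K_MECHANOSENSORY",
    "K_NOCICEPTIVE",
    "CalciumTrial",
    "ResponseScore",
    "delta_f_over_f",
    "peak_response",
    "classify_response",
    "score_trial",
    "animal_summary",
    "group_comparison",
    "load_trials",
]

PEAK_WINDOW_S = 4.5  # scored window after stimulation offset
BASELINE_WINDOW_S = 3.0  # recent-baseline window before stimulation onset
K_MECHANOSENSORY = 1.5  # rejection-band SD multiplier per modality
K_NOCICEPTIVE = 0.5
_MODALITY_K = {"mechanosensory": K_MECHANOSENSORY, "nociceptive": K_NOCICEPTIVE}


@dataclass(frozen=True)
class CalciumTrial:
    times: np.ndarray  # seconds, uniform sampling
    fluorescence: np.ndarray  # arbitrary units per frame
    stim_onset: float
    stim_offset: float
    modality: str = "mechanosensory"
    animal_id: str = ""
    trial_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("times and fluorescence must be equal-length 1-D arrays")
        if not self.stim_onset < self.stim_offset:
            raise ValueError("stimulus onset must precede offset")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluorescence", f)

    @property
    def k(self) -> float:
        return _MODALITY_K[self.modality]


@dataclass(frozen=True)
class ResponseScore:
    animal_id: str
    trial_id: str
    recent_baseline: float
    peak: float
    responded: bool
    k: float


def delta_f_over_f(trial: CalciumTrial) -> np.ndarray:
    """(F_t - F0)/F0 with F0 the median of the whole trace."""
    f0 = float(np.median(trial.fluorescence))
    if f0 == 0:
        raise ValueError("zero median fluorescence: dF/F0 undefined")
    return (trial.fluorescence - f0) / f0


def _windows(trial: CalciumTrial) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks for the recent-baseline and post-offset windows.

    Baseline: [onset - 3 s, onset); response: (offset, offset + 4.5 s].
    Half-open ends avoid double-counting boundary frames.
    """
    t = trial.times
    baseline = (t >= trial.stim_onset - BASELINE_WINDOW_S) & (t < trial.stim_onset)
    window = (t > trial.stim_offset) & (t <= trial.stim_offset + PEAK_WINDOW_S)
    if not baseline.any():
        raise ValueError("no samples in the 3 s recent-baseline window before onset")
    if not window.any():
        raise ValueError("no samples in the 4.5 s window after stimulation offset")
    return baseline, window


def peak_response(trial: CalciumTrial) -> float:
    """Relative maximum dF/F0: post-offset window max minus recent baseline."""
    dff = delta_f_over_f(trial)
    baseline, window = _windows(trial)
    return float(dff[window].max() - dff[baseline].mean())


def classify_response(trial: CalciumTrial, k: float | None = None) -> bool:
    """True when the post-stimulation mean leaves the +-k.SD rejection band.

    The SD is the sample SD of the per-frame dF/F0 over the 3 s recent
    baseline. A zero-variance baseline responds iff the window mean differs
    from it at all.
    """
    if k is None:
        k = trial.k
    dff = delta_f_over_f(trial)
    baseline, window = _windows(trial)
    base_mean = dff[baseline].mean()
    base_sd = dff[baseline].std(ddof=1) if baseline.sum() > 1 else 0.0
    deviation = abs(dff[window].mean() - base_mean)
    if base_sd == 0.0:
        return bool(deviation > 0.0)
    return bool(deviation > k * base_sd)


def score_trial(trial: CalciumTrial, k: float | None = None) -> ResponseScore:
    return ResponseScore(
        animal_id=trial.animal_id,
        trial_id=trial.trial_id,
        recent_baseline=float(
            delta_f_over_f(trial)[_windows(trial)[0]].mean()
        ),
        peak=peak_response(trial),
        responded=classify_response(trial, k),
        k=trial.k if k is None else k,
    )


def animal_summary(
    scores: Iterable[ResponseScore],
) -> tuple[dict[str, float], list[str]]:
    """Mean peak of responding trials per animal.

    Returns ``(per_animal_mean_peak, excluded_animals)``; animals whose trials
    all failed the response criterion are excluded from the averages and
    listed separately.
    """
    peaks: dict[str, list[float]] = {}
    seen: dict[str, bool] = {}
    for s in scores:
        seen.setdefault(s.animal_id, False)
        if s.responded:
            peaks.setdefault(s.animal_id, []).append(s.peak)
            seen[s.animal_id] = True
    means = {a: float(np.mean(v)) for a, v in peaks.items()}
    excluded = sorted(a for a, ok in seen.items() if not ok)
    return means, excluded


def group_comparison(
    experimental: Sequence[float],
    control: Sequence[float],
    alternative: str = stat_tests.GREATER,
) -> stat_tests.TestResult:
    """Single-sided Wilcoxon rank-sum comparison of per-animal peak responses."""
    return stat_tests.wilcoxon_rank_sum(experimental, control, alternative=alternative)


def load_trials(trials_csv, stims_csv) -> list[CalciumTrial]:
    """Assemble trials from a trace table and a stimulus table.

    ``trials_csv``: columns animal_id, trial_id, time_s, fluorescence.
    ``stims_csv``: columns trial_id, onset_s, offset_s, modality.
    """
    traces = pd.read_csv(trials_csv)
    stims = pd.read_csv(stims_csv).set_index("trial_id")
    trials = []
    for (animal, trial_id), grp in traces.groupby(["animal_id", "trial_id"]):
        stim = stims.loc[trial_id]
        grp = grp.sort_values("time_s")
        trials.append(
            CalciumTrial(
                times=grp["time_s"].to_numpy(float),
                fluorescence=grp["fluorescence"].to_numpy(float),
                stim_onset=float(stim["onset_s"]),
                stim_offset=float(stim["offset_s"]),
                modality=str(stim["modality"]),
                animal_id=str(animal),
                trial_id=str(trial_id),
            )
        )
    return trials
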