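"""Trial schedules and intermittent neurofeedback scoring.

Implements the online feedback computation of an intermittent
target-level neurofeedback protocol: per trial, the region-of-interest
percent signal change of the imagery period relative to its preceding
baseline window is normalised by the participant's MaxPSC onto a 0-12
scale, where 10 marks the MaxPSC and the two target levels (60% and 90%)
sit at 6 and 9.

Scoring windows follow the BOLD-delay convention: the baseline is the
mean of the six volumes in [-4, +2) s around imagery onset, the imagery
value the mean of the ten volumes in [+6, +16) s (at TR = 1 s).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .volume import VolumeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "Trial",
    "TrialSchedule",
    "TrialTiming",
    "NFRecord",
    "build_session_schedule",
    "window_indices",
    "extract_windows",
    "trial_psc",
    "normalize_feedback",
    "score_run",
    "TARGET_SCALE_POSITIONS",
    "BASELINE_WINDOW_S",
    "IMAGERY_WINDOW_S",
    "SCALE_MIN",
    "SCALE_MAX",
]

#: Scale positions of the two target levels on the 0-12 feedback scale.
TARGET_SCALE_POSITIONS = {60: 6.0, 90: 9.0}
#: Baseline window relative to imagery onset, half-open, seconds.
BASELINE_WINDOW_S = (-4.0, 2.0)
#: Imagery window relative to imagery onset, half-open, seconds.
IMAGERY_WINDOW_S = (6.0, 16.0)
SCALE_MIN = 0.0
SCALE_MAX = 12.0


@dataclass(frozen=True)
class TrialTiming:
    """Within-trial event durations, seconds.

    Each trial is rest, imagery, a jittered blank, the prediction rating,
    a second jittered blank, the confidence rating, and the feedback
    display. Jitters are 1-3 s in the protocol; the default fixes them at
    the 2 s midpoint so volume counts are deterministic.
    """

    rest_s: float = 16.0
    imagery_s: float = 16.0
    jitter_s: float = 2.0
    rating_s: float = 6.0
    feedback_s: float = 2.0

    @property
    def trial_duration_s(self) -> float:
        return (
            self.rest_s
            + self.imagery_s
            + 2 * self.jitter_s
            + 2 * self.rating_s
            + self.feedback_s
        )


@dataclass(frozen=True)
class Trial:
    onset_s: float  # imagery-period onset within the run
    target_level: int  # 60 or 90
    catch: bool = False
    instructed_prediction: int | None = None
    instructed_confidence: int | None = None

    def __post_init__(self) -> None:
        if self.target_level not in TARGET_SCALE_POSITIONS:
            raise ValueError(f"unknown target level {self.target_level}")


@dataclass
class TrialSchedule:
    """Ordered trials of one neurofeedback run."""

    trials: list[Trial]
    run_duration_s: float
    timing: TrialTiming = field(default_factory=TrialTiming)

    def __len__(self) -> int:
        return len(self.trials)

    def n_volumes(self, tr_s: float) -> int:
        n = self.run_duration_s / tr_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"run duration {self.run_duration_s}s is not an integer "
                f"number of volumes at TR {tr_s}s"
            )
        return int(round(n))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "run_duration_s": self.run_duration_s,
            "timing": asdict(self.timing),
            "trials": [asdict(t) for t in self.trials],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrialSchedule":
        payload = json.loads(Path(path).read_text())
        return cls(
            trials=[Trial(**t) for t in payload["trials"]],
            run_duration_s=payload["run_duration_s"],
            timing=TrialTiming(**payload["timing"]),
        )


@dataclass
class NFRecord:
    """One scored neurofeedback trial."""

    participant: int
    session: int
    run: int
    trial: int
    target_level: int
    catch: bool
    psc_raw: float  # percent signal change before normalisation
    nf_value: float  # 0-12 scale, clipped
    prediction: float = math.nan  # 0-12 integer once rated
    confidence: float = math.nan  # 50-100 step 5 once rated


def build_session_schedule(
    n_runs: int = 6,
    trials_per_run: int = 10,
    seed: int | np.random.SeedSequence = 0,
    timing: TrialTiming | None = None,
) -> list[TrialSchedule]:
    """Pseudorandomised schedules for one session.

    Each run gets an equal split of the two target levels in random order
    and exactly one catch trial at a uniformly random non-first position,
    with instructed prediction (0-12) and confidence (50-100 step 5)
    values drawn for it. Deterministic under the seed.
    """
    if trials_per_run % 2:
        raise ValueError("trials_per_run must be even for a balanced TL split")
    timing = timing or TrialTiming()
    rng = np.random.default_rng(seed)
    schedules = []
    for _ in range(n_runs):
        levels = np.repeat([60, 90], trials_per_run // 2)
        rng.shuffle(levels)
        catch_pos = int(rng.integers(1, trials_per_run))
        trials = []
        for k, tl in enumerate(levels):
            onset = k * timing.trial_duration_s + timing.rest_s
            is_catch = k == catch_pos
            trials.append(
                Trial(
                    onset_s=onset,
                    target_level=int(tl),
                    catch=is_catch,
                    instructed_prediction=int(rng.integers(0, 13)) if is_catch else None,
                    instructed_confidence=int(50 + 5 * rng.integers(0, 11))
                    if is_catch
                    else None,
                )
            )
        schedules.append(
            TrialSchedule(
                trials=trials,
                run_duration_s=trials_per_run * timing.trial_duration_s,
                timing=timing,
            )
        )
    return schedules


def window_indices(
    onset_s: float, window_s: tuple[float, float], tr_s: float
) -> np.ndarray:
    """Volume indices whose acquisition times fall in the half-open window.

    Volume k is acquired at k * tr_s; the window [onset+a, onset+b) is
    rounded inward (ceil on the start, the end is exclusive).
    """
    start = math.ceil((onset_s + window_s[0]) / tr_s - 1e-9)
    stop = math.ceil((onset_s + window_s[1]) / tr_s - 1e-9)
    return np.arange(start, stop)


def extract_windows(
    roi_timecourse: np.ndarray,
    imagery_onset_s: float,
    tr_s: float,
    *,
    baseline_window_s: tuple[float, float] = BASELINE_WINDOW_S,
    imagery_window_s: tuple[float, float] = IMAGERY_WINDOW_S,
) -> tuple[float, float]:
    """Baseline and imagery window means of a region time-course.

    Raises if either window leaves the run.
    """
    tc = np.asarray(roi_timecourse, dtype=float)
    means = []
    for name, window in (("baseline", baseline_window_s), ("imagery", imagery_window_s)):
        idx = window_indices(imagery_onset_s, window, tr_s)
        if len(idx) == 0:
            raise ValueError(f"{name} window empty at TR {tr_s}s")
        if idx[0] < 0 or idx[-1] >= len(tc):
            raise ValueError(
                f"{name} window {window} at onset {imagery_onset_s}s is out of "
                f"bounds for a {len(tc)}-volume run"
            )
        logger.debug("%s window: %d volumes (%d..%d)", name, len(idx), idx[0], idx[-1])
        means.append(float(tc[idx].mean()))
    return means[0], means[1]


def trial_psc(baseline_mean: float, imagery_mean: float) -> float:
    """Percent signal change of one trial: (imagery - baseline)/baseline x 100."""
    if baseline_mean <= 0:
        raise ValueError(
            f"baseline mean must be positive, got {baseline_mean} (corrupted baseline?)"
        )
    return 100.0 * (imagery_mean - baseline_mean) / baseline_mean


def normalize_feedback(psc: float, max_psc: float) -> float:
    """Map a trial PSC onto the 0-12 feedback scale.

    The PSC is divided by the participant's MaxPSC and multiplied by 10,
    so 10 marks the MaxPSC; values outside [0, 12] are clipped.
    """
    if max_psc <= 0:
        raise ValueError(f"max_psc must be positive, got {max_psc}")
    return float(np.clip(psc / max_psc * 10.0, SCALE_MIN, SCALE_MAX))


def score_run(
    series: VolumeSeries,
    roi_mask: np.ndarray,
    schedule: TrialSchedule,
    max_psc: float,
    *,
    participant: int = 0,
    session: int = 1,
    run: int = 1,
    display_rounding: bool = False,
) -> list[NFRecord]:
    """Score every trial of a run from the ROI-mean time-course.

    Catch trials are scored like any other (their feedback was shown to
    participants) and only flagged for later exclusion from behavioural
    analysis. ``display_rounding`` emulates rounding to integer scale
    ticks before display.
    """
    if series.n_volumes < schedule.n_volumes(series.tr_s):
        raise ValueError(
            f"series has {series.n_volumes} volumes, schedule needs "
            f"{schedule.n_volumes(series.tr_s)}"
        )
    tc = series.roi_timecourse(roi_mask)
    records = []
    for k, trial in enumerate(schedule.trials):
        try:
            baseline, imagery = extract_windows(tc, trial.onset_s, series.tr_s)
        except ValueError as err:
            raise ValueError(f"trial {k}: {err}") from err
        psc = trial_psc(baseline, imagery)
        nf = normalize_feedback(psc, max_psc)
        if display_rounding:
            nf = float(round(nf))
        records.append(
            NFRecord(
                participant=participant,
                session=session,
                run=run,
                trial=k,
                target_level=trial.target_level,
                catch=trial.catch,
                psc_raw=psc,
                nf_value=nf,
            )
        )
    return records


def records_to_frame(records: Sequence[NFRecord]) -> pd.DataFrame:
    """Stack NFRecords into the shared behavioural-table schema."""
    return pd.DataFrame([asdict(r) for r in records])
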