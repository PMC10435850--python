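"""FCQV series, per-trial index and the max-over-trials swallowing sound index.

Frame decisions are summarised at two granularities:

* **FCQV** (fine-crackle quantitative value): for each second of the
  auscultation section, the fraction of frames classified as containing
  the target sound.  A trailing partial second (at least one frame) is
  computed over its actual frame count rather than discarded — 3-mL
  swallow recordings are short and would otherwise lose data.
* **Trial index**: target frames / total frames over the whole trimmed
  auscultation section.  The swallowing sound index of a participant is
  the maximum of the per-trial indices over the repeated swallows
  (typically three 3-mL water swallows).

Both a fraction scale ([0, 1]) and a percent scale ([0, 100]) are carried;
the fraction is the reported scale (published index magnitudes are <= 1),
with percent always emitted alongside to match the x100 definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .classifier import FrameDecisions

Scale = Literal["fraction", "percent"]


class IndexError_(ValueError):
    """Raised for empty decision tracks or scale mismatches."""


@dataclass(frozen=True)
class FcqvSeries:
    values: np.ndarray
    scale: Scale

    @property
    def seconds(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class TrialIndex:
    trial_id: str
    n_target_frames: int
    n_total_frames: int

    @property
    def index_fraction(self) -> float:
        return self.n_target_frames / self.n_total_frames

    @property
    def index_percent(self) -> float:
        return 100.0 * self.index_fraction


@dataclass(frozen=True)
class SwallowingSoundIndex:
    """Max over repeated swallow trials of the trial index."""

    trials: tuple[TrialIndex, ...]
    scale: Scale = "fraction"

    @property
    def value(self) -> float:
        per_trial = [
            t.index_fraction if self.scale == "fraction" else t.index_percent
            for t in self.trials
        ]
        return max(per_trial)

    @property
    def value_fraction(self) -> float:
        return max(t.index_fraction for t in self.trials)

    @property
    def value_percent(self) -> float:
        return max(t.index_percent for t in self.trials)


def _frame_seconds(decisions: FrameDecisions) -> np.ndarray:
    """Whole-second bucket of each frame, by frame start time."""
    return np.floor(decisions.grid.frame_start_times()).astype(int)


def compute_fcqv(decisions: FrameDecisions, scale: Scale = "fraction") -> FcqvSeries:
    """Per-second fraction (or percent) of target-sound frames.

    Frames are bucketed by their start time; every second holding at
    least one frame gets a value, including a trailing partial second.
    """
    if decisions.present.shape[0] == 0:
        raise IndexError_("empty decision track")
    if scale not in ("fraction", "percent"):
        raise IndexError_(f"unknown scale {scale!r}")
    sec = _frame_seconds(decisions)
    n_seconds = sec.max() + 1
    totals = np.bincount(sec, minlength=n_seconds)
    hits = np.bincount(sec, weights=decisions.present.astype(float), minlength=n_seconds)
    values = hits / totals
    if scale == "percent":
        values = 100.0 * values
    return FcqvSeries(values=values, scale=scale)


def compute_trial_index(decisions: FrameDecisions, trial_id: str = "") -> TrialIndex:
    """Whole-section frame fraction: target frames / total frames."""
    n_total = int(decisions.present.shape[0])
    if n_total == 0:
        raise IndexError_("empty decision track")
    return TrialIndex(
        trial_id=trial_id,
        n_target_frames=int(decisions.present.sum()),
        n_total_frames=n_total,
    )


def aggregate_trials(
    trials: Sequence[TrialIndex], scale: Scale = "fraction"
) -> SwallowingSoundIndex:
    """The swallowing sound index: the maximum per-trial index."""
    if not trials:
        raise IndexError_("at least one trial required")
    return SwallowingSoundIndex(trials=tuple(trials), scale=scale)


def detect_swallow(
    fcqv: FcqvSeries, fcqv_threshold: float, threshold_scale: Scale | None = None
) -> tuple[np.ndarray, bool]:
    """Per-second presence flags and the overall target-sound verdict.

    ``flag[s] = fcqv[s] > threshold``; the recording is judged to contain
    the target sound if any second exceeds the threshold.  The threshold
    must be on the series' scale (pass ``threshold_scale`` to assert it).
    """
    if threshold_scale is not None and threshold_scale != fcqv.scale:
        raise IndexError_(
            f"threshold on {threshold_scale!r} scale applied to a {fcqv.scale!r} series"
        )
    flags = fcqv.values > fcqv_threshold
    return flags, bool(flags.any())
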