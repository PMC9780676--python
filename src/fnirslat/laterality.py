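"""Per-trial motor-cortex laterality (M1-LAT) from clean ΔHbO.

For each trial a linear slope is fit to the ΔHbO values in the 10 s task
window at each of the 16 measurement locations; M1-LAT at a homotopic
pair is the contralesional-minus-ipsilesional slope difference, giving
eight values per trial. Under this convention a typically lateralized
response (ipsilesional activity exceeding contralesional during paretic
movement) yields negative values, and more bilateral/atypical patterns
shift the values upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import Montage
from .preprocess import CleanSeries

__all__ = ["TrialEpochs", "epoch", "task_slope", "slope_matrix", "m1_lat",
           "LateralityRecord", "laterality_table"]


@dataclass
class TrialEpochs:
    """Task-window samples, one row per (trial, channel).

    ``data`` has shape (n_trials, n_channels, n_window) with the
    half-open window [onset, onset + task_s); the onset sample is
    included, so after baseline correction each epoch starts at 0.
    """

    participant_id: str
    channel_ids: list[str]
    data: np.ndarray
    fs: float

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class LateralityRecord:
    """trial x pair (8) M1-LAT values for one participant."""

    participant_id: str
    lesion_side: str
    values: np.ndarray  # (n_trials, 8)

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != 8:
            raise ValueError("M1-LAT matrix must have 8 pair columns")


def epoch(
    clean: CleanSeries, events=None, task_s: float | None = None
) -> TrialEpochs:
    """Cut the clean series into per-trial task windows.

    Windows are half-open [onset, onset + task_s); overlapping windows or
    windows extending past the recording raise.
    """
    events = clean.events if events is None else np.asarray(events, dtype=float)
    task_s = clean.task_s if task_s is None else task_s
    n_win = int(round(task_s * clean.fs))
    n = clean.hbo.shape[-1]
    starts = np.round(events * clean.fs).astype(int)
    if np.any(starts < 0) or np.any(starts + n_win > n):
        raise ValueError("task window extends outside the recording")
    order = np.sort(starts)
    if np.any(np.diff(order) < n_win):
        raise ValueError("overlapping task windows")
    data = np.stack([clean.hbo[:, s : s + n_win] for s in starts])
    return TrialEpochs(
        participant_id=clean.participant_id,
        channel_ids=list(clean.channel_ids),
        data=data,
        fs=clean.fs,
    )


def task_slope(epoch_values: np.ndarray, fs: float) -> np.ndarray:
    """OLS slope of value vs time (s, origin at onset) along the last axis."""
    y = np.asarray(epoch_values, dtype=float)
    if y.shape[-1] < 2:
        raise ValueError("need at least 2 samples to fit a slope")
    t = np.arange(y.shape[-1]) / fs
    t_c = t - t.mean()
    return (y - y.mean(axis=-1, keepdims=True)) @ t_c / (t_c @ t_c)


def slope_matrix(epochs: TrialEpochs) -> np.ndarray:
    """trial x location matrix of task-window slopes (µM/s)."""
    return task_slope(epochs.data, epochs.fs)


def m1_lat(
    slopes: np.ndarray,
    channel_ids: list[str],
    montage: Montage,
    lesion_side: str,
    participant_id: str = "",
) -> LateralityRecord:
    """Contralesional-minus-ipsilesional slope difference per homotopic pair.

    ``slopes`` is (n_trials, n_channels) aligned with ``channel_ids`` and
    must cover all 16 long-path locations. A missing pair member yields
    NaN for that pair, never a silent zero.
    """
    if lesion_side not in ("left", "right"):
        raise ValueError("lesion_side must be 'left' or 'right'")
    slopes = np.atleast_2d(np.asarray(slopes, dtype=float))
    values = np.full((slopes.shape[0], 8), np.nan)
    for k, (left_id, right_id) in enumerate(montage.homotopic_pairs):
        if left_id not in channel_ids or right_id not in channel_ids:
            continue
        left = slopes[:, channel_ids.index(left_id)]
        right = slopes[:, channel_ids.index(right_id)]
        contra, ipsi = (right, left) if lesion_side == "left" else (left, right)
        values[:, k] = contra - ipsi
    return LateralityRecord(
        participant_id=participant_id, lesion_side=lesion_side, values=values
    )


def laterality_table(records: list[LateralityRecord]) -> pd.DataFrame:
    """Long-format table: participant_id, lesion_side, trial, pair_index, m1lat."""
    rows = []
    for rec in records:
        for trial in range(rec.values.shape[0]):
            for pair in range(8):
                rows.append(
                    {
                        "participant_id": rec.participant_id,
                        "lesion_side": rec.lesion_side,
                        "trial": trial + 1,
                        "pair_index": pair + 1,
                        "m1lat": rec.values[trial, pair],
                    }
                )
    return pd.DataFrame(rows)
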