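"""Brainstem source montage: leadfield pseudo-inverse spatial filtering.

The source waveform is ``SWF = L^+ x FFR`` where ``L`` is the channels x 3
brainstem leadfield (orientations x, y, z) and ``L^+`` its Moore-Penrose
pseudo-inverse.  Sensor data must be common-average referenced before
inversion; the leadfield columns are average-referenced accordingly, so
the filter lives in the same rank-reduced space.  Only the z (vertical)
orientation is retained -- midbrain FFR currents are predominantly
vertically oriented and x/y contribute little.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import LeadfieldModel
from .preprocess import Epochs

MAX_CONDITION = 1e8
ORIENTATIONS = ("x", "y", "z")


@dataclass
class SpatialFilter:
    """3 x channels pseudo-inverse of an (average-referenced) leadfield."""

    matrix: np.ndarray  # 3 x channels
    channel_labels: tuple[str, ...]
    source_label: str = "brainstem/IC regional source"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 3:
            raise ValueError("spatial filter must have exactly 3 rows (x, y, z)")


def build_spatial_filter(leadfield: LeadfieldModel) -> SpatialFilter:
    """Pseudo-invert the leadfield after common-average referencing its columns."""
    L = leadfield.matrix - leadfield.matrix.mean(axis=0, keepdims=True)
    cond = np.linalg.cond(L)
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise ValueError(
            f"leadfield is rank deficient after average referencing "
            f"(condition number {cond:.3g})"
        )
    pinv = np.linalg.pinv(L)
    resid = pinv @ L - np.eye(3)
    if np.abs(resid).max() > 1e-8:
        raise ValueError("pseudo-inverse consistency check failed")
    return SpatialFilter(matrix=pinv, channel_labels=leadfield.channel_labels)


@dataclass
class SourceEpochs:
    """Single-trial z-orientation source waveforms (trials x samples)."""

    data: np.ndarray
    fs: float
    window: tuple[float, float]
    metadata: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.data.shape[1]) / self.fs


def to_source(epochs: Epochs, filt: SpatialFilter) -> SourceEpochs:
    """Apply the spatial filter to multichannel epochs; keep the z row.

    Epochs must be common-average referenced and carry the same channel
    set (and order) the filter was built for.
    """
    if tuple(epochs.channel_labels) != tuple(filt.channel_labels):
        missing = set(filt.channel_labels) - set(epochs.channel_labels)
        raise ValueError(
            f"channel mismatch between epochs and spatial filter"
            + (f"; missing {sorted(missing)}" if missing else " (order differs)")
        )
    z_row = filt.matrix[2]
    # (trials, channels, samples) . (channels,) -> (trials, samples)
    data = np.tensordot(epochs.data.astype(np.float64), z_row, axes=([1], [0]))
    return SourceEpochs(
        data=data, fs=epochs.fs, window=epochs.window, metadata=epochs.metadata
    )
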