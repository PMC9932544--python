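"""32-channel 10-20 montage geometry and the synthetic brainstem leadfield.

Electrode positions come from MNE's standard easycap template.  The
leadfield maps a single brainstem/midbrain regional source (three
orthogonal current orientations x, y, z) to the 32 scalp channels.  It is
built from radial electrode geometry: a deep medial source projects to
each electrode roughly along the electrode's radial direction, which
makes the z (vertical) column dominant along the vertex line -- the
property that motivates analyzing only the z orientation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Standard 32-channel 10-20 layout including the mastoid references
#: (TP9/TP10) and the posterior sites (Pz, Oz) used for the alpha index.
CHANNELS_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT9", "FC5", "FC1", "FC2", "FC6", "FT10",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)


def channel_positions(channels: tuple[str, ...] = CHANNELS_32) -> np.ndarray:
    """Head-frame electrode positions (n_channels, 3) in meters."""
    import mne

    montage = mne.channels.make_standard_montage("easycap-M1")
    pos = montage.get_positions()["ch_pos"]
    missing = [ch for ch in channels if ch not in pos]
    if missing:
        raise ValueError(f"channels missing from template montage: {missing}")
    return np.array([pos[ch] for ch in channels], dtype=float)


@dataclass
class LeadfieldModel:
    """Gain of a unit brainstem dipole (x, y, z orientation) at each electrode.

    ``matrix`` is channels x 3; columns are orientations.  Scaled so the
    largest absolute z-column entry is 1 (gain is in uV per unit source).
    """

    matrix: np.ndarray
    channel_labels: tuple[str, ...] = CHANNELS_32

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 3:
            raise ValueError("leadfield must be channels x 3")
        if self.matrix.shape[0] != len(self.channel_labels):
            raise ValueError("leadfield row count does not match channel labels")
        if np.linalg.matrix_rank(self.matrix) < 3:
            raise ValueError("leadfield is not full column rank")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.matrix, index=list(self.channel_labels), columns=["x", "y", "z"]
        ).to_csv(path, index_label="channel")

    @classmethod
    def from_csv(cls, path) -> "LeadfieldModel":
        import pandas as pd

        df = pd.read_csv(path, index_col="channel")
        return cls(df[["x", "y", "z"]].to_numpy(), tuple(df.index))


def make_leadfield(channels: tuple[str, ...] = CHANNELS_32) -> LeadfieldModel:
    """Synthetic radial-projection leadfield for a deep midline source.

    Each electrode's gain vector is its unit radial direction from the
    head center, softly weighted by distance from a source placed low on
    the midline (below the center, approximating the inferior colliculus).
    The z column therefore peaks at vertex-line electrodes (Cz, FC1/2,
    CP1/2) and is the dominant orientation for vertically oriented
    midbrain currents.
    """
    pos = channel_positions(channels)
    src = np.array([0.0, -0.02, -0.04])  # brainstem: low, slightly posterior
    vec = pos - src
    dist = np.linalg.norm(vec, axis=1, keepdims=True)
    gain = vec / dist**2  # radial direction with 1/r falloff
    gain = gain / np.abs(gain[:, 2]).max()
    return LeadfieldModel(gain, tuple(channels))


def posterior_alpha_topography(
    channels: tuple[str, ...] = CHANNELS_32,
    center: np.ndarray | None = None,
    sigma: float = 0.055,
) -> np.ndarray:
    """Unit-peak posterior scalp weighting for the cortical alpha source.

    Gaussian falloff around a mid parieto-occipital point so alpha is
    strong at Pz/Oz (the POz proxy) and nearly absent at Fz -- the
    premise of the Fz-alpha control analysis.
    """
    pos = channel_positions(channels)
    if center is None:
        center = np.array([0.0, -0.085, 0.02])
    w = np.exp(-np.sum((pos - center) ** 2, axis=1) / (2 * sigma**2))
    return w / w.max()
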