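"""Re-referencing, resampling, band splitting and epoching.

Analysis runs at 5 kHz: acquisition-rate recordings (20 kHz) are
anti-alias resampled first, which reproduces the printed FIR filter
lengths (661 taps for the 100-1,000 Hz brainstem band, 8,251 taps for the
8-12 Hz alpha band) exactly under the automatic length rule below.

Filters are windowed-sinc (Hamming) band-passes applied as compensated
linear-phase convolution (the group delay of ``(n_taps - 1)/2`` samples is
removed), so epoch latencies are undistorted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .synth import RecordingSession

logger = logging.getLogger(__name__)

ANALYSIS_FS = 5000.0
FFR_BAND = (100.0, 1000.0)
ALPHA_BAND = (8.0, 12.0)
BETA_BAND = (18.0, 22.0)
EPOCH_WINDOW = (-0.050, 0.145)  # s, 0 = frequent-token onset


@dataclass(frozen=True)
class FilterSpec:
    """Windowed-sinc band-pass design with automatic transition widths.

    The transition bandwidth at each edge is ``min(max(0.25 * edge, 2),
    margin)`` Hz -- a quarter of the edge frequency, floored at 2 Hz and
    capped by the distance to DC / Nyquist -- and the length is
    ``ceil(3.3 / min_transition * fs)`` forced odd (3.3 is the Hamming
    window's normalized transition width).  The -6 dB cutoffs sit half a
    transition width outside the passband edges.
    """

    fs: float
    band: tuple[float, float]
    transition_bw: tuple[float, float]
    n_taps: int
    minus6db_cutoffs: tuple[float, float]
    taps: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def duration(self) -> float:
        return self.n_taps / self.fs


def design_fir_bandpass(fs: float, low: float, high: float) -> FilterSpec:
    """Design a Hamming-window FIR band-pass with the automatic length rule.

    At fs = 5 kHz this yields 661 taps for (100, 1000) Hz and 8,251 taps
    with -6 dB cutoffs at 7 and 13.5 Hz for (8, 12) Hz.
    """
    nyq = fs / 2
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz invalid for fs = {fs} Hz")
    trans_lo = min(max(0.25 * low, 2.0), low)
    trans_hi = min(max(0.25 * high, 2.0), nyq - high)
    if trans_lo <= 0 or trans_hi <= 0:
        raise ValueError("degenerate transition bandwidth")
    n_taps = int(math.ceil(3.3 / min(trans_lo, trans_hi) * fs))
    if n_taps % 2 == 0:
        n_taps += 1
    cutoffs = (low - trans_lo / 2, high + trans_hi / 2)
    taps = signal.firwin(
        n_taps, cutoffs, window="hamming", pass_zero=False, fs=fs
    )
    return FilterSpec(
        fs=fs,
        band=(low, high),
        transition_bw=(trans_lo, trans_hi),
        n_taps=n_taps,
        minus6db_cutoffs=cutoffs,
        taps=taps,
    )


def apply_fir(data: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Zero-phase (delay-compensated linear-phase) filtering along the last axis."""
    x = np.atleast_2d(np.asarray(data, dtype=np.float64))
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        # 'same' centers the symmetric kernel: full convolution with the
        # (n_taps - 1) / 2 sample group delay removed
        out[i] = signal.fftconvolve(x[i], spec.taps, mode="same")
    return out if np.ndim(data) > 1 else out[0]


# --------------------------------------------------------------------------
# re-referencing and resampling
# --------------------------------------------------------------------------

MASTOIDS = ("TP9", "TP10")


def rereference(session: RecordingSession, scheme: str) -> RecordingSession:
    """Linked-mastoid (TP9/TP10) or common-average re-referencing.

    Channel-level (sensor) analyses use the mastoid reference; the source
    transformation requires the common average, under which the channel sum
    is zero at every sample.
    """
    data = session.data.astype(np.float32, copy=True)
    if scheme in ("linked-mastoids", "mastoids"):
        for ch in MASTOIDS:
            if ch not in session.channel_labels:
                raise ValueError(f"mastoid reference channel {ch} missing from montage")
        idx = [session.channel_labels.index(ch) for ch in MASTOIDS]
        ref = data[idx].mean(axis=0)
    elif scheme == "common-average":
        ref = data.mean(axis=0)
    else:
        raise ValueError(f"unknown reference scheme {scheme!r}")
    data -= ref
    return session.copy_with(data=data)


def resample(session: RecordingSession, target_fs: float = ANALYSIS_FS) -> RecordingSession:
    """Anti-aliased polyphase resampling; event indices are rescaled."""
    if target_fs > session.fs:
        raise ValueError(f"target fs {target_fs} above original {session.fs}")
    if target_fs == session.fs:
        return session
    from fractions import Fraction

    frac = Fraction(target_fs / session.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    n_out = None
    out = []
    for ch in range(session.data.shape[0]):
        y = signal.resample_poly(session.data[ch].astype(np.float64), up, down)
        out.append(y.astype(np.float32))
        n_out = y.size
    data = np.vstack(out)
    events = session.events.copy()
    events["onset_sample"] = np.round(
        events["onset_sample"].to_numpy() * target_fs / session.fs
    ).astype(int)
    truth = session.ground_truth
    if truth is not None:
        truth = truth.copy()
        truth["onset_sample"] = np.round(
            truth["onset_sample"].to_numpy() * target_fs / session.fs
        ).astype(int)
    src = session.source_z
    if src is not None:
        src = signal.resample_poly(src.astype(np.float64), up, down)
    return RecordingSession(
        data=data,
        fs=target_fs,
        channel_labels=session.channel_labels,
        events=events,
        condition=session.condition,
        ground_truth=truth,
        source_z=src,
    )


# --------------------------------------------------------------------------
# band splitting
# --------------------------------------------------------------------------

@dataclass
class BandStreams:
    """The four analysis streams derived from one session.

    ffr            all channels, 100-1,000 Hz, common-average reference
    alpha          POz proxy (mean of Pz and Oz), 8-12 Hz, mastoid reference
    beta           POz proxy, 18-22 Hz, mastoid reference (control)
    alpha_control  Fz, 8-12 Hz, mastoid reference (control)
    """

    ffr: RecordingSession
    alpha: RecordingSession
    beta: RecordingSession
    alpha_control: RecordingSession
    filter_specs: dict


def _single_channel(
    session: RecordingSession, channels: tuple[str, ...], label: str
) -> np.ndarray:
    missing = [ch for ch in channels if ch not in session.channel_labels]
    if missing:
        raise ValueError(f"{label}: channels missing {missing}")
    idx = [session.channel_labels.index(ch) for ch in channels]
    return session.data[idx].astype(np.float64).mean(axis=0)


def bandsplit(
    session: RecordingSession,
    ffr_band: tuple[float, float] = FFR_BAND,
    alpha_band: tuple[float, float] = ALPHA_BAND,
    beta_band: tuple[float, float] = BETA_BAND,
    poz_proxy: tuple[str, ...] = ("Pz", "Oz"),
    control_site: tuple[str, ...] = ("Fz",),
) -> BandStreams:
    """Split a (raw, analysis-rate) session into the four band streams.

    Referencing is stream-specific: common average for the brainstem band
    (required by the source transform), linked mastoids for the cortical
    index streams.
    """
    car = rereference(session, "common-average")
    mast = rereference(session, "linked-mastoids")

    ffr_spec = design_fir_bandpass(session.fs, *ffr_band)
    alpha_spec = design_fir_bandpass(session.fs, *alpha_band)
    beta_spec = design_fir_bandpass(session.fs, *beta_band)

    ffr_data = apply_fir(car.data, ffr_spec).astype(np.float32)
    ffr = car.copy_with(data=ffr_data)

    def scalar_stream(src: RecordingSession, chans, spec, label) -> RecordingSession:
        x = _single_channel(src, chans, label)
        y = apply_fir(x, spec).astype(np.float32)[np.newaxis, :]
        return src.copy_with(data=y, channel_labels=(label,))

    alpha = scalar_stream(mast, poz_proxy, alpha_spec, "POz")
    beta = scalar_stream(mast, poz_proxy, beta_spec, "POz")
    alpha_ctl = scalar_stream(mast, control_site, alpha_spec, "Fz")
    return BandStreams(
        ffr=ffr,
        alpha=alpha,
        beta=beta,
        alpha_control=alpha_ctl,
        filter_specs={"ffr": ffr_spec, "alpha": alpha_spec, "beta": beta_spec},
    )


# --------------------------------------------------------------------------
# epoching
# --------------------------------------------------------------------------

@dataclass
class Epochs:
    """Fixed-window single trials: trials x channels x samples.

    The 195 ms window spans [-50, +145) ms around each frequent-token
    onset (half-open sample convention, ``round(0.195 * fs)`` samples).
    Rare /ta/ trials are excluded upstream of all FFR analyses.
    """

    data: np.ndarray
    fs: float
    window: tuple[float, float]
    metadata: pd.DataFrame
    channel_labels: tuple[str, ...]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_samples) / self.fs


def epoch(
    session: RecordingSession,
    window: tuple[float, float] = EPOCH_WINDOW,
    exclude_tokens: tuple[str, ...] = ("ta",),
) -> Epochs:
    """Cut fixed windows around frequent-token onsets.

    Trials whose window exceeds the recording are dropped (never padded)
    with the count logged.
    """
    fs = session.fs
    n_samp = int(round((window[1] - window[0]) * fs))
    offset = int(round(window[0] * fs))
    events = session.events
    keep = ~events["token"].isin(exclude_tokens)
    events = events[keep]
    starts = events["onset_sample"].to_numpy() + offset
    in_range = (starts >= 0) & (starts + n_samp <= session.n_samples)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.info("epoch: dropped %d edge trials", n_dropped)
    events = events[in_range]
    starts = starts[in_range]
    n_ch = session.data.shape[0]
    data = np.empty((starts.size, n_ch, n_samp), dtype=np.float32)
    for i, s in enumerate(starts):
        data[i] = session.data[:, s : s + n_samp]
    md = events.reset_index(drop=True).copy()
    md["condition"] = session.condition
    return Epochs(
        data=data,
        fs=fs,
        window=window,
        metadata=md,
        channel_labels=session.channel_labels,
    )


def save_epochs(epochs: Epochs, stem) -> None:
    """Write epochs as a compressed array container plus a JSON header.

    The header carries fs, window, channel provenance and trial metadata;
    the array file holds the trials x channels x samples data.
    """
    import json
    from pathlib import Path

    stem = Path(stem)
    np.savez_compressed(stem.with_suffix(".npz"), data=epochs.data)
    header = {
        "fs": epochs.fs,
        "window": list(epochs.window),
        "channel_labels": list(epochs.channel_labels),
        "metadata": epochs.metadata.to_dict(orient="list"),
    }
    stem.with_suffix(".json").write_text(json.dumps(header))


def load_epochs(stem) -> Epochs:
    import json
    from pathlib import Path

    stem = Path(stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    data = np.load(stem.with_suffix(".npz"))["data"]
    return Epochs(
        data=data,
        fs=header["fs"],
        window=tuple(header["window"]),
        metadata=pd.DataFrame(header["metadata"]),
        channel_labels=tuple(header["channel_labels"]),
    )
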