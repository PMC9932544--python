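"""Category-averaged FFR spectra, F0 amplitude, response SNR, and F0 ratio.

The steady-state portion (10-100 ms post onset; 450 samples at 5 kHz) of
each alpha-category average is Blackman-tapered and Fourier transformed
without zero padding, giving a one-sided amplitude spectrum of 226 points
at 11.1 Hz spacing.  F0 amplitude is the spectral maximum within an 11 Hz
search bin centered on 150 Hz, and the F0 ratio -- the pipeline's central
statistic -- is the high-alpha F0 amplitude divided by the low-alpha F0
amplitude: values above 1 mean stronger brainstem responses during high
cortical alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .source import SourceEpochs

STEADY_STATE_WINDOW = (0.010, 0.100)  # s post token onset
F0_HZ = 150.0
F0_SEARCH_WIDTH = 11.0  # Hz, total width of the search bin
SNR_FLANKS = (22.0, 55.0)  # Hz offsets from F0 defining the noise-floor band
SNR_CRITERION_DB = 3.0


@dataclass
class FFRSpectrum:
    """One-sided amplitude spectrum of a category-averaged steady-state FFR.

    Amplitudes are normalized by window length and the taper's coherent
    gain, so a unit-amplitude sinusoid at a bin center reads ~1.
    """

    freqs: np.ndarray
    amps: np.ndarray
    n_trials: int
    f0_amp: float
    f0_peak_freq: float
    response_snr_db: float

    @property
    def snr_flag(self) -> bool:
        """True when the average fails the >= 3 dB response-SNR criterion."""
        return not self.response_snr_db >= SNR_CRITERION_DB  # NaN also flags

    @property
    def bin_spacing(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def average_ffr(
    source_epochs: SourceEpochs,
    categories: np.ndarray,
    which: tuple[str, ...] = ("low", "high"),
) -> dict:
    """Arithmetic trial mean per alpha category (polarities pooled).

    Returns ``{category: (waveform, n_trials)}``; an empty cell is an
    error naming the cell.
    """
    categories = np.asarray(categories)
    if categories.size != source_epochs.n_trials:
        raise ValueError("categories must align with trials")
    out = {}
    for cat in which:
        mask = categories == cat
        if not mask.any():
            raise ValueError(f"no trials in category {cat!r}")
        out[cat] = (source_epochs.data[mask].mean(axis=0), int(mask.sum()))
    return out


def steady_state_spectrum(
    waveform: np.ndarray,
    fs: float,
    epoch_window: tuple[float, float] = (-0.050, 0.145),
    window: tuple[float, float] = STEADY_STATE_WINDOW,
    n_trials: int = 1,
) -> FFRSpectrum:
    """FFT of the Blackman-tapered steady-state segment, no zero padding.

    With fs = 5 kHz and the default 10-100 ms window the segment is 450
    samples (half-open convention), yielding 226 one-sided bins at
    5000/450 = 11.1 Hz resolution.
    """
    waveform = np.asarray(waveform, dtype=float)
    i0 = int(round((window[0] - epoch_window[0]) * fs))
    n_seg = int(round((window[1] - window[0]) * fs))
    if i0 < 0 or i0 + n_seg > waveform.size:
        raise ValueError("steady-state window outside the epoch")
    seg = waveform[i0 : i0 + n_seg]
    taper = windows.blackman(n_seg, sym=False)
    spec = np.fft.rfft(seg * taper)
    # amplitude convention: unit sinusoid at a bin center reads ~1
    amps = np.abs(spec) * 2.0 / taper.sum()
    amps[0] /= 2.0
    if n_seg % 2 == 0:
        amps[-1] /= 2.0
    freqs = np.fft.rfftfreq(n_seg, 1.0 / fs)
    f0_amp, f0_freq = f0_amplitude_with_freq(freqs, amps)
    try:
        snr = response_snr_db(freqs, amps, f0_amp)
    except ValueError:  # degenerate (e.g. all-zero) spectrum: flagged, kept
        snr = float("nan")
    return FFRSpectrum(
        freqs=freqs,
        amps=amps,
        n_trials=n_trials,
        f0_amp=f0_amp,
        f0_peak_freq=f0_freq,
        response_snr_db=snr,
    )


def _search_mask(freqs: np.ndarray, f0: float, width: float) -> np.ndarray:
    # a grid bin qualifies when its spectral extent overlaps the search
    # interval f0 +/- width/2 (the 11.1 Hz grid has no bin center inside
    # an 11 Hz interval centered on 150 Hz, so centers-only would be empty)
    df = freqs[1] - freqs[0]
    return (freqs + df / 2 > f0 - width / 2) & (freqs - df / 2 < f0 + width / 2)


def f0_amplitude_with_freq(
    freqs: np.ndarray,
    amps: np.ndarray,
    f0: float = F0_HZ,
    width: float = F0_SEARCH_WIDTH,
) -> tuple[float, float]:
    """Peak amplitude (and its bin frequency) within the F0 search bin."""
    mask = _search_mask(freqs, f0, width)
    if not mask.any():
        raise ValueError("F0 search interval does not intersect the frequency grid")
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(amps[idx])]
    return float(amps[best]), float(freqs[best])


def f0_amplitude(spectrum: FFRSpectrum, f0: float = F0_HZ, width: float = F0_SEARCH_WIDTH) -> float:
    return f0_amplitude_with_freq(spectrum.freqs, spectrum.amps, f0, width)[0]


def response_snr_db(
    freqs: np.ndarray,
    amps: np.ndarray,
    f0_amp: float,
    f0: float = F0_HZ,
    flanks: tuple[float, float] = SNR_FLANKS,
) -> float:
    """20 log10 of F0 amplitude over the mean flanking-band amplitude.

    The noise floor is the mean amplitude over bins whose centers lie
    within ``flanks`` Hz of F0 on either side -- symmetric bands clear of
    F0 spectral leakage, excluding the search bin itself.
    """
    offset = np.abs(freqs - f0)
    mask = (offset >= flanks[0]) & (offset <= flanks[1])
    mask &= ~_search_mask(freqs, f0, F0_SEARCH_WIDTH)
    if not mask.any():
        raise ValueError("no noise-floor flank bins available")
    floor = amps[mask].mean()
    if floor <= 0:
        raise ValueError("zero noise floor")
    if f0_amp <= 0:
        return float("-inf")
    return float(20.0 * np.log10(f0_amp / floor))


def response_snr(spectrum: FFRSpectrum) -> float:
    return response_snr_db(spectrum.freqs, spectrum.amps, spectrum.f0_amp)


def f0_ratio(f0_low: float, f0_high: float) -> float:
    """High-alpha over low-alpha F0 amplitude (the modulation statistic)."""
    if f0_low <= 0 or f0_high <= 0:
        raise ValueError("F0 amplitudes must be positive")
    return float(f0_high / f0_low)


def participant_spectra(
    source_epochs: SourceEpochs, categories: np.ndarray
) -> dict:
    """Low/high-alpha spectra plus the F0 ratio for one participant-condition."""
    averages = average_ffr(source_epochs, categories)
    spectra = {
        cat: steady_state_spectrum(
            wave, source_epochs.fs, epoch_window=source_epochs.window, n_trials=n
        )
        for cat, (wave, n) in averages.items()
    }
    ratio = f0_ratio(spectra["low"].f0_amp, spectra["high"].f0_amp)
    return {"spectra": spectra, "f0_ratio": ratio}
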