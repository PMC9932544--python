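"""Synthetic cohort generator: sessions, participants, and behavior.

Emulates the study conditions of a speech-evoked EEG experiment in older
adults: trains of /ba/, /pa/ (frequent) and /ta/ (rare target) tokens with
jittered inter-stimulus intervals, a brainstem source phase-locked at the
voice fundamental (F0 = 150 Hz) projected to 32 scalp channels through a
known leadfield, posterior cortical alpha (8-12 Hz) with slowly varying
amplitude, and a programmable coupling between the instantaneous alpha
state and the FFR source amplitude.  The coupling parameter ``coupling_g``
is the ground truth that the analysis-side F0 ratio estimates.

All randomness flows through ``numpy.random.default_rng`` seeded
explicitly, so every output is bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .montage import (
    CHANNELS_32,
    LeadfieldModel,
    make_leadfield,
    posterior_alpha_topography,
)

# --------------------------------------------------------------------------
# stimulus schedule
# --------------------------------------------------------------------------

FREQUENT_TOKENS = ("ba", "pa")
RARE_TOKEN = "ta"


@dataclass(frozen=True)
class StimulusSpec:
    """Token inventory and presentation schedule for one condition.

    Defaults are the full study condition: 3,000 /ba/ + 3,000 /pa/ frequent
    tokens and 210 rare /ta/ targets spread over three blocks, 100 ms token
    duration, ISI jittered uniformly on a 95-155 ms grid in 5 ms steps, and
    alternating stimulus polarity.
    """

    n_ba: int = 3000
    n_pa: int = 3000
    n_rare: int = 210
    token_duration: float = 0.100  # s
    f0: float = 150.0  # Hz
    formants: tuple[float, float] = (885.0, 1389.0)
    isi_min: float = 0.095  # s
    isi_max: float = 0.155  # s
    isi_step: float = 0.005  # s
    n_blocks: int = 3
    block_gap: float = 2.0  # s between blocks
    lead_in: float = 1.0  # s of silence before the first token

    @property
    def n_frequent(self) -> int:
        return self.n_ba + self.n_pa

    @property
    def n_tokens(self) -> int:
        return self.n_frequent + self.n_rare

    @property
    def isi_grid(self) -> np.ndarray:
        n = int(round((self.isi_max - self.isi_min) / self.isi_step)) + 1
        return self.isi_min + self.isi_step * np.arange(n)

    def scaled(self, fraction: float) -> "StimulusSpec":
        """Proportionally smaller condition (same structure, fewer tokens)."""
        return StimulusSpec(
            n_ba=max(1, int(round(self.n_ba * fraction))),
            n_pa=max(1, int(round(self.n_pa * fraction))),
            n_rare=int(round(self.n_rare * fraction)),
            token_duration=self.token_duration,
            f0=self.f0,
            formants=self.formants,
            isi_min=self.isi_min,
            isi_max=self.isi_max,
            isi_step=self.isi_step,
            n_blocks=self.n_blocks,
        )


@dataclass(frozen=True)
class ScheduledToken:
    onset: float  # s from recording start
    token: str
    polarity: int  # +1 / -1, alternating
    block: int


def _token_order(n_frequent: int, n_rare: int, rng: np.random.Generator) -> list[bool]:
    """Boolean sequence (True = rare) with >= 2 frequents before every rare.

    Uniform over all admissible arrangements via the composition bijection:
    gaps of frequent tokens before each rare must be >= 2 (including before
    the first rare), the tail gap >= 0.
    """
    if n_rare == 0:
        return [False] * n_frequent
    if n_frequent < 2 * n_rare:
        raise ValueError(
            f"rare-token spacing unsatisfiable: need >= {2 * n_rare} frequent "
            f"tokens for {n_rare} rare tokens, got {n_frequent}"
        )
    # weak composition of n_frequent - 2*n_rare into n_rare + 1 parts,
    # sampled uniformly by choosing bar positions
    free = n_frequent - 2 * n_rare
    bars = np.sort(rng.choice(free + n_rare, size=n_rare, replace=False))
    h = np.diff(np.concatenate(([-1], bars))) - 1  # extra frequents per gap
    gaps = h + 2
    order: list[bool] = []
    for g in gaps:
        order.extend([False] * g)
        order.append(True)
    order.extend([False] * (n_frequent - int(gaps.sum())))
    return order


def make_event_schedule(
    spec: StimulusSpec, seed: int | np.random.Generator
) -> list[ScheduledToken]:
    """Pseudo-random token schedule honoring the rare-token spacing rule.

    Token counts are spread evenly over ``n_blocks`` blocks; within each
    block rare targets are placed uniformly at random subject to at least
    two frequent tokens intervening, frequent identities (/ba/ vs /pa/) are
    shuffled, ISIs are drawn uniformly from the 5 ms grid, and polarity
    alternates trial by trial across the session.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    per_block_ba = _split_even(spec.n_ba, spec.n_blocks)
    per_block_pa = _split_even(spec.n_pa, spec.n_blocks)
    per_block_rare = _split_even(spec.n_rare, spec.n_blocks)

    events: list[ScheduledToken] = []
    t = spec.lead_in
    polarity = 1
    grid = spec.isi_grid
    for b in range(spec.n_blocks):
        n_f = per_block_ba[b] + per_block_pa[b]
        order = _token_order(n_f, per_block_rare[b], rng)
        idents = [FREQUENT_TOKENS[0]] * per_block_ba[b] + [FREQUENT_TOKENS[1]] * per_block_pa[b]
        rng.shuffle(idents)
        it = iter(idents)
        for is_rare in order:
            token = RARE_TOKEN if is_rare else next(it)
            events.append(ScheduledToken(onset=t, token=token, polarity=polarity, block=b))
            polarity = -polarity
            t += spec.token_duration + float(rng.choice(grid))
        t += spec.block_gap
    return events


def _split_even(n: int, k: int) -> list[int]:
    base = n // k
    out = [base] * k
    for i in range(n - base * k):
        out[i] += 1
    return out


# --------------------------------------------------------------------------
# participants
# --------------------------------------------------------------------------

#: Printed pure-tone-average ranges per hearing group (dB HL).
PTA_RANGE = {"NH": (8.3, 20.83), "HL": (15.8, 45.0)}


@dataclass
class ParticipantParams:
    """Generative parameters for one synthetic listener."""

    participant: str
    group: str  # "NH" or "HL"
    age: float  # years
    pta: float  # dB HL, mean of 0.5/1/2 kHz thresholds
    alpha_base_power: float  # uV RMS of posterior alpha at its scalp peak
    alpha_mod_depth: float  # 0-1 slow amplitude-modulation depth
    ffr_gain: float  # brainstem source F0 amplitude scale (source units)
    coupling_g: float  # fractional FFR amplitude change per unit normalized alpha
    noise_sd: float  # broadband sensor noise, uV per channel
    noise_ffr_scale: float = 0.8  # ffr_gain multiplier in the babble condition
    snr50: float = 2.0  # dB, QuickSiN 50%-keyword threshold
    hit_p_clear: float = 0.88
    hit_p_noise: float = 0.70
    rt_mean: float = 420.0  # ms, clear condition
    rt_sigma: float = 0.12  # lognormal shape of single-trial RTs

    def __post_init__(self) -> None:
        if self.group not in ("NH", "HL"):
            raise ValueError(f"group must be NH or HL, got {self.group!r}")
        lo, hi = PTA_RANGE[self.group]
        if not lo <= self.pta <= hi:
            raise ValueError(f"{self.group} PTA {self.pta} outside [{lo}, {hi}] dB HL")
        if self.coupling_g < 0:
            raise ValueError("coupling_g must be >= 0")
        if self.ffr_gain <= 0:
            raise ValueError("ffr_gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class RecordingSession:
    """Multichannel synthetic EEG for one participant-condition."""

    data: np.ndarray  # channels x samples, uV (float32)
    fs: float
    channel_labels: tuple[str, ...]
    events: pd.DataFrame  # onset_sample, token, polarity, block
    condition: str  # "clear" or "noise"
    ground_truth: pd.DataFrame | None = None  # per-trial alpha_state, source_amp
    source_z: np.ndarray | None = None  # noiseless z source, if kept

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data rows must match channel labels")
        ev = self.events["onset_sample"].to_numpy()
        if np.any(np.diff(ev) < 0):
            raise ValueError("events must be sorted by onset")
        if ev.size and (ev[0] < 0 or ev[-1] >= self.data.shape[1]):
            raise ValueError("event onsets outside data extent")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "RecordingSession":
        fields = dict(
            data=self.data, fs=self.fs, channel_labels=self.channel_labels,
            events=self.events, condition=self.condition,
            ground_truth=self.ground_truth, source_z=self.source_z,
        )
        fields.update(kw)
        return RecordingSession(**fields)


# classic 3-pole/3-zero IIR approximation of a 1/f amplitude spectrum
_PINK_B = [0.049922035, -0.095993537, 0.050612699, -0.004408786]
_PINK_A = [1.0, -2.494956002, 2.017265875, -0.522189400]


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Approximate 1/f noise via the classic 3-pole/3-zero IIR shaper."""
    x = signal.lfilter(_PINK_B, _PINK_A, rng.standard_normal(n + 2000, dtype=np.float32))[2000:]
    return (x / x.std()).astype(np.float32)


def _alpha_source(
    duration: float,
    fs: float,
    band: tuple[float, float],
    mod_depth: float,
    rng: np.random.Generator,
    fs_lo: float = 250.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Narrowband cortical source with slow amplitude modulation.

    Synthesized at a low internal rate and upsampled (content is < 25 Hz).
    Returns ``(waveform, envelope)`` at the requested rate, unit RMS.
    """
    n_lo = int(math.ceil(duration * fs_lo)) + 1
    sos = signal.butter(4, band, btype="bandpass", fs=fs_lo, output="sos")
    nb = signal.sosfiltfilt(sos, rng.standard_normal(n_lo + 1000))[500:-500]
    nb = nb[:n_lo]
    # slow modulation: low-passed noise on a ~10 s timescale
    sos_slow = signal.butter(2, 0.1, btype="lowpass", fs=fs_lo, output="sos")
    slow = signal.sosfiltfilt(sos_slow, rng.standard_normal(n_lo + 4000))[2000:-2000]
    slow = slow[:n_lo]
    slow = slow / max(slow.std(), 1e-12)
    mod = np.clip(1.0 + mod_depth * slow, 0.1, None)
    nb = nb * mod
    nb = nb / nb.std()
    env_lo = np.abs(signal.hilbert(nb))
    up = int(round(fs / fs_lo))
    if abs(up * fs_lo - fs) > 1e-9:
        raise ValueError("fs must be an integer multiple of the internal alpha rate")
    wave = signal.resample_poly(nb, up, 1)
    env = np.maximum(signal.resample_poly(env_lo, up, 1), 0.0)
    return wave, env


def _ffr_burst(spec: StimulusSpec, fs: float) -> np.ndarray:
    """Unit-amplitude evoked template: F0 + 2 harmonics, 10-100 ms post onset.

    5 ms raised-cosine on/off ramps; harmonic amplitudes (1, 0.4, 0.2)
    relative to the fundamental.  The template's fundamental component has
    amplitude 1, so a trial's source F0 amplitude equals its scale factor.
    """
    t0, t1 = 0.010, 0.100
    n = int(round((t1 - t0) * fs))
    t = t0 + np.arange(n) / fs
    w = np.zeros(n)
    for k, amp in enumerate((1.0, 0.4, 0.2), start=1):
        w += amp * np.sin(2 * np.pi * k * spec.f0 * (t - t0))
    ramp = np.ones(n)
    n_r = int(round(0.005 * fs))
    edge = 0.5 * (1 - np.cos(np.pi * np.arange(n_r) / n_r))
    ramp[:n_r] = edge
    ramp[-n_r:] = edge[::-1]
    return w * ramp, int(round(t0 * fs))


def simulate_session(
    params: ParticipantParams,
    leadfield: LeadfieldModel,
    schedule: list[ScheduledToken],
    condition: str,
    seed: int | np.random.Generator,
    spec: StimulusSpec | None = None,
    fs: float = 20000.0,
    keep_source: bool = False,
    epoch_window: tuple[float, float] = (-0.050, 0.145),
    output_fs: float | None = None,
) -> RecordingSession:
    """Project a coupled brainstem + cortical-alpha model to the scalp.

    Every token evokes a phase-locked burst at F0 = 150 Hz (plus two
    harmonics) whose amplitude on trial *t* is::

        ffr_gain * (1 + coupling_g * (alpha_state_t - 1))

    where ``alpha_state_t`` is the mean of the alpha source's Hilbert
    envelope over the trial's epoch window, normalized to the session
    median -- mirroring the analysis-side normalized RMS so ``coupling_g``
    maps interpretably onto the estimated F0 ratio.  The alpha source is
    projected with a posterior topography; white + 1/f noise is added per
    channel.  The babble condition adds band-limited masker energy to the
    evoked source drive at -10 dB relative amplitude and scales the gain
    by ``noise_ffr_scale``.

    ``output_fs`` emits the session already at the analysis rate: each
    channel is synthesized at ``fs`` and immediately anti-alias decimated
    (polyphase), which is numerically identical to synthesizing the whole
    array at ``fs`` and resampling afterwards but never materializes the
    full acquisition-rate multichannel array.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if condition not in ("clear", "noise"):
        raise ValueError(f"condition must be 'clear' or 'noise', got {condition!r}")
    spec = spec or StimulusSpec()
    if fs < 5000:
        raise ValueError("fs must be >= 5 kHz to represent 1 kHz FFR content")
    n_ch = leadfield.n_channels
    duration = schedule[-1].onset + spec.token_duration + 0.5
    n = int(math.ceil(duration * fs))

    alpha_wave, alpha_env = _alpha_source(duration, fs, (8.0, 12.0), params.alpha_mod_depth, rng)
    alpha_wave = alpha_wave[:n]
    alpha_env = alpha_env[:n]
    env_norm = alpha_env / np.median(alpha_env)

    onsets = np.array([int(round(ev.onset * fs)) for ev in schedule])
    w0 = int(round(epoch_window[0] * fs))
    w1 = int(round(epoch_window[1] * fs))
    # per-trial alpha state: mean normalized envelope over the epoch window
    csum = np.concatenate(([0.0], np.cumsum(env_norm)))
    starts = np.clip(onsets + w0, 0, n)
    stops = np.clip(onsets + w1, 0, n)
    with np.errstate(invalid="ignore"):
        alpha_state = (csum[stops] - csum[starts]) / np.maximum(stops - starts, 1)

    gain = params.ffr_gain * (params.noise_ffr_scale if condition == "noise" else 1.0)
    amps = gain * np.clip(1.0 + params.coupling_g * (alpha_state - 1.0), 0.0, None)

    burst, burst_offset = _ffr_burst(spec, fs)
    src_z = np.zeros(n)
    for onset, a in zip(onsets, amps):
        i0 = onset + burst_offset
        i1 = i0 + burst.size
        if 0 <= i0 and i1 <= n:
            src_z[i0:i1] += a * burst
    if condition == "noise":
        # babble band masker degrading the evoked drive, -10 dB re: gain
        sos = signal.butter(4, (100.0, 1000.0), btype="bandpass", fs=fs, output="sos")
        babble = signal.sosfilt(sos, rng.standard_normal(n))
        babble *= (gain * 10 ** (-10 / 20)) / babble.std()
        src_z = src_z + babble

    topo = posterior_alpha_topography(leadfield.channel_labels)
    Lz = leadfield.matrix[:, 2].astype(np.float32)
    alpha_amp = (params.alpha_base_power * topo).astype(np.float32)
    white_sd = np.float32(params.noise_sd / math.sqrt(2))
    src32 = src_z.astype(np.float32)
    alpha32 = alpha_wave.astype(np.float32)
    del alpha_wave, alpha_env, env_norm, csum

    if output_fs is None:
        up = down = 1
        out_fs, n_out = fs, n
    else:
        from fractions import Fraction

        if output_fs > fs:
            raise ValueError("output_fs above synthesis fs")
        frac = Fraction(output_fs / fs).limit_denominator(1000)
        up, down = frac.numerator, frac.denominator
        out_fs = output_fs
        n_out = signal.resample_poly(np.zeros(n, dtype=np.float32), up, down).size

    data = np.empty((n_ch, n_out), dtype=np.float32)
    for ch in range(n_ch):
        x = Lz[ch] * src32
        x += alpha_amp[ch] * alpha32
        if params.noise_sd > 0:
            x += white_sd * rng.standard_normal(n, dtype=np.float32)
            x += white_sd * _pink_noise(n, rng)
        if down > 1 or up > 1:
            x = signal.resample_poly(x, up, down).astype(np.float32)
        data[ch] = x

    if out_fs != fs:
        onsets = np.round(onsets * out_fs / fs).astype(int)
        if keep_source:
            src_z = signal.resample_poly(src_z, up, down)
    events = pd.DataFrame(
        {
            "onset_sample": onsets,
            "token": [ev.token for ev in schedule],
            "polarity": [ev.polarity for ev in schedule],
            "block": [ev.block for ev in schedule],
        }
    )
    truth = events.copy()
    truth["alpha_state"] = alpha_state
    truth["source_amp"] = amps
    return RecordingSession(
        data=data,
        fs=out_fs,
        channel_labels=leadfield.channel_labels,
        events=events,
        condition=condition,
        ground_truth=truth,
        source_z=src_z if keep_source else None,
    )


# --------------------------------------------------------------------------
# cohort and behavior
# --------------------------------------------------------------------------

_GROUP_DEFAULTS = {
    # group-level means for parameter draws; NH alpha power > HL,
    # NH coupling > HL (the programmed group contrast)
    "NH": dict(alpha_mu=4.5, alpha_sd=0.5, coupling=0.35, gain_slope=0.014),
    "HL": dict(alpha_mu=3.5, alpha_sd=0.5, coupling=0.10, gain_slope=0.003),
}


def draw_participant(
    group: str,
    index: int,
    rng: np.random.Generator,
    coupling: float | None = None,
    noise_sd: float = 5.0,
) -> ParticipantParams:
    """Draw one listener's generative parameters for the given group."""
    g = _GROUP_DEFAULTS[group]
    lo, hi = PTA_RANGE[group]
    pta = float(rng.uniform(lo, hi))
    base_gain = 0.15  # source units; unit leadfield peak -> ~0.15 uV at vertex
    gain = base_gain * (1.0 - g["gain_slope"] * (pta - 8.0))
    gain *= float(np.exp(rng.normal(0.0, 0.06)))
    coup = coupling if coupling is not None else g["coupling"]
    coup = max(0.0, coup * float(np.exp(rng.normal(0.0, 0.15))))
    # behavior links: hit probability is logistic in ffr_gain; RT decreases
    # with hit probability (clear condition only)
    p_clear = _logistic(1.8 + 30.0 * (gain - 0.13))
    p_noise = _logistic(1.8 + 30.0 * (gain - 0.13) - 1.2)
    snr50 = 1.6 + 0.10 * pta + float(rng.normal(0.0, 0.7 if group == "NH" else 2.0))
    return ParticipantParams(
        participant=f"{group}{index:02d}",
        group=group,
        age=float(rng.uniform(52, 75)),
        pta=pta,
        alpha_base_power=float(np.clip(rng.normal(g["alpha_mu"], g["alpha_sd"]), 1.5, None)),
        alpha_mod_depth=0.3,
        ffr_gain=gain,
        coupling_g=coup,
        noise_sd=noise_sd,
        snr50=snr50,
        hit_p_clear=p_clear,
        hit_p_noise=p_noise,
        rt_mean=float(420.0 - 150.0 * (p_clear - 0.85) + rng.normal(0.0, 15.0)),
    )


def _logistic(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


QUICKSIN_SNRS = (25, 20, 15, 10, 5, 0)  # dB, one sentence per step per list


def simulate_behavior(
    params: ParticipantParams,
    seed: int | np.random.Generator,
    n_targets: int = 210,
    n_lists: int = 4,
) -> dict:
    """Generate one listener's behavior: target detection, RTs, QuickSiN tallies.

    Per-condition hits are Bernoulli at the participant's hit probability;
    single-trial RTs (hits only) are lognormal around a mean that decreases
    with hit probability in the clear condition.  QuickSiN keyword tallies
    are binomial(5) draws from a logistic psychometric centered on the
    participant's SNR-50 (which tracks PTA), one sentence per SNR step.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out: dict = {"participant": params.participant, "conditions": {}}
    for condition, p_hit, rt_mu in (
        ("clear", params.hit_p_clear, params.rt_mean),
        ("noise", params.hit_p_noise, 480.0 + float(rng.normal(0, 25))),
    ):
        hits = rng.random(n_targets) < p_hit
        n_hits = int(hits.sum())
        if n_hits:
            rts = rt_mu * np.exp(rng.normal(0.0, params.rt_sigma, n_hits))
        else:
            rts = np.array([])
        out["conditions"][condition] = {"hits": hits, "rts": rts}
    tallies = np.empty((n_lists, len(QUICKSIN_SNRS)), dtype=int)
    for li in range(n_lists):
        for si, snr in enumerate(QUICKSIN_SNRS):
            p = _logistic((snr - params.snr50) / 3.0)
            tallies[li, si] = rng.binomial(5, p)
    out["quicksin_tallies"] = tallies
    return out


@dataclass
class Participant:
    params: ParticipantParams
    behavior: dict
    sessions: dict | None = None  # condition -> RecordingSession, if simulated


def make_cohort(
    n_nh: int = 13,
    n_hl: int = 19,
    seed: int | np.random.Generator = 0,
    coupling_nh: float | None = None,
    coupling_hl: float | None = None,
    simulate_sessions: bool = False,
    stimulus: StimulusSpec | None = None,
    leadfield: LeadfieldModel | None = None,
    fs: float = 20000.0,
) -> list[Participant]:
    """Draw a synthetic cohort (default 13 NH + 19 HL) with behavior.

    EEG sessions are simulated only on request (``simulate_sessions=True``,
    both conditions per participant) because full-length sessions are
    large; callers doing signal-level work usually simulate per participant
    with :func:`simulate_session`.
    """
    if n_nh < 1 or n_hl < 1:
        raise ValueError("need at least one participant per group")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cohort: list[Participant] = []
    for group, n_g, coup in (("NH", n_nh, coupling_nh), ("HL", n_hl, coupling_hl)):
        for i in range(n_g):
            params = draw_participant(group, i, rng, coupling=coup)
            behavior = simulate_behavior(params, rng)
            sessions = None
            if simulate_sessions:
                lf = leadfield or make_leadfield()
                sp = stimulus or StimulusSpec()
                sessions = {}
                for condition in ("clear", "noise"):
                    schedule = make_event_schedule(sp, rng)
                    sessions[condition] = simulate_session(
                        params, lf, schedule, condition, rng, spec=sp, fs=fs
                    )
            cohort.append(Participant(params=params, behavior=behavior, sessions=sessions))
    return cohort


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def write_session(session: RecordingSession, stem: Path) -> None:
    """Write a session as FIF raw (+ sidecar CSV event table).

    The sidecar carries onset_sample, token, polarity, block, condition --
    the declared file interface to the preprocessing stage.  Real EDF
    recordings are read back through :func:`read_session` as well (MNE
    reads EDF natively).
    """
    import mne

    stem = Path(stem)
    info = mne.create_info(list(session.channel_labels), session.fs, ch_types="eeg")
    raw = mne.io.RawArray(session.data.astype(np.float64) * 1e-6, info, verbose="error")
    raw.save(stem.with_suffix(".raw.fif"), overwrite=True, verbose="error")
    ev = session.events.copy()
    ev["condition"] = session.condition
    ev.to_csv(stem.with_suffix(".events.csv"), index=False)


def read_session(stem: Path) -> RecordingSession:
    import mne

    stem = Path(stem)
    fif = stem.with_suffix(".raw.fif")
    if fif.exists():
        raw = mne.io.read_raw_fif(fif, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(stem.with_suffix(".edf"), preload=True, verbose="error")
    ev = pd.read_csv(stem.with_suffix(".events.csv"))
    condition = str(ev["condition"].iloc[0])
    return RecordingSession(
        data=(raw.get_data() * 1e6).astype(np.float32),
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        events=ev.drop(columns=["condition"]),
        condition=condition,
    )


def write_cohort_manifest(cohort: list[Participant], path: Path) -> None:
    """Ground-truth parameter manifest as JSON (one entry per participant)."""
    payload = []
    for p in cohort:
        d = asdict(p.params)
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=2))
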