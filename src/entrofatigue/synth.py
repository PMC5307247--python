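"""Synthetic two-state (normal vs fatigue) multi-channel EEG generator.

Real driving-fatigue EEG corpora are rarely shareable, so every stage of the
pipeline is exercised on simulated recordings with a *controllable* contrast
between an alert ("normal") and a drowsy ("fatigue") state.  Each channel is a
sum of

* one band-limited oscillator per classical EEG band (delta, theta, alpha,
  beta) with random frequency and phase and a slowly varying amplitude
  envelope,
* ``1/f^a`` background (pink-ish) noise,
* a high-frequency (> 45 Hz) EMG-like noise component modelling scalp-muscle
  contamination, and
* a small white sensor-noise floor.

The fatigue contrast is governed by a single dimensionless effect size
``regularity_boost`` (written delta below).  As delta grows, three things
happen, all making the fatigue signal more regular:

1. the EMG contamination is suppressed (drowsy drivers have reduced muscle
   tone), removing most of the fast sample-scale jitter;
2. a fraction of the broadband background-noise power is transferred into a
   slowly frequency-wandering tone at the subject's own alpha-band trait
   frequency (the classical drowsy-alpha phenomenon);
3. the band amplitudes blend mildly toward a fatigue profile (more
   theta/alpha, less beta).

All four entropy features decrease in the fatigue state in expectation, and
at ``delta = 0`` the two states are drawn from identical distributions.  The
mechanisms are deliberately *not* equally visible to every feature: the EMG
suppression happens above the 45 Hz edge of the spectral-entropy band, so
spectral entropy sees only the (envelope-masked) alpha and band-profile
changes, while the template entropies — computed in the time domain on the
full preprocessed signal, which retains a residual of the > 45 Hz jitter
after the band-pass roll-off — see the regularity change directly.  Fuzzy
entropy and its relatives therefore discriminate the states better than
spectral entropy, the regime the benchmark design targets.

Generation is deterministic given ``(seed, subject, state, channel index)``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

STATE_NORMAL = "normal"
STATE_FATIGUE = "fatigue"
STATES = (STATE_NORMAL, STATE_FATIGUE)
#: integer class labels used throughout the pipeline (positive class = fatigue)
STATE_LABELS = {STATE_NORMAL: 0, STATE_FATIGUE: 1}

#: conventional EEG band edges in Hz
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: 30 effective channels of a 32-electrode 10-20 cap (two mastoid references excluded)
CHANNELS_30: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T3", "C3", "Cz", "C4", "T4",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
)

DEFAULT_BAND_POWERS_NORMAL = {"delta": 1.0, "theta": 0.7, "alpha": 0.8, "beta": 0.5}
DEFAULT_BAND_POWERS_FATIGUE = {"delta": 1.05, "theta": 0.85, "alpha": 0.95, "beta": 0.42}


#: base oscillator amplitude in microvolts for a band weight of 1.0
_AMP_SCALE_UV = 10.0


class SynthConfigError(ValueError):
    """Invalid synthetic-generator configuration."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the two-state synthetic EEG generator.

    Parameters
    ----------
    n_subjects : int
        Number of simulated subjects; each contributes one normal and one
        fatigue recording.
    channel_names : tuple of str
        Ordered 10-20 electrode labels; the first ``n`` entries of the
        standard 30-channel montage by default.
    fs : float
        Sampling rate in Hz.
    epochs_per_state : int
        Number of epochs each state's recording is later cut into.
    epoch_len_s : float
        Epoch length in seconds.
    band_powers_normal, band_powers_fatigue : dict
        Relative oscillator amplitude per band in the two states.  The
        fatigue profile is only reached asymptotically as
        ``regularity_boost`` grows; at 0 the states are identical.
    noise_exponent : float
        Spectral slope ``a`` of the 1/f^a background noise.
    noise_sd : float
        Standard deviation (microvolts) of the background noise.
    emg_sd : float
        Standard deviation (microvolts) of the high-frequency EMG-like
        component (band-limited above 45 Hz), suppressed in the fatigue
        state as muscle tone drops.
    sensor_noise_sd : float
        White measurement-noise floor (microvolts), identical in both states.
    regularity_boost : float
        Effect size delta >= 0.  Controls both the broadband-to-narrowband
        power transfer and the band-profile blending in the fatigue state.
    delta_overrides : dict or None
        Optional per-channel override of ``regularity_boost`` (e.g. to plant
        a single strongly discriminative channel).
    subject_band_sigma : float
        Log-normal sigma of per-(subject, band) amplitude offsets, shared by
        both states of a subject.
    subject_delta_sigma : float
        Log-normal sigma of per-(subject, channel) multipliers on delta,
        making the most discriminative channel subject-specific.
    envelope_sigma : float
        Log-normal sigma of the per-second oscillator amplitude envelope.
    seed : int
        Master seed; all randomness derives from it.
    """

    n_subjects: int = 12
    channel_names: tuple[str, ...] = CHANNELS_30
    fs: float = 1000.0
    epochs_per_state: int = 300
    epoch_len_s: float = 1.0
    band_powers_normal: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_POWERS_NORMAL))
    band_powers_fatigue: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_POWERS_FATIGUE))
    noise_exponent: float = 1.0
    noise_sd: float = 3.0
    emg_sd: float = 25.0
    sensor_noise_sd: float = 0.5
    regularity_boost: float = 1.0
    delta_overrides: dict[str, float] | None = None
    subject_band_sigma: float = 0.1
    subject_delta_sigma: float = 0.15
    envelope_sigma: float = 0.2
    alpha_wander_hz: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SynthConfigError("n_subjects must be >= 1")
        if len(self.channel_names) < 1:
            raise SynthConfigError("at least one channel is required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise SynthConfigError("channel names must be unique")
        highest_edge = max(hi for _, hi in BANDS.values())
        if self.fs <= 2.0 * highest_edge:
            raise SynthConfigError(
                f"fs={self.fs} Hz aliases the {highest_edge} Hz band edge; "
                f"need fs > {2 * highest_edge} Hz")
        if self.epochs_per_state < 2:
            raise SynthConfigError("epochs_per_state must be >= 2")
        if self.epoch_len_s <= 0:
            raise SynthConfigError("epoch_len_s must be positive")
        for name, powers in (("band_powers_normal", self.band_powers_normal),
                             ("band_powers_fatigue", self.band_powers_fatigue)):
            if set(powers) != set(BANDS):
                raise SynthConfigError(f"{name} must define exactly {sorted(BANDS)}")
            if any(v < 0 for v in powers.values()):
                raise SynthConfigError(f"{name} amplitudes must be >= 0")
        if self.regularity_boost < 0:
            raise SynthConfigError("regularity_boost must be >= 0")
        if self.delta_overrides:
            unknown = set(self.delta_overrides) - set(self.channel_names)
            if unknown:
                raise SynthConfigError(f"delta_overrides for unknown channels: {sorted(unknown)}")
            if any(v < 0 for v in self.delta_overrides.values()):
                raise SynthConfigError("delta_overrides must be >= 0")
        if self.noise_sd < 0 or self.sensor_noise_sd < 0 or self.emg_sd < 0:
            raise SynthConfigError("noise amplitudes must be >= 0")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_len_s * self.fs))

    @property
    def samples_per_state(self) -> int:
        return self.epochs_per_state * self.epoch_samples

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Recording:
    """One subject x one state block of raw multi-channel EEG.

    ``data`` is a ``(n_channels, n_samples)`` float array in microvolts.
    """

    subject_id: int
    state: str
    channels: tuple[str, ...]
    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if self.data.ndim != 2:
            raise ValueError("data must be a (channels, samples) matrix")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel count mismatch between labels and data")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains NaN or Inf samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channels = tuple(self.channels)

    @property
    def label(self) -> int:
        """Integer class label (normal=0, fatigue=1)."""
        return STATE_LABELS[self.state]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# random streams
# ---------------------------------------------------------------------------

def _subject_rng(cfg: SynthConfig, subject_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1, subject_id)))


def _trait_rng(cfg: SynthConfig, subject_id: int, ch_idx: int) -> np.random.Generator:
    """Stream for state-independent channel traits (oscillator frequencies)."""
    return np.random.default_rng(
        np.random.SeedSequence(cfg.seed, spawn_key=(3, subject_id, ch_idx)))


def _channel_rng(cfg: SynthConfig, subject_id: int, state: str, ch_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(cfg.seed, spawn_key=(2, subject_id, STATE_LABELS[state], ch_idx)))


def _subject_offsets(cfg: SynthConfig, subject_id: int) -> tuple[dict[str, float], np.ndarray]:
    """Per-subject traits shared by both states: band-amplitude multipliers
    (log-normal) and per-channel multipliers on the fatigue effect size."""
    rng = _subject_rng(cfg, subject_id)
    band_mult = {b: float(np.exp(rng.normal(0.0, cfg.subject_band_sigma))) for b in BANDS}
    delta_mult = np.exp(rng.normal(0.0, cfg.subject_delta_sigma, size=cfg.n_channels))
    return band_mult, delta_mult


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, fs: float) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^exponent, unit variance."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    shape = np.zeros_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


#: EMG-like contamination occupies this band (upper edge capped below Nyquist)
_EMG_BAND = (45.0, 150.0)


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Gaussian noise band-limited to [lo, hi] Hz, unit variance."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    mask = (freqs >= lo) & (freqs <= hi)
    x = np.fft.irfft(spec * mask, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _blend_factor(delta: float) -> float:
    """Band-profile blending weight in [0, 1); 0 at delta=0."""
    return 1.0 - float(np.exp(-delta))


def _transfer_fraction(delta: float) -> float:
    """Fraction of background-noise power moved into the regular component."""
    return 1.0 - float(np.exp(-delta / 2.0))


def _emg_suppression(delta: float) -> float:
    """Fraction of EMG power removed in the fatigue state (muscle-tone drop)."""
    return 1.0 - float(np.exp(-1.5 * delta))


def generate_channel(cfg: SynthConfig, subject_id: int, state: str, ch_idx: int) -> np.ndarray:
    """Generate one channel of one (subject, state) recording.

    The same random draws are consumed regardless of ``regularity_boost`` or
    the state's band profile, so the effect size only changes deterministic
    mixing coefficients.  That gives common-random-number coupling across
    effect sizes, making the entropy contrast (almost surely) monotone in
    delta for a fixed seed.  Oscillator frequencies are subject/channel
    *traits* shared by both states (a subject's spectral peaks do not move
    between recordings); only phases, envelopes and noise are redrawn per
    state, so at delta=0 the states differ by nothing but those draws.
    """
    if state not in STATES:
        raise ValueError(f"state must be one of {STATES}, got {state!r}")
    n = cfg.samples_per_state
    t = np.arange(n) / cfg.fs
    rng = _channel_rng(cfg, subject_id, state, ch_idx)
    band_mult, delta_mult = _subject_offsets(cfg, subject_id)

    channel = cfg.channel_names[ch_idx]
    base_delta = cfg.regularity_boost
    if cfg.delta_overrides and channel in cfg.delta_overrides:
        base_delta = cfg.delta_overrides[channel]
    delta = base_delta * float(delta_mult[ch_idx])

    if state == STATE_FATIGUE:
        beta = _blend_factor(delta)
        p_transfer = _transfer_fraction(delta)
        p_emg = _emg_suppression(delta)
    else:
        beta, p_transfer, p_emg = 0.0, 0.0, 0.0

    trait_rng = _trait_rng(cfg, subject_id, ch_idx)
    band_freqs = {band: trait_rng.uniform(lo, hi) for band, (lo, hi) in BANDS.items()}

    n_sec = max(1, int(np.ceil(n / cfg.fs)))
    x = np.zeros(n)
    for band in BANDS:
        f = band_freqs[band]
        phase = rng.uniform(0.0, 2.0 * np.pi)
        env = np.repeat(np.exp(rng.normal(0.0, cfg.envelope_sigma, size=n_sec)),
                        int(cfg.fs))[:n]
        w_normal = cfg.band_powers_normal[band]
        w_fatigue = cfg.band_powers_fatigue[band]
        weight = (1.0 - beta) * w_normal + beta * w_fatigue
        amp = _AMP_SCALE_UV * weight * band_mult[band]
        x += amp * env * np.sin(2.0 * np.pi * f * t + phase)

    noise = _pink_noise(rng, n, cfg.noise_exponent, cfg.fs) * cfg.noise_sd

    # regular (fatigue) component: a tone at the subject's own alpha trait
    # frequency with a slowly wandering instantaneous frequency.  Spectrally
    # it reinforces an oscillation that is already there (hiding in the
    # epoch-to-epoch envelope fluctuations of the alpha band), but it
    # replaces *broadband* noise power, which is what the template entropies
    # respond to.
    wander = np.clip(np.cumsum(rng.normal(0.0, 0.4, size=n_sec)),
                     -cfg.alpha_wander_hz, cfg.alpha_wander_hz)
    f_inst = band_freqs["alpha"] + np.repeat(wander, int(cfg.fs))[:n]
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    regular = np.sin(2.0 * np.pi * np.cumsum(f_inst) / cfg.fs + phase0)
    # sin has power 1/2; scale so the component's power is p * noise power
    regular_amp = cfg.noise_sd * np.sqrt(2.0 * p_transfer)

    # EMG-like contamination: suppressed with muscle tone in the fatigue state
    emg_hi = min(_EMG_BAND[1], 0.45 * cfg.fs)
    emg = _band_noise(rng, n, cfg.fs, _EMG_BAND[0], emg_hi) * cfg.emg_sd
    emg_gain = np.sqrt(1.0 - p_emg)

    sensor = rng.normal(0.0, 1.0, size=n) * cfg.sensor_noise_sd

    return (x + np.sqrt(1.0 - p_transfer) * noise + regular_amp * regular
            + emg_gain * emg + sensor)


def generate_recording(cfg: SynthConfig, subject_id: int, state: str) -> Recording:
    """Simulate one (subject, state) block of multi-channel EEG.

    The block is ``epochs_per_state * epoch_len_s`` seconds long per channel,
    so that later 1-epoch segmentation yields exactly ``epochs_per_state``
    epochs.

    Raises
    ------
    ValueError
        If ``state`` is not ``"normal"`` or ``"fatigue"``.
    SynthConfigError
        If the configuration is invalid (checked at construction).
    """
    if state not in STATES:
        raise ValueError(f"state must be one of {STATES}, got {state!r}")
    if not 0 <= subject_id < cfg.n_subjects:
        raise ValueError(f"subject_id {subject_id} outside 0..{cfg.n_subjects - 1}")
    data = np.vstack([generate_channel(cfg, subject_id, state, c)
                      for c in range(cfg.n_channels)])
    return Recording(subject_id=subject_id, state=state,
                     channels=cfg.channel_names, data=data, fs=cfg.fs)


def generate_dataset(cfg: SynthConfig) -> list[Recording]:
    """Simulate the full study: two labeled recordings per subject.

    With the defaults (12 subjects, 300 one-second epochs per state) the
    dataset comprises 3600 normal and 3600 fatigue epochs in total.
    """
    recs = []
    for s in range(cfg.n_subjects):
        for state in STATES:
            recs.append(generate_recording(cfg, s, state))
    logger.info("generated %d recordings (%d subjects x 2 states, %d channels)",
                len(recs), cfg.n_subjects, cfg.n_channels)
    return recs
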