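"""Filtering, epoch segmentation and per-subject feature normalization.

The preprocessing chain mirrors a standard clinical EEG workflow: a mains
notch filter (50 Hz) plus a 0.15-45 Hz band-pass, both applied forward and
backward (zero phase) so epoch boundaries are not shifted; the continuous
recording is then cut into contiguous, non-overlapping 1-second epochs, each
inheriting the recording's state label.  Before classification, every feature
column is min-max scaled to [-1, 1] within each subject.

The contract of :func:`apply_filters` is a frequency-response specification
(>= 20 dB attenuation at the notch, <= 1 dB ripple at 10 Hz), not a specific
kernel; the default design is an IIR Butterworth band-pass in second-order
sections plus a biquad notch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .synth import Recording, STATE_LABELS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Notch + band-pass filter parameters.

    ``notch_freq`` and the band edges are in Hz; ``notch_q`` is the notch
    quality factor (bandwidth = notch_freq / notch_q); ``bp_order`` is the
    Butterworth order of the band-pass prototype.
    """

    notch_freq: float = 50.0
    notch_q: float = 30.0
    bp_low: float = 0.15
    bp_high: float = 45.0
    bp_order: int = 4

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not 0 < self.bp_low < self.bp_high:
            raise ValueError("need 0 < bp_low < bp_high")
        if self.bp_high >= nyq:
            raise ValueError(f"bp_high={self.bp_high} Hz >= Nyquist ({nyq} Hz)")
        if not 0 < self.notch_freq < nyq:
            raise ValueError(f"notch_freq={self.notch_freq} Hz outside (0, {nyq}) Hz")
        if self.notch_q <= 0 or self.bp_order < 1:
            raise ValueError("notch_q must be > 0 and bp_order >= 1")


def apply_filters(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Zero-phase notch + band-pass filtering of every channel.

    Returns a new :class:`Recording` of identical shape.  Zero-phase
    (forward-backward) application preserves the temporal alignment of
    subsequent epoch boundaries; the effective magnitude response is the
    square of the one-pass design.
    """
    spec = spec or FilterSpec()
    spec.validate(rec.fs)
    b_notch, a_notch = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=rec.fs)
    sos = signal.butter(spec.bp_order, [spec.bp_low, spec.bp_high],
                        btype="bandpass", fs=rec.fs, output="sos")
    out = signal.filtfilt(b_notch, a_notch, rec.data, axis=1)
    out = signal.sosfiltfilt(sos, out, axis=1)
    return replace(rec, data=out)


@dataclass
class EpochSet:
    """Per-channel segmentation of recordings into labeled epochs.

    ``epochs`` is ``(n_epochs, epoch_samples)``; ``labels`` holds the state
    of each epoch (normal=0, fatigue=1).
    """

    subject_id: int
    channel: str
    epochs: np.ndarray
    labels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.epochs.ndim != 2:
            raise ValueError("epochs must be a (n_epochs, epoch_samples) matrix")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("labels length must equal the number of epochs")
        if not np.isfinite(self.epochs).all():
            raise ValueError("epochs contain NaN or Inf")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def epoch_recording(rec: Recording, epoch_len_s: float = 1.0) -> dict[str, EpochSet]:
    """Cut a recording into contiguous fixed-length epochs, per channel.

    Epochs are the half-open sample intervals ``[k*L, (k+1)*L)``; a trailing
    remainder shorter than one epoch is discarded.  Every epoch inherits the
    recording's state label.

    Raises
    ------
    ValueError
        If the recording is shorter than one epoch.
    """
    epoch_samples = int(round(epoch_len_s * rec.fs))
    if epoch_samples < 1:
        raise ValueError("epoch_len_s too short for the sampling rate")
    n_epochs = rec.n_samples // epoch_samples
    if n_epochs == 0:
        raise ValueError(
            f"recording has {rec.n_samples} samples, shorter than one "
            f"{epoch_samples}-sample epoch")
    discarded = rec.n_samples - n_epochs * epoch_samples
    if discarded:
        logger.debug("epoching discards %d trailing samples", discarded)
    labels = np.full(n_epochs, STATE_LABELS[rec.state], dtype=int)
    out = {}
    for ch_idx, ch in enumerate(rec.channels):
        segment = rec.data[ch_idx, : n_epochs * epoch_samples]
        out[ch] = EpochSet(subject_id=rec.subject_id, channel=ch,
                           epochs=segment.reshape(n_epochs, epoch_samples),
                           labels=labels.copy(), fs=rec.fs)
    return out


def stack_epochsets(*sets: EpochSet) -> EpochSet:
    """Concatenate epoch sets of the same subject/channel (e.g. both states)."""
    if not sets:
        raise ValueError("need at least one EpochSet")
    first = sets[0]
    for s in sets[1:]:
        if (s.subject_id, s.channel, s.fs, s.epochs.shape[1]) != \
                (first.subject_id, first.channel, first.fs, first.epochs.shape[1]):
            raise ValueError("EpochSets differ in subject, channel, fs or epoch length")
    return EpochSet(subject_id=first.subject_id, channel=first.channel,
                    epochs=np.vstack([s.epochs for s in sets]),
                    labels=np.concatenate([s.labels for s in sets]),
                    fs=first.fs)


def normalize_features(features: pd.DataFrame, scope: str = "subject") -> pd.DataFrame:
    """Min-max scale each feature column to [-1, 1] within each subject.

    ``features`` is the tidy table produced by
    :func:`entrofatigue.entropy.extract_features` (columns ``subject``,
    ``channel``, ``epoch``, ``label``, ``feature``, ``value``).  A feature
    column is the set of values of one ``(subject, channel, feature)`` group,
    pooled over both states — the normalization is fit before classification,
    which mildly leaks the test epochs' range into training; a
    train-fold-only variant is available inside the evaluation harness
    (``fold_normalize=True``).

    Degenerate (constant) columns map to 0 and are counted in a warning.
    """
    if scope != "subject":
        raise ValueError("only per-subject scope is supported")
    required = {"subject", "channel", "feature", "value"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")

    out = features.copy()
    n_constant = 0

    def _scale(col: pd.Series) -> pd.Series:
        nonlocal n_constant
        lo, hi = col.min(), col.max()
        if hi == lo:
            n_constant += 1
            return pd.Series(0.0, index=col.index)
        return (col - lo) / (hi - lo) * 2.0 - 1.0

    out["value"] = (out.groupby(["subject", "channel", "feature"], sort=False)["value"]
                    .transform(_scale))
    if n_constant:
        logger.warning("normalize_features: %d constant column(s) set to 0", n_constant)
    return out


def minmax_fit(train_values: np.ndarray) -> tuple[float, float]:
    """Fit the [-1, 1] min-max map on training values only (strict mode)."""
    lo, hi = float(np.min(train_values)), float(np.max(train_values))
    return lo, hi


def minmax_apply(values: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    """Apply a fitted min-max map, clipping outside values into [-1, 1]."""
    lo, hi = bounds
    if hi == lo:
        return np.zeros_like(np.asarray(values, dtype=float))
    return np.clip((np.asarray(values, dtype=float) - lo) / (hi - lo) * 2.0 - 1.0,
                   -1.0, 1.0)
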