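"""Recording containers, re-referencing, filtering, EMG onset detection, epoching.

Conventions: sample indexing is 0-based; epoch windows are half-open
``[onset - pre, onset + post)`` so the time-zero sample of an epoch holds the
onset sample itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

from .errors import (
    EmptyResultError,
    InvalidInputError,
    InvalidParameterError,
)

logger = logging.getLogger(__name__)

#: Default epoch window (ms before / after EMG onset).
DEFAULT_PRE_MS = 2000.0
DEFAULT_POST_MS = 4000.0


@dataclass
class Recording:
    """Multichannel ECoG plus one bipolar EMG channel at a common rate.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_ids : sequence of str
        Ordered channel labels, one per data row.
    emg : ndarray, shape (n_samples,), optional
        Bipolar EMG at the same rate.
    geometry_ref : str, optional
        Identifier of the electrode grid the channels belong to.
    excluded_channels : set of str
        Labels excluded from analysis (bad contacts); must be a subset of
        ``channel_ids``.
    """

    data: np.ndarray
    fs: float
    channel_ids: list[str]
    emg: np.ndarray | None = None
    geometry_ref: str | None = None
    excluded_channels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidInputError("data must be a 2-D (channels x samples) array")
        if self.fs <= 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        self.channel_ids = list(self.channel_ids)
        if len(self.channel_ids) != self.data.shape[0]:
            raise InvalidInputError(
                f"{len(self.channel_ids)} channel ids for {self.data.shape[0]} rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise InvalidInputError("channel ids must be unique")
        if self.emg is not None:
            self.emg = np.asarray(self.emg, dtype=float)
            if self.emg.shape != (self.data.shape[1],):
                raise InvalidInputError("emg length must match the signal length")
        self.excluded_channels = set(self.excluded_channels)
        unknown = self.excluded_channels - set(self.channel_ids)
        if unknown:
            raise InvalidInputError(f"excluded channels not in recording: {sorted(unknown)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def usable_channels(self) -> list[str]:
        """Channel labels that are not excluded, in recording order."""
        return [c for c in self.channel_ids if c not in self.excluded_channels]


@dataclass
class EventSet:
    """EMG onset sample indices, one per trial (time zero of the trial)."""

    onsets: np.ndarray
    source: str = "annotated"  # "annotated" | "detected"

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64).ravel()
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise InvalidInputError("onsets must be strictly increasing")
        if self.source not in ("annotated", "detected"):
            raise InvalidInputError(f"unknown event source {self.source!r}")

    def __len__(self) -> int:
        return int(self.onsets.size)


@dataclass
class TrialSet:
    """Epochs cut on a fixed window around EMG onset.

    ``epochs`` is trials x channels x time; time zero (the onset sample) sits
    at index ``pre_ms * fs / 1000``. ``trial_keep_mask`` marks trials that
    survived artifact rejection; rejected trials keep their data.
    """

    epochs: np.ndarray
    fs: float
    channel_ids: list[str]
    pre_ms: float = DEFAULT_PRE_MS
    post_ms: float = DEFAULT_POST_MS
    trial_keep_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise InvalidInputError("epochs must be trials x channels x time")
        expected = int(round((self.pre_ms + self.post_ms) * self.fs / 1000.0))
        if self.epochs.shape[2] != expected:
            raise InvalidInputError(
                f"epoch length {self.epochs.shape[2]} != window {expected} samples"
            )
        if self.epochs.shape[1] != len(self.channel_ids):
            raise InvalidInputError("channel_ids must match epoch channel axis")
        if self.trial_keep_mask is None:
            self.trial_keep_mask = np.ones(self.epochs.shape[0], dtype=bool)
        else:
            self.trial_keep_mask = np.asarray(self.trial_keep_mask, dtype=bool)
            if self.trial_keep_mask.shape != (self.epochs.shape[0],):
                raise InvalidInputError("trial_keep_mask must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.trial_keep_mask.sum())

    @property
    def zero_index(self) -> int:
        """Epoch sample index of the EMG onset."""
        return int(round(self.pre_ms * self.fs / 1000.0))

    def kept_epochs(self) -> np.ndarray:
        """Epoch array restricted to kept trials."""
        return self.epochs[self.trial_keep_mask]

    def channel_index(self, channel: str) -> int:
        try:
            return self.channel_ids.index(channel)
        except ValueError:
            raise InvalidInputError(f"unknown channel {channel!r}") from None

    def time_ms(self) -> np.ndarray:
        """Time axis in ms relative to onset."""
        n = self.epochs.shape[2]
        return (np.arange(n) - self.zero_index) / self.fs * 1000.0


def apply_car(rec: Recording) -> Recording:
    """Re-reference to the common average of the non-excluded channels.

    Excluded channels do not enter the average and are dropped from the
    output. After the operation the cross-channel mean is zero at every
    sample.
    """
    usable = rec.usable_channels()
    if len(usable) < 2:
        raise InvalidInputError(
            f"common average reference needs >=2 usable channels, have {len(usable)}"
        )
    if len(usable) == len(rec.channel_ids):
        sub = rec.data  # no exclusions: skip the fancy-index copy
    else:
        idx = [rec.channel_ids.index(c) for c in usable]
        sub = rec.data[idx]
    ref = sub.mean(axis=0, keepdims=True)
    out = replace(rec, data=sub - ref, channel_ids=usable, excluded_channels=set())
    return out


def _butter_band(low: float, high: float, fs: float, order: int):
    if high >= fs / 2:
        raise InvalidParameterError(
            f"high cutoff {high} Hz must be below Nyquist {fs / 2} Hz"
        )
    if not 0 < low < high:
        raise InvalidParameterError(f"need 0 < low < high, got ({low}, {high})")
    return _sig.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_mrcp(
    rec: Recording, low: float = 0.05, high: float = 3.0, order: int = 2
) -> Recording:
    """Band-pass for the slow cortical potential, default 0.05-3 Hz.

    Applied forward-backward (zero phase) so waveform latencies are
    preserved; the effective magnitude response is the squared Butterworth
    response of the given order.
    """
    sos = _butter_band(low, high, rec.fs, order)
    out = _sig.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=out)


def detect_emg_onsets(
    emg: np.ndarray,
    fs: float,
    threshold_frac: float = 0.1,
    refractory_s: float = 4.0,
) -> EventSet:
    """Detect movement onsets as upward threshold crossings of rectified EMG.

    The threshold is ``threshold_frac`` times the maximum rectified
    amplitude; crossings closer than ``refractory_s`` to the previous onset
    are suppressed. An all-zero signal yields an empty event set.
    """
    emg = np.asarray(emg, dtype=float).ravel()
    if not 0 < threshold_frac < 1:
        raise InvalidParameterError(f"threshold_frac must be in (0,1), got {threshold_frac}")
    rect = np.abs(emg)
    peak = rect.max() if rect.size else 0.0
    if peak == 0.0:
        return EventSet(onsets=np.empty(0, dtype=np.int64), source="detected")
    thr = threshold_frac * peak
    above = rect >= thr
    # first samples above threshold whose predecessor is below
    crossings = np.flatnonzero(above & ~np.concatenate(([True], above[:-1])))
    if above[0]:
        crossings = np.concatenate(([0], crossings))
    gap = int(round(refractory_s * fs))
    onsets: list[int] = []
    for c in crossings:
        if not onsets or c - onsets[-1] >= gap:
            onsets.append(int(c))
    return EventSet(onsets=np.asarray(onsets, dtype=np.int64), source="detected")


def epoch_trials(
    rec: Recording,
    events: EventSet,
    pre_ms: float = DEFAULT_PRE_MS,
    post_ms: float = DEFAULT_POST_MS,
) -> TrialSet:
    """Cut one epoch per onset on ``[onset - pre, onset + post)``.

    Onsets whose window overruns the recording edges are dropped and logged;
    if none survive an :class:`EmptyResultError` is raised.
    """
    pre = int(round(pre_ms * rec.fs / 1000.0))
    post = int(round(post_ms * rec.fs / 1000.0))
    n = rec.n_samples
    kept, dropped = [], []
    for onset in events.onsets:
        if onset - pre >= 0 and onset + post <= n:
            kept.append(int(onset))
        else:
            dropped.append(int(onset))
    if dropped:
        logger.info("dropped %d onset(s) overrunning the recording edges: %s",
                    len(dropped), dropped)
    if not kept:
        raise EmptyResultError("no onset leaves a full epoch inside the recording")
    epochs = np.stack([rec.data[:, o - pre : o + post] for o in kept])
    return TrialSet(
        epochs=epochs,
        fs=rec.fs,
        channel_ids=list(rec.channel_ids),
        pre_ms=pre_ms,
        post_ms=post_ms,
    )


def reject_trials(ts: TrialSet, amplitude_z_max: float = 5.0) -> TrialSet:
    """Mask out trials whose peak amplitude is a robust-z outlier.

    The per-trial peak absolute amplitude (over channels and time) is
    z-scored with median/MAD; trials beyond ``amplitude_z_max`` are masked.
    Data is retained; only the keep mask changes.
    """
    if ts.n_trials < 1:
        raise InvalidInputError("need at least one trial")
    peaks = np.abs(ts.epochs).max(axis=(1, 2))
    med = np.median(peaks)
    mad = np.median(np.abs(peaks - med))
    scale = 1.4826 * mad
    if scale == 0.0:
        z = np.zeros_like(peaks)
    else:
        z = (peaks - med) / scale
    keep = ts.trial_keep_mask & (z <= amplitude_z_max)
    if not keep.any():
        raise EmptyResultError("all trials rejected by the amplitude criterion")
    n_rej = int(ts.trial_keep_mask.sum() - keep.sum())
    if n_rej:
        logger.info("rejected %d trial(s) with robust z > %g", n_rej, amplitude_z_max)
    return TrialSet(
        epochs=ts.epochs,
        fs=ts.fs,
        channel_ids=list(ts.channel_ids),
        pre_ms=ts.pre_ms,
        post_ms=ts.post_ms,
        trial_keep_mask=keep,
    )
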