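"""Frequency alteration mapping: normalized band power task/rest comparison.

For every trial one 1 s task segment (0..1000 ms after onset) and one 1 s
rest segment (-3500..-2500 ms) are Hanning-tapered and Fourier transformed
at 1 Hz resolution. Log power is normalized by the ensemble mean per
frequency, summed over a low (8-32 Hz) and a high (66-90 Hz) band, and the
task and rest sums are compared with a signed squared effect statistic and
a balanced one-way ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy import stats as _stats

from .errors import (
    DegenerateInputError,
    InvalidConfigurationError,
    InvalidInputError,
    InvalidParameterError,
)
from .preproc import TrialSet

logger = logging.getLogger(__name__)

TASK_WINDOW_MS = (0.0, 1000.0)
REST_WINDOW_MS = (-3500.0, -2500.0)

LFB = (8, 32)
HFB = (66, 90)

ALPHA = 0.01


@dataclass
class SpectralEnsemble:
    """Per-segment power spectra of one channel, plus their log-normalized form.

    ``power`` is segments x frequencies (strictly positive where analyzed);
    ``norm_log_power`` follows the ensemble normalization: per frequency the
    mean over segments of ``exp(norm_log_power)`` is 1. The first
    ``n_task`` rows are task segments, the rest are rest segments.
    """

    power: np.ndarray
    norm_log_power: np.ndarray
    freqs: np.ndarray
    n_task: int

    @property
    def n_segments(self) -> int:
        return self.power.shape[0]

    @property
    def segment_labels(self) -> np.ndarray:
        lab = np.full(self.n_segments, "rest", dtype=object)
        lab[: self.n_task] = "task"
        return lab


@dataclass
class BandActivation:
    """Task/rest band-sum comparison for one channel and band."""

    channel: str
    band: tuple[int, int]
    task_sums: np.ndarray
    rest_sums: np.ndarray
    weight: float
    p_raw: float
    p_corrected: float
    significant: bool

    @property
    def task_mean(self) -> float:
        return float(self.task_sums.mean())

    @property
    def rest_mean(self) -> float:
        return float(self.rest_sums.mean())


def spectral_segments(ts: TrialSet, channel: str) -> tuple[np.ndarray, np.ndarray]:
    """Cut the 1 s task and rest segments of every kept trial.

    The epoch window must reach back to -3500 ms; re-epoch with
    ``pre_ms=3500`` when coming from the 2 s default window.
    """
    fs = ts.fs
    if ts.pre_ms < -REST_WINDOW_MS[0]:
        raise InvalidConfigurationError(
            f"epoch window starts at {-ts.pre_ms:.0f} ms; the rest segment "
            f"needs {REST_WINDOW_MS[0]:.0f} ms — re-epoch with pre_ms="
            f"{-REST_WINDOW_MS[0]:.0f}"
        )
    ci = ts.channel_index(channel)
    z = ts.zero_index
    one_s = int(round(fs))
    task_a = z + int(round(TASK_WINDOW_MS[0] * fs / 1000.0))
    rest_a = z + int(round(REST_WINDOW_MS[0] * fs / 1000.0))
    data = ts.epochs[:, ci, :][ts.trial_keep_mask]
    task = data[:, task_a : task_a + one_s]
    rest = data[:, rest_a : rest_a + one_s]
    return task, rest


def segment_psd(segment: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Single Hanning-tapered FFT power spectrum of a 1 s segment.

    Returns ``(freqs, power)`` on a 1 Hz grid from 0 to the Nyquist
    frequency.
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.shape[-1]
    if n != int(round(fs)):
        raise InvalidInputError(
            f"segment must be exactly 1 s ({int(round(fs))} samples), got {n}"
        )
    freqs, power = _sig.periodogram(segment, fs=fs, window="hann", axis=-1)
    return freqs, power


def normalize_psd(power: np.ndarray) -> np.ndarray:
    """Log power relative to the ensemble mean, per frequency.

    ``power`` is segments x frequencies over the whole task+rest ensemble.
    Output satisfies mean-over-segments of ``exp(out)`` = 1 at every
    frequency. Any non-positive power bin makes the channel degenerate.
    """
    power = np.asarray(power, dtype=float)
    if power.ndim != 2:
        raise InvalidInputError("power must be segments x frequencies")
    if np.any(power <= 0.0) or not np.all(np.isfinite(power)):
        raise DegenerateInputError("non-positive or non-finite power bin in ensemble")
    return np.log(power) - np.log(power.mean(axis=0, keepdims=True))


def band_sum(
    norm_log_power: np.ndarray, freqs: np.ndarray, band: tuple[int, int]
) -> np.ndarray:
    """Sum normalized power over the inclusive integer-Hz band ``lo..hi``."""
    lo, hi = band
    if lo > hi:
        raise InvalidParameterError(f"band lo {lo} > hi {hi}")
    if hi > freqs.max():
        raise InvalidParameterError(
            f"band edge {hi} Hz beyond spectrum range {freqs.max():.0f} Hz"
        )
    mask = (freqs >= lo) & (freqs <= hi)
    return np.asarray(norm_log_power)[..., mask].sum(axis=-1)


def activation_weight(m: np.ndarray, r: np.ndarray) -> float:
    """Signed squared effect of task band sums ``m`` against rest sums ``r``.

    ``A = sign(m̄−r̄) · (m̄−r̄)² / σ²_{m∪r} · N_m·N_r / N²_{m∪r}`` with the
    population variance of the pooled values; equal to the signed squared
    point-biserial correlation between the pooled values and the group
    label, so ``A ∈ [−1, 1]``.
    """
    m = np.asarray(m, dtype=float).ravel()
    r = np.asarray(r, dtype=float).ravel()
    if m.size < 2 or r.size < 2:
        raise InvalidInputError("need at least two segments per group")
    diff = m.mean() - r.mean()
    pooled = np.concatenate([m, r])
    var_union = pooled.var()  # population convention
    if var_union == 0.0:
        if diff == 0.0:
            return 0.0
        raise DegenerateInputError("zero pooled variance with unequal group means")
    a = np.sign(diff) * diff**2 / var_union * (m.size * r.size) / pooled.size**2
    return float(np.clip(a, -1.0, 1.0))


def channel_spectra(ts: TrialSet, channel: str) -> SpectralEnsemble:
    """PSD ensemble (task rows first) with the normalized log form."""
    task, rest = spectral_segments(ts, channel)
    freqs, p_task = segment_psd(task, ts.fs)
    _, p_rest = segment_psd(rest, ts.fs)
    power = np.vstack([p_task, p_rest])
    # exclude the DC and Nyquist half-bins from normalization concerns by
    # analyzing 1 Hz upward; DC of a demeaned taper can underflow to 0
    analyzed = freqs >= 1.0
    norm = np.full_like(power, np.nan)
    norm[:, analyzed] = normalize_psd(power[:, analyzed])
    return SpectralEnsemble(
        power=power, norm_log_power=norm, freqs=freqs, n_task=task.shape[0]
    )


def band_activation(
    ens: SpectralEnsemble,
    channel: str,
    band: tuple[int, int],
    n_tests: int,
    alpha: float = ALPHA,
) -> BandActivation:
    """Compare task vs rest band sums of one channel's spectral ensemble."""
    sums = band_sum(ens.norm_log_power, ens.freqs, band)
    m = sums[: ens.n_task]
    r = sums[ens.n_task :]
    try:
        a = activation_weight(m, r)
    except DegenerateInputError:
        a = 0.0
    res = _stats.f_oneway(m, r)
    p_raw = float(res.pvalue)
    if np.isnan(p_raw):
        p_raw = 1.0 if m.mean() == r.mean() else 0.0
    p_corr = min(1.0, p_raw * n_tests)
    return BandActivation(
        channel=channel, band=band, task_sums=m, rest_sums=r, weight=a,
        p_raw=p_raw, p_corrected=p_corr, significant=p_corr < alpha,
    )


def efam_map(
    ts: TrialSet,
    bands: tuple[tuple[int, int], ...] = (LFB, HFB),
    alpha: float = ALPHA,
    pool_bands: bool = False,
) -> list[BandActivation]:
    """Band activation for every channel and band.

    Bonferroni corrects per band across channels by default; with
    ``pool_bands`` the factor becomes channels x bands. A channel is
    EFAM-positive if any of its bands is significant (see
    :func:`efam_positive_channels`).
    """
    n_channels = len(ts.channel_ids)
    n_tests = n_channels * (len(bands) if pool_bands else 1)
    # vectorized over channels: one periodogram call per condition
    z = ts.zero_index
    one_s = int(round(ts.fs))
    task_a = z + int(round(TASK_WINDOW_MS[0] * ts.fs / 1000.0))
    rest_a = z + int(round(REST_WINDOW_MS[0] * ts.fs / 1000.0))
    if ts.pre_ms < -REST_WINDOW_MS[0]:
        raise InvalidConfigurationError(
            f"epoch window starts at {-ts.pre_ms:.0f} ms; re-epoch with "
            f"pre_ms={-REST_WINDOW_MS[0]:.0f}"
        )
    kept = ts.epochs[ts.trial_keep_mask]  # trials x channels x time
    freqs, p_task = segment_psd(kept[:, :, task_a : task_a + one_s], ts.fs)
    _, p_rest = segment_psd(kept[:, :, rest_a : rest_a + one_s], ts.fs)
    analyzed = freqs >= 1.0
    out: list[BandActivation] = []
    for c, ch in enumerate(ts.channel_ids):
        power = np.vstack([p_task[:, c, :], p_rest[:, c, :]])
        norm = np.full_like(power, np.nan)
        norm[:, analyzed] = normalize_psd(power[:, analyzed])
        ens = SpectralEnsemble(
            power=power, norm_log_power=norm, freqs=freqs, n_task=p_task.shape[0]
        )
        for band in bands:
            out.append(band_activation(ens, ch, band, n_tests, alpha=alpha))
    return out


def efam_positive_channels(activations: list[BandActivation]) -> set[str]:
    """Channels significant in at least one band."""
    return {a.channel for a in activations if a.significant}


def activations_to_frame(activations: list[BandActivation]) -> pd.DataFrame:
    """Tabulate as (channel, band, A, p_raw, p_corrected, significant)."""
    return pd.DataFrame(
        {
            "channel": [a.channel for a in activations],
            "band": [f"{a.band[0]}-{a.band[1]}" for a in activations],
            "A": [a.weight for a in activations],
            "p_raw": [a.p_raw for a in activations],
            "p_corrected": [a.p_corrected for a in activations],
            "significant": [bool(a.significant) for a in activations],
        }
    )
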