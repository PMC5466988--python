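"""Temporal alteration mapping: MRCP template correlation and signed R².

Per channel, every trial's post-onset task component (0-500 ms) and
pre-movement rest component (-2000..-1500 ms) are correlated with a 500 ms
template; the two correlation sets are compared with a signed
between-over-total sum-of-squares statistic and a balanced one-way ANOVA.
A positive statistic marks channels whose task segment resembles the
(negative-going) template more than their rest segment does.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import DegenerateInputError, EmptyResultError, InvalidInputError
from .preproc import TrialSet

logger = logging.getLogger(__name__)

#: Analysis windows in ms relative to EMG onset.
TASK_WINDOW_MS = (0.0, 500.0)
REST_WINDOW_MS = (-2000.0, -1500.0)
BASELINE_WINDOW_MS = (-2000.0, -1600.0)  # first 400 ms of the epoch

#: Corrected significance level for flagging a channel.
ALPHA = 0.01


@dataclass
class GrandAverage:
    """Trial-average waveform of one channel, baseline-corrected."""

    waveform: np.ndarray
    fs: float
    n_trials: int
    channel: str | None = None
    subject: str | None = None
    baseline: float = 0.0


@dataclass
class MRCPTemplate:
    """500 ms canonical waveform correlated against every trial."""

    waveform: np.ndarray
    fs: float
    provenance: list[tuple[str | None, str | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float).ravel()
        expected = int(round(0.5 * self.fs))
        if self.waveform.size != expected:
            raise InvalidInputError(
                f"template must span 500 ms = {expected} samples, got {self.waveform.size}"
            )
        if np.ptp(self.waveform) == 0.0:
            raise DegenerateInputError("template has zero variance")

    @property
    def mean(self) -> float:
        return float(self.waveform.mean())

    def to_csv(self, path: str | Path) -> None:
        """Write (time_ms, amplitude_uV) CSV plus a JSON sidecar."""
        path = Path(path)
        t = np.arange(self.waveform.size) / self.fs * 1000.0
        pd.DataFrame({"time_ms": t, "amplitude_uV": self.waveform}).to_csv(
            path, index=False
        )
        sidecar = {
            "fs": self.fs,
            "provenance": [list(p) for p in self.provenance],
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "MRCPTemplate":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar_path = path.with_suffix(".json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            fs = float(sidecar["fs"])
            prov = [tuple(p) for p in sidecar.get("provenance", [])]
        else:
            dt = np.diff(df["time_ms"].to_numpy()).mean()
            fs = 1000.0 / dt
            prov = []
        return cls(waveform=df["amplitude_uV"].to_numpy(), fs=fs, provenance=prov)


@dataclass
class ChannelScore:
    """Per-channel result: correlation vectors, signed R², and significance."""

    channel: str
    task_cc: np.ndarray
    rest_cc: np.ndarray
    signed_r2: float
    g_term: float
    p_raw: float
    p_corrected: float
    significant: bool
    n_dropped: int = 0
    analyzable: bool = True

    @property
    def n(self) -> int:
        return int(self.task_cc.size)


def _window_slice(ts: TrialSet, window_ms: tuple[float, float]) -> slice:
    z = ts.zero_index
    a = z + int(round(window_ms[0] * ts.fs / 1000.0))
    b = z + int(round(window_ms[1] * ts.fs / 1000.0))
    if a < 0 or b > ts.epochs.shape[2]:
        raise InvalidInputError(
            f"window {window_ms} ms falls outside the epoch "
            f"({-ts.pre_ms:.0f}..{ts.post_ms:.0f} ms)"
        )
    return slice(a, b)


def _grand_average_matrix(ts: TrialSet) -> np.ndarray:
    """Baseline-corrected trial mean for every channel, (channels, time)."""
    if ts.n_kept < 1:
        raise EmptyResultError("no kept trials to average")
    mean_wave = ts.epochs[ts.trial_keep_mask].mean(axis=0)
    bsl = _window_slice(ts, BASELINE_WINDOW_MS)
    return mean_wave - mean_wave[:, bsl].mean(axis=1, keepdims=True)


def grand_average(ts: TrialSet, channel: str) -> GrandAverage:
    """Average the kept trials of one channel and subtract the baseline.

    The baseline is the mean over the first 400 ms of the epoch window
    (-2000..-1600 ms relative to onset).
    """
    if ts.n_kept < 1:
        raise EmptyResultError("no kept trials to average")
    ci = ts.channel_index(channel)
    mean_wave = ts.epochs[:, ci, :][ts.trial_keep_mask].mean(axis=0)
    bsl = _window_slice(ts, BASELINE_WINDOW_MS)
    baseline = float(mean_wave[bsl].mean())
    return GrandAverage(
        waveform=mean_wave - baseline,
        fs=ts.fs,
        n_trials=ts.n_kept,
        channel=channel,
        baseline=baseline,
    )


def select_representative(
    ts: TrialSet, amplitude_floor: float = 0.0
) -> tuple[str, bool]:
    """Pick the channel whose grand average is largest within 0-500 ms.

    Amplitude is the peak absolute value of the baseline-corrected grand
    average inside the task window. Ties go to the lowest channel index
    (logged). Returns ``(channel, confident)`` where ``confident`` is False
    when the winning peak is below ``amplitude_floor``.
    """
    if not ts.channel_ids:
        raise InvalidInputError("trial set has no channels")
    task = _window_slice(ts, TASK_WINDOW_MS)
    amps = np.abs(_grand_average_matrix(ts)[:, task]).max(axis=1)
    best = int(np.argmax(amps))  # argmax takes the lowest index on ties
    if np.count_nonzero(amps == amps[best]) > 1:
        logger.info("representative amplitude tie; keeping lowest index %s",
                    ts.channel_ids[best])
    best_ch, best_amp = ts.channel_ids[best], float(amps[best])
    confident = best_amp >= amplitude_floor
    if not confident:
        logger.warning(
            "representative channel %s peak %.3g below floor %.3g (low confidence)",
            best_ch, best_amp, amplitude_floor,
        )
    return best_ch, confident


def build_template(reps: list[GrandAverage], ts_like: TrialSet | None = None) -> MRCPTemplate:
    """Average representative grand averages and cut the 0-500 ms segment.

    ``reps`` waveforms must share a sampling rate and span the full epoch
    window; the template is the post-onset 500 ms of their element-wise mean.
    """
    if not reps:
        raise InvalidInputError("need at least one representative grand average")
    fs = reps[0].fs
    if any(r.fs != fs for r in reps):
        raise InvalidInputError("representatives have mixed sampling rates")
    lengths = {r.waveform.size for r in reps}
    if len(lengths) != 1:
        raise InvalidInputError("representatives have mixed waveform lengths")
    mean_wave = np.mean([r.waveform for r in reps], axis=0)
    if ts_like is not None:
        zero = ts_like.zero_index
    else:
        # waveforms span the default -2000..+4000 ms window
        zero = int(round(2.0 * fs))
        if mean_wave.size < zero + int(round(0.5 * fs)):
            raise InvalidInputError(
                "waveform too short for the default epoch window; pass ts_like"
            )
    seg = mean_wave[zero : zero + int(round(0.5 * fs))]
    if np.ptp(seg) == 0.0:
        raise DegenerateInputError("averaged template segment has zero variance")
    return MRCPTemplate(
        waveform=seg,
        fs=fs,
        provenance=[(r.subject, r.channel) for r in reps],
    )


def loso_template(
    subject_reps: dict[str, GrandAverage], held_out: str
) -> MRCPTemplate:
    """Leave-one-subject-out template: mean of the other subjects' representatives."""
    if held_out not in subject_reps:
        raise InvalidInputError(f"unknown subject {held_out!r}")
    if len(subject_reps) < 2:
        raise InvalidInputError("leave-one-out needs at least two subjects")
    reps = [ga for sub, ga in subject_reps.items() if sub != held_out]
    return build_template(reps)


def correlation_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise InvalidInputError(f"length mismatch {x.size} != {y.size}")
    if x.size < 2:
        raise InvalidInputError("need at least two samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx, sy = xc @ xc, yc @ yc
    # relative tolerance catches constant signals stored with rounding residue
    if sx <= 1e-24 * (x @ x) or sy <= 1e-24 * (y @ y):
        raise DegenerateInputError("zero variance input to correlation")
    return float(np.clip((xc @ yc) / np.sqrt(sx * sy), -1.0, 1.0))


def trial_ccs(
    ts: TrialSet, channel: str, tmpl: MRCPTemplate
) -> tuple[np.ndarray, np.ndarray, int]:
    """Correlate every kept trial's task and rest component with the template.

    Returns ``(q, t, n_dropped)``: task and rest correlation vectors, always
    of equal length, plus the number of trials dropped because either
    component had zero variance (dropped pairwise to preserve balance).
    """
    ci = ts.channel_index(channel)
    task_sl = _window_slice(ts, TASK_WINDOW_MS)
    rest_sl = _window_slice(ts, REST_WINDOW_MS)
    n_comp = task_sl.stop - task_sl.start
    if tmpl.waveform.size != n_comp:
        raise InvalidInputError(
            f"template length {tmpl.waveform.size} != component length {n_comp}"
        )
    q, t = [], []
    n_dropped = 0
    for trial in ts.epochs[:, ci, :][ts.trial_keep_mask]:
        try:
            qi = correlation_coefficient(trial[task_sl], tmpl.waveform)
            ti = correlation_coefficient(trial[rest_sl], tmpl.waveform)
        except DegenerateInputError:
            n_dropped += 1
            continue
        q.append(qi)
        t.append(ti)
    if n_dropped:
        logger.info("channel %s: dropped %d degenerate trial(s)", channel, n_dropped)
    return np.asarray(q), np.asarray(t), n_dropped


def signed_r2(q: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    """Signed between-group over total sum-of-squares of two balanced samples.

    Magnitude is ``((Σq)²/n + (Σt)²/n − G) / (Σq² + Σt² − G)`` with the grand
    correction term ``G = (Σq + Σt)² / (2n)``; the sign is that of
    ``mean(q) − mean(t)``. Returns ``(R², G)``.
    """
    q = np.asarray(q, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    n = q.size
    if n != t.size:
        raise InvalidInputError("task and rest vectors must have equal length")
    if n < 2:
        raise InvalidInputError("need at least two trials per group")
    sq, st = q.sum(), t.sum()
    g = (sq + st) ** 2 / (2 * n)
    num = sq**2 / n + st**2 / n - g
    den = (q @ q) + (t @ t) - g
    if den <= 0.0:
        raise DegenerateInputError("zero total variance in correlation sets")
    r2 = num / den
    sign = np.sign(q.mean() - t.mean())
    return float(np.clip(sign * r2, -1.0, 1.0)), float(g)


def channel_significance(
    q: np.ndarray, t: np.ndarray, n_channels: int, alpha: float = ALPHA
) -> tuple[float, float, bool]:
    """Balanced one-way ANOVA of task vs rest correlations, Bonferroni corrected.

    Returns ``(p_raw, p_corrected, significant)`` where the correction
    multiplies by the number of analyzed channels and the flag tests the
    corrected p against ``alpha``.
    """
    q = np.asarray(q, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    if q.size != t.size:
        raise InvalidInputError("task and rest vectors must have equal length")
    if q.size < 2:
        raise InvalidInputError("need at least two trials per group")
    if n_channels < 1:
        raise InvalidInputError("n_channels must be positive")
    res = _stats.f_oneway(q, t)
    p_raw = float(res.pvalue)
    if np.isnan(p_raw):  # zero within-group variance in both groups
        p_raw = 1.0 if q.mean() == t.mean() else 0.0
    p_corr = min(1.0, p_raw * n_channels)
    return p_raw, p_corr, p_corr < alpha


def _corr_with_template(comps: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of every (trial, channel) component against the template.

    ``comps`` is trials x channels x length; degenerate (zero-variance)
    components come back as NaN.
    """
    raw_ss = np.einsum("tcl,tcl->tc", comps, comps)
    comps = comps - comps.mean(axis=-1, keepdims=True)
    yc = y - y.mean()
    num = comps @ yc
    xss = np.einsum("tcl,tcl->tc", comps, comps)
    ok = xss > 1e-24 * raw_ss  # same degeneracy rule as correlation_coefficient
    den = np.sqrt(xss * (yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(ok, num / np.where(ok, den, 1.0), np.nan)
    return np.clip(r, -1.0, 1.0)


def etam_map(
    ts: TrialSet,
    tmpl: MRCPTemplate,
    alpha: float = ALPHA,
    max_dropped_frac: float = 0.5,
) -> list[ChannelScore]:
    """Score every channel of the trial set against the template.

    Vectorized equivalent of calling :func:`trial_ccs` per channel.
    Channels that lose more than ``max_dropped_frac`` of their trials to
    degenerate components are marked unanalyzable (score kept, flag off)
    but still count toward the Bonferroni factor.
    """
    n_channels = len(ts.channel_ids)
    task_sl = _window_slice(ts, TASK_WINDOW_MS)
    rest_sl = _window_slice(ts, REST_WINDOW_MS)
    if tmpl.waveform.size != task_sl.stop - task_sl.start:
        raise InvalidInputError(
            f"template length {tmpl.waveform.size} != component length "
            f"{task_sl.stop - task_sl.start}"
        )
    keep = ts.trial_keep_mask
    q_all = _corr_with_template(ts.epochs[:, :, task_sl][keep], tmpl.waveform)
    t_all = _corr_with_template(ts.epochs[:, :, rest_sl][keep], tmpl.waveform)
    scores: list[ChannelScore] = []
    for c, ch in enumerate(ts.channel_ids):
        valid = np.isfinite(q_all[:, c]) & np.isfinite(t_all[:, c])
        q, t = q_all[valid, c], t_all[valid, c]
        n_dropped = int((~valid).sum())
        total = q.size + n_dropped
        analyzable = total > 0 and q.size >= 2 and n_dropped <= max_dropped_frac * total
        if not analyzable:
            scores.append(
                ChannelScore(
                    channel=ch, task_cc=q, rest_cc=t, signed_r2=np.nan,
                    g_term=np.nan, p_raw=np.nan, p_corrected=np.nan,
                    significant=False, n_dropped=n_dropped, analyzable=False,
                )
            )
            continue
        try:
            r2, g = signed_r2(q, t)
        except DegenerateInputError:
            r2, g = 0.0, np.nan
        p_raw, p_corr, flag = channel_significance(q, t, n_channels, alpha=alpha)
        scores.append(
            ChannelScore(
                channel=ch, task_cc=q, rest_cc=t, signed_r2=r2, g_term=g,
                p_raw=p_raw, p_corrected=p_corr, significant=flag,
                n_dropped=n_dropped,
            )
        )
    return scores


def scores_to_frame(scores: list[ChannelScore]) -> pd.DataFrame:
    """Tabulate channel scores as (channel, R2, p_raw, p_corrected, significant)."""
    return pd.DataFrame(
        {
            "channel": [s.channel for s in scores],
            "R2": [s.signed_r2 for s in scores],
            "p_raw": [s.p_raw for s in scores],
            "p_corrected": [s.p_corrected for s in scores],
            "significant": [bool(s.significant) for s in scores],
        }
    )
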