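"""Synthetic multichannel ECoG + EMG with known ground truth.

The generator emulates the target recording protocol: 2,000 Hz sampling,
4 mm electrodes at 10 mm pitch in rectangular grids, ~40 brisk-movement
trials at 5-16 s intervals. Designated channels carry a movement-locked
slow negativity, an 8-32 Hz power dip, and/or a 66-90 Hz power boost on a
power-law background; everything derives from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import fft as _fft

from .errors import FixtureIOError, InvalidConfigurationError
from .evaluate import ElectrodeGrid
from .io import write_edf, write_events_csv
from .preproc import Recording


@dataclass
class MrcpParams:
    """Morphology of the synthetic movement-related potential.

    A slow pre-movement ramp, a sharp negative peak just after onset, and a
    positive rebound; all components are smooth so the waveform stays below
    3 Hz.
    """

    amplitude_uv: float = 100.0
    ramp_duration_s: float = 1.5
    ramp_depth: float = 0.3  # ramp floor as a fraction of amplitude
    peak_latency_s: float = 0.1
    peak_sigma_s: float = 0.13
    rebound_latency_s: float = 0.8
    rebound_gain: float = 0.35
    rebound_sigma_s: float = 0.3


@dataclass
class SimulationConfig:
    n_rows: int = 4
    n_cols: int = 8
    pitch_mm: float = 10.0
    fs: float = 2000.0
    n_trials: int = 40
    iti_range_s: tuple[float, float] = (5.0, 16.0)
    mrcp_channels: tuple[str, ...] = ("chan_11", "chan_12")
    mrcp: MrcpParams = field(default_factory=MrcpParams)
    mrcp_amp_jitter: float = 0.2
    mrcp_latency_jitter_s: float = 0.025
    erd_channels: tuple[str, ...] = ("chan_11", "chan_12", "chan_13")
    erd_band: tuple[float, float] = (8.0, 32.0)
    erd_depth: float = 0.8  # fractional amplitude drop of the band component
    lfb_background_uv: float = 15.0  # low-band rhythm present on every channel
    ers_channels: tuple[str, ...] = ("chan_12",)
    ers_band: tuple[float, float] = (66.0, 90.0)
    ers_gain: float = 2.0  # fractional amplitude boost
    hfb_background_uv: float = 4.0  # high-band rhythm present on every channel
    noise_exponent: float = 2.0  # power ~ 1/f**exponent
    noise_scale_uv: float = 20.0
    delta_background_uv: float = 25.0  # slow-band (0.5-3 Hz) rhythm, every channel
    line_noise_uv: float = 0.0
    emg_burst_s: float = 1.0
    saturate_clip_uv: float | None = None
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    @classmethod
    def for_grid(cls, n_rows: int, n_cols: int, **kwargs) -> "SimulationConfig":
        """Config with effect channels scaled to an arbitrary grid size.

        Unless given explicitly, the movement-potential channels sit near
        the grid center, the low-band-drop set adds their neighbour, and
        the high-band-boost channel is the second potential channel.
        """
        n = n_rows * n_cols
        if n < 2:
            raise InvalidConfigurationError("grid must have at least 2 electrodes")
        mid = min(max(1, n // 3 + 1), n - 1)  # 4x8 grid reproduces the defaults
        mrcp = kwargs.pop("mrcp_channels", None)
        if mrcp is None:
            mrcp = tuple(f"chan_{i}" for i in (mid, mid + 1) if i <= n)
        erd = kwargs.pop("erd_channels", None)
        if erd is None:
            erd = mrcp + tuple(
                f"chan_{i}" for i in (mid + 2,) if i <= n and f"chan_{i}" not in mrcp
            )
        ers = kwargs.pop("ers_channels", None)
        if ers is None:
            ers = (mrcp[-1],)
        return cls(
            n_rows=n_rows, n_cols=n_cols,
            mrcp_channels=tuple(mrcp), erd_channels=tuple(erd),
            ers_channels=tuple(ers), **kwargs,
        )

    def channel_ids(self) -> list[str]:
        return [f"chan_{i + 1}" for i in range(self.n_channels)]

    def grid(self) -> ElectrodeGrid:
        coords = {}
        for i, ch in enumerate(self.channel_ids()):
            row, col = divmod(i, self.n_cols)
            coords[ch] = (col * self.pitch_mm, row * self.pitch_mm)
        return ElectrodeGrid(
            coords=coords,
            pitch_mm=self.pitch_mm,
            layout=f"{self.n_rows}x{self.n_cols}",
        )

    def validate(self) -> None:
        chans = set(self.channel_ids())
        for name, subset in (
            ("mrcp_channels", self.mrcp_channels),
            ("erd_channels", self.erd_channels),
            ("ers_channels", self.ers_channels),
        ):
            extra = set(subset) - chans
            if extra:
                raise InvalidConfigurationError(
                    f"{name} outside the grid: {sorted(extra)}"
                )
        lo, hi = self.iti_range_s
        if not 0 < lo <= hi:
            raise InvalidConfigurationError(f"bad inter-trial range {self.iti_range_s}")
        if self.fs <= 0 or self.n_trials < 1 or self.n_rows < 1 or self.n_cols < 1:
            raise InvalidConfigurationError("fs, n_trials and grid shape must be positive")
        if self.erd_band[1] >= self.fs / 2 or self.ers_band[1] >= self.fs / 2:
            raise InvalidConfigurationError("band edges must stay below Nyquist")


@dataclass
class GroundTruth:
    """What the simulator actually injected, for parameter-recovery tests."""

    onsets: np.ndarray
    channel_labels: dict[str, list[str]]  # channel -> subset of {mrcp, erd, ers}
    decs_positive: set[str]
    fs: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fs": self.fs,
            "onsets": [int(o) for o in self.onsets],
            "channel_labels": {k: sorted(v) for k, v in self.channel_labels.items()},
            "decs_positive": sorted(self.decs_positive),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        missing = {"fs", "onsets", "channel_labels", "decs_positive"} - set(payload)
        if missing:
            raise FixtureIOError(f"{path}: ground-truth JSON missing keys {sorted(missing)}")
        return cls(
            onsets=np.asarray(payload["onsets"], dtype=np.int64),
            channel_labels={k: list(v) for k, v in payload["channel_labels"].items()},
            decs_positive=set(payload["decs_positive"]),
            fs=float(payload["fs"]),
        )


def mrcp_waveform(
    params: MrcpParams,
    fs: float,
    pre_s: float = 2.0,
    post_s: float = 4.0,
) -> np.ndarray:
    """Deterministic movement-locked waveform on ``[-pre_s, post_s)``.

    Negative ramp into the onset, sharpest negativity ~100 ms after it,
    positive rebound, return to baseline; the most negative value equals
    ``-amplitude_uv``. More than 99% of the energy lies below 3 Hz.
    """
    n = int(round((pre_s + post_s) * fs))
    t = (np.arange(n) - int(round(pre_s * fs))) / fs
    a = params.amplitude_uv
    if a == 0.0:
        return np.zeros(n)

    ramp = np.zeros(n)
    rising = (t >= -params.ramp_duration_s) & (t < 0)
    ramp[rising] = -0.5 * (1 + np.cos(np.pi * t[rising] / params.ramp_duration_s))
    after = t >= 0
    ramp[after] = -np.exp(-(t[after] ** 2) / (2 * 0.35**2))
    ramp *= params.ramp_depth

    peak = -np.exp(-((t - params.peak_latency_s) ** 2) / (2 * params.peak_sigma_s**2))
    rebound = params.rebound_gain * np.exp(
        -((t - params.rebound_latency_s) ** 2) / (2 * params.rebound_sigma_s**2)
    )
    wave = ramp + peak + rebound
    return a * wave / np.abs(wave.min())


def _normalized_shape(shape: np.ndarray, n_fft: int) -> np.ndarray:
    """Rescale an amplitude-spectrum shape so shaped unit white noise has std 1.

    Uses Parseval on the one-sided spectrum: white noise rfft bins have
    expected squared magnitude ``n_fft`` (interior bins).
    """
    full_sq = 2.0 * np.sum(shape**2) - shape[0] ** 2 - shape[-1] ** 2
    var = full_sq / n_fft
    if var <= 0:
        return shape
    return shape / np.sqrt(var)


def _powerlaw_shape(f: np.ndarray, exponent: float) -> np.ndarray:
    s = np.zeros_like(f)
    s[1:] = f[1:] ** (-exponent / 2.0)
    return s


def _band_shape(
    f: np.ndarray, band: tuple[float, float], transition_hz: float = 2.0
) -> np.ndarray:
    """Unit passband with raised-cosine edges."""
    lo, hi = band
    mask = np.zeros_like(f)
    mask[(f >= lo) & (f <= hi)] = 1.0
    rise = (f >= lo - transition_hz) & (f < lo)
    mask[rise] = 0.5 * (1 + np.cos(np.pi * (lo - f[rise]) / transition_hz))
    fall = (f > hi) & (f <= hi + transition_hz)
    mask[fall] = 0.5 * (1 + np.cos(np.pi * (f[fall] - hi) / transition_hz))
    return mask


def _shaped_noise(
    rng: np.random.Generator, n: int, fs: float, shape_fn, scale: float
) -> np.ndarray:
    """White noise spectrally shaped by ``shape_fn(f)``, rescaled to std ``scale``."""
    n_fft = _fft.next_fast_len(n)
    white = rng.standard_normal(n_fft)
    spec = _fft.rfft(white)
    f = _fft.rfftfreq(n_fft, 1.0 / fs)
    x = _fft.irfft(spec * shape_fn(f), n_fft)[:n]
    sd = x.std()
    return x * (scale / sd) if sd > 0 else x


def _powerlaw_noise(
    rng: np.random.Generator, n: int, fs: float, exponent: float, scale: float
) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, std = scale."""
    return _shaped_noise(rng, n, fs, lambda f: _powerlaw_shape(f, exponent), scale)


def _band_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    band: tuple[float, float],
    scale: float,
    transition_hz: float = 2.0,
) -> np.ndarray:
    """Band-limited Gaussian noise with raised-cosine band edges, std = scale."""
    return _shaped_noise(rng, n, fs, lambda f: _band_shape(f, band, transition_hz), scale)


def _task_envelope(
    n: int,
    fs: float,
    onsets: np.ndarray,
    level: float,
    duration_s: float = 1.0,
    ramp_s: float = 0.1,
) -> np.ndarray:
    """Multiplicative envelope: 1 at rest, ``level`` during the task window."""
    env = np.ones(n)
    n_ramp = int(round(ramp_s * fs))
    n_hold = int(round(duration_s * fs))
    half = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / max(n_ramp, 1)))
    for o in onsets:
        a, b = o, min(o + n_hold, n)
        env[a:b] = level
        ra = max(o - n_ramp, 0)
        env[ra:o] = 1 + (level - 1) * half[n_ramp - (o - ra) :]
        rb = min(b + n_ramp, n)
        env[b:rb] = level + (1 - level) * half[: rb - b]
    return env


def _emg_signal(
    rng: np.random.Generator, n: int, fs: float, onsets: np.ndarray, burst_s: float
) -> np.ndarray:
    """Quiet baseline with a high-frequency burst at every onset."""
    emg = 0.01 * rng.standard_normal(n)
    n_rise = int(round(0.01 * fs))
    n_hold = int(round(burst_s * fs))
    n_fall = int(round(0.2 * fs))
    env = np.concatenate(
        [
            np.linspace(0, 1, n_rise, endpoint=False),
            np.ones(n_hold),
            0.5 * (1 + np.cos(np.pi * np.arange(n_fall) / n_fall)),
        ]
    )
    for o in onsets:
        seg = env[: max(0, min(len(env), n - o))]
        emg[o : o + len(seg)] += seg * rng.standard_normal(len(seg))
    return emg


def simulate_recording(cfg: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Generate one seeded recording plus its ground truth.

    Identical configs (same seed) produce bit-identical output; all
    randomness flows from ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs

    # onset schedule: start margin covers the deepest pre-window (3.5 s)
    itis = rng.uniform(*cfg.iti_range_s, size=cfg.n_trials - 1)
    onset_times = 4.0 + np.concatenate([[0.0], np.cumsum(itis)])
    onsets = np.round(onset_times * fs).astype(np.int64)
    n = int(onsets[-1] + round(5.0 * fs))

    chans = cfg.channel_ids()

    # stationary background: power-law floor plus slow/low/high-band rhythms.
    # Independent Gaussian components add in power, so each channel draws one
    # white vector shaped by the root-sum-square amplitude spectrum; only the
    # task-modulated band carriers are generated separately below.
    n_fft = _fft.next_fast_len(n)
    f = _fft.rfftfreq(n_fft, 1.0 / fs)
    comp_sq = {
        "pl": (cfg.noise_scale_uv * _normalized_shape(
            _powerlaw_shape(f, cfg.noise_exponent), n_fft)) ** 2,
        "delta": (cfg.delta_background_uv * _normalized_shape(
            _band_shape(f, (0.5, 3.0)), n_fft)) ** 2,
        "lfb": (cfg.lfb_background_uv * _normalized_shape(
            _band_shape(f, cfg.erd_band), n_fft)) ** 2,
        "hfb": (cfg.hfb_background_uv * _normalized_shape(
            _band_shape(f, cfg.ers_band), n_fft)) ** 2,
    }
    shapes = np.empty((len(chans), f.size))
    for i, ch in enumerate(chans):
        sq = comp_sq["pl"] + comp_sq["delta"]
        if ch not in cfg.erd_channels:
            sq = sq + comp_sq["lfb"]
        if ch not in cfg.ers_channels:
            sq = sq + comp_sq["hfb"]
        shapes[i] = np.sqrt(sq)
    data = np.empty((len(chans), n))
    for i in range(len(chans)):  # per channel: keeps peak memory flat
        spec = _fft.rfft(rng.standard_normal(n_fft))
        data[i] = _fft.irfft(spec * shapes[i], n_fft)[:n]

    # movement-locked slow negativity with per-trial amplitude/latency jitter
    wave = mrcp_waveform(cfg.mrcp, fs)
    pre = int(round(2.0 * fs))
    for ch in cfg.mrcp_channels:
        i = chans.index(ch)
        for o in onsets:
            gain = 1.0 + cfg.mrcp_amp_jitter * (2 * rng.random() - 1)
            shift = int(round(cfg.mrcp_latency_jitter_s * fs * (2 * rng.random() - 1)))
            a = o - pre + shift
            b = a + wave.size
            wa, wb = max(0, -a), wave.size - max(0, b - n)
            data[i, max(a, 0) : min(b, n)] += gain * wave[wa:wb]

    # task-modulated band carriers (drop for the low band, boost for the high)
    if cfg.lfb_background_uv > 0 and cfg.erd_channels:
        erd_env = _task_envelope(n, fs, onsets, level=1.0 - cfg.erd_depth)
        for ch in cfg.erd_channels:
            i = chans.index(ch)
            data[i] += _band_noise(rng, n, fs, cfg.erd_band, cfg.lfb_background_uv) * erd_env
    if cfg.hfb_background_uv > 0 and cfg.ers_channels:
        ers_env = _task_envelope(n, fs, onsets, level=1.0 + cfg.ers_gain)
        for ch in cfg.ers_channels:
            i = chans.index(ch)
            data[i] += _band_noise(rng, n, fs, cfg.ers_band, cfg.hfb_background_uv) * ers_env

    if cfg.line_noise_uv > 0:
        t = np.arange(n) / fs
        phases = rng.uniform(0, 2 * np.pi, size=len(chans))
        data += cfg.line_noise_uv * np.sin(
            2 * np.pi * 50.0 * t[None, :] + phases[:, None]
        )

    if cfg.saturate_clip_uv is not None:
        np.clip(data, -cfg.saturate_clip_uv, cfg.saturate_clip_uv, out=data)

    emg = _emg_signal(rng, n, fs, onsets, cfg.emg_burst_s)

    labels: dict[str, list[str]] = {ch: [] for ch in chans}
    for ch in cfg.mrcp_channels:
        labels[ch].append("mrcp")
    for ch in cfg.erd_channels:
        labels[ch].append("erd")
    for ch in cfg.ers_channels:
        labels[ch].append("ers")

    rec = Recording(
        data=data, fs=fs, channel_ids=chans, emg=emg, geometry_ref="grid"
    )
    gt = GroundTruth(
        onsets=onsets,
        channel_labels=labels,
        decs_positive=set(cfg.mrcp_channels),
        fs=fs,
    )
    return rec, gt


def write_fixture(
    rec: Recording, gt: GroundTruth, cfg: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write EDF signals, events CSV, geometry CSV and ground-truth JSON.

    The EMG goes into the EDF as a final signal labeled ``EMG``. Returns the
    paths keyed by artifact name.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FixtureIOError(f"cannot create {out_dir}: {exc}") from exc
    paths = {
        "signals": out_dir / "signals.edf",
        "events": out_dir / "events.csv",
        "geometry": out_dir / "geometry.csv",
        "ground_truth": out_dir / "ground_truth.json",
        "config": out_dir / "config.json",
    }
    signals = np.vstack([rec.data, rec.emg[None, :]])
    write_edf(paths["signals"], signals, rec.fs, rec.channel_ids + ["EMG"])
    write_events_csv(paths["events"], gt.onsets)
    cfg.grid().to_csv(paths["geometry"])
    gt.to_json(paths["ground_truth"])
    cfg_dict = asdict(cfg)
    paths["config"].write_text(json.dumps(cfg_dict, indent=2, default=list))
    return paths


def load_fixture(in_dir: str | Path) -> tuple[Recording, GroundTruth]:
    """Read back what :func:`write_fixture` wrote."""
    from .io import read_edf

    in_dir = Path(in_dir)
    sig = read_edf(in_dir / "signals.edf")
    if sig.labels[-1] != "EMG":
        raise FixtureIOError(f"{in_dir}: expected the last EDF signal to be 'EMG'")
    gt = GroundTruth.from_json(in_dir / "ground_truth.json")
    rec = Recording(
        data=sig.data[:-1],
        fs=sig.fs,
        channel_ids=sig.labels[:-1],
        emg=sig.data[-1],
        geometry_ref="grid",
    )
    return rec, gt
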