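"""File I/O: European Data Format signals, event CSVs, geometry CSVs.

The EDF reader/writer here is deliberately minimal — contiguous 16-bit
records, one-second record duration — but standard-conformant, so files
interoperate with the usual viewers. The true sample count is stashed in
the reserved header field so zero-padding of the final record can be
trimmed on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FixtureIOError, InvalidInputError

_EDF_VERSION = b"0       "
_DIGITAL_MIN = -32768
_DIGITAL_MAX = 32767


@dataclass
class EdfSignals:
    """Raw contents of an EDF file: per-signal samples, labels, rate."""

    data: np.ndarray  # signals x samples, physical units
    fs: float
    labels: list[str]
    physical_ranges: list[tuple[float, float]]


def _pad_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise InvalidInputError(f"EDF header field too long: {value!r} > {width}")
    return b.ljust(width)


def write_edf(
    path: str | Path,
    data: np.ndarray,
    fs: float,
    labels: list[str],
    physical_dim: str = "uV",
) -> None:
    """Write a signals x samples matrix as a 16-bit EDF file.

    Record duration is 1 s, so ``fs`` must be a positive integer rate; the
    final record is zero-padded and the true sample count recorded in the
    reserved header field.
    """
    path = Path(path)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if len(labels) != data.shape[0]:
        raise InvalidInputError("one label per signal required")
    if fs <= 0 or fs != int(fs):
        raise InvalidInputError(f"EDF writer needs an integer sampling rate, got {fs}")
    spr = int(fs)  # samples per 1 s record
    n_sig, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_sig, n_rec * spr))
    padded[:, :n_samp] = data

    phys_ranges = []
    digital = np.empty_like(padded, dtype="<i2")
    for i in range(n_sig):
        # integer physical bounds: exactly representable in the 8-char
        # header fields, so reader and writer agree on the scaling
        lo = float(np.floor(padded[i].min()))
        hi = float(np.ceil(padded[i].max()))
        if lo == hi:  # flat signal: give it a token range
            lo, hi = lo - 1.0, hi + 1.0
        if max(abs(lo), abs(hi)) >= 1e7:
            raise InvalidInputError(
                "signal amplitude too large for EDF physical-range fields"
            )
        phys_ranges.append((lo, hi))
        gain = (_DIGITAL_MAX - _DIGITAL_MIN) / (hi - lo)
        quantized = np.round((padded[i] - lo) * gain + _DIGITAL_MIN)
        digital[i] = np.clip(quantized, _DIGITAL_MIN, _DIGITAL_MAX).astype("<i2")

    header = bytearray()
    header += _EDF_VERSION
    header += _pad_field("synthetic ECoG", 80)  # patient id
    header += _pad_field(f"NSAMP={n_samp}", 80)  # recording id (reserved use)
    header += _pad_field("01.01.00", 8)
    header += _pad_field("00.00.00", 8)
    header += _pad_field(str(256 * (1 + n_sig)), 8)
    header += _pad_field("", 44)
    header += _pad_field(str(n_rec), 8)
    header += _pad_field("1", 8)  # record duration, s
    header += _pad_field(str(n_sig), 4)
    for lab in labels:
        header += _pad_field(lab[:16], 16)
    header += b" " * (80 * n_sig)  # transducer
    for _ in labels:
        header += _pad_field(physical_dim, 8)
    for lo, hi in phys_ranges:
        header += _pad_field(str(int(lo)), 8)
    for lo, hi in phys_ranges:
        header += _pad_field(str(int(hi)), 8)
    for _ in labels:
        header += _pad_field(str(_DIGITAL_MIN), 8)
    for _ in labels:
        header += _pad_field(str(_DIGITAL_MAX), 8)
    header += b" " * (80 * n_sig)  # prefiltering
    for _ in labels:
        header += _pad_field(str(spr), 8)
    header += b" " * (32 * n_sig)

    try:
        with open(path, "wb") as fh:
            fh.write(bytes(header))
            # record-major layout: for each record, each signal's chunk
            for rec in range(n_rec):
                sl = slice(rec * spr, (rec + 1) * spr)
                fh.write(digital[:, sl].tobytes())
    except OSError as exc:
        raise FixtureIOError(f"cannot write EDF file {path}: {exc}") from exc


def read_edf(path: str | Path) -> EdfSignals:
    """Read an EDF file written by :func:`write_edf` (or any contiguous EDF)."""
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise FixtureIOError(f"cannot read EDF file {path}: {exc}") from exc
    if len(raw) < 256:
        raise FixtureIOError(f"{path}: truncated EDF header")

    def fld(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    recording_id = fld(88, 80)
    n_rec = int(fld(236, 8))
    rec_dur = float(fld(244, 8))
    n_sig = int(fld(252, 4))
    off = 256
    labels = [fld(off + 16 * i, 16) for i in range(n_sig)]
    off += 16 * n_sig + 80 * n_sig + 8 * n_sig  # labels, transducer, dim
    phys_min = [float(fld(off + 8 * i, 8)) for i in range(n_sig)]
    off += 8 * n_sig
    phys_max = [float(fld(off + 8 * i, 8)) for i in range(n_sig)]
    off += 8 * n_sig
    dig_min = [int(fld(off + 8 * i, 8)) for i in range(n_sig)]
    off += 8 * n_sig
    dig_max = [int(fld(off + 8 * i, 8)) for i in range(n_sig)]
    off += 8 * n_sig + 80 * n_sig
    spr = [int(fld(off + 8 * i, 8)) for i in range(n_sig)]
    if len(set(spr)) != 1:
        raise FixtureIOError(f"{path}: mixed per-signal rates are not supported")
    header_bytes = 256 * (1 + n_sig)
    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    per_rec = sum(spr)
    body = body[: n_rec * per_rec].reshape(n_rec, n_sig, spr[0])
    data = np.empty((n_sig, n_rec * spr[0]), dtype=float)
    for i in range(n_sig):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        dig = body[:, i, :].reshape(-1).astype(np.float64)  # avoid i2 overflow
        data[i] = (dig - dig_min[i]) * gain + phys_min[i]
    if recording_id.startswith("NSAMP="):
        n_true = int(recording_id.split("=", 1)[1])
        data = data[:, :n_true]
    fs = spr[0] / rec_dur
    return EdfSignals(
        data=data,
        fs=fs,
        labels=labels,
        physical_ranges=list(zip(phys_min, phys_max)),
    )


def write_events_csv(path: str | Path, onsets: np.ndarray) -> None:
    """Events as a 2-column CSV (trial_id, onset_sample)."""
    df = pd.DataFrame(
        {"trial_id": np.arange(len(onsets)), "onset_sample": np.asarray(onsets, int)}
    )
    df.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if "onset_sample" not in df.columns:
        raise FixtureIOError(f"{path}: missing 'onset_sample' column")
    return df["onset_sample"].to_numpy(dtype=np.int64)


def read_stim_sites_csv(path: str | Path) -> list[tuple[float, float]]:
    """Stimulation sites CSV (site_id, x_mm, y_mm[, response_label]).

    Rows labeled negative (response_label falsy/absent counts as positive)
    are skipped.
    """
    df = pd.read_csv(path)
    for col in ("x_mm", "y_mm"):
        if col not in df.columns:
            raise FixtureIOError(f"{path}: missing '{col}' column")
    if "response_label" in df.columns:
        keep = df["response_label"].astype(str).str.lower().isin(
            {"positive", "pos", "+", "1", "true", "yes"}
        )
        df = df[keep]
    return [(float(r.x_mm), float(r.y_mm)) for r in df.itertuples()]
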