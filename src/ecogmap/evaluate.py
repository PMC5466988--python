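"""Evaluation against stimulation ground truth and topographic map rendering."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import (
    InvalidInputError,
    UndefinedMetricError,
)

#: Radius (mm) around a stimulation site within which an electrode counts
#: as stimulation-positive.
DECS_RADIUS_MM = 6.0

#: Gaussian kernel defaults for the topographic raster: the kernel support
#: diameter in mm and the spread in units of the support radius.
KERNEL_DIAMETER_MM = 25.0
KERNEL_SIGMA_REL = 0.4


@dataclass
class ElectrodeGrid:
    """Electrode coordinates in mm on the cortical plane."""

    coords: dict[str, tuple[float, float]]
    electrode_diameter_mm: float = 4.0
    pitch_mm: float = 10.0
    layout: str | None = None  # e.g. "4x8", "6x8", "strip"

    def __post_init__(self) -> None:
        pts = list(self.coords.values())
        if len({tuple(p) for p in pts}) != len(pts):
            raise InvalidInputError("electrode coordinates must be unique")
        arr = np.asarray(pts, dtype=float)
        if len(arr) > 1:
            from scipy.spatial.distance import pdist

            if pdist(arr).min() < self.electrode_diameter_mm:
                raise InvalidInputError(
                    "electrodes closer than one electrode diameter"
                )

    @property
    def channels(self) -> list[str]:
        return list(self.coords)

    def xy(self, channel: str) -> np.ndarray:
        return np.asarray(self.coords[channel], dtype=float)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ElectrodeGrid":
        df = pd.read_csv(path)
        coords = {
            str(row.channel_id): (float(row.x_mm), float(row.y_mm))
            for row in df.itertuples()
        }
        return cls(coords=coords, **kwargs)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"channel_id": ch, "x_mm": x, "y_mm": y}
            for ch, (x, y) in self.coords.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class ConfusionCounts:
    """2x2 table of a test outcome against stimulation ground truth."""

    tp: int  # test+ truth+
    fp: int  # test+ truth-
    fn: int  # test- truth+
    tn: int  # test- truth-

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def n_truth_positive(self) -> int:
        return self.tp + self.fn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_table(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=float)


@dataclass
class ActivationMapRaster:
    """Weighted-kernel activation raster on a regular mm grid."""

    values: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    kernel_sigma_mm: float
    kernel_radius_mm: float

    def to_text(self, path: str | Path) -> None:
        np.savetxt(path, self.values, fmt="%.6g")

    def to_png(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        vmax = np.abs(self.values).max() or 1.0
        im = ax.imshow(
            self.values,
            origin="lower",
            extent=(self.x_mm[0], self.x_mm[-1], self.y_mm[0], self.y_mm[-1]),
            cmap="RdBu_r",
            vmin=-vmax,
            vmax=vmax,
        )
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        fig.colorbar(im, ax=ax, label="activation")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)


def decs_positive_electrodes(
    grid: ElectrodeGrid,
    stim_sites: list[tuple[float, float]],
    radius_mm: float = DECS_RADIUS_MM,
) -> set[str]:
    """Electrodes whose center lies within ``radius_mm`` of any stimulation site."""
    if not stim_sites:
        raise InvalidInputError("need at least one stimulation site")
    sites = np.asarray(stim_sites, dtype=float).reshape(-1, 2)
    out: set[str] = set()
    for ch in grid.channels:
        d = np.linalg.norm(sites - grid.xy(ch), axis=1)
        if (d <= radius_mm).any():
            out.add(ch)
    return out


def confusion(
    test_pos: set[str], truth_pos: set[str], all_electrodes: set[str]
) -> ConfusionCounts:
    """Tally the 2x2 table of test-positive vs truth-positive electrodes."""
    test_pos, truth_pos, all_electrodes = (
        set(test_pos), set(truth_pos), set(all_electrodes),
    )
    if not test_pos <= all_electrodes or not truth_pos <= all_electrodes:
        raise InvalidInputError("test/truth sets must be subsets of all electrodes")
    tp = len(test_pos & truth_pos)
    fp = len(test_pos - truth_pos)
    fn = len(truth_pos - test_pos)
    tn = len(all_electrodes) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """Percent sensitivity ``100·TP/(TP+FN)`` and specificity ``100·TN/(TN+FP)``."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("no truth-positive electrodes: sensitivity undefined")
    if c.fp + c.tn == 0:
        raise UndefinedMetricError("no truth-negative electrodes: specificity undefined")
    sens = 100.0 * c.tp / (c.tp + c.fn)
    spec = 100.0 * c.tn / (c.tn + c.fp)
    return sens, spec


def chi_square_independence(
    c: ConfusionCounts, yates: bool = True
) -> tuple[float, int, float]:
    """2x2 chi-square test of test/truth independence.

    Yates continuity correction is applied by default. Returns
    ``(statistic, df, p)`` with df = 1. The critical value at alpha=0.001 is
    10.83.
    """
    a, b, cc, d = c.tp, c.fp, c.fn, c.tn
    n = c.total
    margins = [a + b, cc + d, a + cc, b + d]
    if min(margins) == 0:
        raise InvalidInputError("all row/column marginals must be positive")
    diff = abs(a * d - b * cc)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    stat = n * diff**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(_stats.chi2.sf(stat, df=1))
    return float(stat), 1, p


def chi2_critical_value(alpha: float = 0.001, df: int = 1) -> float:
    """Upper-tail chi-square quantile."""
    return float(_stats.chi2.isf(alpha, df=df))


def activation_map(
    grid: ElectrodeGrid,
    weights: dict[str, float],
    resolution_mm: float = 0.5,
    kernel_diameter_mm: float = KERNEL_DIAMETER_MM,
    kernel_sigma_rel: float = KERNEL_SIGMA_REL,
    margin_mm: float | None = None,
) -> ActivationMapRaster:
    """Sum weighted, truncated Gaussian kernels centered on the electrodes.

    ``weights`` maps channel -> scalar; channels absent from the mapping get
    weight 0 (the caller supplies weights only for significant electrodes).
    The kernel spread is ``kernel_sigma_rel`` in units of the kernel radius,
    i.e. 5 mm physical at the defaults, and the kernel is truncated to its
    support circle.
    """
    unknown = set(weights) - set(grid.channels)
    if unknown:
        raise InvalidInputError(f"weights for unknown electrodes: {sorted(unknown)}")
    radius = kernel_diameter_mm / 2.0
    sigma = kernel_sigma_rel * radius
    if margin_mm is None:
        margin_mm = radius
    pts = np.asarray([grid.xy(ch) for ch in grid.channels])
    x0, y0 = pts.min(axis=0) - margin_mm
    x1, y1 = pts.max(axis=0) + margin_mm
    x = np.arange(x0, x1 + resolution_mm / 2, resolution_mm)
    y = np.arange(y0, y1 + resolution_mm / 2, resolution_mm)
    xx, yy = np.meshgrid(x, y)
    values = np.zeros_like(xx)
    for ch, w in weights.items():
        if w == 0.0:
            continue
        cx, cy = grid.xy(ch)
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        kern = np.exp(-d2 / (2.0 * sigma**2))
        kern[d2 > radius**2] = 0.0
        values += w * kern
    return ActivationMapRaster(
        values=values, x_mm=x, y_mm=y, kernel_sigma_mm=sigma, kernel_radius_mm=radius
    )


def site_risk_partition(
    etam_pos: set[str], efam_pos: set[str], all_electrodes: set[str]
) -> dict[str, set[str]]:
    """Triage electrodes by agreement of the two mapping methods.

    Both positive -> ``functional_convinced``; exactly one positive ->
    ``functional_high_risk``; neither -> ``negative``.
    """
    etam_pos, efam_pos = set(etam_pos), set(efam_pos)
    all_electrodes = set(all_electrodes)
    if not etam_pos <= all_electrodes or not efam_pos <= all_electrodes:
        raise InvalidInputError("flag sets must be subsets of all electrodes")
    convinced = etam_pos & efam_pos
    high_risk = etam_pos ^ efam_pos
    negative = all_electrodes - etam_pos - efam_pos
    return {
        "functional_convinced": convinced,
        "functional_high_risk": high_risk,
        "negative": negative,
    }
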