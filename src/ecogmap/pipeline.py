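"""End-to-end convenience wrappers: raw recording to channel flag sets.

These compose the preprocessing, temporal-map and spectral-map stages in
the canonical order (channel exclusion, common average reference, then the
method-specific windowing) so the CLI, tests and acceptance runs all share
one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import efam as _efam
from . import etam as _etam
from . import preproc as _pp
from .errors import EmptyResultError
from .preproc import EventSet, Recording, TrialSet


@dataclass
class EtamResult:
    template: _etam.MRCPTemplate
    scores: list[_etam.ChannelScore]
    trial_set: TrialSet

    @property
    def positive(self) -> set[str]:
        return {s.channel for s in self.scores if s.significant}


@dataclass
class EfamResult:
    activations: list[_efam.BandActivation]
    trial_set: TrialSet

    @property
    def positive(self) -> set[str]:
        return _efam.efam_positive_channels(self.activations)

    def band_positive(self, band: tuple[int, int]) -> set[str]:
        return {a.channel for a in self.activations if a.band == band and a.significant}


def _events(rec: Recording, events: EventSet | None) -> EventSet:
    if events is not None:
        return events
    if rec.emg is None:
        raise EmptyResultError("no events given and no EMG channel to detect them from")
    ev = _pp.detect_emg_onsets(rec.emg, rec.fs)
    if len(ev) == 0:
        raise EmptyResultError("EMG onset detection found no events")
    return ev


def run_etam(
    rec: Recording,
    events: EventSet | None = None,
    template: _etam.MRCPTemplate | None = None,
    band: tuple[float, float] = (0.05, 3.0),
    alpha: float = _etam.ALPHA,
    reject_z: float | None = 5.0,
) -> EtamResult:
    """CAR, slow-potential band-pass, epoching, template scoring.

    When no template is supplied one is built from the recording's own
    representative channel (the single-subject route); pass a
    leave-one-out template for cross-validated use.
    """
    ev = _events(rec, events)
    car = _pp.apply_car(rec)
    filt = _pp.bandpass_mrcp(car, low=band[0], high=band[1])
    ts = _pp.epoch_trials(filt, ev)
    if reject_z is not None and np.isfinite(reject_z):
        ts = _pp.reject_trials(ts, amplitude_z_max=reject_z)
    if template is None:
        rep, _ = _etam.select_representative(ts)
        template = _etam.build_template([_etam.grand_average(ts, rep)], ts_like=ts)
    scores = _etam.etam_map(ts, template, alpha=alpha)
    return EtamResult(template=template, scores=scores, trial_set=ts)


def run_efam(
    rec: Recording,
    events: EventSet | None = None,
    bands: tuple[tuple[int, int], ...] = (_efam.LFB, _efam.HFB),
    alpha: float = _efam.ALPHA,
    pool_bands: bool = False,
    reject_z: float | None = 5.0,
) -> EfamResult:
    """CAR, wide epoching (pre 3500 ms), spectral band comparison.

    No slow-potential filtering here: the spectral map works on the
    re-referenced broadband signal.
    """
    ev = _events(rec, events)
    car = _pp.apply_car(rec)
    ts = _pp.epoch_trials(car, ev, pre_ms=3500.0, post_ms=1500.0)
    if reject_z is not None and np.isfinite(reject_z):
        ts = _pp.reject_trials(ts, amplitude_z_max=reject_z)
    activations = _efam.efam_map(ts, bands=bands, alpha=alpha, pool_bands=pool_bands)
    return EfamResult(activations=activations, trial_set=ts)


def run_both(
    rec: Recording,
    events: EventSet | None = None,
    template: _etam.MRCPTemplate | None = None,
    reject_z: float | None = 5.0,
) -> tuple[EtamResult, EfamResult]:
    """Temporal and spectral maps off a single shared re-referencing pass."""
    ev = _events(rec, events)
    car = _pp.apply_car(rec)

    filt = _pp.bandpass_mrcp(car)
    ts_t = _pp.epoch_trials(filt, ev)
    if reject_z is not None and np.isfinite(reject_z):
        ts_t = _pp.reject_trials(ts_t, amplitude_z_max=reject_z)
    if template is None:
        rep, _ = _etam.select_representative(ts_t)
        template = _etam.build_template([_etam.grand_average(ts_t, rep)], ts_like=ts_t)
    scores = _etam.etam_map(ts_t, template)
    etam_res = EtamResult(template=template, scores=scores, trial_set=ts_t)

    ts_f = _pp.epoch_trials(car, ev, pre_ms=3500.0, post_ms=1500.0)
    if reject_z is not None and np.isfinite(reject_z):
        ts_f = _pp.reject_trials(ts_f, amplitude_z_max=reject_z)
    activations = _efam.efam_map(ts_f)
    efam_res = EfamResult(activations=activations, trial_set=ts_f)
    return etam_res, efam_res
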