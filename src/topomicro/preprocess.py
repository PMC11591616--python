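"""Continuous-signal preprocessing: band-pass filtering, epoching,
baseline correction, amplitude-based artifact rejection, grand averaging.

The filter is a 2nd-order Butterworth band-pass (0.5–40 Hz by default,
−12 dB/oct roll-off) applied in two passes (forward and backward), which
cancels the phase shift; the effective magnitude response is the squared
single-pass response.  Edge transients are suppressed by reflective
padding of three times the filter's effective impulse-response length.

Artifact rejection is a deterministic peak-to-peak amplitude threshold
(default 150 µV) replacing by-eye trial inspection: an epoch is dropped
iff any channel's peak-to-peak amplitude exceeds the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .topography import EvokedERP

__all__ = [
    "PreprocParams",
    "RejectionLog",
    "bandpass_filter",
    "epoch_and_baseline",
    "reject_artifacts",
    "grand_average",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocParams:
    band: tuple[float, float] = (0.5, 40.0)
    filter_order: int = 2
    two_pass: bool = True
    epoch_ms: tuple[float, float] = (-100.0, 700.0)
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    reject_peak_to_peak_uV: float = 150.0

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high):
            raise ValueError("band must satisfy 0 < low < high")
        if self.filter_order < 1:
            raise ValueError("filter_order must be ≥ 1")
        if self.reject_peak_to_peak_uV <= 0:
            raise ValueError("rejection threshold must be positive")


def _impulse_response_length(b: np.ndarray, a: np.ndarray, tol: float = 1e-4) -> int:
    """Effective IR length: samples until |h| decays below tol × peak."""
    n = 10_000
    h = sps.lfilter(b, a, np.r_[1.0, np.zeros(n - 1)])
    peak = np.max(np.abs(h))
    above = np.nonzero(np.abs(h) > tol * peak)[0]
    return int(above[-1]) + 1 if above.size else 1


def bandpass_filter(
    data: np.ndarray, params: PreprocParams, sfreq: float
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a channels × samples array.

    Two passes (forward + backward) double the attenuation and cancel
    phase; DC is rejected by the high-pass edge.  Raises for a band edge
    at or above Nyquist.
    """
    low, high = params.band
    nyq = sfreq / 2.0
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz is at or above Nyquist ({nyq} Hz)")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    b, a = sps.butter(params.filter_order, [low, high], btype="bandpass", fs=sfreq)
    irlen = _impulse_response_length(b, a)
    pad = min(3 * irlen, data.shape[1] - 1)
    if data.shape[1] <= 3 * params.filter_order:
        raise ValueError("signal too short for the requested filter order")
    if not params.two_pass:
        padded = np.pad(data, [(0, 0), (pad, pad)], mode="reflect")
        out = sps.lfilter(b, a, padded, axis=1)
        return out[:, pad : pad + data.shape[1]]
    return sps.filtfilt(b, a, data, axis=1, padtype="even", padlen=pad)


def epoch_and_baseline(
    continuous: np.ndarray,
    events: np.ndarray,
    params: PreprocParams,
    sfreq: float,
) -> list[np.ndarray]:
    """Cut stimulus-locked epochs and subtract the baseline mean.

    Each epoch spans ``params.epoch_ms`` around its event sample with the
    window half-open [start, end); the per-channel mean over the baseline
    window is subtracted.  Events too close to the record edge are
    skipped with a warning.  Sample counts use round-half-up.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    t0, t1 = params.epoch_ms
    start_off = int(np.floor(t0 / 1000.0 * sfreq + 0.5))
    n_len = int(np.floor((t1 - t0) / 1000.0 * sfreq + 0.5))
    b0, b1 = params.baseline_ms
    bl_lo = int(np.floor((b0 - t0) / 1000.0 * sfreq + 0.5))
    bl_hi = int(np.floor((b1 - t0) / 1000.0 * sfreq + 0.5))
    epochs: list[np.ndarray] = []
    for ev in np.asarray(events, dtype=int):
        lo = ev + start_off
        hi = lo + n_len
        if lo < 0 or hi > continuous.shape[1]:
            logger.warning("event at sample %d too close to record edge; skipped", ev)
            continue
        ep = continuous[:, lo:hi].copy()
        ep -= ep[:, bl_lo:bl_hi].mean(axis=1, keepdims=True)
        epochs.append(ep)
    return epochs


@dataclass(frozen=True)
class RejectionLog:
    """Per-epoch artifact decisions: (kept, worst peak-to-peak µV, channel)."""

    decisions: tuple[tuple[bool, float, int], ...]

    @property
    def n_rejected(self) -> int:
        return sum(1 for kept, _, _ in self.decisions if not kept)


def reject_artifacts(
    epochs: list[np.ndarray], params: PreprocParams
) -> tuple[list[np.ndarray], RejectionLog]:
    """Drop epochs whose worst-channel peak-to-peak exceeds the threshold."""
    retained: list[np.ndarray] = []
    decisions: list[tuple[bool, float, int]] = []
    thr = params.reject_peak_to_peak_uV
    for ep in epochs:
        ptp = ep.max(axis=1) - ep.min(axis=1)
        worst = int(np.argmax(ptp))
        keep = bool(ptp[worst] <= thr)
        decisions.append((keep, float(ptp[worst]), worst))
        if keep:
            retained.append(ep)
    log = RejectionLog(decisions=tuple(decisions))
    if log.n_rejected:
        logger.info("rejected %d / %d epochs (> %g µV)", log.n_rejected, len(epochs), thr)
    return retained, log


def grand_average(erps: list[EvokedERP]) -> EvokedERP:
    """Unweighted mean across subjects of one condition's evoked ERPs."""
    if not erps:
        raise ValueError("no ERPs to average")
    first = erps[0]
    for e in erps[1:]:
        if e.data.shape != first.data.shape:
            raise ValueError("all ERPs must share channels × samples shape")
        if e.sfreq != first.sfreq or e.t0_ms != first.t0_ms:
            raise ValueError("all ERPs must share sfreq and epoch origin")
        if e.cell != first.cell:
            raise ValueError("grand average mixes conditions")
    data = np.mean([e.data for e in erps], axis=0)
    return replace(
        first,
        data=data,
        subject_id="grand-average",
        is_avg_ref=all(e.is_avg_ref for e in erps),
    )
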