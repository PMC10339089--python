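"""Time synchronization, filtering and protocol segmentation.

Processing order is fixed (and logged by the pipeline driver):
synchronize → convert to chromophores → 0.05 Hz low-pass → 5 s moving
average → segment by posture.

The low-pass is a 4th-order Butterworth applied forward-backward
(zero-phase).  Zero phase matters here: transition timing (t95, time
constants) is the estimand, and a causal filter's group delay would bias
every kinetic metric.  Edges are handled by `sosfiltfilt`'s odd reflection
padding; the moving average uses centered windows truncated at the edges.
Both choices are documented because the first/last minute of each segment
is itself an analysis window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .protocol import ProtocolDefinition
from .types import ChromophoreSeries, RawRecording, SegmentedSeries

log = logging.getLogger("nirskinetics")

#: analysis defaults: cutoff of the cadence-removal low-pass and the
#: smoothing window applied after it
DEFAULT_CUTOFF_HZ = 0.05
DEFAULT_SMOOTH_S = 5.0

#: sync residual spread (s) above which a warning is emitted
RESIDUAL_WARN_S = 0.5


@dataclass(frozen=True)
class SyncResult:
    """Clock shift applied to device b and per-event residual misalignment."""

    shift_s: float
    residuals_s: tuple[float, ...]

    @property
    def max_residual_s(self) -> float:
        return float(max(abs(r) for r in self.residuals_s))


def synchronize(
    a: RawRecording, b: RawRecording, n_events: int = 6
) -> tuple[RawRecording, RawRecording, SyncResult]:
    """Align device b's clock to device a's from the shared event markers.

    The shift is the mean of the per-event time differences (a − b); the
    per-event residuals after shifting are reported, and a spread beyond
    ``RESIDUAL_WARN_S`` raises a warning in the run log.  Applying the
    operation twice is a no-op (the residuals then average zero).
    """
    ev_a = dict(a.events)
    ev_b = dict(b.events)
    common = sorted(set(ev_a) & set(ev_b))
    if len(common) < n_events:
        raise ValueError(
            f"need {n_events} paired synchronization events, found {len(common)} "
            f"(device a: {sorted(ev_a)}, device b: {sorted(ev_b)})"
        )
    diffs = np.array([ev_a[i] - ev_b[i] for i in common])
    shift = float(diffs.mean())
    residuals = tuple(float(d - shift) for d in diffs)
    result = SyncResult(shift_s=shift, residuals_s=residuals)
    if result.max_residual_s > RESIDUAL_WARN_S:
        msg = (f"synchronization residuals up to {result.max_residual_s:.3f} s "
               f"after mean shift {shift:.3f} s")
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return a, b.shifted(shift), result


def lowpass(
    x: np.ndarray, sample_rate_hz: float, cutoff_hz: float = DEFAULT_CUTOFF_HZ
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass."""
    if sample_rate_hz <= 2 * cutoff_hz:
        raise ValueError(
            f"sample rate {sample_rate_hz} Hz must exceed twice the cutoff {cutoff_hz} Hz"
        )
    sos = signal.butter(4, cutoff_hz, btype="low", fs=sample_rate_hz, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[-1] <= 3 * padlen:
        raise ValueError(
            f"series of {x.shape[-1]} samples too short to filter stably "
            f"(need more than {3 * padlen})"
        )
    return signal.sosfiltfilt(sos, x, axis=-1)


def moving_average(
    x: np.ndarray, sample_rate_hz: float, window_s: float = DEFAULT_SMOOTH_S
) -> np.ndarray:
    """Centered moving mean; edge windows are truncated, not padded."""
    w = int(round(window_s * sample_rate_hz))
    if w < 2:
        raise ValueError(f"window {window_s} s is under 2 samples at {sample_rate_hz} Hz")
    return (
        pd.Series(x).rolling(window=w, center=True, min_periods=1).mean().to_numpy()
    )


def filter_series(
    series: ChromophoreSeries,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    smooth_s: float = DEFAULT_SMOOTH_S,
) -> ChromophoreSeries:
    """Apply the paper-order filtering chain (low-pass, then moving average)
    to every channel of a chromophore series."""
    fs = series.sample_rate_hz

    def chain(x: np.ndarray) -> np.ndarray:
        return moving_average(lowpass(x, fs, cutoff_hz), fs, smooth_s)

    return series.map(chain)


def segment(
    series: ChromophoreSeries,
    protocol: ProtocolDefinition,
    start_time: float = 0.0,
) -> SegmentedSeries:
    """Label every sample with its posture segment.

    ``start_time`` is the protocol start on the series' (common) clock.
    Samples beyond the protocol end are labeled ``''`` and ignored with a
    log notice; a series shorter than the protocol is an error.
    """
    bounds = protocol.boundaries(start_time)
    t = series.time
    end = start_time + protocol.total_duration
    last_needed = end - 1.0 / series.sample_rate_hz
    if t[-1] < last_needed - 1e-9:
        raise ValueError(
            f"series ends at {t[-1]:.2f} s but the protocol spans "
            f"[{start_time:.2f}, {end:.2f}) s: missing {end - t[-1]:.2f} s"
        )
    labels = np.full(t.shape, "", dtype=object)
    for name, (t0, t1) in bounds.items():
        labels[(t >= t0) & (t < t1)] = name
    n_tail = int(np.sum(t >= end))
    if n_tail:
        log.info("ignoring %d samples beyond the protocol end", n_tail)
    return SegmentedSeries(series=series, labels=labels, boundaries=bounds)
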