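"""Preprocessing of dF/F traces and display-time smoothing.

Calcium imaging reports a nonnegative proxy of activity, so small negative
dF/F excursions (noise, baseline estimation) are clipped at zero; traces are
then scaled by the single per-subject maximum so every recording lives in
[0, 1] and reconstruction error is comparable across traces.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.signal

from .datatypes import CoefficientTrajectory, NeuralRecording, PreprocessReport

__all__ = ["preprocess", "smooth_for_display", "first_difference"]


def preprocess(recording: NeuralRecording,
               expected_max_clip_fraction: float = 0.03,
               ) -> tuple[NeuralRecording, PreprocessReport]:
    """Clip negatives to zero and scale by the per-subject maximum.

    The scaling maximum is shared across all traces of the subject (per-subject,
    not per-trace).  Traces whose clipped fraction exceeds
    ``expected_max_clip_fraction`` (3% by default, the level expected of
    well-extracted dF/F) are flagged in the report.  Idempotent: a preprocessed
    recording passes through unchanged.
    """
    Y = recording.traces
    clip_fractions = np.mean(Y < 0, axis=1)
    clipped = np.clip(Y, 0.0, None)
    scale_max = float(clipped.max())
    if scale_max <= 0:
        raise ValueError("recording is all zero after clipping; no valid scale")
    flagged = np.flatnonzero(clip_fractions > expected_max_clip_fraction)
    if flagged.size:
        warnings.warn(
            f"{flagged.size} trace(s) exceed the expected "
            f"{expected_max_clip_fraction:.0%} clip fraction", RuntimeWarning)
    out = dataclasses.replace(recording, traces=clipped / scale_max)
    report = PreprocessReport(
        clip_fractions=clip_fractions, scale_max=scale_max,
        flagged_traces=flagged,
        expected_max_clip_fraction=expected_max_clip_fraction)
    return out, report


def smooth_for_display(trace: np.ndarray, window: int = 15, polyorder: int = 3
                       ) -> np.ndarray:
    """Savitzky-Golay smoothed copy of a trace — for reporting, never fitting.

    Defaults (window 15 samples = 5 s at 3 Hz, cubic) suit display of worm
    calcium traces.
    """
    trace = np.asarray(trace, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if trace.shape[-1] < window:
        raise ValueError("trace shorter than the smoothing window")
    return scipy.signal.savgol_filter(trace, window, polyorder, axis=-1)


def first_difference(c, sampling_rate: float | None = None) -> np.ndarray:
    """Forward difference dc/dt of a coefficient trajectory, shape (M, T-1).

    The sampling interval comes from ``sampling_rate`` (Hz) when given,
    otherwise differences are per-sample.
    """
    C = c.c if isinstance(c, CoefficientTrajectory) else np.asarray(c, dtype=float)
    if C.ndim == 1:
        C = C[None, :]
    if C.shape[1] < 2:
        raise ValueError("need at least two timepoints for a first difference")
    dt = 1.0 / sampling_rate if sampling_rate else 1.0
    return np.diff(C, axis=1) / dt
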