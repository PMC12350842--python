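"""Dynamic connectivity in trace space from a fitted model.

Freezing the dynamics coefficients at an instant (or at any chosen operator
mixture) yields an equivalent linear time-invariant system whose trace-space
interaction structure is ``D F D'`` — a directed, weighted map from source
traces (rows) to target traces (columns).  The module also simulates the
ambient effect of a mixture via an impulse response, thresholds maps for
export, compares them against user-supplied reference connectomes, and
computes coefficient coactivation statistics and presence tallies.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    CoefficientTrajectory,
    ConnectivityMap,
    DLDSModel,
    OperatorMixture,
)
from .model import compose_dynamics

__all__ = [
    "dynamic_connectivity",
    "combine_and_normalize",
    "impulse_response",
    "instantaneous_connectivity",
    "threshold_map",
    "compare_reference",
    "coactivation_probability",
    "tally_presence",
]


def dynamic_connectivity(D: np.ndarray, F: np.ndarray,
                         source_description: str = "") -> ConnectivityMap:
    """Trace-space interaction map ``D F D'`` of the frozen linear system."""
    D = np.asarray(D, dtype=float)
    F = np.asarray(F, dtype=float)
    if F.shape != (D.shape[1], D.shape[1]):
        raise ValueError(
            f"F must be ({D.shape[1]}, {D.shape[1]}) for D with {D.shape[1]} "
            f"columns, got {F.shape}"
        )
    return ConnectivityMap(weights=D @ F @ D.T,
                           source_description=source_description)


def combine_and_normalize(operators: np.ndarray, weights: np.ndarray) -> OperatorMixture:
    """Compose ``sum_m w_m f_m`` and rescale to unit Frobenius norm.

    Normalization happens after linearly combining the operators (so the
    impulse response is scale-comparable across mixtures).  An all-zero
    mixture is returned as the zero matrix with ``zero_mixture=True``.
    """
    weights = np.asarray(weights, dtype=float).ravel()
    F = compose_dynamics(operators, weights)
    norm = np.linalg.norm(F)
    if norm == 0.0:
        return OperatorMixture(weights=weights, normalized_operator=F,
                               zero_mixture=True)
    return OperatorMixture(weights=weights, normalized_operator=F / norm)


def impulse_response(F: np.ndarray, D: np.ndarray, steps: int = 500) -> np.ndarray:
    """Mean simulated trace activity from an all-ones latent impulse.

    Starting from ``x_0 = 1``, iterates ``x_t = F x_{t-1}`` for ``steps``
    steps and returns the mean over t = 1..steps of ``D x_t`` per trace
    (the impulse state itself is excluded from the mean).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    F = np.asarray(F, dtype=float)
    D = np.asarray(D, dtype=float)
    p = F.shape[0]
    if F.shape != (p, p) or D.shape[1] != p:
        raise ValueError("shape mismatch between F and D")
    x = np.ones(p)
    acc = np.zeros(p)
    for _ in range(steps):
        x = F @ x
        acc += x
    return D @ (acc / steps)


def instantaneous_connectivity(model: DLDSModel, c, t: int) -> ConnectivityMap:
    """Dynamic connectivity with the coefficients frozen at timepoint ``t``.

    Row i of the map is the connectivity *from* trace i; column i is the
    connectivity *to* trace i.  The map also carries the impulse-response
    node activity of the frozen mixture.
    """
    C = c.c if isinstance(c, CoefficientTrajectory) else np.asarray(c, dtype=float)
    if not (-C.shape[1] <= t < C.shape[1]):
        raise IndexError(f"timepoint {t} out of range for T={C.shape[1]}")
    mix = combine_and_normalize(model.operators, C[:, t])
    cmap = dynamic_connectivity(model.D, mix.normalized_operator,
                                source_description=f"instantaneous t={t}")
    cmap.zero_mixture = mix.zero_mixture
    if not mix.zero_mixture:
        cmap.node_activity = impulse_response(mix.normalized_operator, model.D)
    else:
        cmap.node_activity = np.zeros(model.n_traces)
    return cmap


def threshold_map(cmap: ConnectivityMap, top_fraction: float) -> ConnectivityMap:
    """Keep only the ``ceil(top_fraction * n^2)`` strongest-|weight| entries.

    Deterministic tie-break: among equal magnitudes, entries earlier in
    row-major (row, column) order survive first.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    W = cmap.weights
    n = W.shape[0]
    keep = math.ceil(top_fraction * n * n)
    flat = np.abs(W).ravel()
    order = np.argsort(-flat, kind="stable")     # stable => row-major tie-break
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:keep]] = True
    out = np.where(mask.reshape(W.shape), W, 0.0)
    return ConnectivityMap(
        weights=out,
        source_description=f"{cmap.source_description} | top {top_fraction:g}",
        node_activity=cmap.node_activity,
        trace_labels=cmap.trace_labels,
        subject_id=cmap.subject_id,
        zero_mixture=cmap.zero_mixture,
    )


def compare_reference(cmap: ConnectivityMap, reference: np.ndarray) -> ConnectivityMap:
    """Sign-code map entries by presence in a reference adjacency.

    Entry magnitudes are preserved exactly; entries whose (i, j) pair has an
    edge in the reference become positive (matched), the rest negative
    (novel).  Note the sign is repurposed here as matched/novel — distinct
    from the excitatory/inhibitory sign of raw maps.
    """
    ref = np.asarray(reference)
    if ref.shape != cmap.weights.shape:
        raise ValueError(
            f"reference shape {ref.shape} != map shape {cmap.weights.shape}"
        )
    signs = np.where(ref != 0, 1.0, -1.0)
    return ConnectivityMap(
        weights=np.abs(cmap.weights) * signs,
        source_description=f"{cmap.source_description} | vs reference",
        node_activity=cmap.node_activity,
        trace_labels=cmap.trace_labels,
        subject_id=cmap.subject_id,
        zero_mixture=cmap.zero_mixture,
    )


def coactivation_probability(a: np.ndarray, b: np.ndarray, threshold: float) -> float:
    """P(a active and b active | b active) for two coefficient traces.

    Asymmetric by construction: the denominator counts timepoints where ``b``
    is active.  Returns NaN (undefined, distinct from 0) when ``b`` is never
    active.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("coefficient traces must have equal length")
    a_on = np.abs(a) > threshold
    b_on = np.abs(b) > threshold
    denom = int(b_on.sum())
    if denom == 0:
        warnings.warn("conditioning trace is never active; probability undefined",
                      RuntimeWarning)
        return float("nan")
    return float((a_on & b_on).sum() / denom)


def _neuron_trace_indices(trace_labels: list[list[str]] | None,
                          neuron_names: list[str]) -> list[int]:
    if trace_labels is None:
        return []
    wanted = set(neuron_names)
    return [i for i, names in enumerate(trace_labels) if wanted & set(names)]


def tally_presence(maps: list[ConnectivityMap], neuron_names: list[str],
                   labels: list[str], activity_quantile: float = 0.95,
                   ) -> pd.DataFrame:
    """Tally, per condition, the maps in which any named neuron participates.

    A neuron "participates" in a (thresholded) map when one of its traces
    touches a surviving edge, or when its |node activity| exceeds the
    ``activity_quantile`` quantile of the map's node activities.  Returns one
    row per condition tag with map-level and subject-level ``k/n`` counts.
    Neuron names resolving to no trace in any map are counted absent with a
    warning.
    """
    if len(maps) != len(labels):
        raise ValueError("need one condition label per map")
    if not maps:
        return pd.DataFrame(columns=["condition", "maps_present", "maps_total",
                                     "subjects_present", "subjects_total"])
    found_anywhere = any(
        _neuron_trace_indices(m.trace_labels, neuron_names) for m in maps
    )
    if not found_anywhere:
        warnings.warn(
            f"none of {neuron_names} found in any map's trace labels",
            RuntimeWarning,
        )
    rows = []
    for cond in dict.fromkeys(labels):           # preserve first-seen order
        subset = [m for m, tag in zip(maps, labels) if tag == cond]
        present_flags = []
        for m in subset:
            idx = _neuron_trace_indices(m.trace_labels, neuron_names)
            present = False
            if idx:
                W = m.weights
                if np.any(W[idx, :] != 0) or np.any(W[:, idx] != 0):
                    present = True
                elif m.node_activity is not None and m.node_activity.size:
                    thr = np.quantile(np.abs(m.node_activity), activity_quantile)
                    if np.any(np.abs(m.node_activity[idx]) >= thr) and thr > 0:
                        present = True
            present_flags.append(present)
        subjects = {}
        for m, flag in zip(subset, present_flags):
            sid = m.subject_id or "unknown"
            subjects[sid] = subjects.get(sid, False) or flag
        rows.append({
            "condition": cond,
            "maps_present": int(sum(present_flags)),
            "maps_total": len(subset),
            "subjects_present": int(sum(subjects.values())),
            "subjects_total": len(subjects),
        })
    return pd.DataFrame(rows)
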