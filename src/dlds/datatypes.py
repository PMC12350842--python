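"""Core data containers.

All containers are thin dataclasses around :class:`numpy.ndarray` with shape and
finiteness validation.  Orientation conventions throughout the package:

* recorded traces ``y`` are ``(n_traces, T)`` (rows are traces, columns are time),
* latent states ``x`` are ``(p, T)``,
* dynamics coefficients ``c`` are ``(M, T)``,
* the operator dictionary is a stacked array ``(M, p, p)``.

Time is indexed 0-based with half-open ranges.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "NeuralRecording",
    "Hyperparameters",
    "LatentTrajectory",
    "CoefficientTrajectory",
    "DLDSModel",
    "SubjectFit",
    "AlignedModel",
    "GroundTruth",
    "DuffingParams",
    "DuffingTrajectory",
    "ConnectivityMap",
    "OperatorMixture",
    "PreprocessReport",
    "BinarizedSeries",
]


def _as_float_matrix(a: Any, name: str) -> np.ndarray:
    out = np.asarray(a, dtype=float)
    if out.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {out.shape}")
    return out


@dataclass
class NeuralRecording:
    """A multivariate neural time series (e.g. dF/F calcium traces).

    Parameters
    ----------
    traces
        ``(n_traces, T)`` activity matrix.  dF/F is dimensionless.
    sampling_rate
        Acquisition rate in Hz (whole-brain *C. elegans* recordings run at ~3 Hz).
    trace_labels
        Optional per-trace list of neuron names.  A single trace may carry several
        names (merged ROIs) and the same name may label several traces.
    behavior
        Optional per-timepoint integer behavior-state code.
    behavior_names
        Optional mapping from behavior code to human-readable state name.
    stimulus
        Optional per-timepoint stimulus level (e.g. oxygen concentration in %).
    stimulus_phase
        Optional per-timepoint phase flag: 0 for the first (constant-stimulus)
        half of a trial, 1 for the second (alternating) half.
    subject_id
        Identifier of the animal/recording session.
    """

    traces: np.ndarray
    sampling_rate: float = 1.0
    trace_labels: list[list[str]] | None = None
    behavior: np.ndarray | None = None
    behavior_names: dict[int, str] | None = None
    stimulus: np.ndarray | None = None
    stimulus_phase: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.traces = _as_float_matrix(self.traces, "traces")
        if self.traces.shape[1] < 1:
            raise ValueError("recording must contain at least one timepoint")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces contain non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        T = self.traces.shape[1]
        if self.trace_labels is not None:
            if len(self.trace_labels) != self.n_traces:
                raise ValueError(
                    f"trace_labels has {len(self.trace_labels)} entries for "
                    f"{self.n_traces} traces"
                )
            self.trace_labels = [list(map(str, names)) for names in self.trace_labels]
        for name in ("behavior", "stimulus", "stimulus_phase"):
            vec = getattr(self, name)
            if vec is None:
                continue
            vec = np.asarray(vec)
            if vec.shape != (T,):
                raise ValueError(f"{name} must have length T={T}, got shape {vec.shape}")
            setattr(self, name, vec)

    @property
    def n_traces(self) -> int:
        return self.traces.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.traces.shape[1]


@dataclass
class Hyperparameters:
    """dLDS model and fitting hyperparameters.

    The regularization weights follow the per-timepoint inference objective

    ``||y_t - D x_t||^2 + lam_dyn ||x_t - F~_t c_t||^2 + lam_x_sparse ||x_t||_1
    + lam_c_sparse ||c_t||_1 + lam_c_smooth ||c_t - c_{t-1}||^2``.

    Defaults mirror the settings used for whole-brain *C. elegans* models
    (10 latent dimensions, 10 operators, dynamics-fidelity weight 0.9, state
    sparsity 0.1, coefficient sparsity 0.01, no explicit coefficient-smoothness
    term).
    """

    p: int = 10
    M: int = 10
    lam_dyn: float = 0.9         # weight of ||x_t - F~_t c_t||^2 (dynamics fidelity)
    lam_x_sparse: float = 0.1    # l1 weight on latent states x
    lam_c_sparse: float = 0.01   # l1 weight on dynamics coefficients c
    lam_c_smooth: float = 0.0    # weight of ||c_t - c_{t-1}||^2 (coefficient continuity)
    eta_D: float = 1e-3
    eta_f: float = 1e-3
    max_iter: int = 3000
    conv_tol: float = 1e-3
    seed: int = 0
    projection_spec: str = "unit-norm columns of D; Frobenius ball (<=1) per operator"
    inner_tol: float = 1e-8      # reserved; per-coordinate solver tolerance is fixed
    inner_max_iter: int = 2000   # max coordinate-descent sweeps per timepoint
    n_operator_steps: int = 5    # dictionary gradient steps per outer iteration
    activity_threshold: float = 1e-6

    def __post_init__(self) -> None:
        if self.p < 1 or self.M < 1:
            raise ValueError("p and M must be >= 1")
        for name in ("lam_dyn", "lam_x_sparse", "lam_c_sparse", "lam_c_smooth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.eta_D <= 0 or self.eta_f <= 0:
            raise ValueError("step sizes eta_D, eta_f must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def replace(self, **kwargs: Any) -> "Hyperparameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class LatentTrajectory:
    """Inferred latent states ``x`` with per-timepoint solver diagnostics."""

    x: np.ndarray                                  # (p, T)
    objective: np.ndarray | None = None            # (T,) achieved inference objective
    solver_converged: np.ndarray | None = None     # (T,) bool

    def __post_init__(self) -> None:
        self.x = _as_float_matrix(self.x, "x")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("latent states contain non-finite values")

    @property
    def p(self) -> int:
        return self.x.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.x.shape[1]


@dataclass
class CoefficientTrajectory:
    """Sparse dynamics coefficients ``c`` and the threshold declaring one active."""

    c: np.ndarray                       # (M, T)
    activity_threshold: float = 1e-6

    def __post_init__(self) -> None:
        self.c = _as_float_matrix(self.c, "c")
        if not np.all(np.isfinite(self.c)):
            raise ValueError("coefficients contain non-finite values")
        if self.activity_threshold < 0:
            raise ValueError("activity_threshold must be >= 0")

    @property
    def M(self) -> int:
        return self.c.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.c.shape[1]

    def active(self) -> np.ndarray:
        """Boolean (M, T) mask of coefficients above the activity threshold."""
        return np.abs(self.c) > self.activity_threshold

    def median_active_count(self) -> float:
        """Median over time of the number of simultaneously active coefficients."""
        return float(np.median(self.active().sum(axis=0)))


@dataclass
class DLDSModel:
    """A fitted decomposed linear dynamical system.

    ``D`` maps latent states to trace space; ``operators`` is the learned
    dictionary of dynamics operators stacked ``(M, p, p)``.
    """

    D: np.ndarray
    operators: np.ndarray
    hyper: Hyperparameters
    fit_log: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.D = _as_float_matrix(self.D, "D")
        self.operators = np.asarray(self.operators, dtype=float)
        if self.operators.ndim != 3 or self.operators.shape[1] != self.operators.shape[2]:
            raise ValueError("operators must be a (M, p, p) stack of square matrices")
        if self.D.shape[1] != self.operators.shape[1]:
            raise ValueError(
                f"D has {self.D.shape[1]} columns but operators are "
                f"{self.operators.shape[1]}x{self.operators.shape[2]}"
            )

    @property
    def n_traces(self) -> int:
        return self.D.shape[0]

    @property
    def p(self) -> int:
        return self.D.shape[1]

    @property
    def M(self) -> int:
        return self.operators.shape[0]


@dataclass
class SubjectFit:
    """Per-subject part of an aligned multi-subject model."""

    D: np.ndarray
    latents: LatentTrajectory
    coefficients: CoefficientTrajectory


@dataclass
class AlignedModel:
    """Multi-subject model: one shared operator dictionary, per-subject D/x/c."""

    operators: np.ndarray                  # shared (M, p, p)
    per_subject: dict[str, SubjectFit]
    hyper: Hyperparameters
    fit_log: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.operators = np.asarray(self.operators, dtype=float)
        p = self.operators.shape[1]
        M = self.operators.shape[0]
        for sid, sub in self.per_subject.items():
            if sub.D.shape[1] != p:
                raise ValueError(f"subject {sid}: D column count != shared p={p}")
            if sub.coefficients.M != M:
                raise ValueError(f"subject {sid}: coefficient rows != shared M={M}")

    def subject_model(self, subject_id: str) -> DLDSModel:
        """Per-subject view sharing the aligned operator dictionary."""
        sub = self.per_subject[subject_id]
        return DLDSModel(D=sub.D, operators=self.operators, hyper=self.hyper,
                         fit_log=self.fit_log)


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic recording (for recovery tests)."""

    D_true: np.ndarray
    operators_true: np.ndarray            # (M, p, p)
    x_true: np.ndarray                    # (p, T)
    c_true: np.ndarray                    # (M, T) effective coefficients (x_t = sum c f x_{t-1})
    noise_sd: float
    seed: int
    renorm_factors: np.ndarray | None = None   # per-step latent rescaling applied
    clip_fraction: float = 0.0                 # fraction of y entries clipped at 0
    y_unclipped: np.ndarray | None = None


@dataclass
class DuffingParams:
    """Parameters of the discrete-time Duffing oscillator.

    The discrete iteration uses ``alpha``, ``beta``, ``gamma`` and ``dt`` only;
    ``delta`` (damping) and ``omega`` (drive frequency) belong to the underlying
    continuous equation and enter the simulator only in its optional
    continuous-consistent mode.
    """

    alpha: float = 1.0
    beta: float = 5.0
    gamma: float = -1.0
    delta: float = 0.0
    omega: float = 1.0
    dt: float = 0.01
    x0: float = 1.0
    y0: float = 0.0
    T: int = 2000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass
class DuffingTrajectory:
    """Simulated Duffing states (position; velocity) stacked ``(2, T)``."""

    states: np.ndarray
    truncated: bool = False
    params: DuffingParams | None = None


@dataclass
class ConnectivityMap:
    """Directed trace-by-trace influence map.

    ``weights[i, j]`` is the influence of trace ``i`` on trace ``j`` (rows are
    sources, columns are targets).
    """

    weights: np.ndarray
    source_description: str = ""
    node_activity: np.ndarray | None = None     # per-trace mean simulated activity
    trace_labels: list[list[str]] | None = None
    subject_id: str = ""
    zero_mixture: bool = False

    def __post_init__(self) -> None:
        self.weights = _as_float_matrix(self.weights, "weights")
        if self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("connectivity weights must be square")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("connectivity weights contain non-finite values")

    @property
    def n_traces(self) -> int:
        return self.weights.shape[0]


@dataclass
class OperatorMixture:
    """A linear combination of dynamics operators rescaled to unit Frobenius norm."""

    weights: np.ndarray
    normalized_operator: np.ndarray
    zero_mixture: bool = False


@dataclass
class PreprocessReport:
    """Record of the clipping/scaling applied to a recording."""

    clip_fractions: np.ndarray           # per-trace fraction of negative values set to 0
    scale_max: float                     # per-subject maximum used for scaling
    flagged_traces: np.ndarray           # indices of traces whose clip fraction > expected
    expected_max_clip_fraction: float = 0.03


@dataclass
class BinarizedSeries:
    """A thresholded on/off series with the threshold that produced it."""

    values: np.ndarray                   # boolean (T,)
    threshold_kind: str                  # "weak" (median) or "strong" (median + 3 SD)
    threshold_value: float
    degenerate: bool = False             # zero-variance input under the strong rule
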