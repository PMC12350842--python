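"""Decomposed linear dynamical systems: generative model, inference and learning.

The model explains observed traces ``y_t`` by latent states ``x_t`` through a
constant observation matrix ``D`` (``y_t = D x_t``), and explains the latent
trajectory by a time-varying linear system ``x_t = F_t x_{t-1}`` whose
transition matrix is a sparse linear combination of a small dictionary of
learned dynamics operators, ``F_t = sum_m c_mt f_m``.

Fitting alternates between

1. sequential joint sparse inference of states and coefficients (x, c), and
2. projected-gradient updates of ``D`` and the operator dictionary,

until the per-iteration change of both falls below a tolerance.  A final
inference pass with the converged parameters yields the reported trajectories.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.linalg

from .datatypes import (
    AlignedModel,
    CoefficientTrajectory,
    DLDSModel,
    Hyperparameters,
    LatentTrajectory,
    NeuralRecording,
    SubjectFit,
)
from ._solvers import _infer_path

__all__ = [
    "compose_dynamics",
    "project_observation",
    "project_operator",
    "project_dictionary",
    "infer",
    "update_observation",
    "update_operators",
    "fit",
    "fit_aligned",
    "reconstruct",
    "select_num_operators",
    "align_latent_bases",
    "operator_span_angles",
    "FitDivergenceError",
]


class FitDivergenceError(RuntimeError):
    """Raised when the fitting objective grows by more than 10x its initial value."""

    def __init__(self, message: str, fit_log: pd.DataFrame | None = None):
        super().__init__(message)
        self.fit_log = fit_log


# ---------------------------------------------------------------------------
# projections onto the constraint sets
# ---------------------------------------------------------------------------

def project_observation(D: np.ndarray) -> np.ndarray:
    """Project D onto the set of matrices with unit-Euclidean-norm columns.

    Zero columns are left untouched (the projection is undefined there).
    Idempotent.
    """
    D = np.asarray(D, dtype=float)
    norms = np.linalg.norm(D, axis=0)
    # columns already unit (to fp tolerance) pass through bit-identically,
    # making the projection exactly idempotent
    safe = np.where((norms > 0) & (np.abs(norms - 1.0) > 1e-12), norms, 1.0)
    return D / safe


def project_operator(f: np.ndarray) -> np.ndarray:
    """Project one operator onto the Frobenius ball of radius 1. Idempotent."""
    f = np.asarray(f, dtype=float)
    norm = np.linalg.norm(f)
    if norm > 1.0 + 1e-12:
        return f / norm
    return f.copy()


def project_dictionary(operators: np.ndarray) -> np.ndarray:
    """Apply the operator projection to every element of a stacked dictionary."""
    operators = np.asarray(operators, dtype=float)
    return np.stack([project_operator(f) for f in operators])


# ---------------------------------------------------------------------------
# model algebra
# ---------------------------------------------------------------------------

def compose_dynamics(operators: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Linear combination ``sum_m weights[m] * f_m`` of the dynamics operators."""
    operators = np.asarray(operators, dtype=float)
    weights = np.asarray(weights, dtype=float).ravel()
    if operators.ndim != 3:
        raise ValueError("operators must be stacked (M, p, p)")
    if weights.shape[0] != operators.shape[0]:
        raise ValueError(
            f"got {weights.shape[0]} weights for {operators.shape[0]} operators"
        )
    return np.tensordot(weights, operators, axes=1)


def _dynamics_prediction(operators: np.ndarray, X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Predicted latents ``F~_t c_t`` for t = 1..T-1, shape (p, T-1)."""
    # (M, p, T-1): operator m applied to x_{t-1}
    Fx = np.einsum("mjk,kt->mjt", operators, X[:, :-1])
    return np.einsum("mjt,mt->jt", Fx, C[:, 1:])


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _coerce_y(y) -> np.ndarray:
    if isinstance(y, NeuralRecording):
        return y.traces
    Y = np.asarray(y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("y must be a (n_traces, T) matrix or NeuralRecording")
    if not np.all(np.isfinite(Y)):
        raise ValueError("y contains non-finite values")
    return Y


def infer(model: DLDSModel, y) -> tuple[LatentTrajectory, CoefficientTrajectory]:
    """Jointly infer latent states and dynamics coefficients for a recording.

    Timepoints are processed sequentially so the continuity penalty can
    reference the previous estimates.  Each per-timepoint problem is convex and
    solved by alternating exact lasso steps in x and c; timepoints where the
    inner loop hit its iteration cap are flagged in
    ``LatentTrajectory.solver_converged`` rather than silently accepted.
    """
    Y = _coerce_y(y)
    h = model.hyper
    if Y.shape[0] != model.n_traces:
        raise ValueError(
            f"recording has {Y.shape[0]} traces, model expects {model.n_traces}"
        )
    X, C, obj, conv = _infer_path(
        np.ascontiguousarray(Y),
        np.ascontiguousarray(model.D),
        np.ascontiguousarray(model.operators),
        h.lam_dyn, h.lam_x_sparse, h.lam_c_sparse, h.lam_c_smooth,
        h.inner_tol, h.inner_max_iter,
    )
    if not conv.all():
        warnings.warn(
            f"inference inner loop hit its iteration cap at "
            f"{int((~conv).sum())}/{conv.size} timepoints",
            RuntimeWarning,
        )
    lat = LatentTrajectory(x=X, objective=obj, solver_converged=conv)
    coef = CoefficientTrajectory(c=C, activity_threshold=h.activity_threshold)
    return lat, coef


# ---------------------------------------------------------------------------
# dictionary updates
# ---------------------------------------------------------------------------

def update_observation(D: np.ndarray, x, y, eta_D: float) -> np.ndarray:
    """One projected gradient step on D for the reconstruction loss.

    Returns ``Pi_D( D + eta_D * sum_t (y_t - D x_t) x_t' )``.  A zero step
    size is a legal null step (projection only).
    """
    if eta_D < 0:
        raise ValueError("eta_D must be >= 0")
    D = np.asarray(D, dtype=float)
    X = x.x if isinstance(x, LatentTrajectory) else np.asarray(x, dtype=float)
    Y = _coerce_y(y)
    grad = (Y - D @ X) @ X.T
    return project_observation(D + eta_D * grad)


def _operator_gradient(operators: np.ndarray, X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Gradient-ascent direction for each operator on the dynamics-fit loss.

    grad_m = sum_{t>=2} c_mt (x_t - F~_t c_t) x_{t-1}'  (stacked (M, p, p)).
    """
    resid = X[:, 1:] - _dynamics_prediction(operators, X, C)   # (p, T-1)
    return np.einsum("mt,jt,kt->mjk", C[:, 1:], resid, X[:, :-1])


def update_operators(operators: np.ndarray, x, c, eta_f: float) -> np.ndarray:
    """One projected gradient step on every dynamics operator.

    With T = 1 there are no dynamics terms and the dictionary is returned
    unchanged.  A zero step size is a legal null step.
    """
    if eta_f < 0:
        raise ValueError("eta_f must be >= 0")
    operators = np.asarray(operators, dtype=float)
    X = x.x if isinstance(x, LatentTrajectory) else np.asarray(x, dtype=float)
    C = c.c if isinstance(c, CoefficientTrajectory) else np.asarray(c, dtype=float)
    if X.shape[1] != C.shape[1]:
        raise ValueError("x and c must share T")
    if X.shape[1] < 2:
        return operators.copy()
    grad = _operator_gradient(operators, X, C)
    return project_dictionary(operators + eta_f * grad)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _observation_step(D: np.ndarray, Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Projected gradient step on D with the exact line-search step size.

    The reconstruction loss is quadratic in D, so the optimal step along the
    gradient direction is closed-form; the result is then projected back onto
    unit-norm columns.
    """
    R = Y - D @ X
    grad = R @ X.T
    dfit = grad @ X
    denom = float(np.sum(dfit * dfit))
    if denom <= 0.0:
        return D
    step = float(np.sum(R * dfit)) / denom
    return project_observation(D + step * grad)


def _dictionary_step(operators: np.ndarray,
                     trajectories: list[tuple[np.ndarray, np.ndarray]],
                     n_steps: int) -> np.ndarray:
    """Projected gradient steps on the shared dictionary, exact line search.

    Gradients accumulate the dynamics terms of every subject (t >= 2 within
    each subject only).  The dynamics loss is quadratic in the stacked
    operators, giving a closed-form optimal step; a few repeated steps per
    outer iteration speed up the ill-conditioned weak directions of the
    operator subproblem.
    """
    for _ in range(n_steps):
        grad = np.zeros_like(operators)
        num = 0.0
        den = 0.0
        resids = []
        for (X, C) in trajectories:
            if X.shape[1] < 2:
                resids.append(None)
                continue
            R = X[:, 1:] - _dynamics_prediction(operators, X, C)
            resids.append(R)
            grad += np.einsum("mt,jt,kt->mjk", C[:, 1:], R, X[:, :-1])
        for (X, C), R in zip(trajectories, resids):
            if R is None:
                continue
            dpred = _dynamics_prediction(grad, X, C)
            num += float(np.sum(R * dpred))
            den += float(np.sum(dpred * dpred))
        if den <= 0.0:
            break
        operators = project_dictionary(operators + (num / den) * grad)
    return operators


def fit_aligned(recordings: list, hyper: Hyperparameters) -> AlignedModel:
    """Fit one shared operator dictionary across subjects.

    Latent states, coefficients and the observation matrix are inferred and
    updated separately per subject; the dictionary gradient accumulates every
    subject's dynamics terms, with the t >= 2 lower bound restarting at each
    subject boundary (no dynamics link across animals).
    """
    if not recordings:
        raise ValueError("fit_aligned requires at least one recording")
    Ys = [np.ascontiguousarray(_coerce_y(r)) for r in recordings]
    ids = []
    for i, r in enumerate(recordings):
        sid = r.subject_id if isinstance(r, NeuralRecording) and r.subject_id else f"subject_{i}"
        ids.append(sid)
    if len(set(ids)) != len(ids):
        ids = [f"{sid}_{i}" for i, sid in enumerate(ids)]
    S = len(Ys)
    p, M = hyper.p, hyper.M

    rng = np.random.default_rng(hyper.seed)
    Ds = [project_observation(rng.standard_normal((Y.shape[0], p))) for Y in Ys]
    operators = project_dictionary(rng.standard_normal((M, p, p)))

    log_rows: list[dict] = []
    initial_obj: float | None = None

    for it in range(hyper.max_iter):
        infers: list[tuple[np.ndarray, np.ndarray]] = []
        total_obj = 0.0
        for s in range(S):
            X, C, obj, conv = _infer_path(
                Ys[s], np.ascontiguousarray(Ds[s]), np.ascontiguousarray(operators),
                hyper.lam_dyn, hyper.lam_x_sparse, hyper.lam_c_sparse,
                hyper.lam_c_smooth, hyper.inner_tol, hyper.inner_max_iter,
            )
            infers.append((X, C))
            total_obj += float(obj.sum())
        if initial_obj is None:
            initial_obj = total_obj
        if initial_obj > 0 and total_obj > 10.0 * initial_obj:
            raise FitDivergenceError(
                f"objective grew to {total_obj:.3g} (> 10x initial "
                f"{initial_obj:.3g}) at iteration {it}",
                fit_log=pd.DataFrame(log_rows),
            )

        new_Ds = [_observation_step(Ds[s], Ys[s], infers[s][0]) for s in range(S)]
        new_operators = _dictionary_step(operators, infers, hyper.n_operator_steps)

        dD = float(np.sqrt(sum(np.sum((a - b) ** 2) for a, b in zip(new_Ds, Ds))))
        dF = float(np.linalg.norm(new_operators - operators))
        log_rows.append({
            "iteration": it, "delta_D": dD, "delta_F": dF,
            "objective": total_obj,
        })
        Ds = new_Ds
        operators = new_operators
        if dD < hyper.conv_tol and dF < hyper.conv_tol:
            break

    # final inference with the converged parameters
    per_subject: dict[str, SubjectFit] = {}
    for s in range(S):
        X, C, obj, conv = _infer_path(
            Ys[s], np.ascontiguousarray(Ds[s]), np.ascontiguousarray(operators),
            hyper.lam_dyn, hyper.lam_x_sparse, hyper.lam_c_sparse,
            hyper.lam_c_smooth, hyper.inner_tol, hyper.inner_max_iter,
        )
        per_subject[ids[s]] = SubjectFit(
            D=Ds[s],
            latents=LatentTrajectory(x=X, objective=obj, solver_converged=conv),
            coefficients=CoefficientTrajectory(
                c=C, activity_threshold=hyper.activity_threshold),
        )
    return AlignedModel(
        operators=operators, per_subject=per_subject, hyper=hyper,
        fit_log=pd.DataFrame(log_rows),
    )


def fit(y, hyper: Hyperparameters) -> tuple[DLDSModel, LatentTrajectory, CoefficientTrajectory]:
    """Fit a per-subject dLDS model.

    Equivalent to a single-subject aligned fit: alternates inference with
    projected-gradient dictionary updates from a seeded random initialization,
    stops at ``max_iter`` or when the per-iteration change of both D and the
    dictionary falls below ``conv_tol``, then runs one final inference pass.
    """
    aligned = fit_aligned([y], hyper)
    (sid, sub), = aligned.per_subject.items()
    model = DLDSModel(D=sub.D, operators=aligned.operators, hyper=hyper,
                      fit_log=aligned.fit_log)
    return model, sub.latents, sub.coefficients


# ---------------------------------------------------------------------------
# reconstruction and model selection
# ---------------------------------------------------------------------------

def reconstruct(D: np.ndarray, x, y=None, scale: float = 1.0
                ) -> tuple[np.ndarray, float]:
    """Reconstruct traces as ``scale * D x`` and score them against ``y``.

    R^2 is pooled over all entries: ``1 - SS_res / SS_tot`` with SS_tot about
    the grand mean of y.  Returns ``(y_hat, r2)``; r2 is NaN when y is absent
    or has zero total variance (undefined).
    """
    D = np.asarray(D, dtype=float)
    X = x.x if isinstance(x, LatentTrajectory) else np.asarray(x, dtype=float)
    y_hat = scale * (D @ X)
    if y is None:
        return y_hat, float("nan")
    Y = _coerce_y(y)
    if Y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: y {Y.shape} vs reconstruction {y_hat.shape}")
    ss_res = float(np.sum((Y - y_hat) ** 2))
    ss_tot = float(np.sum((Y - Y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("zero total variance: R^2 undefined", RuntimeWarning)
        return y_hat, float("nan")
    return y_hat, 1.0 - ss_res / ss_tot


def select_num_operators(traces: np.ndarray,
                         candidate_counts: list[int] | None = None,
                         median_active_counts: dict[int, float] | None = None,
                         variance_target: float = 0.95) -> int:
    """Heuristic for the number of dynamics operators.

    The starting point is twice the number of principal components needed to
    reach ``variance_target`` explained variance.  When fitted
    median-active-coefficient counts for candidate dictionary sizes are
    supplied, returns the smallest candidate whose median count equals that of
    the largest candidate (decreasing M further would start shrinking the
    number of concurrently active dynamics).
    """
    traces = np.asarray(traces, dtype=float)
    if traces.size == 0:
        raise ValueError("traces must be non-empty")
    if candidate_counts and median_active_counts is None:
        raise ValueError(
            "candidate_counts given without their fitted median_active_counts"
        )
    if candidate_counts:
        missing = [m for m in candidate_counts if m not in median_active_counts]
        if missing:
            raise ValueError(f"median_active_counts missing candidates {missing}")
        target = median_active_counts[max(candidate_counts)]
        eligible = [m for m in sorted(candidate_counts)
                    if np.isclose(median_active_counts[m], target)]
        return int(eligible[0])
    centered = traces - traces.mean(axis=1, keepdims=True)
    svals = np.linalg.svd(centered, compute_uv=False)
    var = svals ** 2
    if var.sum() == 0:
        raise ValueError("traces have zero variance")
    cum = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    return 2 * k


# ---------------------------------------------------------------------------
# recovery diagnostics
# ---------------------------------------------------------------------------

def align_latent_bases(D_learned: np.ndarray, D_true: np.ndarray) -> np.ndarray:
    """Least-squares change of basis R minimizing ``||D_learned R - D_true||_F``.

    The dLDS likelihood is invariant to any invertible change of latent basis
    (D -> DR with operators conjugated by R), so recovery of the operator
    dictionary is only defined after aligning the latent spaces of the learned
    and generating models.  The ambiguity is general linear, hence the
    pseudoinverse map rather than an orthogonal Procrustes rotation.
    """
    return np.linalg.pinv(np.asarray(D_learned, float)) @ np.asarray(D_true, float)


def operator_span_angles(ops_a: np.ndarray, ops_b: np.ndarray,
                         basis_change: np.ndarray | None = None) -> np.ndarray:
    """Principal angles (radians, descending) between vectorized operator spans.

    If ``basis_change`` is given, each operator in ``ops_a`` is first
    conjugated ``f -> R^-1 f R`` (the change of latent basis mapping the
    learned latent coordinates onto the generating ones, from
    :func:`align_latent_bases`).
    """
    ops_a = np.asarray(ops_a, dtype=float)
    ops_b = np.asarray(ops_b, dtype=float)
    if basis_change is not None:
        R = np.asarray(basis_change, dtype=float)
        Rinv = np.linalg.inv(R)
        ops_a = np.einsum("ij,mjk,kl->mil", Rinv, ops_a, R)
    A = ops_a.reshape(ops_a.shape[0], -1).T     # (p^2, M)
    B = ops_b.reshape(ops_b.shape[0], -1).T
    return scipy.linalg.subspace_angles(A, B)
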