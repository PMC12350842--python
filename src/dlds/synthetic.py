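"""Synthetic data generators.

Three families of inputs:

* :func:`simulate_duffing` — the discrete-time Duffing oscillator, a classic
  nonautonomous nonlinear system used to validate that the model separates
  linear and state-dependent components of the dynamics;
* :func:`generate_dlds_data` / :func:`generate_multi_subject` — data sampled
  from the dLDS generative model itself with known observation matrix,
  operator dictionary and sparse smooth coefficients (ground truth for
  recovery tests);
* :func:`generate_worm_fixture` — a worm-like labeled recording (~100 traces
  at 3 Hz) with behavior-state-driven coefficient motifs and a two-phase
  oxygen-like stimulus schedule.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import (
    DuffingParams,
    DuffingTrajectory,
    GroundTruth,
    NeuralRecording,
)

__all__ = [
    "simulate_duffing",
    "generate_dlds_data",
    "generate_multi_subject",
    "generate_worm_fixture",
]


def simulate_duffing(params: DuffingParams,
                     continuous_consistent: bool = False) -> DuffingTrajectory:
    """Iterate the discrete-time Duffing recursion.

    The default mode implements the discrete matrix recursion exactly as
    stated for the validation system:

        [x_{t+1}; y_{t+1}] = ([[1, dt], [-alpha*dt, 1]]
                              + [[0, 0], [-beta*x_t^2*dt, 0]]) [x_t; y_t]
                             + [0; gamma*cos(t)],

    i.e. an undamped iteration whose drive is ``gamma*cos(t)`` with t the
    integer step index.  The optional ``continuous_consistent`` mode is the
    full Euler discretization of the underlying second-order equation instead:
    it restores the damping term ``-delta*y*dt`` and uses the dt-scaled slow
    drive ``dt*gamma*cos(omega*t*dt)`` (off by default).

    Non-finite blow-up truncates the trajectory (remaining columns hold the
    last finite state) and sets ``truncated=True``.
    """
    a, b, g, d, w, dt = (params.alpha, params.beta, params.gamma,
                         params.delta, params.omega, params.dt)
    T = params.T
    states = np.zeros((2, T))
    states[:, 0] = (params.x0, params.y0)
    truncated = False
    # overflow on the way to a detected blow-up is expected and handled here
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(T - 1):
            x, y = states[:, t]
            x_next = x + dt * y
            if continuous_consistent:
                y_next = y + dt * (-a * x - b * x ** 3 - d * y
                                   + g * np.cos(w * t * dt))
            else:
                y_next = (-a * dt - b * x * x * dt) * x + y + g * np.cos(float(t))
            if not (np.isfinite(x_next) and np.isfinite(y_next)):
                warnings.warn(
                    f"Duffing iteration became non-finite at step {t + 1}; "
                    "truncating", RuntimeWarning,
                )
                states[:, t + 1:] = states[:, t:t + 1]
                truncated = True
                break
            states[0, t + 1] = x_next
            states[1, t + 1] = y_next
    return DuffingTrajectory(states=states, truncated=truncated, params=params)


# ---------------------------------------------------------------------------
# dLDS generative-model sampling
# ---------------------------------------------------------------------------

def _draw_observation(rng: np.random.Generator, n_traces: int, p: int,
                      baseline: float = 0.08) -> np.ndarray:
    """Nonnegative observation matrix with unit-norm columns.

    Each column is a sparse group of strongly co-active traces plus a small
    dense baseline loading (every trace carries some background activity),
    emulating how latent processes project onto overlapping neuron groups in
    nonnegative dF/F data.
    """
    D = baseline * np.abs(rng.standard_normal((n_traces, p)))
    participation = max(2, n_traces // 3)
    for j in range(p):
        members = rng.choice(n_traces, size=participation, replace=False)
        D[members, j] += np.abs(rng.standard_normal(participation))
    norms = np.linalg.norm(D, axis=0)
    return D / np.where(norms > 0, norms, 1.0)


def _draw_operators(rng: np.random.Generator, M: int, p: int,
                    strength: float = 0.6, density: float = 0.4) -> np.ndarray:
    """Unit-Frobenius operators: identity plus a sparse nonnegative interaction.

    Each operator is ``(I + strength * N_m)`` with ``N_m`` a sparse random
    nonnegative matrix, normalized to unit Frobenius norm.  Nonnegative
    operators preserve the positive orthant, so latent trajectories (and hence
    the nonnegative observations) stay sign-consistent the way dF/F activity
    does; the near-identity structure keeps consecutive states close (smooth
    calcium dynamics) while distinct interaction patterns keep the operators
    separable.
    """
    ops = np.zeros((M, p, p))
    eye = np.eye(p)
    for m in range(M):
        N = np.abs(rng.standard_normal((p, p))) * (rng.random((p, p)) < density)
        f = eye + strength * N
        ops[m] = f / np.linalg.norm(f)
    return ops


def _draw_coefficients(rng: np.random.Generator, M: int, T: int, k_active: int,
                       smoothness: float) -> np.ndarray:
    """Sparse, smoothly varying coefficients: at most k_active nonzero per t.

    The active support is a persistent random set (one member resampled with
    probability ``1 - smoothness`` per step); magnitudes follow a first-order
    autoregression with persistence ``smoothness``.
    """
    if k_active > M:
        raise ValueError("k_active must be <= M")
    C = np.zeros((M, T))
    support = list(rng.choice(M, size=k_active, replace=False))
    mags = 0.5 + 0.5 * rng.random(M)
    for t in range(T):
        if t > 0 and rng.random() > smoothness:
            leave = int(rng.integers(k_active))
            candidates = [m for m in range(M) if m not in support]
            if candidates:
                support[leave] = int(rng.choice(candidates))
        mags = smoothness * mags + (1.0 - smoothness) * (0.5 + 0.5 * rng.random(M))
        C[support, t] = mags[support]
    return C


def generate_dlds_data(p: int = 5, M: int = 5, T: int = 300, n_traces: int = 30,
                       k_active: int = 2, smoothness: float = 0.97,
                       noise_sd: float = 0.01, seed: int = 0,
                       ) -> tuple[NeuralRecording, GroundTruth]:
    """Sample a recording from the dLDS generative model with known parameters.

    Latent states propagate as ``x_t = sum_m c_mt f_m x_{t-1}`` with a
    per-step renormalization to the initial norm to prevent blow-up or decay;
    the rescaling is folded into the stored effective coefficients so that
    ``x_t = sum_m c_true[m, t] f_m x_{t-1}`` holds exactly.  Observations are
    ``y = D x + noise`` clipped at zero (dF/F is nonnegative); the clipped
    fraction is recorded in the ground truth.
    """
    rng = np.random.default_rng(seed)
    D = _draw_observation(rng, n_traces, p)
    ops = _draw_operators(rng, M, p)
    C_raw = _draw_coefficients(rng, M, T, k_active, smoothness)

    X = np.zeros((p, T))
    x = np.abs(rng.standard_normal(p)) + 0.5
    x /= np.linalg.norm(x)
    X[:, 0] = x
    target_norm = 1.0
    renorm = np.ones(T)
    C_eff = C_raw.copy()
    for t in range(1, T):
        F = np.tensordot(C_raw[:, t], ops, axes=1)
        x_raw = F @ X[:, t - 1]
        norm = np.linalg.norm(x_raw)
        if norm <= 1e-12:
            warnings.warn(f"latent trajectory collapsed at t={t}", RuntimeWarning)
            rho = 1.0
        else:
            rho = norm / target_norm
        renorm[t] = rho
        X[:, t] = x_raw / rho
        C_eff[:, t] = C_raw[:, t] / rho

    Y_clean = D @ X
    Y = Y_clean + noise_sd * rng.standard_normal(Y_clean.shape)
    clip_fraction = float(np.mean(Y < 0))
    Y = np.clip(Y, 0.0, None)

    recording = NeuralRecording(traces=Y, sampling_rate=1.0,
                                subject_id=f"synthetic_{seed}")
    truth = GroundTruth(D_true=D, operators_true=ops, x_true=X, c_true=C_eff,
                        noise_sd=noise_sd, seed=seed, renorm_factors=renorm,
                        clip_fraction=clip_fraction, y_unclipped=Y_clean)
    return recording, truth


def generate_multi_subject(n_subjects: int, p: int = 5, M: int = 5,
                           T: int | list[int] = 300,
                           n_traces: int | list[int] = 30,
                           k_active: int = 2, smoothness: float = 0.97,
                           noise_sd: float = 0.01, seed: int = 0,
                           ) -> list[tuple[NeuralRecording, GroundTruth]]:
    """Sample several subjects sharing one operator dictionary.

    Every subject receives the *same* dictionary object (shared ground truth)
    but an independent observation matrix, coefficient trajectory and duration.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    Ts = T if isinstance(T, (list, tuple)) else [T] * n_subjects
    ns = n_traces if isinstance(n_traces, (list, tuple)) else [n_traces] * n_subjects
    if len(Ts) != n_subjects or len(ns) != n_subjects:
        raise ValueError("per-subject T / n_traces lists must match n_subjects")

    rng = np.random.default_rng(seed)
    shared_ops = _draw_operators(rng, M, p)
    out: list[tuple[NeuralRecording, GroundTruth]] = []
    for s in range(n_subjects):
        sub_seed = int(rng.integers(2 ** 31 - 1))
        srng = np.random.default_rng(sub_seed)
        D = _draw_observation(srng, ns[s], p)
        C_raw = _draw_coefficients(srng, M, Ts[s], k_active, smoothness)
        X = np.zeros((p, Ts[s]))
        x = np.abs(srng.standard_normal(p)) + 0.5
        X[:, 0] = x / np.linalg.norm(x)
        renorm = np.ones(Ts[s])
        C_eff = C_raw.copy()
        for t in range(1, Ts[s]):
            F = np.tensordot(C_raw[:, t], shared_ops, axes=1)
            x_raw = F @ X[:, t - 1]
            rho = max(np.linalg.norm(x_raw), 1e-12)
            renorm[t] = rho
            X[:, t] = x_raw / rho
            C_eff[:, t] = C_raw[:, t] / rho
        Y_clean = D @ X
        Y = Y_clean + noise_sd * srng.standard_normal(Y_clean.shape)
        clip_fraction = float(np.mean(Y < 0))
        Y = np.clip(Y, 0.0, None)
        rec = NeuralRecording(traces=Y, sampling_rate=1.0, subject_id=f"worm_{s}")
        truth = GroundTruth(D_true=D, operators_true=shared_ops, x_true=X,
                            c_true=C_eff, noise_sd=noise_sd, seed=sub_seed,
                            renorm_factors=renorm, clip_fraction=clip_fraction,
                            y_unclipped=Y_clean)
        out.append((rec, truth))
    return out


# ---------------------------------------------------------------------------
# worm-like labeled fixture
# ---------------------------------------------------------------------------

_NEURON_NAMES = [
    "BAGL", "BAGR", "RMED", "RMEV", "AVAL", "AVAR", "AVBL", "AVBR",
    "AVFR", "RIS", "RIGL", "SABD", "SABVL", "SABVR", "RIFR", "AIBL",
    "AIBR", "RIML", "RIMR", "AVEL", "AVER", "SMDDL", "SMDDR", "SMDVL",
    "SMDVR", "RIVL", "RIVR", "OLQDL", "OLQDR", "URYDL", "URYDR", "ASKL",
    "ASKR", "AWCL", "AWCR", "VB01", "VB02", "DB01", "DB02", "AUAL",
]

_BEHAVIOR_NAMES = {1: "FWD", 2: "REV", 3: "REVSUS", 4: "TURN"}


def generate_worm_fixture(seed: int = 0, n_traces: int = 100, T: int = 3000,
                          sampling_rate: float = 3.0, p: int = 6, M: int = 8,
                          n_labeled: int = 40, noise_sd: float = 0.02,
                          ) -> tuple[NeuralRecording, GroundTruth]:
    """A worm-like labeled recording with behavior-driven coefficient motifs.

    Emulates the shape of whole-brain *C. elegans* datasets: ~100 traces at
    3 Hz, ~40 of them labeled with neuron names (some traces carry multiple
    names, some names label multiple traces), a 4-state behavior sequence
    (FWD/REV/REVSUS/TURN) evolving as a sticky Markov chain, and a two-phase
    stimulus schedule — constant 21% oxygen in the first half, 21%/4%
    alternating every 30 s from the midpoint on.

    Each behavior state drives a distinct sparse motif of dynamics
    coefficients, so the state sequence is linearly decodable from the
    ground-truth coefficients.
    """
    rng = np.random.default_rng(seed)

    # sticky Markov behavior chain over 4 states, mean dwell ~ 15 s at 3 Hz
    n_states = 4
    stay = 1.0 - 1.0 / (15.0 * sampling_rate)
    behavior = np.zeros(T, dtype=int)
    state = 1
    for t in range(T):
        behavior[t] = state
        if rng.random() > stay:
            state = int(rng.choice([s for s in range(1, n_states + 1) if s != state]))

    # per-state coefficient motifs: distinct supports of size 2 out of M
    motifs = np.zeros((n_states + 1, M))
    for s in range(1, n_states + 1):
        idx = [(2 * (s - 1)) % M, (2 * (s - 1) + 1) % M]
        motifs[s, idx] = 1.0

    ops = _draw_operators(rng, M, p)
    D = _draw_observation(rng, n_traces, p)

    C_raw = np.zeros((M, T))
    mags = 0.6 + 0.4 * rng.random(M)
    smooth = 0.9
    for t in range(T):
        mags = smooth * mags + (1 - smooth) * (0.6 + 0.4 * rng.random(M))
        C_raw[:, t] = motifs[behavior[t]] * mags

    X = np.zeros((p, T))
    x = np.abs(rng.standard_normal(p)) + 0.5
    X[:, 0] = x / np.linalg.norm(x)
    renorm = np.ones(T)
    C_eff = C_raw.copy()
    for t in range(1, T):
        F = np.tensordot(C_raw[:, t], ops, axes=1)
        x_raw = F @ X[:, t - 1]
        rho = max(np.linalg.norm(x_raw), 1e-12)
        renorm[t] = rho
        X[:, t] = x_raw / rho
        C_eff[:, t] = C_raw[:, t] / rho

    Y_clean = D @ X
    Y = Y_clean + noise_sd * rng.standard_normal(Y_clean.shape)
    clip_fraction = float(np.mean(Y < 0))
    Y = np.clip(Y, 0.0, None)

    # stimulus: constant 21% first half; alternating 21/4 every 30 s after
    midpoint = T // 2
    switch = int(round(30.0 * sampling_rate))
    stimulus = np.full(T, 21.0)
    phase = np.zeros(T, dtype=int)
    phase[midpoint:] = 1
    level = 4.0
    for start in range(midpoint, T, switch):
        stimulus[start:start + switch] = level
        level = 21.0 if level == 4.0 else 4.0

    # labels: first n_labeled traces get names; a few carry two names and a
    # few names repeat across traces
    labels: list[list[str]] = [[] for _ in range(n_traces)]
    for i in range(min(n_labeled, n_traces)):
        labels[i] = [_NEURON_NAMES[i % len(_NEURON_NAMES)]]
    for i in range(0, min(6, n_traces), 2):        # multi-name traces
        labels[i].append(_NEURON_NAMES[(i + 20) % len(_NEURON_NAMES)])
    if n_labeled + 2 < n_traces:                   # duplicated names
        labels[n_labeled] = [_NEURON_NAMES[0]]
        labels[n_labeled + 1] = [_NEURON_NAMES[2]]

    recording = NeuralRecording(
        traces=Y, sampling_rate=sampling_rate, trace_labels=labels,
        behavior=behavior, behavior_names=dict(_BEHAVIOR_NAMES),
        stimulus=stimulus, stimulus_phase=phase,
        subject_id=f"fixture_worm_{seed}",
    )
    truth = GroundTruth(D_true=D, operators_true=ops, x_true=X, c_true=C_eff,
                        noise_sd=noise_sd, seed=seed, renorm_factors=renorm,
                        clip_fraction=clip_fraction, y_unclipped=Y_clean)
    return recording, truth
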