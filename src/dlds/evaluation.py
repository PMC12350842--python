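"""Categorical analyses and decoding harness over model outputs.

Reconstructed activity and connectivity series are binarized at a weak
(median) or strong (median + 3 SD) threshold and tested against categorical
factors (behavior state, stimulation phase) with Pearson chi-squared tests
under a Bonferroni-adjusted alpha.  Behavior, stimulation half, and speed
class can be decoded from coefficients, latent states, or coefficient
derivatives with an off-the-shelf linear classifier.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .connectivity import instantaneous_connectivity
from .datatypes import BinarizedSeries, CoefficientTrajectory, DLDSModel, LatentTrajectory
from .model import reconstruct

__all__ = [
    "binarize",
    "contingency_and_chi2",
    "bonferroni_alpha",
    "decode",
    "activity_and_connectivity_series",
    "categorical_test_table",
    "manova_design",
]


def binarize(series: np.ndarray, kind: str = "weak") -> BinarizedSeries:
    """Threshold a series into on/off at the weak (median) or strong
    (median + 3 SD) level.  Strictly above the threshold counts as active.

    A zero-variance series under the strong rule is all-inactive and flagged
    ``degenerate``.
    """
    series = np.asarray(series, dtype=float).ravel()
    if series.size < 2:
        raise ValueError("series must have length >= 2")
    med = float(np.median(series))
    if kind == "weak":
        thr = med
        degenerate = False
    elif kind == "strong":
        sd = float(np.std(series))
        thr = med + 3.0 * sd
        degenerate = sd == 0.0
        if degenerate:
            warnings.warn("zero-variance series under the strong threshold",
                          RuntimeWarning)
    else:
        raise ValueError("kind must be 'weak' or 'strong'")
    return BinarizedSeries(values=series > thr, threshold_kind=kind,
                           threshold_value=thr, degenerate=degenerate)


def contingency_and_chi2(binary, category,
                         on_zero_expected: str = "error",
                         ) -> tuple[pd.DataFrame, float, int]:
    """Activity x category contingency table with its Pearson chi-squared test.

    Returns ``(table, statistic, dof)``.  Categories producing a zero expected
    count are either dropped (``on_zero_expected='drop'``) or raise.
    """
    values = binary.values if isinstance(binary, BinarizedSeries) else np.asarray(binary)
    category = np.asarray(category)
    if values.shape[0] != category.shape[0]:
        raise ValueError("binary series and category labels must share length")
    table = pd.crosstab(pd.Series(values, name="active"),
                        pd.Series(category, name="category"))
    arr = table.to_numpy(dtype=float)
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    bad_cols = np.flatnonzero((expected == 0).any(axis=0))
    if bad_cols.size:
        if on_zero_expected == "drop":
            table = table.drop(columns=table.columns[bad_cols])
            arr = table.to_numpy(dtype=float)
        else:
            raise ValueError(
                f"categories {list(table.columns[bad_cols])} have zero expected "
                "counts (pass on_zero_expected='drop' to merge them away)")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table is degenerate (needs >= 2x2)")
    stat, _, dof, _ = scipy.stats.chi2_contingency(arr, correction=False)
    return table, float(stat), int(dof)


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Family-wise-corrected per-test alpha: ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def decode(features: np.ndarray, labels: np.ndarray, scheme: str = "svm",
           folds: int = 5, seed: int = 0,
           ) -> tuple[float, np.ndarray, float]:
    """Cross-validated decoding of per-timepoint labels from model features.

    ``features`` is ``(n_features, T)`` — coefficient, latent-state, or
    dc/dt matrices in their native orientation.  Uses a standard linear
    classifier (linear SVM, LDA, or logistic regression) with stratified
    k-fold splits; classification operates on individual timepoints.

    Returns ``(mean accuracy, confusion matrix, majority-class base rate)``.
    """
    F = features.c if isinstance(features, CoefficientTrajectory) else features
    F = F.x if isinstance(F, LatentTrajectory) else np.asarray(F, dtype=float)
    labels = np.asarray(labels)
    if F.ndim != 2:
        raise ValueError("features must be 2-D (n_features, T)")
    X = F.T
    if X.shape[0] != labels.shape[0]:
        raise ValueError("features and labels must align over time")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("decoding requires at least two label classes")
    base_rate = float(counts.max() / counts.sum())

    if scheme == "svm":
        from sklearn.svm import LinearSVC
        clf = LinearSVC(random_state=seed)
    elif scheme == "lda":
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        clf = LinearDiscriminantAnalysis()
    elif scheme == "logistic":
        from sklearn.linear_model import LogisticRegression
        clf = LogisticRegression(max_iter=2000, random_state=seed)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    pipe = make_pipeline(StandardScaler(), clf)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(pipe, X, labels, cv=cv)
    acc = float(np.mean(pred == labels))
    cm = confusion_matrix(labels, pred, labels=classes)
    return acc, cm, base_rate


def activity_and_connectivity_series(model: DLDSModel, x, c, trace_index: int,
                                     reduce: str | None = None,
                                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-timepoint activity and incoming/outgoing connectivity of one trace.

    Returns ``(activity, conn_to, conn_from)`` where ``activity`` is the
    reconstructed trace (length T) and ``conn_to`` / ``conn_from`` are the
    column / row slices of the instantaneous connectivity map at each t —
    ``(n_traces, T)`` matrices, or length-T sums when ``reduce='sum'``.  These
    series feed :func:`binarize` / :func:`contingency_and_chi2` and external
    ANOVA/MANOVA calls.
    """
    X = x.x if isinstance(x, LatentTrajectory) else np.asarray(x, dtype=float)
    C = c.c if isinstance(c, CoefficientTrajectory) else np.asarray(c, dtype=float)
    n = model.n_traces
    if not (0 <= trace_index < n):
        raise IndexError(f"trace index {trace_index} out of range for {n} traces")
    T = C.shape[1]
    y_hat, _ = reconstruct(model.D, X)
    activity = y_hat[trace_index]
    conn_to = np.zeros((n, T))
    conn_from = np.zeros((n, T))
    for t in range(T):
        W = instantaneous_connectivity(model, C, t).weights
        conn_to[:, t] = W[:, trace_index]
        conn_from[:, t] = W[trace_index, :]
    if reduce == "sum":
        return activity, conn_to.sum(axis=0), conn_from.sum(axis=0)
    if reduce is not None:
        raise ValueError("reduce must be None or 'sum'")
    return activity, conn_to, conn_from


def categorical_test_table(series_by_name: dict[str, np.ndarray],
                           factors: dict[str, np.ndarray],
                           alpha: float = 0.05,
                           path=None) -> pd.DataFrame:
    """Tidy chi-squared results: one row per series x factor x threshold level.

    Each named series (a neuron's reconstructed activity, or its summed
    incoming/outgoing connectivity) is binarized at both the weak and strong
    thresholds and tested against every categorical factor.  The table
    reports the statistic, degrees of freedom, p-value, and both the raw and
    Bonferroni-adjusted significance (the correction counts all tests in the
    table).  Written as TSV when ``path`` is given.
    """
    rows = []
    n_tests = len(series_by_name) * len(factors) * 2
    adj_alpha = bonferroni_alpha(alpha, max(n_tests, 1))
    for name, series in series_by_name.items():
        for kind in ("weak", "strong"):
            binary = binarize(series, kind)
            for factor_name, labels in factors.items():
                if binary.degenerate or binary.values.all() or \
                        not binary.values.any():
                    rows.append({"series": name, "factor": factor_name,
                                 "threshold": kind, "statistic": np.nan,
                                 "dof": 0, "p_value": np.nan,
                                 "significant_raw": False,
                                 "significant_bonferroni": False})
                    continue
                _, stat, dof = contingency_and_chi2(binary, labels)
                p = float(scipy.stats.chi2.sf(stat, dof))
                rows.append({"series": name, "factor": factor_name,
                             "threshold": kind, "statistic": stat,
                             "dof": dof, "p_value": p,
                             "significant_raw": p < alpha,
                             "significant_bonferroni": p < adj_alpha})
    table = pd.DataFrame(rows)
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table


def manova_design(activity: np.ndarray, behavior: np.ndarray,
                  stimulus_phase: np.ndarray) -> pd.DataFrame:
    """Tidy design frame for external ANOVA/MANOVA routines.

    One row per timepoint with the response and categorical factors
    (behavior, stimulation phase, and their interaction); statistical
    routines (e.g. statsmodels MANOVA with Roy's largest root) consume this
    directly.
    """
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    T = activity.shape[1]
    behavior = np.asarray(behavior)
    stimulus_phase = np.asarray(stimulus_phase)
    if behavior.shape[0] != T or stimulus_phase.shape[0] != T:
        raise ValueError("factors must align with the response over time")
    df = pd.DataFrame({f"response_{i}": activity[i] for i in range(activity.shape[0])})
    df["behavior"] = pd.Categorical(behavior)
    df["stimulation"] = pd.Categorical(stimulus_phase)
    df["interaction"] = pd.Categorical(
        [f"{b}|{s}" for b, s in zip(behavior, stimulus_phase)])
    return df
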