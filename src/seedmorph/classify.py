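"""Linear discriminant classification with class-balanced resampling.

The benchmark protocol: classes over-represented in the reference set are
randomly subsampled to a common size, leave-one-out cross-validated LDA
accuracy is recorded per class, and the whole procedure is repeated over
many resampling permutations so each accuracy comes with a distribution.
A shuffled-label run of the same machinery provides the chance ceiling
(the maximum class accuracy obtainable from label noise alone).  Unknown
specimens are assigned by majority vote of per-permutation LDA predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LDAModel",
    "BenchmarkReport",
    "AssignmentResult",
    "FEATURE_SETS",
    "feature_columns",
    "lda_fit",
    "lda_predict",
    "loocv_accuracy",
    "balanced_benchmark",
    "shuffled_label_baseline",
    "assign_unknowns",
]

_RIDGE_REL = 1e-8

# canonical descriptor combinations benchmarked against each other;
# "shape" expands to whatever coefficient columns the table carries
FEATURE_SETS = {
    "cells": ["cells"],
    "size": ["log_length", "log_width"],
    "shape": ["shape"],
    "size+cells": ["log_length", "log_width", "cells"],
    "all": ["log_length", "log_width", "cells", "shape"],
}


def feature_columns(df: pd.DataFrame, feature_set: str) -> list:
    """Resolve a feature-set name to concrete columns of ``df``."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; "
                         f"choose from {sorted(FEATURE_SETS)}")
    cols: list = []
    shape_cols = [c for c in df.columns
                  if c[:1] in "abcd" and c[1:].isdigit()]
    for c in FEATURE_SETS[feature_set]:
        if c == "shape":
            if not shape_cols:
                raise ValueError("no shape coefficient columns in table")
            cols.extend(shape_cols)
        else:
            if c not in df.columns:
                raise ValueError(f"missing feature column {c!r}")
            cols.append(c)
    return cols


# ---------------------------------------------------------------------------
# LDA

@dataclass
class LDAModel:
    """Gaussian linear discriminant model with shared covariance."""

    classes: np.ndarray
    class_means: np.ndarray      # (g, p)
    pooled_cov: np.ndarray       # (p, p)
    priors: np.ndarray           # (g,)
    _cov_inv: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self._cov_inv is None:
            self._cov_inv = _safe_inv(self.pooled_cov)


def _safe_inv(cov: np.ndarray) -> np.ndarray:
    """Invert a covariance, ridge-regularizing if singular."""
    try:
        np.linalg.cholesky(cov)
        return np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        p = cov.shape[0]
        eps = _RIDGE_REL * np.trace(cov) / p
        if eps <= 0:
            eps = _RIDGE_REL
        warnings.warn(
            f"singular pooled covariance; adding ridge {eps:.3g}",
            RuntimeWarning)
        return np.linalg.inv(cov + eps * np.eye(p))


def lda_fit(X, y, priors=None) -> LDAModel:
    """Fit LDA: per-class means plus a pooled within-class covariance.

    ``priors`` defaults to equal across classes (the benchmark balances
    classes by construction); pass "proportional" for empirical priors or
    an explicit vector.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    classes, inv = np.unique(y, return_inverse=True)
    g = len(classes)
    if g < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 rows")
    n, p = X.shape
    means = np.vstack([X[inv == k].mean(axis=0) for k in range(g)])
    W = np.zeros((p, p))
    for k in range(g):
        d = X[inv == k] - means[k]
        W += d.T @ d
    pooled = W / (n - g)
    if priors is None:
        pr = np.full(g, 1.0 / g)
    elif isinstance(priors, str) and priors == "proportional":
        pr = counts / n
    else:
        pr = np.asarray(priors, dtype=float)
        if len(pr) != g or not np.isclose(pr.sum(), 1.0):
            raise ValueError("priors must be one per class and sum to 1")
    return LDAModel(classes=classes, class_means=means, pooled_cov=pooled,
                    priors=pr)


def _discriminants(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Log discriminant scores delta_k(x), up to a shared constant."""
    Si = model._cov_inv
    A = model.class_means @ Si                     # (g, p)
    const = -0.5 * np.einsum("kp,kp->k", A, model.class_means) \
        + np.log(model.priors)
    return X @ A.T + const


def lda_predict(model: LDAModel, X_new):
    """Predict labels and posterior probabilities for new rows."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[:, None]
    if X_new.shape[1] != model.class_means.shape[1]:
        raise ValueError("feature count mismatch with the fitted model")
    delta = _discriminants(model, X_new)
    delta = delta - delta.max(axis=1, keepdims=True)
    post = np.exp(delta)
    post /= post.sum(axis=1, keepdims=True)
    labels = model.classes[np.argmax(delta, axis=1)]
    return labels, post


def loocv_accuracy(X, y, priors=None) -> pd.Series:
    """Per-class leave-one-out cross-validated LDA accuracy.

    Each row is predicted from a model refit without it; the refit reuses
    the full-data class sums and within-class scatter through a rank-one
    downdate rather than recomputing them from scratch.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    classes, inv = np.unique(y, return_inverse=True)
    g = len(classes)
    if g < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 rows")
    n, p = X.shape
    if priors is None:
        pr = np.full(g, 1.0 / g)
    elif isinstance(priors, str) and priors == "proportional":
        pr = counts / n
    else:
        pr = np.asarray(priors, dtype=float)
    sums = np.vstack([X[inv == k].sum(axis=0) for k in range(g)])
    means = sums / counts[:, None]
    W = np.zeros((p, p))
    for k in range(g):
        d = X[inv == k] - means[k]
        W += d.T @ d
    log_pr = np.log(pr)
    correct = np.zeros(g, dtype=int)
    for i in range(n):
        k = inv[i]
        x = X[i]
        nk = counts[k]
        mean_k = (sums[k] - x) / (nk - 1)
        v = x - means[k]
        Wd = W - (nk / (nk - 1)) * np.outer(v, v)
        cov = Wd / (n - 1 - g)
        means_i = means.copy()
        means_i[k] = mean_k
        try:
            Si_mu = np.linalg.solve(cov, means_i.T).T        # (g, p)
        except np.linalg.LinAlgError:
            Si = _safe_inv(cov)
            Si_mu = means_i @ Si
        delta = Si_mu @ x - 0.5 * np.einsum(
            "kp,kp->k", Si_mu, means_i) + log_pr
        if np.argmax(delta) == k:
            correct[k] += 1
    return pd.Series(correct / counts, index=classes, name="accuracy")


# ---------------------------------------------------------------------------
# balanced resampling benchmark

@dataclass
class BenchmarkReport:
    """Accuracy distributions of one feature set over balanced resamples."""

    feature_set: str
    per_class_accuracy: pd.DataFrame     # columns: class, perm, accuracy
    n_perm: int
    baseline_max_accuracy: float | None = None

    def summary(self) -> pd.DataFrame:
        return (self.per_class_accuracy.groupby("class")["accuracy"]
                .agg(["mean", "std"]).reset_index()
                .assign(feature_set=self.feature_set))


def _balanced_indices(inv: np.ndarray, g: int, n_per_class: int,
                      rng: np.random.Generator) -> np.ndarray:
    idx = []
    for k in range(g):
        rows = np.nonzero(inv == k)[0]
        if len(rows) > n_per_class:
            rows = rng.choice(rows, n_per_class, replace=False)
        idx.append(rows)
    return np.concatenate(idx)


def balanced_benchmark(df: pd.DataFrame, feature_sets,
                       n_per_class: int = 30, n_perm: int = 1000,
                       seed: int | None = None,
                       label_col: str = "taxon") -> dict:
    """Class-balanced repeated LOOCV benchmark per feature set.

    Per permutation, every class larger than ``n_per_class`` is subsampled
    to that size (smaller classes enter whole); per-class LOOCV accuracy is
    recorded for each requested feature set on the same subsample, so
    feature sets are compared on identical data.  Returns
    {feature_set: BenchmarkReport}.
    """
    labels = df[label_col].to_numpy()
    classes, inv = np.unique(labels, return_inverse=True)
    g = len(classes)
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 rows")
    feats = {fs: df[feature_columns(df, fs)].to_numpy(float)
             for fs in feature_sets}
    rng = np.random.default_rng(seed)
    rows: dict = {fs: [] for fs in feature_sets}
    for perm in range(n_perm):
        sel = _balanced_indices(inv, g, n_per_class, rng)
        y_sel = labels[sel]
        for fs in feature_sets:
            acc = loocv_accuracy(feats[fs][sel], y_sel)
            for cls, a in acc.items():
                rows[fs].append({"class": cls, "perm": perm, "accuracy": a})
    return {fs: BenchmarkReport(feature_set=fs,
                                per_class_accuracy=pd.DataFrame(rows[fs]),
                                n_perm=n_perm)
            for fs in feature_sets}


def shuffled_label_baseline(df: pd.DataFrame, feature_set: str,
                            n_per_class: int = 30, n_perm: int = 100,
                            seed: int | None = None,
                            label_col: str = "taxon"):
    """Chance ceiling: LOOCV accuracy after shuffling labels.

    Labels are permuted within each balanced subsample before LOOCV; the
    maximum per-class accuracy observed across permutations is the ceiling
    attributable to chance (its distribution follows the extremes of a
    multinomial draw).  Returns (max_accuracy, per-permutation DataFrame).
    """
    labels = df[label_col].to_numpy()
    classes, inv = np.unique(labels, return_inverse=True)
    g = len(classes)
    X = df[feature_columns(df, feature_set)].to_numpy(float)
    rng = np.random.default_rng(seed)
    rows = []
    for perm in range(n_perm):
        sel = _balanced_indices(inv, g, n_per_class, rng)
        y_shuf = rng.permutation(labels[sel])
        if len(np.unique(y_shuf)) < 2 or np.bincount(
                np.unique(y_shuf, return_inverse=True)[1]).min() < 2:
            continue
        acc = loocv_accuracy(X[sel], y_shuf)
        for cls, a in acc.items():
            rows.append({"class": cls, "perm": perm, "accuracy": a})
    frame = pd.DataFrame(rows)
    return float(frame["accuracy"].max()), frame


# ---------------------------------------------------------------------------
# assignment of unknowns

@dataclass
class AssignmentResult:
    """Majority-vote classification of one unknown specimen."""

    seed_id: str
    votes: dict
    predicted: str
    vote_share: float
    ambiguous: bool


def assign_unknowns(df_known: pd.DataFrame, df_unknown: pd.DataFrame,
                    feature_set: str, n_per_class: int = 30,
                    n_perm: int = 100, seed: int | None = None,
                    label_col: str = "taxon"):
    """Assign unknown specimens by majority vote over balanced LDA fits.

    Per permutation, an LDA is trained on a balanced subsample of the known
    records and every unknown is predicted; the modal class over the
    permutations is the assignment.  Vote ties set ``ambiguous`` and report
    the lexicographically first tied class.  Returns (list of
    AssignmentResult, composition Series counting predicted classes).
    """
    cols = feature_columns(df_known, feature_set)
    missing = [c for c in cols if c not in df_unknown.columns]
    if missing:
        raise ValueError(f"unknown records miss feature columns {missing}")
    labels = df_known[label_col].to_numpy()
    classes, inv = np.unique(labels, return_inverse=True)
    g = len(classes)
    Xk = df_known[cols].to_numpy(float)
    Xu = df_unknown[cols].to_numpy(float)
    ids = df_unknown["id"].astype(str).tolist() if "id" in df_unknown \
        else [str(i) for i in df_unknown.index]
    rng = np.random.default_rng(seed)
    votes = np.zeros((len(Xu), g), dtype=int)
    for _ in range(n_perm):
        sel = _balanced_indices(inv, g, n_per_class, rng)
        model = lda_fit(Xk[sel], labels[sel])
        pred, _ = lda_predict(model, Xu)
        for j, cls in enumerate(model.classes):
            votes[:, list(classes).index(cls)] += (pred == cls)
    results = []
    for i, sid in enumerate(ids):
        v = votes[i]
        top = v.max()
        winners = [classes[j] for j in range(g) if v[j] == top]
        results.append(AssignmentResult(
            seed_id=sid,
            votes={str(classes[j]): int(v[j]) for j in range(g)},
            predicted=str(sorted(winners)[0]),
            vote_share=float(top / n_perm),
            ambiguous=len(winners) > 1))
    composition = pd.Series(
        [r.predicted for r in results]).value_counts().sort_index()
    composition.name = "n_assigned"
    return results, composition
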