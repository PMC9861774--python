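"""Stability-based feature (SNP) signature selection.

Features are ranked per cross-validation fold by the absolute point-biserial
(Pearson) correlation between their values and the binary outcome; the
ranking's top-k is recorded for every fold of every repetition, and the
signature keeps the features whose relative selection frequency reaches
``f_min``.  Repeating a 10-fold split many times makes the selection robust
to how the samples happen to be partitioned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


@dataclass
class SelectionParams:
    """Knobs of the repeated-CV stability selection.

    ``k`` (top-f) is the number of top-ranked features recorded per fold,
    ``f_min`` (min-fr) the minimum relative selection frequency for a
    feature to enter the signature; the frequency denominator is
    ``n_folds * n_repeats`` fold-instances.
    """

    k: int = 500
    f_min: float = 0.1
    n_folds: int = 10
    n_repeats: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.f_min <= 1:
            raise ValueError("f_min must be in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class StabilityResult:
    """Per-feature selection frequencies and the thresholded signature."""

    frequencies: pd.Series  # feature id -> selection frequency in [0, 1]
    signature: list  # feature ids with frequency >= f_min (frequency order)
    mean_abs_corr: pd.Series  # feature id -> mean |r| over fold-instances
    params: SelectionParams


def point_biserial(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of ``X`` with the 0/1 vector ``y``.

    Constant columns get correlation 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be (n, p) and y length n")
    yc = y - y.mean()
    ssy = float(yc @ yc)
    Xc = X - X.mean(axis=0)
    ssx = (Xc**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / np.sqrt(ssx * ssy)
    r[~np.isfinite(r)] = 0.0
    return r


def rank_features(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Feature order by decreasing |point-biserial correlation|.

    Ties (including the constant-column r=0 case) break by feature index so
    the ranking is deterministic.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    r = point_biserial(X, y)
    return np.lexsort((np.arange(X.shape[1]), -np.abs(r)))


def stability_select(
    X,
    y,
    params: SelectionParams,
    feature_ids=None,
) -> StabilityResult:
    """Repeated stratified-CV stability selection.

    For each of ``n_repeats`` repetitions the samples are shuffled into
    ``n_folds`` outcome-stratified folds; features are ranked on each fold's
    training portion and its top-k recorded.  frequency(feature) =
    (#fold-instances with the feature in the top-k) / (n_folds * n_repeats).
    """
    params.validate()
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.columns) if feature_ids is None else list(feature_ids)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if feature_ids is None:
        feature_ids = list(range(p))
    if len(feature_ids) != p:
        raise ValueError("feature_ids length must match number of columns")
    if n < params.n_folds:
        raise ValueError("need at least n_folds samples")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    k = params.k
    if k >= p:
        warnings.warn(
            f"k={k} >= {p} features: every feature is selected in every fold",
            stacklevel=2,
        )
        k = p

    counts = np.zeros(p, dtype=int)
    corr_sums = np.zeros(p)
    ss = np.random.SeedSequence(params.seed)
    repeat_seeds = ss.generate_state(params.n_repeats)
    _, y01 = np.unique(y, return_inverse=True)  # two classes -> 0/1
    for rep in range(params.n_repeats):
        skf = StratifiedKFold(
            n_splits=params.n_folds,
            shuffle=True,
            random_state=int(repeat_seeds[rep] % (2**31)),
        )
        for train_idx, _ in skf.split(X, y01):
            r = point_biserial(X[train_idx], np.asarray(y01)[train_idx])
            order = np.lexsort((np.arange(p), -np.abs(r)))
            top = order[:k]
            counts[top] += 1
            corr_sums += np.abs(r)
    denom = params.n_folds * params.n_repeats
    freq = counts / denom
    feature_index = pd.Index(feature_ids, name="feature")
    frequencies = pd.Series(freq, index=feature_index)
    mean_abs_corr = pd.Series(corr_sums / denom, index=feature_index)
    selected = np.flatnonzero(freq >= params.f_min - 1e-12)
    # report the signature in decreasing frequency (ties by feature order)
    selected = selected[np.lexsort((selected, -freq[selected]))]
    signature = [feature_ids[i] for i in selected]
    return StabilityResult(
        frequencies=frequencies,
        signature=signature,
        mean_abs_corr=mean_abs_corr,
        params=params,
    )
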