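"""Random forests with a view tag per tree, and validation-set model search.

The forest is assembled tree by tree: each decision tree is trained on its
own bootstrap sample drawn from a single view (the genetic dosage block or
the clinical block), and the consensus prediction is the unweighted mean of
the per-tree class-1 (EDA) probabilities across all trees.  A single-view
forest is simply the degenerate allocation.  Hyper-parameters follow the
conventions of the classical randomForest implementation: ``ntree`` trees,
``maxn`` maximum terminal nodes per tree, ``nodesize`` minimum samples per
leaf, ``mtry`` features tried per split (default floor(sqrt(p))).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .evaluate import MetricsReport, evaluate_scores


@dataclass
class RFParams:
    ntree: int = 100
    maxn: int | None = None  # maximum terminal nodes per tree (None: unlimited)
    nodesize: int = 1  # minimum samples per leaf
    mtry: int | None = None  # features tried per split (None: floor(sqrt(p)))
    seed: int = 0

    def validate(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.maxn is not None and self.maxn < 1:
            raise ValueError("maxn must be >= 1")
        if self.nodesize < 1:
            raise ValueError("nodesize must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


def impute_mode(X: pd.DataFrame) -> pd.DataFrame:
    """Per-column mode imputation for dosage frames (ties: lower dosage)."""
    X = X.copy()
    for col in X.columns:
        vals = X[col]
        if vals.isna().any():
            counts = vals.value_counts()
            if counts.empty:
                fill = 0.0
            else:
                top = counts[counts == counts.max()]
                fill = min(top.index)
            X[col] = vals.fillna(fill)
    return X


class _ConstantTree:
    """Single-node tree: predicts the bootstrap class-1 frequency."""

    def __init__(self, p1: float):
        self.p1 = float(p1)

    def predict_p1(self, X: np.ndarray) -> np.ndarray:
        return np.full(X.shape[0], self.p1)


class _FittedTree:
    """A sklearn decision tree plus its class bookkeeping."""

    def __init__(self, tree: DecisionTreeClassifier):
        self.tree = tree

    def predict_p1(self, X: np.ndarray) -> np.ndarray:
        proba = self.tree.predict_proba(X)
        classes = list(self.tree.classes_)
        if 1 in classes:
            return proba[:, classes.index(1)]
        return np.zeros(X.shape[0])


class MultiViewRandomForest:
    """Forest whose trees each see exactly one feature view.

    ``view_allocation`` maps view name -> fraction of the ``ntree`` trees;
    fractions must sum to 1.  Consensus prediction is the unweighted mean of
    per-tree class-1 probabilities over all trees, regardless of view.
    """

    def __init__(self, params: RFParams, view_allocation: dict[str, float]):
        params.validate()
        if abs(sum(view_allocation.values()) - 1.0) > 1e-9:
            raise ValueError("view allocation fractions must sum to 1")
        if any(f < 0 for f in view_allocation.values()):
            raise ValueError("view allocation fractions must be non-negative")
        self.params = params
        self.view_allocation = dict(view_allocation)
        self.trees_: list[tuple[str, object]] = []
        self.feature_names_: dict[str, list] = {}

    def _tree_views(self) -> list[str]:
        views = list(self.view_allocation)
        counts = []
        remaining = self.params.ntree
        for i, v in enumerate(views):
            if i == len(views) - 1:
                counts.append(remaining)
            else:
                c = round(self.params.ntree * self.view_allocation[v])
                c = min(c, remaining)
                counts.append(c)
                remaining -= c
        return [v for v, c in zip(views, counts) for _ in range(c)]

    def fit(self, views: dict[str, pd.DataFrame], y) -> "MultiViewRandomForest":
        y = np.asarray(y)
        if set(views) != set(self.view_allocation):
            raise ValueError("views do not match the allocation keys")
        lengths = {v: len(X) for v, X in views.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"views are not row-aligned: {lengths}")
        indexes = [
            tuple(X.index) for X in views.values() if isinstance(X, pd.DataFrame)
        ]
        if indexes and len(set(indexes)) != 1:
            raise ValueError("view row indexes (sample ids) are misaligned")
        n = len(y)
        if lengths.popitem()[1] != n:
            raise ValueError("y length does not match the views")
        if len(np.unique(y)) < 2:
            raise ValueError("y must contain both classes")

        mats = {}
        for v, X in views.items():
            arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else (
                np.asarray(X, dtype=float)
            )
            if np.isnan(arr).any():
                raise ValueError(
                    f"view {v!r} contains missing values; impute upstream"
                )
            mats[v] = arr
            self.feature_names_[v] = (
                list(X.columns)
                if isinstance(X, pd.DataFrame)
                else list(range(arr.shape[1]))
            )

        p = self.params
        tree_seeds = np.random.SeedSequence(p.seed).spawn(p.ntree)
        self.trees_ = []
        for view, seed in zip(self._tree_views(), tree_seeds):
            rng = np.random.default_rng(seed)
            boot = rng.integers(0, n, size=n)
            Xb, yb = mats[view][boot], y[boot]
            if p.maxn == 1 or len(np.unique(yb)) < 2:
                fitted: object = _ConstantTree(float(np.mean(yb == 1)))
            else:
                mtry = p.mtry
                if mtry is None:
                    mtry = max(1, math.floor(math.sqrt(Xb.shape[1])))
                tree = DecisionTreeClassifier(
                    max_leaf_nodes=p.maxn,
                    min_samples_leaf=p.nodesize,
                    max_features=min(mtry, Xb.shape[1]),
                    random_state=int(rng.integers(2**31)),
                )
                tree.fit(Xb, yb)
                fitted = _FittedTree(tree)
            self.trees_.append((view, fitted))
        return self

    def _view_arrays(self, views: dict) -> dict[str, np.ndarray]:
        mats = {}
        for v, names in self.feature_names_.items():
            if v not in views:
                raise ValueError(f"missing view {v!r} at prediction time")
            X = views[v]
            if isinstance(X, pd.DataFrame):
                absent = [c for c in names if c not in X.columns]
                if absent:
                    raise KeyError(f"view {v!r} missing features: {absent[:10]}")
                X = X[names].to_numpy(dtype=float)
            else:
                X = np.asarray(X, dtype=float)
            if X.shape[1] != len(names):
                raise ValueError(f"view {v!r} has wrong number of features")
            if np.isnan(X).any():
                raise ValueError(f"view {v!r} contains missing values")
            mats[v] = X
        return mats

    def predict_proba1(self, views: dict) -> np.ndarray:
        """Consensus class-1 (EDA) probability: mean over all trees."""
        if not self.trees_:
            raise RuntimeError("forest is not fitted")
        mats = self._view_arrays(views)
        n = next(iter(mats.values())).shape[0]
        acc = np.zeros(n)
        for view, tree in self.trees_:
            acc += tree.predict_p1(mats[view])
        return acc / len(self.trees_)

    def predict(self, views: dict, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba1(views) >= threshold).astype(int)


def train_rf(
    X, y, params: RFParams, view: str = "genetic"
) -> MultiViewRandomForest:
    """Single-view random forest (all trees on one feature block)."""
    forest = MultiViewRandomForest(params, {view: 1.0})
    return forest.fit({view: X}, y)


def train_multiview(
    X_genetic,
    X_clinical,
    y,
    params: RFParams,
    allocation: float = 0.5,
) -> MultiViewRandomForest:
    """Multi-view forest: ``allocation`` fraction of trees on the genetic view.

    ``allocation`` = 1.0 (0.0) degenerates to a genetic-only (clinical-only)
    forest with identical trees to :func:`train_rf` at the same seed.
    """
    if not 0 <= allocation <= 1:
        raise ValueError("allocation must be in [0, 1]")
    if allocation == 1.0:
        return train_rf(X_genetic, y, params, view="genetic")
    if allocation == 0.0:
        return train_rf(X_clinical, y, params, view="clinical")
    forest = MultiViewRandomForest(
        params, {"genetic": allocation, "clinical": 1.0 - allocation}
    )
    return forest.fit({"genetic": X_genetic, "clinical": X_clinical}, y)


# ---------------------------------------------------------------------------
# model selection


@dataclass
class ModelSelectionRecord:
    """One candidate of the hyper-parameter search."""

    model_id: str
    signature_name: str
    selection_params: object  # SelectionParams or None for fixed signatures
    rf_params: RFParams
    signature: list
    metrics_tr: MetricsReport
    metrics_v: MetricsReport
    metrics_te: MetricsReport | None = None
    model: MultiViewRandomForest | None = field(default=None, repr=False)

    def row(self) -> dict:
        sel = self.selection_params
        out = {
            "model": self.model_id,
            "top_f": getattr(sel, "k", None),
            "min_fr": getattr(sel, "f_min", None),
            "sign": len(self.signature),
            "ntree": self.rf_params.ntree,
            "nodesize": self.rf_params.nodesize,
            "maxn": self.rf_params.maxn,
            "mtry": self.rf_params.mtry,
        }
        for tag, rep in (
            ("tr", self.metrics_tr),
            ("v", self.metrics_v),
            ("te", self.metrics_te),
        ):
            if rep is None:
                continue
            out.update(
                {
                    f"{tag}_auroc": round(rep.auroc, 4),
                    f"{tag}_auprc": round(rep.auprc, 4),
                    f"{tag}_f": round(rep.f_score, 4),
                    f"{tag}_acc": round(rep.accuracy, 4),
                }
            )
        return out


def grid_search(
    signatures: dict,
    X_tr: pd.DataFrame,
    y_tr,
    X_v: pd.DataFrame,
    y_v,
    rf_grid: list[RFParams],
    view: str = "genetic",
    top: int = 4,
    threshold: float = 0.5,
) -> list[ModelSelectionRecord]:
    """Train every (signature x RF parameters) candidate on TR, rank on V.

    ``signatures`` maps name -> (selection_params_or_None, feature id list).
    Candidates are ranked by validation AUROC, ties by AUPRC then F-score
    then model id; the ``top`` best records (with their fitted models) are
    returned.  TR and V must be disjoint sample sets.
    """
    overlap = X_tr.index.intersection(X_v.index)
    if len(overlap):
        raise ValueError(
            f"training and validation sets overlap: {list(overlap[:5])}"
        )
    y_tr = np.asarray(y_tr)
    y_v = np.asarray(y_v)
    records = []
    i = 0
    for name, (sel_params, features) in signatures.items():
        features = list(features)
        if not features:
            raise ValueError(f"signature {name!r} is empty; nothing to train on")
        Xtr, Xv = X_tr[features], X_v[features]
        for rf_params in rf_grid:
            i += 1
            model = train_rf(Xtr, y_tr, rf_params, view=view)
            s_tr = model.predict_proba1({view: Xtr})
            s_v = model.predict_proba1({view: Xv})
            records.append(
                ModelSelectionRecord(
                    model_id=f"{view[0]}{i}",
                    signature_name=name,
                    selection_params=sel_params,
                    rf_params=rf_params,
                    signature=features,
                    metrics_tr=evaluate_scores(s_tr, y_tr, "TRset", threshold),
                    metrics_v=evaluate_scores(s_v, y_v, "Vset", threshold),
                    model=model,
                )
            )
    records.sort(
        key=lambda r: (
            -r.metrics_v.auroc,
            -r.metrics_v.auprc,
            -r.metrics_v.f_score,
            r.model_id,
        )
    )
    return records[:top]


def expand_rf_grid(
    ntree=(10, 100),
    maxn=(1, 100),
    nodesize=(1, 10),
    mtry=(None,),
    base_seed: int = 0,
) -> list[RFParams]:
    """Cartesian RF-parameter grid with per-candidate derived seeds."""
    grid = []
    i = 0
    for nt in ntree:
        for mx in maxn:
            for ns in nodesize:
                for mt in mtry:
                    grid.append(
                        RFParams(
                            ntree=int(nt),
                            maxn=None if mx is None else int(mx),
                            nodesize=int(ns),
                            mtry=None if mt is None else int(mt),
                            seed=int(
                                np.random.SeedSequence([base_seed, i]).generate_state(
                                    1
                                )[0]
                                % (2**31)
                            ),
                        )
                    )
                    i += 1
    return grid
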