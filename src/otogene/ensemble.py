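"""Partitioned heterogeneous ensemble for single-audiogram gene prediction.

Training audiograms are stratified along three axes — per-gene data volume
(high/low about the median class count), patient age (young < 20, mid
20-59, old >= 60) and audiogram shape (flat / downsloping / other) — and
eleven submodels are each bound to one stratum: three k-nearest-neighbour
models on the age strata, six AdaBoost models on the volume x shape cells,
and two random forests on the volume strata.  A multinomial logistic
regression fuses the submodels' probability vectors, trained on
out-of-fold submodel outputs (internal 5-fold stacking) to avoid leakage.

At prediction time every submodel emits a probability vector for the input
(the volume stratum of the true gene is unknowable for a new patient) and
the fuser weighs them; the partitioning acts through what each submodel
saw in training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .data import DEFAULT_PANEL, Audiogram
from .preprocess import N_FEATURES, design_matrix, from_feature_vector, shape_class

AGE_EDGES = (20.0, 60.0)
AGE_STRATA = ("young", "mid", "old")
SHAPE_GROUPS = ("flat", "downsloping", "other")


def age_stratum(age: float) -> str:
    """young < 20 <= mid < 60 <= old (boundary ages join the older band)."""
    if age < AGE_EDGES[0]:
        return "young"
    if age < AGE_EDGES[1]:
        return "mid"
    return "old"


def shape_group(shape: str) -> str:
    return shape if shape in ("flat", "downsloping") else "other"


def partition_training(X: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    """Stratum labels per training audiogram along the three axes.

    Volume: a gene is 'high' when its audiogram count is at least the
    median per-gene count.  Every audiogram belongs to exactly one stratum
    per axis, so each reaches at least one submodel.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    ages = np.array([age_stratum(a) for a in X[:, 0]])
    shapes = np.array([shape_group(shape_class(from_feature_vector(row))) for row in X])
    genes, counts = np.unique(y, return_counts=True)
    median = np.median(counts)
    high = {g for g, c in zip(genes, counts) if c >= median}
    volume = np.array(["high" if g in high else "low" for g in y])
    return {"age": ages, "shape": shapes, "volume": volume}


#: Default stratum-to-submodel binding: (name, kind, axis predicate).
def _default_bindings(knn_ks: Sequence[int]) -> list[tuple[str, str, dict]]:
    b: list[tuple[str, str, dict]] = []
    for stratum, k in zip(AGE_STRATA, knn_ks):
        b.append((f"knn_{stratum}", "knn", {"age": stratum, "k": k}))
    for vol in ("high", "low"):
        for shp in SHAPE_GROUPS:
            b.append((f"ada_{vol}_{shp}", "adaboost", {"volume": vol, "shape": shp}))
    for vol in ("high", "low"):
        b.append((f"rf_{vol}", "rf", {"volume": vol}))
    return b


class PartitionedEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Stacked KNN/AdaBoost/RF committee fused by logistic regression.

    Parameters
    ----------
    knn_ks : tuple of int
        Neighbourhood sizes of the three KNN submodels (young/mid/old).
    adaboost_estimators, rf_estimators : int
        Boosting rounds (decision stumps) and forest size.
    stacking_folds : int
        Folds for the out-of-fold stacking that trains the fuser.
    panel : sequence of str, optional
        Gene panel for full-panel probability output (default 23 genes).
    random_state : int

    Attributes
    ----------
    classes_ : genes seen with >= 2 training audiograms, sorted.
    excluded_classes_ : singleton genes dropped with a warning.
    submodel_names_ : the eleven submodel identifiers.
    fuser_ : fitted logistic-regression combiner.
    """

    def __init__(
        self,
        knn_ks: tuple[int, ...] = (5, 15, 31),
        adaboost_estimators: int = 100,
        rf_estimators: int = 200,
        stacking_folds: int = 5,
        panel: Optional[Sequence[str]] = None,
        random_state: int = 0,
    ):
        self.knn_ks = knn_ks
        self.adaboost_estimators = adaboost_estimators
        self.rf_estimators = rf_estimators
        self.stacking_folds = stacking_folds
        self.panel = panel
        self.random_state = random_state

    # -- submodel construction -------------------------------------------
    def _make(self, kind: str, spec: dict, n_train: int):
        rs = self.random_state
        if kind == "knn":
            k = min(spec["k"], max(1, n_train))
            return Pipeline([
                ("scale", StandardScaler()),
                ("clf", KNeighborsClassifier(n_neighbors=k)),
            ])
        if kind == "adaboost":
            return AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1, random_state=rs),
                n_estimators=self.adaboost_estimators,
                random_state=rs,
            )
        if kind == "rf":
            return RandomForestClassifier(
                n_estimators=self.rf_estimators, random_state=rs, n_jobs=1
            )
        raise ValueError(kind)

    def _stratum_mask(self, strata: dict, spec: dict, n: int) -> np.ndarray:
        mask = np.ones(n, dtype=bool)
        for axis in ("age", "shape", "volume"):
            if axis in spec:
                mask &= strata[axis] == spec[axis]
        return mask

    def _fit_one(self, kind: str, spec: dict, X, y, mask):
        """Train one submodel on its stratum; fall back to the full data
        when the stratum is empty or single-class."""
        if mask.sum() < 2 or len(np.unique(y[mask])) < 2:
            self.fallback_submodels_.append(spec.get("_name", kind))
            mask = np.ones(len(y), dtype=bool)
        est = self._make(kind, spec, int(mask.sum()))
        est.fit(X[mask], y[mask])
        return est

    def _expand(self, est, X) -> np.ndarray:
        """Submodel probabilities aligned onto the full ``classes_`` axis."""
        out = np.zeros((len(X), len(self.classes_)))
        proba = est.predict_proba(X)
        cols = np.searchsorted(self.classes_, est.classes_)
        out[:, cols] = proba
        return out

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object).astype(str)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ValueError(f"X must be (n, {N_FEATURES})")
        # canonical ordering makes the fit invariant to row order
        codes = np.searchsorted(np.unique(y), y)
        order = np.lexsort(tuple(X[:, i] for i in range(X.shape[1] - 1, -1, -1)) + (codes,))
        X, y = X[order], y[order]

        classes, counts = np.unique(y, return_counts=True)
        self.excluded_classes_ = [str(c) for c in classes[counts < 2]]
        if self.excluded_classes_:
            warnings.warn(
                f"excluding singleton classes {self.excluded_classes_}", UserWarning
            )
            keep = ~np.isin(y, self.excluded_classes_)
            X, y = X[keep], y[keep]
        self.classes_ = np.unique(y)
        self.fallback_submodels_: list[str] = []
        self.bindings_ = _default_bindings(self.knn_ks)
        self.submodel_names_ = [name for name, _, _ in self.bindings_]

        if len(self.classes_) < 2:
            # degenerate single-class model: predict that gene with certainty
            self.submodels_ = {}
            self.fuser_ = None
            return self

        strata = partition_training(X, y)
        masks = {
            name: self._stratum_mask(strata, spec, len(y))
            for name, _, spec in self.bindings_
        }

        # out-of-fold submodel outputs -> training matrix for the fuser
        min_count = np.unique(y, return_counts=True)[1].min()
        n_folds = int(min(self.stacking_folds, min_count))
        oof = np.zeros((len(y), len(self.bindings_) * len(self.classes_)))
        if n_folds >= 2:
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=self.random_state)
            for tr, te in skf.split(X, y):
                trmask = np.zeros(len(y), dtype=bool)
                trmask[tr] = True
                for j, (name, kind, spec) in enumerate(self.bindings_):
                    est = self._fit_one(kind, {**spec, "_name": name}, X, y, masks[name] & trmask)
                    oof[np.ix_(te, range(j * len(self.classes_), (j + 1) * len(self.classes_)))] = \
                        self._expand(est, X[te])
        self.submodels_ = {
            name: self._fit_one(kind, {**spec, "_name": name}, X, y, masks[name])
            for name, kind, spec in self.bindings_
        }
        if n_folds < 2:  # stacking impossible; fuse in-sample outputs
            oof = self._meta_features(X)
        self.fuser_ = LogisticRegression(max_iter=2000, random_state=self.random_state)
        self.fuser_.fit(oof, y)
        return self

    def _meta_features(self, X) -> np.ndarray:
        return np.hstack([self._expand(self.submodels_[n], X) for n in self.submodel_names_])

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        if len(self.classes_) == 1:
            return np.ones((len(X), 1))
        # fuser classes match classes_ (both sorted over the same labels)
        return self.fuser_.predict_proba(self._meta_features(X))

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    # -- panel-level output ----------------------------------------------
    def predict_panel(self, X) -> list[dict[str, float]]:
        """Full-panel gene-probability maps, one per row.

        Genes absent from training receive probability 0 before
        renormalization over the panel.
        """
        panel = tuple(self.panel) if self.panel is not None else DEFAULT_PANEL
        proba = self.predict_proba(np.asarray(X, dtype=float))
        out = []
        for row in proba:
            d = {g: 0.0 for g in panel}
            for g, p in zip(self.classes_, row):
                d[str(g)] = float(p)
            s = sum(d.values())
            out.append({g: v / s for g, v in d.items()})
        return out

    def predict_audiogram(self, audiogram: Audiogram) -> dict[str, float]:
        """Gene probabilities for one (possibly incomplete) audiogram."""
        return self.predict_panel(design_matrix([audiogram]))[0]
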