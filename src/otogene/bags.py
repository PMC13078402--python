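"""Multi-instance gene ranking via pairwise-coupled margin classifiers.

Patients with several audiograms are treated as *bags*: one calibrated
margin classifier (SVM + Platt sigmoid) is trained per unordered class
pair on per-audiogram feature vectors; at prediction time the pairwise
win-probabilities of each audiogram are coupled into a multiclass
distribution (Hastie–Tibshirani iterative scheme) and the bag's
distributions are aggregated by arithmetic mean.

The historical engine this follows used "modified" SVM probability
outputs whose exact modification is unpublished; here calibration is the
standard Platt sigmoid, and a semisupervised hook exists but is disabled
by default (no unlabeled-data mechanism is part of the default path).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .data import DEFAULT_PANEL, PatientRecord
from .preprocess import N_FEATURES, design_matrix

_EPS = 1e-6


def pairwise_coupling(
    pairwise: Mapping[tuple[str, str], float],
    classes: Sequence[str],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> dict[str, float]:
    """Couple one-vs-one win probabilities into a multiclass distribution.

    ``pairwise[(i, j)]`` is P(class i beats class j); every unordered pair
    of ``classes`` must be present (either orientation).  Uses the
    iterative minimum-KL scheme of Hastie & Tibshirani: with current
    estimate p, mu_ij = p_i / (p_i + p_j) and

        p_i  <-  p_i * sum_j r_ij / sum_j mu_ij

    renormalized each sweep, until the largest update falls below ``tol``.
    For two classes the fixed point is the input probability itself.
    """
    classes = list(classes)
    k = len(classes)
    if k == 1:
        return {classes[0]: 1.0}
    r = np.full((k, k), np.nan)
    index = {c: i for i, c in enumerate(classes)}
    for (a, b), p in pairwise.items():
        i, j = index[a], index[b]
        r[i, j] = p
        r[j, i] = 1.0 - p
    iu = np.triu_indices(k, 1)
    if np.isnan(r[iu]).any():
        missing = [(classes[i], classes[j]) for i, j in zip(*iu) if np.isnan(r[i, j])]
        raise ValueError(f"missing pairwise estimates: {missing}")
    r = np.clip(r, _EPS, 1 - _EPS)
    np.fill_diagonal(r, 0.0)
    off = ~np.eye(k, dtype=bool)
    p = np.full(k, 1.0 / k)
    for _ in range(max_iter):
        P = p[:, None] + p[None, :]
        mu = np.where(off, p[:, None] / np.where(P == 0, 1.0, P), 0.0)
        num = np.where(off, r, 0.0).sum(axis=1)
        den = mu.sum(axis=1)
        new = p * num / np.where(den == 0, 1.0, den)
        new /= new.sum()
        if np.max(np.abs(new - p)) < tol:
            p = new
            break
        p = new
    return {c: float(v) for c, v in zip(classes, p)}


class PairwiseCoupledBagClassifier(ClassifierMixin, BaseEstimator):
    """One-vs-one calibrated SVMs with coupled multiclass output.

    Parameters
    ----------
    C, gamma : SVC hyperparameters (RBF kernel).
    calibration_folds : int
        Cross-fitting folds for the Platt sigmoid on decision values.
    panel : optional gene panel for full-panel output.
    random_state : int

    Attributes
    ----------
    classes_ : genes with >= 2 training audiograms, sorted.
    pair_models_ : {(gene_i, gene_j): (pipeline, platt)} for i < j.
    """

    def __init__(
        self,
        C: float = 1.0,
        gamma: str | float = "scale",
        calibration_folds: int = 3,
        panel: Optional[Sequence[str]] = None,
        random_state: int = 0,
    ):
        self.C = C
        self.gamma = gamma
        self.calibration_folds = calibration_folds
        self.panel = panel
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object).astype(str)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ValueError(f"X must be (n, {N_FEATURES})")
        classes, counts = np.unique(y, return_counts=True)
        self.excluded_classes_ = [str(c) for c in classes[counts < 2]]
        if self.excluded_classes_:
            warnings.warn(f"excluding singleton classes {self.excluded_classes_}", UserWarning)
            keep = ~np.isin(y, self.excluded_classes_)
            X, y = X[keep], y[keep]
        self.classes_ = np.unique(y)
        self.pair_models_ = {}
        for a_idx in range(len(self.classes_)):
            for b_idx in range(a_idx + 1, len(self.classes_)):
                a, b = self.classes_[a_idx], self.classes_[b_idx]
                mask = (y == a) | (y == b)
                Xp, yp = X[mask], (y[mask] == a).astype(int)  # 1 = first class wins
                pipe = Pipeline([
                    ("scale", StandardScaler()),
                    ("svc", SVC(kernel="rbf", C=self.C, gamma=self.gamma,
                                random_state=self.random_state)),
                ])
                cv = int(min(self.calibration_folds, np.bincount(yp).min()))
                if cv >= 2:
                    dec = cross_val_predict(pipe, Xp, yp, cv=cv, method="decision_function")
                else:
                    dec = pipe.fit(Xp, yp).decision_function(Xp)
                pipe.fit(Xp, yp)
                platt = LogisticRegression(max_iter=1000)
                platt.fit(dec.reshape(-1, 1), yp)
                self.pair_models_[(str(a), str(b))] = (pipe, platt)
        return self

    def pair_probabilities(self, X) -> list[dict[tuple[str, str], float]]:
        """Per-row P(gene_i beats gene_j) for every trained pair."""
        check_is_fitted(self, "pair_models_")
        X = np.asarray(X, dtype=float)
        rows: list[dict[tuple[str, str], float]] = [dict() for _ in range(len(X))]
        for pair, (pipe, platt) in self.pair_models_.items():
            dec = pipe.decision_function(X).reshape(-1, 1)
            p = np.clip(platt.predict_proba(dec)[:, 1], _EPS, 1 - _EPS)
            for row, v in zip(rows, p):
                row[pair] = float(v)
        return rows

    def predict_proba(self, X):
        """Coupled multiclass probabilities per audiogram."""
        X = np.asarray(X, dtype=float)
        if len(self.classes_) == 1:
            return np.ones((len(X), 1))
        out = np.empty((len(X), len(self.classes_)))
        for i, table in enumerate(self.pair_probabilities(X)):
            coupled = pairwise_coupling(table, self.classes_)
            out[i] = [coupled[str(c)] for c in self.classes_]
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    # -- bag level --------------------------------------------------------
    def predict_bag(self, record: PatientRecord) -> dict[str, float]:
        """Mean of the bag's per-audiogram coupled distributions.

        Symmetric in audiogram order and idempotent under duplication; a
        one-audiogram bag reduces to the single-instance coupled output.
        """
        panel = tuple(self.panel) if self.panel is not None else DEFAULT_PANEL
        X = design_matrix(record.audiograms)
        proba = self.predict_proba(X).mean(axis=0)
        d = {g: 0.0 for g in panel}
        for g, p in zip(self.classes_, proba):
            d[str(g)] = float(p)
        s = sum(d.values())
        return {g: v / s for g, v in d.items()}


def route(
    record: PatientRecord,
    si_model,
    mi_model: PairwiseCoupledBagClassifier,
) -> tuple[str, dict[str, float]]:
    """Dispatch a patient to the right engine by bag size.

    One audiogram goes to the single-instance ensemble; two or more go to
    the multi-instance bag classifier.  Returns (route name, probabilities).
    """
    if len(record.audiograms) == 1:
        return "single_instance", si_model.predict_audiogram(record.audiograms[0])
    return "multi_instance", mi_model.predict_bag(record)
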