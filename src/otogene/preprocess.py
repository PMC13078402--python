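"""Missing-threshold imputation and the 11-feature representation.

Every downstream model consumes the same 11-dimensional vector per
audiogram: age in years followed by the ten grid thresholds in ascending
frequency order.  Missing thresholds are filled by linear interpolation
against the grid *index* (audiometric frequencies are near-logarithmic, so
index-linear interpolation is the conventional choice), with linear
extrapolation from the two nearest observed points at the edges.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .data import (
    FREQUENCIES,
    MIN_OBSERVED,
    THRESHOLD_RANGE,
    Audiogram,
    PatientRecord,
)

N_FEATURES = 11

SHAPE_CLASSES = ("flat", "downsloping", "upsloping", "mid_dip")

#: Frequency bands for shape classification: low = 125-500 Hz,
#: mid = 1000-2000 Hz, high = 3000-8000 Hz (grid-index edges).
SHAPE_BAND_EDGES = (3, 6)
SHAPE_DELTA_DB = 15.0


class DegenerateAudiogramError(ValueError):
    """Fewer observed thresholds than imputation can work with."""


def impute(audiogram: Audiogram) -> Audiogram:
    """Complete an audiogram on the ten-frequency grid.

    Interior gaps are linearly interpolated against grid index; leading and
    trailing gaps are linearly extrapolated from the two nearest observed
    points.  Observed values are never altered; filled values are clamped
    to the audiometer range.  Idempotent.
    """
    if audiogram.n_observed < MIN_OBSERVED:
        raise DegenerateAudiogramError(
            f"audiogram {audiogram.audiogram_id!r} has {audiogram.n_observed} "
            f"observed thresholds; imputation needs >= {MIN_OBSERVED}"
        )
    if audiogram.is_complete:
        return audiogram
    obs_idx = np.array([i for i, f in enumerate(FREQUENCIES) if f in audiogram.thresholds])
    obs_val = np.array([audiogram.thresholds[FREQUENCIES[i]] for i in obs_idx], dtype=float)
    full = np.interp(np.arange(len(FREQUENCIES)), obs_idx, obs_val)
    # np.interp holds edge values constant; replace with 2-point extrapolation
    lo, hi = obs_idx[0], obs_idx[-1]
    if lo > 0:
        slope = (obs_val[1] - obs_val[0]) / (obs_idx[1] - obs_idx[0])
        full[:lo] = obs_val[0] + slope * (np.arange(lo) - lo)
    if hi < len(FREQUENCIES) - 1:
        slope = (obs_val[-1] - obs_val[-2]) / (obs_idx[-1] - obs_idx[-2])
        full[hi + 1:] = obs_val[-1] + slope * (np.arange(hi + 1, len(FREQUENCIES)) - hi)
    full = np.clip(full, *THRESHOLD_RANGE)
    thresholds = dict(zip(FREQUENCIES, full))
    thresholds.update(audiogram.thresholds)  # observed values win verbatim
    return dataclasses.replace(audiogram, thresholds=thresholds)


def to_feature_vector(audiogram: Audiogram) -> np.ndarray:
    """``[age, thr_125, ..., thr_8000]`` for a grid-complete audiogram."""
    if not audiogram.is_complete:
        raise ValueError("audiogram must be complete on the grid; impute() first")
    return np.concatenate(([audiogram.age], audiogram.threshold_array()))


def from_feature_vector(x: Sequence[float], patient_id: str = "?", audiogram_id: str = "?") -> Audiogram:
    """Inverse of :func:`to_feature_vector` (identifiers are not encoded)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (N_FEATURES,):
        raise ValueError(f"expected {N_FEATURES} features, got shape {x.shape}")
    return Audiogram(patient_id, audiogram_id, float(x[0]), dict(zip(FREQUENCIES, x[1:])))


def shape_class(
    audiogram: Audiogram,
    *,
    band_edges: tuple[int, int] = SHAPE_BAND_EDGES,
    delta_db: float = SHAPE_DELTA_DB,
) -> str:
    """Coarse audiogram morphology: flat, downsloping, upsloping or mid_dip.

    Band means L (low), M (mid), H (high) are compared against ``delta_db``;
    the first matching rule in the listed order wins, and an audiogram
    matching none of them defaults to flat.
    """
    thr = impute(audiogram).threshold_array()
    e0, e1 = band_edges
    L, M, H = thr[:e0].mean(), thr[e0:e1].mean(), thr[e1:].mean()
    if max(abs(L - M), abs(L - H), abs(M - H)) <= delta_db:
        return "flat"
    if H - L > delta_db:
        return "downsloping"
    if L - H > delta_db:
        return "upsloping"
    if M - L > delta_db and M - H > delta_db:
        return "mid_dip"
    return "flat"


def design_matrix(audiograms: Iterable[Audiogram]) -> np.ndarray:
    """Impute and stack audiograms into an ``(n, 11)`` feature matrix."""
    rows = [to_feature_vector(impute(a)) for a in audiograms]
    return np.vstack(rows) if rows else np.empty((0, N_FEATURES))


def features_from_records(records: Iterable[PatientRecord]):
    """Flatten labeled patient bags into per-audiogram training arrays.

    Returns
    -------
    X : ndarray (n, 11)
    y : ndarray (n,) of gene labels ('' where unlabeled)
    groups : ndarray (n,) of patient ids
    """
    X, y, groups = [], [], []
    for r in records:
        for a in r.audiograms:
            X.append(to_feature_vector(impute(a)))
            y.append(r.gene or "")
            groups.append(r.patient_id)
    if not X:
        return np.empty((0, N_FEATURES)), np.array([], dtype=object), np.array([], dtype=object)
    return np.vstack(X), np.asarray(y, dtype=object), np.asarray(groups, dtype=object)
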