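"""Per-gene audioprofiles and fitted audioprofile surfaces.

An *audioprofile* is the gene's mean audiogram stratified by age bin — the
characteristic hearing-loss shape clinicians compare a patient against.
The *audioprofile surface* generalises it to a smooth function
``threshold = f(age, frequency)`` fitted by ordinary least squares on a
tensor-product polynomial basis, rendering gene-specific progression as a
3-D surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.polynomial import polynomial as P
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data import FREQUENCIES, THRESHOLD_RANGE, Audiogram, PatientRecord
from .preprocess import impute

#: Decade age bins [0,10), ..., [90,100).
DEFAULT_AGE_BINS: tuple[tuple[float, float], ...] = tuple(
    (float(lo), float(lo + 10)) for lo in range(0, 100, 10)
)


@dataclass
class Audioprofile:
    """Mean thresholds by age bin for one gene.

    ``mean_thr`` and ``sd_thr`` are ``(n_bins, 10)`` arrays; cells are NaN
    where no (respectively fewer than two) audiograms contribute.
    Audiograms are weighted equally regardless of patient.
    """

    gene: str
    age_bins: tuple[tuple[float, float], ...]
    mean_thr: np.ndarray
    sd_thr: np.ndarray
    count: np.ndarray

    def bin_index(self, age: float) -> int:
        """Half-open convention: age equal to an edge joins the upper bin."""
        for i, (lo, hi) in enumerate(self.age_bins):
            if lo <= age < hi:
                return i
        raise ValueError(f"age {age} outside binned range")

    def nonempty_bins(self) -> np.ndarray:
        return np.flatnonzero(self.count.sum(axis=1) > 0)


def build_audioprofile(
    records: Iterable[PatientRecord],
    gene: str,
    age_bins: Sequence[tuple[float, float]] = DEFAULT_AGE_BINS,
) -> Audioprofile:
    """Average the imputed audiograms of a gene's patients per age bin."""
    age_bins = tuple(tuple(b) for b in age_bins)
    rows = [impute(a) for r in records if r.gene == gene for a in r.audiograms]
    if not rows:
        raise ValueError(f"no audiograms labeled {gene!r}")
    n_bins, n_f = len(age_bins), len(FREQUENCIES)
    sums = np.zeros((n_bins, n_f))
    sq = np.zeros((n_bins, n_f))
    count = np.zeros((n_bins, n_f), dtype=int)
    for a in rows:
        b = next((i for i, (lo, hi) in enumerate(age_bins) if lo <= a.age < hi), None)
        if b is None:
            continue
        t = a.threshold_array()
        sums[b] += t
        sq[b] += t**2
        count[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count >= 1, sums / np.maximum(count, 1), np.nan)
        var = np.where(count >= 2, (sq - sums**2 / np.maximum(count, 1)) / np.maximum(count - 1, 1), np.nan)
    sd = np.sqrt(np.where(np.isnan(var), np.nan, np.clip(np.nan_to_num(var), 0, None)))
    sd = np.where(np.isnan(var), np.nan, sd)
    return Audioprofile(gene, age_bins, mean, sd, count)


class AudioprofileSurface(RegressorMixin, BaseEstimator):
    """OLS tensor-product polynomial surface ``thr = f(age, freq index)``.

    Parameters
    ----------
    degree_age, degree_freq : int
        Polynomial degree along each axis (default cubic x cubic).

    Attributes
    ----------
    coef_ : ndarray (degree_age+1, degree_freq+1)
        Coefficient ``coef_[i, j]`` multiplies ``age**i * index**j``.
    rmse_ : float
        Root-mean-square residual of the fit, dB.
    """

    def __init__(self, degree_age: int = 3, degree_freq: int = 3):
        self.degree_age = degree_age
        self.degree_freq = degree_freq

    def fit(self, X, y):
        """Fit on ``X = [[age, freq_index], ...]`` against thresholds ``y``."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n_coef = (self.degree_age + 1) * (self.degree_freq + 1)
        if len(y) < n_coef:
            raise ValueError(
                f"underdetermined surface: {len(y)} observations for {n_coef} "
                "coefficients; lower degree_age/degree_freq"
            )
        V = P.polyvander2d(X[:, 0], X[:, 1], [self.degree_age, self.degree_freq])
        coef, *_ = np.linalg.lstsq(V, y, rcond=None)
        self.coef_ = coef.reshape(self.degree_age + 1, self.degree_freq + 1)
        self.rmse_ = float(np.sqrt(np.mean((V @ coef - y) ** 2)))
        return self

    def predict(self, X):
        """Evaluate the surface, clamped to the audiometer range."""
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        vals = P.polyval2d(X[:, 0], X[:, 1], self.coef_)
        return np.clip(vals, *THRESHOLD_RANGE)


def fit_aps(
    records: Iterable[PatientRecord],
    gene: str,
    degree_age: int = 3,
    degree_freq: int = 3,
) -> AudioprofileSurface:
    """Fit a gene's audioprofile surface from its labeled audiograms."""
    rows = [impute(a) for r in records if r.gene == gene for a in r.audiograms]
    if not rows:
        raise ValueError(f"no audiograms labeled {gene!r}")
    ages = np.repeat([a.age for a in rows], len(FREQUENCIES))
    idx = np.tile(np.arange(len(FREQUENCIES), dtype=float), len(rows))
    thr = np.concatenate([a.threshold_array() for a in rows])
    model = AudioprofileSurface(degree_age=degree_age, degree_freq=degree_freq)
    model.fit(np.column_stack([ages, idx]), thr)
    model.gene = gene
    return model


def eval_aps(model: AudioprofileSurface, age: float, frequency: int) -> float:
    """Surface threshold at an (age, grid frequency) point, dB HL."""
    if frequency not in FREQUENCIES:
        raise ValueError(f"frequency {frequency} Hz is not on the grid")
    idx = FREQUENCIES.index(frequency)
    return float(model.predict([[age, idx]])[0])


@dataclass(frozen=True)
class ProfileDistance:
    """RMS distance of an audiogram to a profile row, with a fallback flag."""

    rms: float
    bin_index: int
    fallback: bool  # True when the audiogram's own age bin was empty

    def __float__(self) -> float:
        return self.rms


def profile_distance(audiogram: Audiogram, profile: Audioprofile) -> ProfileDistance:
    """Root-mean-square dB difference to the profile row of the age bin.

    If the audiogram's own age bin holds no data, the nearest non-empty bin
    is used instead and the result is flagged as a fallback.
    """
    a = impute(audiogram)
    b = profile.bin_index(a.age)
    nonempty = profile.nonempty_bins()
    if len(nonempty) == 0:
        raise ValueError(f"profile for {profile.gene!r} is empty")
    fallback = b not in nonempty
    if fallback:
        b = int(nonempty[np.argmin(np.abs(nonempty - b))])
    diff = a.threshold_array() - profile.mean_thr[b]
    return ProfileDistance(float(np.sqrt(np.mean(diff**2))), b, fallback)


def profile_payload(profile: Audioprofile) -> dict:
    """JSON-ready audioprofile curves for the dashboard panel."""
    return {
        "gene": profile.gene,
        "frequencies_hz": list(FREQUENCIES),
        "curves": [
            {
                "age_bin": list(profile.age_bins[b]),
                "mean_db": [None if np.isnan(v) else round(float(v), 2) for v in profile.mean_thr[b]],
                "sd_db": [None if np.isnan(v) else round(float(v), 2) for v in profile.sd_thr[b]],
                "n": int(profile.count[b].max()),
            }
            for b in profile.nonempty_bins()
        ],
    }


def surface_payload(model: AudioprofileSurface, ages: Optional[Sequence[float]] = None) -> dict:
    """JSON-ready surface grid (age x frequency) for the 3-D panel."""
    if ages is None:
        ages = np.arange(0, 101, 5, dtype=float)
    ages = np.asarray(ages, dtype=float)
    idx = np.arange(len(FREQUENCIES), dtype=float)
    A, F = np.meshgrid(ages, idx, indexing="ij")
    Z = model.predict(np.column_stack([A.ravel(), F.ravel()])).reshape(A.shape)
    return {
        "gene": getattr(model, "gene", None),
        "ages": ages.tolist(),
        "frequencies_hz": list(FREQUENCIES),
        "threshold_db": np.round(Z, 2).tolist(),
        "fit_rmse_db": round(model.rmse_, 3),
    }
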