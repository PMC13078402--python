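"""Synthetic audiogram cohorts with gene-specific progressive phenotypes.

The generator emulates the statistical structure of clinical ADNSHL
audiometry: each gene carries a characteristic baseline audiogram shape at
age 0 and per-frequency progression slopes (dB/year), thresholds are
observed with i.i.d. Gaussian measurement noise, gene prevalence is
long-tailed (Zipf-like) so classes are heavily imbalanced, and patients
contribute one to three audiograms taken one to three years apart.

Shapes cover the archetypes of the dominant hearing-loss literature:
low-frequency ascending (WFS1-like), mid-frequency "cookie-bite"
(TECTA/COL11A2-like), flat progressive (MYO7A/TMC1-like) and
high-frequency downsloping (KCNQ4/COCH-like) profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import DEFAULT_PANEL, FREQUENCIES, THRESHOLD_RANGE, Audiogram, PatientRecord

DEFAULT_NOISE_SD = 10.0
DEFAULT_AGE_RANGE = (5.0, 80.0)
DEFAULT_VISIT_SPACING = (1.0, 3.0)

_BASE_REGIONS = {"Dutch": 0.30, "German": 0.20, "American": 0.25, "British": 0.15, "Chinese": 0.10}
_DEFAULT_VISITS = {1: 0.40, 2: 0.35, 3: 0.25}


@dataclass(frozen=True)
class GeneSimProfile:
    """Generative parameters for one gene class.

    ``baseline`` is the expected audiogram at age 0 (dB HL, ten grid
    frequencies); ``slope`` the per-frequency progression in dB/year, so the
    expected threshold at age *a* and frequency *f* is
    ``baseline[f] + slope[f] * a`` before clamping to audiometer limits.
    """

    gene: str
    baseline: tuple[float, ...]
    slope: tuple[float, ...]
    noise_sd: float = DEFAULT_NOISE_SD
    prevalence: float = 1.0
    region_dist: Mapping[str, float] = field(default_factory=lambda: dict(_BASE_REGIONS))
    visits_dist: Mapping[int, float] = field(default_factory=lambda: dict(_DEFAULT_VISITS))

    def expected(self, age: float) -> np.ndarray:
        raw = np.asarray(self.baseline) + np.asarray(self.slope) * age
        return np.clip(raw, *THRESHOLD_RANGE)


# (baseline, slope) per gene; archetype noted inline.
_PANEL_PARAMS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    # low-frequency ascending, early onset
    "WFS1": ((45, 42, 38, 30, 24, 20, 16, 13, 11, 10),
             (.25, .25, .2, .2, .2, .2, .2, .2, .2, .2)),
    # progressive, flat becoming downsloping
    "ACTG1": ((10, 12, 15, 18, 22, 26, 30, 34, 38, 40),
              (.7, .7, .75, .8, .85, .9, .95, 1.0, 1.0, 1.0)),
    # late-onset high-frequency, steep progression
    "COCH": ((0, 2, 4, 8, 12, 16, 22, 28, 32, 35),
             (.9, .9, 1.0, 1.0, 1.1, 1.1, 1.2, 1.2, 1.2, 1.2)),
    # high-frequency downsloping, young onset
    "KCNQ4": ((8, 8, 10, 14, 20, 28, 38, 48, 55, 60),
              (.3, .3, .35, .4, .45, .5, .55, .6, .6, .6)),
    # flat moderate progressive
    "MYO7A": ((25, 27, 30, 32, 34, 36, 38, 40, 42, 44),
              (.5, .5, .5, .5, .5, .5, .5, .5, .5, .5)),
    "EYA4": ((20, 22, 25, 30, 33, 35, 37, 38, 39, 40),
             (.6, .6, .6, .55, .55, .5, .5, .5, .45, .45)),
    "MYO6": ((15, 17, 20, 25, 30, 34, 38, 42, 45, 48),
             (.4, .4, .42, .45, .48, .5, .52, .55, .55, .55)),
    # mid-frequency cookie-bite, stable
    "TECTA": ((20, 25, 35, 48, 52, 50, 42, 34, 28, 24),
              (.15, .15, .15, .15, .15, .15, .15, .15, .15, .15)),
    # mid-frequency, moderate progression
    "COL11A2": ((25, 32, 42, 52, 56, 54, 48, 40, 34, 30),
                (.3, .3, .3, .3, .3, .3, .3, .3, .3, .3)),
    # downsloping, strong progression from youth
    "GSDME": ((5, 6, 8, 12, 18, 26, 36, 46, 54, 58),
              (.8, .8, .85, .9, .9, .9, .9, .85, .8, .8)),
    "POU4F3": ((12, 14, 16, 18, 20, 22, 25, 28, 30, 32),
               (.65, .65, .65, .65, .65, .65, .65, .65, .65, .65)),
    # flat progressive, severe
    "TMC1": ((30, 32, 35, 38, 40, 42, 45, 48, 50, 52),
             (.7, .7, .7, .7, .7, .7, .7, .7, .7, .7)),
    # mild flat, slow
    "MYH14": ((18, 19, 20, 21, 22, 23, 24, 25, 26, 27),
              (.35, .35, .35, .35, .35, .35, .35, .35, .35, .35)),
    "MYH9": ((5, 6, 8, 10, 13, 16, 20, 24, 28, 30),
             (.45, .45, .45, .5, .5, .5, .55, .55, .6, .6)),
    # low-frequency onset, generalising with age
    "DIAPH1": ((35, 33, 28, 22, 18, 16, 14, 12, 11, 10),
               (.5, .5, .5, .55, .55, .6, .6, .65, .65, .7)),
    "CCDC50": ((30, 28, 26, 22, 18, 14, 12, 10, 9, 8),
               (.3, .32, .35, .4, .45, .5, .55, .6, .6, .6)),
    # mild flat, very slow
    "GRHL2": ((8, 9, 10, 11, 12, 13, 14, 15, 16, 17),
              (.4, .4, .4, .4, .4, .4, .4, .4, .4, .4)),
    # high-frequency, mid-life onset
    "SLC17A8": ((2, 3, 5, 10, 16, 24, 34, 42, 48, 52),
                (.5, .5, .5, .5, .55, .55, .6, .6, .6, .6)),
    # flat moderate-severe progressive
    "P2RX2": ((35, 37, 40, 43, 45, 47, 50, 52, 54, 56),
              (.45, .45, .45, .45, .45, .45, .45, .45, .45, .45)),
    # mid-frequency mild
    "CEACAM16": ((10, 14, 22, 32, 36, 34, 28, 22, 18, 15),
                 (.5, .5, .5, .5, .5, .5, .5, .5, .5, .5)),
    # flat, steep progression from childhood
    "MIR96": ((18, 20, 23, 26, 28, 30, 33, 36, 38, 40),
              (.85, .85, .85, .85, .85, .85, .85, .85, .85, .85)),
    # high-frequency steeply sloping
    "TJP2": ((0, 0, 2, 5, 10, 18, 30, 42, 52, 58),
             (.7, .7, .7, .75, .75, .8, .8, .85, .85, .9)),
    # mild low-frequency ascending
    "CRYM": ((32, 30, 27, 24, 20, 17, 14, 12, 10, 8),
             (.25, .25, .25, .25, .25, .25, .25, .25, .25, .25)),
}


def default_panel(noise_sd: float = DEFAULT_NOISE_SD) -> list[GeneSimProfile]:
    """The 23-gene generative panel with Zipf-like prevalence weights.

    Prevalence is proportional to 1/rank in panel order, so the head genes
    dominate and the tail classes are rare — the class-imbalance regime the
    classifiers must cope with.
    """
    weights = np.array([1.0 / (i + 1) for i in range(len(DEFAULT_PANEL))])
    weights /= weights.sum()
    panel = []
    for gene, w in zip(DEFAULT_PANEL, weights):
        base, slope = _PANEL_PARAMS[gene]
        regions = dict(_BASE_REGIONS)
        if gene == "COCH":  # founder-effect style regional concentration
            regions = {"Dutch": 0.70, "German": 0.10, "American": 0.10, "British": 0.05, "Chinese": 0.05}
        panel.append(GeneSimProfile(gene, base, slope, noise_sd=noise_sd,
                                    prevalence=float(w), region_dist=regions))
    return panel


def _draw_categorical(rng: np.random.Generator, dist: Mapping) -> object:
    keys = list(dist.keys())
    p = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def simulate(
    panel: Sequence[GeneSimProfile],
    n_patients: int,
    seed: int,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
) -> list[PatientRecord]:
    """Draw a deterministic synthetic cohort of patient bags.

    Per patient: gene ~ prevalence; first-visit age ~ Uniform(age_range);
    visit count ~ the gene's visit distribution with 1-3-year spacing;
    every threshold = expected(age) + N(0, noise_sd), clamped to the
    audiometer range; region ~ the gene's region distribution.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    prev = np.array([g.prevalence for g in panel], dtype=float)
    prev /= prev.sum()
    records = []
    for i in range(n_patients):
        prof = panel[rng.choice(len(panel), p=prev)]
        n_visits = int(_draw_categorical(rng, prof.visits_dist))
        age = float(rng.uniform(*age_range))
        region = str(_draw_categorical(rng, prof.region_dist))
        pid = f"P{i:05d}"
        bag = []
        for k in range(n_visits):
            mean = np.asarray(prof.baseline) + np.asarray(prof.slope) * age
            thr = mean + rng.normal(0.0, prof.noise_sd, size=len(FREQUENCIES))
            thr = np.clip(thr, *THRESHOLD_RANGE)
            bag.append(Audiogram(
                patient_id=pid,
                audiogram_id=f"{pid}-{k + 1}",
                age=round(age, 2),
                thresholds=dict(zip(FREQUENCIES, np.round(thr, 1))),
                region=region,
                gene=prof.gene,
            ))
            age += float(rng.uniform(*DEFAULT_VISIT_SPACING))
        records.append(PatientRecord(pid, bag, gene=prof.gene))
    return records


def inject_missingness(
    records: Sequence[PatientRecord], rate: float, seed: int
) -> list[PatientRecord]:
    """Delete thresholds independently with probability ``rate``.

    An audiogram is never reduced below three observed thresholds: when the
    draws would delete more, the three frequencies with the highest
    retention draws are kept.  ``rate`` must lie in [0, 0.5].
    """
    if not 0.0 <= rate <= 0.5:
        raise ValueError(f"rate must be in [0, 0.5], got {rate}")
    if rate == 0.0:
        return list(records)
    rng = np.random.default_rng(seed)
    out = []
    for r in records:
        bag = []
        for a in r.audiograms:
            freqs = [f for f in FREQUENCIES if f in a.thresholds]
            u = rng.random(len(freqs))
            keep = u >= rate
            if keep.sum() < 3:
                keep = np.zeros(len(freqs), dtype=bool)
                keep[np.argsort(u)[-3:]] = True
            thr = {f: a.thresholds[f] for f, k in zip(freqs, keep) if k}
            bag.append(Audiogram(a.patient_id, a.audiogram_id, a.age, thr,
                                 region=a.region, gene=a.gene))
        out.append(PatientRecord(r.patient_id, bag, gene=r.gene))
    return out
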