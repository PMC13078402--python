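"""Top-k ranking, the green/red confidence flag, and evaluation metrics.

A prediction is useful to a clinician only with context: the top-3 gene
list is annotated with per-gene *concordance* — how far the patient's
audiograms sit from each candidate gene's audioprofile (RMS dB) and how
strongly the patient's k-means cluster supports the gene (fraction of the
cluster's confirmed cases carrying it).  A *green* flag means at least one
top-3 gene is both profile-close and cluster-supported; otherwise *red* —
the prediction deserves caution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data import DEFAULT_PANEL, Audiogram, PatientRecord
from .preprocess import design_matrix
from .profiles import Audioprofile, profile_distance

#: Flag thresholds: profile RMS within tau_rms dB and cluster support of at
#: least tau_sup.  Heuristics informed by the few-dB similarity clinicians
#: read as a match, plus measurement-noise headroom.
TAU_RMS = 15.0
TAU_SUP = 0.05


def top_k(probs: Mapping[str, float], k: int = 3, panel: Sequence[str] = DEFAULT_PANEL) -> list[str]:
    """The k highest-probability genes; ties break by panel order.

    Nested: the top-1 list is always a prefix of the top-3 list.
    """
    if k > len(panel):
        raise ValueError(f"k={k} exceeds panel size {len(panel)}")
    order = sorted(panel, key=lambda g: (-probs.get(g, 0.0), panel.index(g)))
    return order[:k]


@dataclass
class GeneConcordance:
    profile_rms: Optional[float]  # mean RMS dB over the patient's audiograms
    cluster_support: Optional[float]  # fraction of the cluster labeled with the gene
    available: bool = True


def concordance(
    audiograms: Sequence[Audiogram],
    top_genes: Sequence[str],
    profiles: Mapping[str, Audioprofile],
    atlas,
    train_assignments: Sequence[int],
    train_genes: Sequence[str],
) -> dict[str, GeneConcordance]:
    """Per-candidate concordance of a patient against the trained artifacts.

    For each gene: the mean, over the patient's audiograms, of the RMS
    distance to the gene's audioprofile, and the mean fraction of the
    audiogram's assigned cluster carrying the gene's label.
    """
    from .atlas import cluster_support  # local import avoids cycle at module load

    X = design_matrix(audiograms)
    clusters = atlas.assign(X) if atlas is not None else None
    out: dict[str, GeneConcordance] = {}
    for g in top_genes:
        if g not in profiles:
            out[g] = GeneConcordance(None, None, available=False)
            continue
        rms = float(np.mean([profile_distance(a, profiles[g]).rms for a in audiograms]))
        sup = None
        if clusters is not None:
            sup = float(np.mean([
                cluster_support(train_assignments, train_genes, int(c), g) for c in clusters
            ]))
        out[g] = GeneConcordance(rms, sup)
    return out


def flag(
    scores: Mapping[str, GeneConcordance],
    tau_rms: float = TAU_RMS,
    tau_sup: float = TAU_SUP,
) -> str:
    """green iff any candidate is profile-close AND cluster-supported.

    Boundary values count as close/supported (<= / >= convention), and the
    rule is monotone: lowering any profile RMS or raising any support can
    only move red -> green.
    """
    for s in scores.values():
        if not s.available or s.profile_rms is None:
            continue
        sup_ok = s.cluster_support is None or s.cluster_support >= tau_sup
        if s.profile_rms <= tau_rms and sup_ok:
            return "green"
    return "red"


@dataclass
class PredictionReport:
    """Everything the dashboard shows for one patient."""

    patient_id: str
    route: str  # single_instance | multi_instance
    ranked: list[tuple[str, float]]
    concordance: dict[str, GeneConcordance]
    flag: str

    @property
    def top3(self) -> list[str]:
        return [g for g, _ in self.ranked[:3]]

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "route": self.route,
            "ranked": [[g, round(p, 6)] for g, p in self.ranked],
            "top3": self.top3,
            "concordance": {
                g: {
                    "profile_rms_db": None if c.profile_rms is None else round(c.profile_rms, 3),
                    "cluster_support": None if c.cluster_support is None else round(c.cluster_support, 4),
                    "available": c.available,
                }
                for g, c in self.concordance.items()
            },
            "flag": self.flag,
        }


def build_report(
    record: PatientRecord,
    route_name: str,
    probs: Mapping[str, float],
    profiles: Mapping[str, Audioprofile],
    atlas,
    train_assignments,
    train_genes,
    panel: Sequence[str] = DEFAULT_PANEL,
    tau_rms: float = TAU_RMS,
    tau_sup: float = TAU_SUP,
) -> PredictionReport:
    ranked_genes = top_k(probs, k=len(panel), panel=panel)
    ranked = [(g, float(probs.get(g, 0.0))) for g in ranked_genes]
    scores = concordance(
        record.audiograms, [g for g, _ in ranked[:3]], profiles, atlas,
        train_assignments, train_genes,
    )
    return PredictionReport(
        patient_id=record.patient_id,
        route=route_name,
        ranked=ranked,
        concordance=scores,
        flag=flag(scores, tau_rms, tau_sup),
    )


def evaluate(
    predictions: Sequence[Mapping[str, float]],
    labels: Sequence[str],
    panel: Sequence[str] = DEFAULT_PANEL,
) -> dict:
    """Top-k accuracy and macro precision/recall with top-1 as the hard call.

    Precision and recall are macro-averaged over the classes present in
    the labels; a class never predicted contributes precision 0.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("need at least one labeled patient")
    panel = list(panel)
    top1 = [top_k(p, 1, panel)[0] for p in predictions]
    top3 = [top_k(p, 3, panel) for p in predictions]
    top1_acc = float(np.mean([l == t for l, t in zip(labels, top1)]))
    top3_acc = float(np.mean([l in t for l, t in zip(labels, top3)]))
    classes = sorted(set(labels))
    per_class = {}
    precisions, recalls = [], []
    for c in classes:
        tp = sum(1 for l, t in zip(labels, top1) if l == c and t == c)
        fp = sum(1 for l, t in zip(labels, top1) if l != c and t == c)
        fn = sum(1 for l, t in zip(labels, top1) if l == c and t != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        per_class[c] = {"support": tp + fn, "precision": prec, "recall": rec}
        precisions.append(prec)
        recalls.append(rec)
    return {
        "n": len(labels),
        "top1_acc": top1_acc,
        "top3_acc": top3_acc,
        "macro_precision": float(np.mean(precisions)),
        "macro_recall": float(np.mean(recalls)),
        "per_class": per_class,
    }


def dataset_summaries(records: Iterable[PatientRecord]) -> dict:
    """Gene counts, region pie fractions and the (gene, age) scatter.

    Audiograms with no region are bucketed as ``unknown``; pie fractions
    sum to one.
    """
    gene_counts: dict[str, int] = {}
    region_counts: dict[str, int] = {}
    scatter: list[tuple[str, float]] = []
    n = 0
    for r in records:
        for a in r.audiograms:
            n += 1
            g = a.gene or r.gene or "unlabeled"
            gene_counts[g] = gene_counts.get(g, 0) + 1
            reg = a.region or "unknown"
            region_counts[reg] = region_counts.get(reg, 0) + 1
            scatter.append((g, a.age))
    pie = {k: v / n for k, v in region_counts.items()} if n else {}
    return {"gene_counts": gene_counts, "region_pie": pie, "age_scatter": scatter}
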