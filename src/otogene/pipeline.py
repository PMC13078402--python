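"""End-to-end orchestration: ingest -> fit -> predict -> evaluate -> export.

Everything here is a thin composition of the library modules; a single
seed drives every random component so a rerun under the same configuration
reproduces byte-identical metrics and payloads.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np

from . import __version__
from .atlas import AudiogramAtlas, cluster_composition
from .bags import PairwiseCoupledBagClassifier, route
from .data import DEFAULT_PANEL, PatientRecord, read_dataset, write_dataset
from .ensemble import PartitionedEnsembleClassifier
from .preprocess import features_from_records
from .profiles import (
    Audioprofile,
    build_audioprofile,
    fit_aps,
    profile_payload,
    surface_payload,
)
from .reporting import (
    PredictionReport,
    build_report,
    dataset_summaries,
    evaluate,
)
from .simulate import default_panel, inject_missingness, simulate


@dataclass
class TrainedArtifacts:
    """Every fitted object the dashboard and reports need."""

    panel: tuple[str, ...]
    seed: int
    si_model: PartitionedEnsembleClassifier
    mi_model: PairwiseCoupledBagClassifier
    atlas: Optional[AudiogramAtlas]
    profiles: dict[str, Audioprofile]
    surfaces: dict
    train_assignments: np.ndarray
    train_genes: np.ndarray
    train_embedding: Optional[np.ndarray]


def train_artifacts(
    records: Sequence[PatientRecord],
    seed: int,
    panel: Sequence[str] = DEFAULT_PANEL,
    with_atlas: bool = True,
    aps_degree: tuple[int, int] = (3, 3),
) -> TrainedArtifacts:
    """Fit both classifiers, the cluster/embedding atlas, and per-gene
    audioprofiles + surfaces on labeled records."""
    labeled = [r for r in records if r.gene]
    X, y, _ = features_from_records(labeled)
    si = PartitionedEnsembleClassifier(panel=panel, random_state=seed).fit(X, y)
    mi = PairwiseCoupledBagClassifier(panel=panel, random_state=seed).fit(X, y)
    atlas = None
    embedding = None
    if with_atlas:
        atlas = AudiogramAtlas(random_state=seed).fit(X)
        embedding = atlas.embedding_
    profiles, surfaces = {}, {}
    for gene in sorted(set(y)):
        profiles[gene] = build_audioprofile(labeled, gene)
        n_obs = sum(len(r.audiograms) for r in labeled if r.gene == gene) * 10
        da, df_ = aps_degree
        while n_obs < (da + 1) * (df_ + 1) and da > 0:
            da -= 1  # thin classes get a lower-order surface
        surfaces[gene] = fit_aps(labeled, gene, degree_age=da, degree_freq=df_)
    return TrainedArtifacts(
        panel=tuple(panel),
        seed=seed,
        si_model=si,
        mi_model=mi,
        atlas=atlas,
        profiles=profiles,
        surfaces=surfaces,
        train_assignments=atlas.labels_ if atlas is not None else np.array([], dtype=int),
        train_genes=y,
        train_embedding=embedding,
    )


def predict_record(artifacts: TrainedArtifacts, record: PatientRecord) -> PredictionReport:
    """Route a patient to the right engine and assemble the full report."""
    route_name, probs = route(record, artifacts.si_model, artifacts.mi_model)
    return build_report(
        record, route_name, probs,
        artifacts.profiles, artifacts.atlas,
        artifacts.train_assignments, artifacts.train_genes,
        panel=artifacts.panel,
    )


def _fold_assignment(records: Sequence[PatientRecord], n_splits: int, seed: int) -> np.ndarray:
    """Stratified patient-level folds that tolerate classes smaller than
    ``n_splits`` (their patients simply occupy fewer folds)."""
    rng = np.random.default_rng(seed)
    folds = np.zeros(len(records), dtype=int)
    by_gene: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_gene.setdefault(r.gene or "", []).append(i)
    for gene in sorted(by_gene):
        idx = np.array(by_gene[gene])
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[i] = j % n_splits
    return folds


def cross_validate(
    records: Sequence[PatientRecord],
    seed: int,
    n_splits: int = 5,
    panel: Sequence[str] = DEFAULT_PANEL,
) -> dict:
    """Patient-level cross-validated routing metrics.

    Each fold trains both engines on the training patients' audiograms and
    routes every held-out patient (single audiogram -> ensemble, several
    -> bag classifier); metrics pool all held-out predictions.
    """
    labeled = [r for r in records if r.gene]
    folds = _fold_assignment(labeled, n_splits, seed)
    predictions: list[dict[str, float]] = [None] * len(labeled)  # type: ignore
    routes = [""] * len(labeled)
    for f in range(n_splits):
        train = [r for r, k in zip(labeled, folds) if k != f]
        test_idx = [i for i, k in enumerate(folds) if k == f]
        if not test_idx:
            continue
        X, y, _ = features_from_records(train)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            si = PartitionedEnsembleClassifier(panel=panel, random_state=seed).fit(X, y)
            mi = PairwiseCoupledBagClassifier(panel=panel, random_state=seed).fit(X, y)
        for i in test_idx:
            routes[i], predictions[i] = route(labeled[i], si, mi)
    metrics = evaluate(predictions, [r.gene for r in labeled], panel)
    metrics["n_splits"] = n_splits
    metrics["route_counts"] = {
        "single_instance": routes.count("single_instance"),
        "multi_instance": routes.count("multi_instance"),
    }
    return metrics


# ---------------------------------------------------------------------------
# dashboard payloads

def export_dashboard(
    artifacts: TrainedArtifacts,
    records: Sequence[PatientRecord],
    patient: Optional[PatientRecord] = None,
) -> dict[str, dict]:
    """The six renderer-agnostic visualization payloads.

    audioprofiles (2-D curves), surfaces (3-D grids), gene_counts (bar),
    region_pie, clusters (composition + 3-D scatter + optional red patient
    marker), age_scatter.  Schemas are versioned via ``schema`` keys.
    """
    summaries = dataset_summaries(records)
    payloads: dict[str, dict] = {}
    payloads["audioprofiles"] = {
        "schema": "audioprofiles/1",
        "genes": {g: profile_payload(p) for g, p in artifacts.profiles.items()},
    }
    payloads["surfaces"] = {
        "schema": "surfaces/1",
        "genes": {g: surface_payload(s) for g, s in artifacts.surfaces.items()},
    }
    payloads["gene_counts"] = {"schema": "gene_counts/1", "counts": summaries["gene_counts"]}
    payloads["region_pie"] = {"schema": "region_pie/1", "fractions": summaries["region_pie"]}
    cluster_payload: dict = {"schema": "clusters/1"}
    if artifacts.atlas is not None:
        comp = cluster_composition(artifacts.train_assignments, artifacts.train_genes)
        cluster_payload.update({
            "composition": {str(c): comp.loc[c].to_dict() for c in comp.index},
            "points": [
                {"coord": [round(float(v), 4) for v in xyz], "cluster": int(c), "gene": str(g)}
                for xyz, c, g in zip(
                    artifacts.train_embedding, artifacts.train_assignments, artifacts.train_genes
                )
            ],
        })
        if patient is not None:
            from .preprocess import design_matrix

            Xp = design_matrix(patient.audiograms)
            cluster_payload["patient_marker"] = [
                {"coord": [round(float(v), 4) for v in artifacts.atlas.transform(Xp[i:i + 1])[0]],
                 "cluster": int(artifacts.atlas.assign(Xp[i:i + 1])[0])}
                for i in range(len(Xp))
            ]
    payloads["clusters"] = cluster_payload
    payloads["age_scatter"] = {
        "schema": "age_scatter/1",
        "points": [{"gene": g, "age": round(float(a), 2)} for g, a in summaries["age_scatter"]],
    }
    return payloads


# ---------------------------------------------------------------------------
# model artifact I/O

def save_artifacts(artifacts: TrainedArtifacts, path) -> None:
    """Versioned binary artifact with embedded config and panel metadata."""
    import sklearn

    joblib.dump(
        {
            "format": "otogene-artifact/1",
            "version": __version__,
            "sklearn_version": sklearn.__version__,
            "panel": artifacts.panel,
            "seed": artifacts.seed,
            "artifacts": artifacts,
        },
        path,
    )


def load_artifacts(path) -> TrainedArtifacts:
    blob = joblib.load(path)
    if blob.get("format") != "otogene-artifact/1":
        raise ValueError(f"not an otogene artifact: {path}")
    return blob["artifacts"]


# ---------------------------------------------------------------------------
# configured pipeline

REQUIRED_CONFIG_KEYS = ("seed", "outdir")


def run_pipeline(config: Mapping) -> dict:
    """Execute the full pipeline from a config mapping.

    Config keys: ``seed``, ``outdir``, and either ``input`` (CSV path) or
    ``simulate`` ({"n_patients": int, "missing_rate": float}).  Optional:
    ``cv_splits`` (default 5, 0 disables evaluation).  Returns a manifest
    of what was produced; every output lands under ``outdir``.
    """
    missing = [k for k in REQUIRED_CONFIG_KEYS if k not in config]
    if missing:
        raise ValueError(f"config missing keys: {missing}")
    if "input" not in config and "simulate" not in config:
        raise ValueError("config needs 'input' (CSV path) or 'simulate' parameters")
    seed = int(config["seed"])
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name: str, **params):
        log.append({"stage": name, **params})

    if "input" in config:
        records = read_dataset(config["input"])
        stage("ingest", input=str(config["input"]), n_patients=len(records))
    else:
        sim = config["simulate"]
        records = simulate(default_panel(), int(sim["n_patients"]), seed)
        rate = float(sim.get("missing_rate", 0.0))
        if rate:
            records = inject_missingness(records, rate, seed + 1)
        write_dataset(records, outdir / "dataset.csv")
        stage("simulate", n_patients=len(records), missing_rate=rate, seed=seed)

    artifacts = train_artifacts(records, seed)
    save_artifacts(artifacts, outdir / "model.joblib")
    stage("train", n_classes=len(artifacts.si_model.classes_), seed=seed)

    reports = [predict_record(artifacts, r) for r in records[: int(config.get("n_reports", 20))]]
    (outdir / "reports.json").write_text(
        json.dumps([r.to_dict() for r in reports], indent=1, sort_keys=True)
    )
    stage("predict", n_reports=len(reports))

    cv_splits = int(config.get("cv_splits", 5))
    if cv_splits:
        metrics = cross_validate(records, seed, n_splits=cv_splits)
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))
        stage("evaluate", **{k: metrics[k] for k in ("top1_acc", "top3_acc")})

    payloads = export_dashboard(artifacts, records)
    (outdir / "payloads").mkdir(exist_ok=True)
    for name, payload in payloads.items():
        (outdir / "payloads" / f"{name}.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True)
        )
    stage("export", payloads=sorted(payloads))

    (outdir / "pipeline_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return {"outdir": str(outdir), "stages": [s["stage"] for s in log]}
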