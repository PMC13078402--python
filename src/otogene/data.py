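"""Domain types and tabular I/O for audiograms and patient records.

An audiogram records pure-tone air-conduction thresholds (dB HL) at up to
ten standard audiometric frequencies together with the patient's age at
testing.  Patients may contribute several audiograms taken years apart; a
:class:`PatientRecord` bundles them into a "bag" that optionally carries a
causative-gene label for the 23-gene autosomal dominant nonsyndromic
hearing loss (ADNSHL) panel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: The ten audiometric test frequencies (Hz), 125 Hz to 8 kHz including the
#: two half-octave interludes (1.5 and 3 kHz) and 6 kHz.
FREQUENCIES: tuple[int, ...] = (125, 250, 500, 1000, 1500, 2000, 3000, 4000, 6000, 8000)

#: Clinical audiometer output limits, dB HL.
THRESHOLD_RANGE: tuple[float, float] = (-10.0, 130.0)

#: Gene symbols recoverable from published ADNSHL audioprofiling work.
CORE_GENES: tuple[str, ...] = (
    "WFS1", "ACTG1", "COCH", "KCNQ4", "MYO7A", "EYA4",
    "MYO6", "TECTA", "COL11A2", "GSDME", "POU4F3",
)

#: Default 23-gene ADNSHL panel: the eleven core symbols plus twelve further
#: dominant hearing-loss genes commonly curated alongside them.
DEFAULT_PANEL: tuple[str, ...] = CORE_GENES + (
    "TMC1", "MYH14", "MYH9", "DIAPH1", "CCDC50", "GRHL2",
    "SLC17A8", "P2RX2", "CEACAM16", "MIR96", "TJP2", "CRYM",
)

#: Bit-exact CSV column layout.
CSV_COLUMNS: tuple[str, ...] = (
    "patient_id", "audiogram_id", "age", "region", "gene",
) + tuple(f"thr_{f}" for f in FREQUENCIES)

MIN_OBSERVED = 3


class DatasetError(ValueError):
    """Raised for malformed rows or inconsistent patient labelling."""


@dataclass(frozen=True)
class Audiogram:
    """One hearing test: age plus a (possibly partial) threshold map.

    Parameters
    ----------
    patient_id, audiogram_id : str
        Opaque identifiers.
    age : float
        Age in years at the time of testing, >= 0.
    thresholds : mapping of int -> float
        dB HL keyed by frequency; keys must belong to :data:`FREQUENCIES`.
    region : str, optional
        Region of origin (e.g. "Dutch").
    gene : str, optional
        Causative-gene label if genetically confirmed.
    """

    patient_id: str
    audiogram_id: str
    age: float
    thresholds: Mapping[int, float]
    region: Optional[str] = None
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", dict(self.thresholds))

    @property
    def n_observed(self) -> int:
        return len(self.thresholds)

    @property
    def is_complete(self) -> bool:
        return all(f in self.thresholds for f in FREQUENCIES)

    def threshold_array(self) -> np.ndarray:
        """Thresholds on the grid, NaN where unobserved."""
        return np.array([self.thresholds.get(f, np.nan) for f in FREQUENCIES])


@dataclass
class PatientRecord:
    """A bag of one or more audiograms sharing a patient id."""

    patient_id: str
    audiograms: list[Audiogram]
    gene: Optional[str] = None

    def __len__(self) -> int:
        return len(self.audiograms)


def validate(record: PatientRecord) -> list[str]:
    """Check every domain invariant; return human-readable violations.

    Never raises: an empty list means the record is clean.
    """
    v: list[str] = []
    if not record.audiograms:
        v.append("audiograms: bag is empty")
    for a in record.audiograms:
        tag = f"audiogram {a.audiogram_id!r}"
        if a.patient_id != record.patient_id:
            v.append(f"{tag}: patient_id {a.patient_id!r} != record {record.patient_id!r}")
        if not np.isfinite(a.age) or a.age < 0:
            v.append(f"{tag}: age must be a finite non-negative number, got {a.age}")
        if a.n_observed < MIN_OBSERVED:
            v.append(f"{tag}: only {a.n_observed} observed thresholds (need >= {MIN_OBSERVED})")
        for f, t in a.thresholds.items():
            if f not in FREQUENCIES:
                v.append(f"{tag}: frequency {f} Hz not on the grid")
            elif not (THRESHOLD_RANGE[0] <= t <= THRESHOLD_RANGE[1]):
                v.append(f"{tag}: threshold {t} dB at {f} Hz outside {THRESHOLD_RANGE}")
        if record.gene is not None and a.gene is not None and a.gene != record.gene:
            v.append(f"{tag}: gene {a.gene!r} != record gene {record.gene!r}")
    return v


def _parse_row(row: pd.Series, idx: int) -> Audiogram:
    try:
        age = float(row["age"])
    except (TypeError, ValueError):
        raise DatasetError(f"row {idx}: malformed age {row['age']!r}")
    if not np.isfinite(age):
        raise DatasetError(f"row {idx}: malformed age {row['age']!r}")
    thr: dict[int, float] = {}
    for f in FREQUENCIES:
        raw = row[f"thr_{f}"]
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
            continue
        try:
            thr[f] = float(raw)
        except (TypeError, ValueError):
            raise DatasetError(f"row {idx}: malformed threshold {raw!r} at {f} Hz")
    region = row.get("region")
    gene = row.get("gene")
    return Audiogram(
        patient_id=str(row["patient_id"]),
        audiogram_id=str(row["audiogram_id"]),
        age=age,
        thresholds=thr,
        region=None if pd.isna(region) or region == "" else str(region),
        gene=None if pd.isna(gene) or gene == "" else str(gene),
    )


def read_dataset(path) -> list[PatientRecord]:
    """Read the canonical CSV schema into patient bags.

    Rows are grouped by ``patient_id``; within a patient, audiograms are
    ordered by age ascending with ties broken by ``audiogram_id``.
    Grouping is a partition: every row lands in exactly one record.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "audiogram_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing columns: {missing}")
    if df["audiogram_id"].duplicated().any():
        dups = df.loc[df["audiogram_id"].duplicated(), "audiogram_id"].tolist()
        raise DatasetError(f"duplicate audiogram_id values: {dups}")
    records: dict[str, list[Audiogram]] = {}
    for idx, row in df.iterrows():
        a = _parse_row(row, int(idx) + 2)  # +2: header line + 1-based
        records.setdefault(a.patient_id, []).append(a)
    out: list[PatientRecord] = []
    for pid, bag in records.items():
        bag.sort(key=lambda a: (a.age, a.audiogram_id))
        genes = {a.gene for a in bag if a.gene is not None}
        if len(genes) > 1:
            raise DatasetError(f"patient {pid!r}: conflicting gene labels {sorted(genes)}")
        out.append(PatientRecord(pid, bag, gene=genes.pop() if genes else None))
    return out


def write_dataset(records: Iterable[PatientRecord], path) -> None:
    """Write records in the canonical CSV schema (round-trips with read)."""
    rows = []
    for r in records:
        for a in r.audiograms:
            row = {
                "patient_id": a.patient_id,
                "audiogram_id": a.audiogram_id,
                "age": a.age,
                "region": a.region if a.region is not None else "",
                "gene": (a.gene if a.gene is not None else (r.gene or "")),
            }
            for f in FREQUENCIES:
                row[f"thr_{f}"] = a.thresholds.get(f, "")
            rows.append(row)
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def iter_audiograms(records: Iterable[PatientRecord]) -> Iterable[tuple[PatientRecord, Audiogram]]:
    for r in records:
        for a in r.audiograms:
            yield r, a
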