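"""Dataset-level procedures: common-spacing selection and weak-pair formation.

Cohorts of CT/CBCT scans come with heterogeneous voxel spacings; to minimise
interpolation, all scans are resampled to the *most frequent* spacing in the
cohort, ties broken toward the smaller spacing.  For quantitative evaluation
of unpaired translation, "weak pairs" are formed: per patient, the CT and
CBCT acquired closest together in time, and no more than one calendar day
apart (larger gaps risk real anatomical change).  Deformable registration of
the paired CT onto the CBCT is deliberately delegated to external tooling;
this module emits the machine-readable pair manifest that drives it.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ScanRecord",
    "SpacingTable",
    "WeakPair",
    "select_common_spacing",
    "select_weak_pairs",
    "read_metadata_csv",
    "pairs_to_dataframe",
]


@dataclass(frozen=True)
class ScanRecord:
    """One row of scan bookkeeping metadata."""

    patient_id: str
    modality: str  # "CT" | "CBCT"
    acquisition_date: _dt.date
    path: str

    def __post_init__(self):
        if self.modality not in ("CT", "CBCT"):
            raise ValueError(f"modality must be CT or CBCT, got {self.modality!r}")


@dataclass(frozen=True)
class SpacingTable:
    """Frequency counts of (x, y, z) spacings across a cohort."""

    entries: tuple  # of ((sx, sy, sz), count)

    def __post_init__(self):
        for spacing, count in self.entries:
            if count <= 0:
                raise ValueError(f"counts must be positive, got {count} for {spacing}")
            if any(s <= 0 for s in spacing):
                raise ValueError(f"spacings must be positive, got {spacing}")

    @classmethod
    def from_counts(cls, counts: dict) -> "SpacingTable":
        return cls(tuple((tuple(float(s) for s in k), int(v)) for k, v in counts.items()))


@dataclass(frozen=True)
class WeakPair:
    ct: ScanRecord
    cbct: ScanRecord
    delta_days: int

    def __post_init__(self):
        if self.ct.patient_id != self.cbct.patient_id:
            raise ValueError("weak pair must join scans of the same patient")
        if not 0 <= self.delta_days <= 1:
            raise ValueError(f"weak pair time delta must be <= 1 day, got {self.delta_days}")


def select_common_spacing(table: SpacingTable) -> tuple:
    """The most frequent spacing; ties broken toward the smaller spacing.

    Spacings are sorted ascending, so among equal counts the smallest wins —
    the reading that minimises interpolation for the majority of the cohort.
    """
    if not table.entries:
        raise ValueError("spacing table is empty")
    ordered = sorted(table.entries, key=lambda e: e[0])
    best = max(ordered, key=lambda e: e[1])  # first max in ascending spacing order
    return best[0]


def _parse_date(value, context: str) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"malformed date {value!r} in record {context}") from exc


def select_weak_pairs(records: list[ScanRecord]) -> list[WeakPair]:
    """Per patient, the (CT, CBCT) pair with minimal calendar-day gap among
    pairs at most one day apart; ties broken by earlier CT date, then earlier
    CBCT date.  Patients with no qualifying pair yield nothing."""
    by_patient: dict[str, dict[str, list[ScanRecord]]] = {}
    for rec in records:
        date = _parse_date(rec.acquisition_date, f"{rec.patient_id}/{rec.path}")
        if date is not rec.acquisition_date:
            rec = ScanRecord(rec.patient_id, rec.modality, date, rec.path)
        by_patient.setdefault(rec.patient_id, {"CT": [], "CBCT": []})[rec.modality].append(rec)

    pairs = []
    for pid in sorted(by_patient):
        cts = by_patient[pid]["CT"]
        cbcts = by_patient[pid]["CBCT"]
        best = None
        for ct in cts:
            for cb in cbcts:
                delta = abs((ct.acquisition_date - cb.acquisition_date).days)
                if delta > 1:
                    continue
                key = (delta, ct.acquisition_date, cb.acquisition_date)
                if best is None or key < best[0]:
                    best = (key, WeakPair(ct, cb, delta))
        if best is not None:
            pairs.append(best[1])
    return pairs


def read_metadata_csv(path) -> list[ScanRecord]:
    """Load scan records from a CSV with columns patient_id, modality, date, path."""
    df = pd.read_csv(path, dtype=str)
    required = {"patient_id", "modality", "date", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    return [
        ScanRecord(
            patient_id=row.patient_id,
            modality=row.modality,
            acquisition_date=_parse_date(row.date, f"{row.patient_id}/{row.path}"),
            path=row.path,
        )
        for row in df.itertuples()
    ]


def pairs_to_dataframe(pairs: list[WeakPair]) -> pd.DataFrame:
    """Weak pairs as the manifest consumed by registration / evaluation."""
    return pd.DataFrame(
        [(p.ct.patient_id, p.ct.path, p.cbct.path, p.delta_days) for p in pairs],
        columns=["patient_id", "ct_path", "cbct_path", "delta_days"],
    )
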