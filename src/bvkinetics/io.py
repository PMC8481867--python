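"""CSV/JSON artifact I/O.

Subject time series travel as CSV with the fixed header
``t_min,infusion_ml_min,hemorrhage_ml_min,delta_vb_ml`` (missing ΔV_B values
mark prediction-only rows).  Protocols, which the rate samples alone cannot
encode losslessly, travel as JSON segment lists; a cohort is one CSV per
subject plus a manifest JSON holding ids, weights, protocols, seeds, true
parameters and mismatch tags.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .model import InputProtocol, ModelParams

__all__ = [
    "SUBJECT_CSV_HEADER",
    "read_subject_csv",
    "write_subject_csv",
    "protocol_to_json",
    "protocol_from_json",
    "write_cohort",
    "read_cohort",
]

SUBJECT_CSV_HEADER = ["t_min", "infusion_ml_min", "hemorrhage_ml_min", "delta_vb_ml"]


def write_subject_csv(record: SubjectRecord, path: str | Path) -> None:
    """Write the measured series with protocol rates sampled at measurement
    times.  The rates column is informational; the exact protocol lives in
    the manifest/protocol JSON."""
    u, v = record.protocol.rates_at(record.measurement_times)
    pd.DataFrame(
        {
            "t_min": record.measurement_times,
            "infusion_ml_min": u,
            "hemorrhage_ml_min": v,
            "delta_vb_ml": record.measured_delta_vb,
        }
    ).to_csv(path, index=False)


def read_subject_csv(path: str | Path) -> pd.DataFrame:
    """Read a subject series CSV, validating header and time monotonicity.

    Returns the table as a DataFrame; ``delta_vb_ml`` may contain NaN for
    prediction-only rows.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != SUBJECT_CSV_HEADER:
        raise ValueError(
            f"malformed header in {path}: expected {','.join(SUBJECT_CSV_HEADER)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    if len(df) == 0:
        raise ValueError(f"empty data section in {path} (line 2)")
    t = df["t_min"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 3  # 1-based line after header
        raise ValueError(f"non-monotone time in {path} at line {bad}")
    return df


def protocol_to_json(protocol: InputProtocol) -> list[dict]:
    return [
        {"t_start": t0, "t_end": t1, "infusion_ml_min": u, "hemorrhage_ml_min": v}
        for t0, t1, u, v in protocol.segments
    ]


def protocol_from_json(data: list[dict]) -> InputProtocol:
    return InputProtocol(
        [(d["t_start"], d["t_end"], d["infusion_ml_min"], d["hemorrhage_ml_min"]) for d in data]
    )


def write_cohort(records: list[SubjectRecord], directory: str | Path) -> Path:
    """Write one CSV per subject plus ``manifest.json``; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in records:
        csv_path = directory / f"{rec.subject_id}.csv"
        write_subject_csv(rec, csv_path)
        entry = {
            "subject_id": rec.subject_id,
            "weight_kg": rec.weight_kg,
            "csv": csv_path.name,
            "protocol": protocol_to_json(rec.protocol),
            "mismatch_tag": rec.mismatch_tag,
            "mismatch_values": rec.mismatch_values,
        }
        if rec.true_params is not None:
            entry["true_params"] = {
                "alpha_u": rec.true_params.alpha_u,
                "alpha_v": rec.true_params.alpha_v,
                "k_p": rec.true_params.k_p,
            }
        manifest.append(entry)
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_cohort(directory: str | Path) -> list[SubjectRecord]:
    """Rebuild SubjectRecords from a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    records = []
    for entry in manifest:
        df = read_subject_csv(directory / entry["csv"])
        tp = entry.get("true_params")
        records.append(
            SubjectRecord(
                subject_id=entry["subject_id"],
                weight_kg=entry["weight_kg"],
                protocol=protocol_from_json(entry["protocol"]),
                measurement_times=df["t_min"].to_numpy(float),
                measured_delta_vb=df["delta_vb_ml"].to_numpy(float),
                true_params=ModelParams(**tp) if tp else None,
                mismatch_tag=entry.get("mismatch_tag", "none"),
                mismatch_values=entry.get("mismatch_values", {}),
            )
        )
    return records
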