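"""CSV readers/writers for the two file schemas the pipeline exchanges.

Samples CSV: ``subject_id,group,ventricle,thickness_mm,dolp`` — one tissue
specimen per row; ``thickness_mm`` may be empty for records whose thickness
was never recorded.  Sweep CSV: ``angle_deg,voltage_mv`` — one polarizer
position per row.  Both are UTF-8 with '.' decimal separators.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cohort import TissueSample
from .sweep import AngularSweep, SweepReduction

__all__ = [
    "read_samples",
    "write_samples",
    "read_sweep",
    "write_sweep",
    "write_reduced",
]

SAMPLES_COLUMNS = ["subject_id", "group", "ventricle", "thickness_mm", "dolp"]
SWEEP_COLUMNS = ["angle_deg", "voltage_mv"]
REDUCED_COLUMNS = ["sample_id", "s1", "s2", "s3", "dolp", "r2", "residual_rms"]


class SchemaError(ValueError):
    """A file does not conform to its CSV schema."""


def _check_header(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    if list(df.columns) != list(expected):
        raise SchemaError(
            f"{path}: expected header {','.join(expected)}, "
            f"got {','.join(map(str, df.columns))}"
        )


def read_samples(path) -> list[TissueSample]:
    """Read and validate a samples CSV; malformed rows are reported with
    their 1-based file line numbers (header is line 1)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df, SAMPLES_COLUMNS, path)
    samples: list[TissueSample] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            raw_t = row["thickness_mm"].strip()
            thickness = float(raw_t) if raw_t else None
            if thickness is not None and math.isnan(thickness):
                raise ValueError("thickness_mm is NaN")
            samples.append(
                TissueSample(
                    subject_id=row["subject_id"].strip(),
                    group=row["group"].strip(),
                    ventricle=row["ventricle"].strip(),
                    thickness_mm=thickness,
                    dolp=float(row["dolp"]),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise SchemaError(f"{path}: " + "; ".join(errors))
    return samples


def write_samples(samples: Iterable[TissueSample], path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "ventricle": s.ventricle,
            "thickness_mm": "" if s.thickness_mm is None else repr(s.thickness_mm),
            "dolp": repr(s.dolp),
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=SAMPLES_COLUMNS).to_csv(path, index=False)


def read_sweep(path, sample_id: str | None = None) -> AngularSweep:
    """Read one angular sweep; duplicate angles are rejected."""
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(df, SWEEP_COLUMNS, path)
    angles = df["angle_deg"].astype(float).tolist()
    if len(set(angles)) != len(angles):
        raise SchemaError(f"{path}: duplicate angles in sweep")
    return AngularSweep(
        tuple(angles),
        tuple(df["voltage_mv"].astype(float)),
        sample_id if sample_id is not None else path.stem,
    )


def write_sweep(sweep: AngularSweep, path) -> None:
    pd.DataFrame(
        {"angle_deg": sweep.angles_deg, "voltage_mv": sweep.voltages_mv}
    ).to_csv(path, index=False)


def write_reduced(
    reductions: Iterable[tuple[str, SweepReduction]], path
) -> None:
    """Write reduced sweeps as ``sample_id,s1,s2,s3,dolp,r2,residual_rms``."""
    rows = [
        {
            "sample_id": sid,
            "s1": red.stokes.s1,
            "s2": red.stokes.s2,
            "s3": red.stokes.s3,
            "dolp": red.dolp,
            "r2": red.r2,
            "residual_rms": red.residual_rms,
        }
        for sid, red in reductions
    ]
    pd.DataFrame(rows, columns=REDUCED_COLUMNS).to_csv(path, index=False)
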