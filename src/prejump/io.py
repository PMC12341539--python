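"""CSV/YAML input and output with fail-fast validation.

Cohort tables are plain UTF-8 CSV (header row, comma separator, decimal
point); reading then writing round-trips values at full precision
(``repr``-level float formatting).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import CohortParseError
from .synthetic_cohort import CohortMatrix, MomentSpec

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_moment_spec",
    "write_report",
]


def read_cohort(path: str | Path, criterion: str) -> CohortMatrix:
    """Read a cohort CSV, naming the offending row/column on any defect."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortParseError(f"{path}: file is empty") from exc
    cols = list(frame.columns)
    if len(cols) != len(set(cols)) or any(c.endswith(".1") for c in cols):
        raise CohortParseError(f"{path}: duplicate column names in header")
    for col in cols:
        series = pd.to_numeric(frame[col], errors="coerce")
        bad = series.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise CohortParseError(
                f"{path}: non-numeric value {frame[col][bad.idxmax()]!r} "
                f"at row {row}, column {col!r}"
            )
        missing = series.isna()
        if missing.any():
            row = int(missing.idxmax()) + 2
            raise CohortParseError(f"{path}: empty cell at row {row}, column {col!r}")
        frame[col] = series.astype(float)
    return CohortMatrix(frame=frame, criterion=criterion)


def write_cohort(cohort: CohortMatrix, path: str | Path) -> Path:
    """Write a cohort CSV at full float precision (round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.frame.to_csv(path, index=False, float_format=None)
    return path


def read_moment_spec(path: str | Path) -> MomentSpec:
    """Read a moment specification from YAML or JSON."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return MomentSpec.from_dict(payload)


def write_report(tables: dict[str, pd.DataFrame], directory: str | Path) -> list[Path]:
    """Write each named table as <name>.csv under the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        out = directory / f"{name}.csv"
        table.to_csv(out, index=False)
        written.append(out)
    return written
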