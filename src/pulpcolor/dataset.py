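"""Per-fruit replicate tables: the in-memory container and its CSV layout.

A :class:`FruitDataset` holds the replicate-level rows for one fruit and one
analyte (TAC, TCC or TPC): sample id, replicate id, the (L*, a*, b*) pulp
color, the measured content, and an optional outlier flag used by the
synthetic generator.  On disk the exchange format is a plain CSV with header
``fruit,sample_id,replicate,L,a,b,analyte,content,is_outlier``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .colorimetry import ColorTriplet
from .exceptions import SchemaError, ValidationError

ANALYTES = ("TAC", "TCC", "TPC")

#: Columns every sample CSV must carry; ``is_outlier`` is optional.
CSV_COLUMNS = (
    "fruit",
    "sample_id",
    "replicate",
    "L",
    "a",
    "b",
    "analyte",
    "content",
)

_FRAME_COLUMNS = ["sample_id", "replicate", "L", "a", "b", "content", "is_outlier"]


@dataclass
class FruitDataset:
    """Replicate rows for one fruit x analyte combination.

    The backing frame has columns ``sample_id, replicate, L, a, b, content,
    is_outlier``.  At least 5 rows are required to fit the 4-parameter
    linear color model downstream.
    """

    fruit_label: str
    analyte: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValidationError(
                f"analyte must be one of {ANALYTES}, got {self.analyte!r}"
            )
        frame = self.frame.copy()
        if "is_outlier" not in frame.columns:
            frame["is_outlier"] = False
        missing = [c for c in _FRAME_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"dataset frame missing columns {missing}")
        frame = frame[_FRAME_COLUMNS].reset_index(drop=True)
        bad = frame.index[(frame["L"] < 0) | (frame["L"] > 100)].tolist()
        if bad:
            raise ValidationError(
                f"L* out of [0, 100] in rows {bad} of {self.fruit_label!r}"
            )
        self.frame = frame

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def design_matrix(self) -> np.ndarray:
        """n x 4 matrix [1, L*, a*, b*]."""
        n = self.n_rows
        return np.column_stack(
            [np.ones(n), self.frame["L"], self.frame["a"], self.frame["b"]]
        )

    @property
    def response(self) -> np.ndarray:
        return self.frame["content"].to_numpy(dtype=float)

    def mean_color(self) -> ColorTriplet:
        return ColorTriplet(
            float(self.frame["L"].mean()),
            float(self.frame["a"].mean()),
            float(self.frame["b"].mean()),
        )

    def subset(self, indices) -> "FruitDataset":
        """New dataset restricted to the given positional indices."""
        return FruitDataset(
            self.fruit_label,
            self.analyte,
            self.frame.iloc[np.asarray(indices, dtype=int)].reset_index(drop=True),
        )

    def to_records(self) -> pd.DataFrame:
        out = self.frame.copy()
        out.insert(0, "fruit", self.fruit_label)
        out.insert(6, "analyte", self.analyte)
        return out


def write_samples_csv(datasets: list[FruitDataset], path: str | Path) -> None:
    """Write one or more datasets to the standard sample CSV layout."""
    pd.concat([d.to_records() for d in datasets], ignore_index=True).to_csv(
        path, index=False
    )


def read_samples_csv(path: str | Path) -> list[FruitDataset]:
    """Read a sample CSV into one dataset per (fruit, analyte) group.

    Raises :class:`SchemaError` on missing columns or an empty file and
    :class:`ValidationError` listing 1-based line numbers for malformed
    rows (non-numeric fields, L* outside [0, 100], unknown analyte).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty") from None
    missing = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path} missing required columns {missing}")
    if raw.empty:
        raise SchemaError(f"{path} has a header but no data rows")

    issues: list[str] = []
    numeric = {}
    for col in ("L", "a", "b", "content"):
        numeric[col] = pd.to_numeric(raw[col], errors="coerce")
    for idx in raw.index:
        line = idx + 2  # header is line 1
        problems = [c for c in numeric if np.isnan(numeric[c][idx])]
        if problems:
            issues.append(f"line {line}: non-numeric {problems}")
            continue
        if not 0 <= numeric["L"][idx] <= 100:
            issues.append(f"line {line}: L*={numeric['L'][idx]} outside [0, 100]")
        if raw.loc[idx, "analyte"] not in ANALYTES:
            issues.append(f"line {line}: unknown analyte {raw.loc[idx, 'analyte']!r}")
    if issues:
        raise ValidationError("malformed rows: " + "; ".join(issues))

    for col in ("L", "a", "b", "content"):
        raw[col] = numeric[col]
    if "is_outlier" not in raw.columns:
        raw["is_outlier"] = False

    datasets = []
    for (fruit, analyte), group in raw.groupby(["fruit", "analyte"], sort=True):
        datasets.append(FruitDataset(str(fruit), str(analyte), group))
    return datasets
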