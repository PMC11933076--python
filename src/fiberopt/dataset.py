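"""Formulation table container and CSV I/O.

A :class:`NanofiberDataset` holds the feature matrix (n x 12, original
units), the label matrix (n x 4) and a boolean missing-cell mask over the
features.  Missing values are encoded on disk as *empty* CSV cells only;
literal "NA"/"NaN" strings are rejected so the dialect stays unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    FEATURE_SCHEMA,
    FEATURES,
    LABELS,
    LABEL_BOUNDS,
    SCHEMA_BY_NAME,
    FeatureSchema,
)

ALL_COLUMNS: tuple[str, ...] = FEATURES + LABELS


class SchemaError(ValueError):
    """A CSV does not match the fixed column schema."""


class ParseError(ValueError):
    """A CSV cell cannot be interpreted as a number."""


@dataclass
class NanofiberDataset:
    """Feature/label matrices plus missing-cell mask, in original units.

    ``features`` and ``labels`` are pandas DataFrames sharing a RangeIndex;
    missing feature cells are NaN and mirrored in ``missing_mask``.  Labels
    may be NaN for rows where an outcome was not reported, but are never
    treated as imputable.
    """

    features: pd.DataFrame
    labels: pd.DataFrame
    schema: tuple[FeatureSchema, ...] = field(default=FEATURE_SCHEMA)

    def __post_init__(self) -> None:
        if tuple(self.features.columns) != FEATURES:
            raise SchemaError(
                f"feature columns must be {list(FEATURES)}, "
                f"got {list(self.features.columns)}"
            )
        if tuple(self.labels.columns) != LABELS:
            raise SchemaError(
                f"label columns must be {list(LABELS)}, got {list(self.labels.columns)}"
            )
        if len(self.features) != len(self.labels):
            raise SchemaError("feature and label row counts differ")
        self.features = self.features.reset_index(drop=True).astype(float)
        self.labels = self.labels.reset_index(drop=True).astype(float)

    @property
    def n_rows(self) -> int:
        return len(self.features)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask over feature cells; True where the value is absent."""
        return self.features.isna()

    def copy(self) -> "NanofiberDataset":
        return NanofiberDataset(self.features.copy(), self.labels.copy(), self.schema)

    def equals(self, other: "NanofiberDataset") -> bool:
        return self.features.equals(other.features) and self.labels.equals(other.labels)


def load_dataset(path: str | Path) -> NanofiberDataset:
    """Read a formulation CSV, mapping empty cells to missing.

    Raises :class:`SchemaError` naming the first absent required column and
    :class:`ParseError` with (row, column) coordinates for any cell that is
    neither empty nor numeric (including literal "NA"/"NaN" strings).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ALL_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} is missing from {path}")
    extra = [c for c in raw.columns if c not in ALL_COLUMNS]
    if extra:
        raise SchemaError(f"unexpected columns {extra} in {path}")

    parsed = {}
    for col in ALL_COLUMNS:
        vals = []
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell == "":
                vals.append(math.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"non-numeric cell {cell!r} at row {i}, column {col!r}"
                ) from None
        parsed[col] = vals
    frame = pd.DataFrame(parsed)
    return NanofiberDataset(frame[list(FEATURES)], frame[list(LABELS)])


def write_dataset(ds: NanofiberDataset, path: str | Path) -> None:
    """Write the dataset as UTF-8 CSV; missing cells become empty cells.

    Floats are written with shortest round-trip repr so write/load is the
    identity on values and mask.
    """
    frame = pd.concat([ds.features, ds.labels], axis=1)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, na_rep="")


def validate_bounds(
    ds: NanofiberDataset, label_bounds: dict[str, tuple[float, float]] | None = None
) -> list[tuple[int, str, float]]:
    """Report every observed cell outside its column's closed bounds.

    Returns (row, column, value) triples; an empty list means the dataset is
    valid.  Bounds are inclusive at both ends.  Row permutations permute but
    never change the violation set.
    """
    label_bounds = label_bounds or LABEL_BOUNDS
    violations: list[tuple[int, str, float]] = []
    for col in FEATURES:
        lo, hi = SCHEMA_BY_NAME[col].bounds
        vals = ds.features[col]
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        violations.extend((int(i), col, float(vals[i])) for i in np.flatnonzero(bad))
    for col in LABELS:
        lo, hi = label_bounds[col]
        vals = ds.labels[col]
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        violations.extend((int(i), col, float(vals[i])) for i in np.flatnonzero(bad))
    return violations
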