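"""Central dataset container for cell-level multiplexed-imaging intensities.

A *cell table* is a long-format :class:`pandas.DataFrame` with one row per
segmented cell: a slide identifier, an image identifier (images nest in
slides), one nonnegative numeric column per marker channel, and any number
of metadata columns. :class:`MxDataset` bundles the raw table with the
column-role assignments, an optional normalized table, normalization
provenance, and the result tables attached by the analysis functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MxDataset",
    "create_dataset",
    "MxDatasetError",
    "MissingColumnError",
    "MarkerTypeError",
    "NegativeValueError",
    "NestingError",
]


class MxDatasetError(ValueError):
    """Base class for dataset construction/validation failures."""


class MissingColumnError(MxDatasetError):
    """A named column is absent from the input table."""


class MarkerTypeError(MxDatasetError):
    """A marker column is not numeric (or contains missing values)."""


class NegativeValueError(MxDatasetError):
    """A raw marker column contains negative values."""


class NestingError(MxDatasetError):
    """An image identifier occurs under more than one slide."""


TABLE_CHOICES = ("raw", "normalized", "both")


@dataclass
class MxDataset:
    """Validated container used throughout the normalization workflow.

    Attributes
    ----------
    data:
        Raw cell table (never mutated by any operation).
    slide_id, image_id:
        Names of the identifier columns.
    marker_cols, metadata_cols:
        Ordered column-role assignments.
    norm_data:
        Normalized cell table; ``None`` until :func:`~slidenorm.normalization.normalize`
        has been run. Shares row count, row order, ids and metadata with ``data``.
    transform, method:
        Normalization provenance, ``"None"`` until normalization runs.
    discordance, umap, var_props:
        Result tables attached by the analysis functions, ``None`` until run.
    """

    data: pd.DataFrame
    slide_id: str
    image_id: str
    marker_cols: list[str]
    metadata_cols: list[str] = field(default_factory=list)
    norm_data: Optional[pd.DataFrame] = None
    transform: str = "None"
    method: str = "None"
    discordance: Optional[pd.DataFrame] = None
    umap: Optional[pd.DataFrame] = None
    var_props: Optional[pd.DataFrame] = None

    # -- accessors ---------------------------------------------------------

    @property
    def slides(self) -> list[str]:
        return list(pd.unique(self.data[self.slide_id]))

    def table(self, which: str) -> pd.DataFrame:
        """Return the ``"raw"`` or ``"normalized"`` cell table."""
        if which == "raw":
            return self.data
        if which == "normalized":
            if self.norm_data is None:
                raise MxDatasetError(
                    "normalized table requested but normalization has not been run"
                )
            return self.norm_data
        raise MxDatasetError(f"unknown table selector {which!r}; use 'raw' or 'normalized'")

    def resolve_tables(self, selector: str) -> list[str]:
        """Expand a table selector ('raw'/'normalized'/'both') to table names."""
        if selector not in TABLE_CHOICES:
            raise MxDatasetError(
                f"table selector must be one of {TABLE_CHOICES}, got {selector!r}"
            )
        names = ["raw", "normalized"] if selector == "both" else [selector]
        if "normalized" in names and self.norm_data is None:
            raise MxDatasetError(
                f"table={selector!r} requires normalization to have been run first"
            )
        return names

    def with_(self, **changes) -> "MxDataset":
        """Return a shallow copy with the given fields replaced."""
        return replace(self, **changes)


def _check_unique(names: Sequence[str], what: str) -> None:
    seen = pd.Index(names)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise MxDatasetError(f"duplicate {what}: {dupes}")


def create_dataset(
    data: pd.DataFrame,
    slide_id: str,
    image_id: str,
    marker_cols: Sequence[str],
    metadata_cols: Sequence[str] = (),
) -> MxDataset:
    """Validate a long-format cell table and wrap it in an :class:`MxDataset`.

    Parameters
    ----------
    data:
        One row per cell. Input row order is preserved and treated as
        significant throughout the pipeline.
    slide_id, image_id:
        Identifier column names; values are coerced to strings so numeric
        slide labels cannot be accidentally treated as quantities.
    marker_cols:
        At least one numeric, nonnegative intensity column.
    metadata_cols:
        Optional additional columns carried (not modeled) through the pipeline.

    Raises
    ------
    MissingColumnError, MarkerTypeError, NegativeValueError, NestingError
    """
    marker_cols = list(marker_cols)
    metadata_cols = list(metadata_cols)
    if not marker_cols:
        raise MxDatasetError("at least one marker column is required")

    wanted = [slide_id, image_id, *marker_cols, *metadata_cols]
    _check_unique(wanted, "column assignment")
    missing = [c for c in wanted if c not in data.columns]
    if missing:
        raise MissingColumnError(f"columns not found in input table: {missing}")
    _check_unique(list(data.columns), "column name in input table")

    df = data.copy()
    for col in (slide_id, image_id):
        if df[col].isna().any():
            n = int(df[col].isna().sum())
            raise MxDatasetError(f"identifier column {col!r} has {n} missing values")
        df[col] = df[col].astype(str)

    for col in marker_cols:
        try:
            values = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise MarkerTypeError(f"marker column {col!r} is not numeric: {exc}") from exc
        if values.isna().any():
            n = int(values.isna().sum())
            raise MarkerTypeError(f"marker column {col!r} has {n} missing values")
        arr = values.to_numpy(dtype=float)
        if (arr < 0).any():
            n = int((arr < 0).sum())
            raise NegativeValueError(
                f"marker column {col!r} has {n} negative raw values; raw intensities must be >= 0"
            )
        df[col] = arr

    # images must nest in slides
    n_parents = df.groupby(image_id, observed=True)[slide_id].nunique()
    bad = n_parents[n_parents > 1]
    if len(bad):
        raise NestingError(
            f"image ids occurring in more than one slide: {bad.index.tolist()}"
        )
    if df.shape[0] == 0:
        raise MxDatasetError("input table has no rows")

    df = df.reset_index(drop=True)
    return MxDataset(
        data=df,
        slide_id=slide_id,
        image_id=image_id,
        marker_cols=marker_cols,
        metadata_cols=metadata_cols,
    )


def validate_normalized(dataset: MxDataset, norm: pd.DataFrame) -> pd.DataFrame:
    """Check a candidate normalized table against the shape contract.

    The normalized table must have the same row count and order, identical
    id and metadata columns, and numeric marker columns. Negative marker
    values are permitted (some adjustments legitimately produce them).
    """
    raw = dataset.data
    required = [dataset.slide_id, dataset.image_id, *dataset.marker_cols, *dataset.metadata_cols]
    missing = [c for c in required if c not in norm.columns]
    if missing:
        raise MxDatasetError(f"normalized table is missing columns: {missing}")
    if len(norm) != len(raw):
        raise MxDatasetError(
            f"normalized table has {len(norm)} rows, raw has {len(raw)}"
        )
    norm = norm.reset_index(drop=True)
    for col in (dataset.slide_id, dataset.image_id, *dataset.metadata_cols):
        if not norm[col].reset_index(drop=True).equals(raw[col]):
            raise MxDatasetError(
                f"normalized table altered non-marker column {col!r}"
            )
    for col in dataset.marker_cols:
        arr = pd.to_numeric(norm[col], errors="coerce").to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise MxDatasetError(f"normalized marker column {col!r} has missing/non-numeric values")
        norm[col] = arr
    return norm[list(raw.columns)]
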