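"""Reading, writing and cropping of SMLM localization tables.

A localization table is the basic currency of the package: one row per
detected blink, coordinates in nanometres, with optional frame index and
per-event localization precision. Readers convert units so that everything
downstream works in nm; the input row order is preserved and used as the
stable localization index by every other module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LocalizationTable",
    "read_localizations",
    "crop_roi",
    "write_table",
    "write_blob_assignments",
    "write_feature_matrix",
    "FormatError",
]

#: column maps for the supported text dialects
_DIALECTS = {
    "generic_xy": {"x": "x", "y": "y"},
    "generic_xyz": {"x": "x", "y": "y", "z": "z"},
    "thunderstorm_csv": {
        "x": "x [nm]",
        "y": "y [nm]",
        "z": "z [nm]",
        "frame": "frame",
        "precision": "uncertainty [nm]",
    },
}


class FormatError(ValueError):
    """Raised when an input file does not match the requested dialect."""


@dataclass(frozen=True)
class LocalizationTable:
    """An immutable table of localization events in nanometres.

    Parameters
    ----------
    coords : (n, d) float array
        Event positions in nm, d in {2, 3}.
    frame : optional (n,) int array
        Acquisition frame per event.
    precision_nm : optional (n,) float array
        Per-event localization precision.
    roi : (d, 2) float array
        Axis-aligned region of interest, ``roi[k] = (min_k, max_k)`` in nm.
        Defaults to the data bounding box.
    """

    coords: np.ndarray
    frame: Optional[np.ndarray] = None
    precision_nm: Optional[np.ndarray] = None
    roi: Optional[np.ndarray] = field(default=None)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] not in (2, 3):
            raise ValueError("coords must be an (n, 2) or (n, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        if self.frame is not None:
            object.__setattr__(self, "frame", np.asarray(self.frame, dtype=int))
        if self.precision_nm is not None:
            object.__setattr__(
                self, "precision_nm", np.asarray(self.precision_nm, dtype=float)
            )
        roi = self.roi
        if roi is None:
            roi = self.bounding_box()
        else:
            roi = np.asarray(roi, dtype=float)
            if roi.shape != (coords.shape[1], 2):
                raise ValueError("roi must have shape (d, 2)")
            if np.any(roi[:, 0] > roi[:, 1]):
                raise ValueError("roi bounds must satisfy min <= max per axis")
        object.__setattr__(self, "roi", roi)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n

    def bounding_box(self) -> np.ndarray:
        """Axis-aligned data bounding box, (d, 2). Zero box for empty tables."""
        if self.n == 0:
            return np.zeros((self.coords.shape[1], 2))
        return np.stack(
            [self.coords.min(axis=0), self.coords.max(axis=0)], axis=1
        )

    def roi_measure(self) -> float:
        """Area (2D, nm^2) or volume (3D, nm^3) of the ROI box."""
        return float(np.prod(self.roi[:, 1] - self.roi[:, 0]))

    def subset(self, mask_or_indices) -> "LocalizationTable":
        """Row subset preserving metadata and the current ROI."""
        idx = np.asarray(mask_or_indices)
        return LocalizationTable(
            coords=self.coords[idx],
            frame=None if self.frame is None else self.frame[idx],
            precision_nm=None
            if self.precision_nm is None
            else self.precision_nm[idx],
            roi=self.roi,
        )

    def with_roi(self, roi) -> "LocalizationTable":
        return replace(self, roi=np.asarray(roi, dtype=float))


def _find_column(df: pd.DataFrame, name: str) -> str:
    for col in df.columns:
        if str(col).strip().lower() == name.strip().lower():
            return col
    raise FormatError(f"required coordinate column {name!r} not found "
                      f"(columns present: {list(df.columns)})")


def read_localizations(
    path,
    dialect: str = "generic_xy",
    unit: str = "nm",
    pixel_size: Optional[float] = None,
) -> LocalizationTable:
    """Read a delimited-text localization list into a :class:`LocalizationTable`.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file; the delimiter is auto-detected.
    dialect : {"generic_xy", "generic_xyz", "thunderstorm_csv"}
        Column-naming convention of the file.
    unit : {"nm", "px"}
        Unit of the coordinate columns. ``"px"`` requires ``pixel_size`` (nm).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; "
                         f"choose from {sorted(_DIALECTS)}")
    if unit not in ("nm", "px"):
        raise ValueError("unit must be 'nm' or 'px'")
    if unit == "px" and (pixel_size is None or pixel_size <= 0):
        raise ValueError("unit='px' requires a positive pixel_size in nm")

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python")

    colmap = _DIALECTS[dialect]
    axes = ["x", "y"] + (["z"] if "z" in colmap else [])
    # z is optional in the thunderstorm dialect (2D exports omit it)
    if dialect == "thunderstorm_csv":
        axes = ["x", "y"]
        if any(str(c).strip().lower() == colmap["z"].lower() for c in df.columns):
            axes.append("z")

    cols = []
    for axis in axes:
        col = _find_column(df, colmap[axis])
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[values.isna() & df[col].notna()]
        if len(bad) > 0:
            raise FormatError(
                f"non-numeric value in column {col!r} at row {int(bad[0])}"
            )
        if values.isna().any():
            row = int(values.index[values.isna()][0])
            raise FormatError(f"missing value in column {col!r} at row {row}")
        cols.append(values.to_numpy(dtype=float))
    coords = np.column_stack(cols)
    if unit == "px":
        coords = coords * float(pixel_size)

    frame = precision = None
    if dialect == "thunderstorm_csv":
        for key, attr in (("frame", "frame"), ("precision", "precision")):
            try:
                col = _find_column(df, colmap[key])
            except FormatError:
                continue
            if key == "frame":
                frame = pd.to_numeric(df[col], errors="coerce").to_numpy()
                frame = frame.astype(int)
            else:
                precision = pd.to_numeric(df[col], errors="coerce").to_numpy(
                    dtype=float
                )
    return LocalizationTable(coords=coords, frame=frame, precision_nm=precision)


def crop_roi(table: LocalizationTable, bounds) -> LocalizationTable:
    """Crop to the half-open axis-aligned box ``[min, max)`` per axis.

    An empty result is legal. The result's ROI is set to ``bounds``.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.shape != (table.dim, 2):
        raise ValueError(f"bounds must have shape ({table.dim}, 2)")
    if np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("bounds must satisfy min < max per axis")
    mask = np.all(
        (table.coords >= bounds[:, 0]) & (table.coords < bounds[:, 1]), axis=1
    )
    return table.subset(mask).with_roi(bounds)


def write_table(table: LocalizationTable, path) -> None:
    """Write a localization table as CSV (columns x, y[, z], frame, precision_nm)."""
    cols = {}
    names = ["x", "y", "z"][: table.dim]
    for k, name in enumerate(names):
        cols[name] = table.coords[:, k]
    if table.frame is not None:
        cols["frame"] = table.frame
    if table.precision_nm is not None:
        cols["precision_nm"] = table.precision_nm
    pd.DataFrame(cols, columns=list(cols)).to_csv(path, index=False,
                                                  float_format="%.9f")


def write_blob_assignments(labels: Sequence[int], path) -> None:
    """Write per-localization blob labels as CSV (loc_index, blob_id)."""
    labels = np.asarray(labels, dtype=int)
    pd.DataFrame(
        {"loc_index": np.arange(len(labels)), "blob_id": labels}
    ).to_csv(path, index=False)


def write_feature_matrix(matrix: np.ndarray, names: Sequence[str], path) -> None:
    """Write a blobs x features matrix as CSV with one named column per feature."""
    matrix = np.asarray(matrix, dtype=float)
    df = pd.DataFrame(matrix, columns=list(names))
    df.insert(0, "blob_id", np.arange(matrix.shape[0]))
    df.to_csv(path, index=False, float_format="%.9f")
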