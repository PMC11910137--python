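"""Labelled single-cell Raman spectra: in-memory container and plain-text I/O.

A :class:`SpectraDataset` couples an intensity matrix (cells x wavenumber
channels) with a label table carrying strain, genus, phylum and growth-stage
annotations.  All spectra live on a single shared wavenumber grid; spectra
acquired on different grids must be resampled explicitly
(:func:`ramantax.preprocess.resample`) before assembly — nothing here
resamples silently.

On-disk convention: a CSV matrix whose first column is ``cell_id`` and whose
header row holds the wavenumbers, plus a TSV label table with columns
``cell_id, strain, genus, phylum, stage``.  UTF-8, dot decimal separator.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The four growth-stage labels: exponential phase and the beginning,
#: mid-point and end of the stationary phase.
STAGES = ("Exp", "S1", "S2", "S3")

#: Sentinel for spectra without growth-stage annotation (e.g. environmental
#: cells).  Stored explicitly — never an empty string.
STAGE_UNKNOWN = "unknown"

LABEL_COLUMNS = ("cell_id", "strain", "genus", "phylum", "stage")

# numeric round-trip at full float64 precision
_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """Malformed on-disk spectra file or label table."""


class ConsistencyError(ValueError):
    """Spectra matrix and label table disagree with each other."""


@dataclass(frozen=True, eq=False)
class WavenumberGrid:
    """Strictly increasing wavenumber axis (cm^-1) shared by all spectra."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise FormatError("wavenumber grid needs at least 2 points")
        if not np.all(np.isfinite(v)):
            raise FormatError("wavenumber grid contains non-finite values")
        if not np.all(np.diff(v) > 0):
            raise FormatError("wavenumber grid must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with custom eq
        return hash(self.values.tobytes())


@dataclass
class SpectraDataset:
    """Intensity matrix on a shared grid plus per-cell labels.

    Parameters
    ----------
    grid:
        Shared :class:`WavenumberGrid`.
    intensities:
        ``(n_cells, n_channels)`` float array, arbitrary units.
    labels:
        Table with columns ``cell_id, strain, genus, phylum, stage``;
        row *i* annotates spectrum *i*.  ``stage`` is one of
        :data:`STAGES` or :data:`STAGE_UNKNOWN`.
    meta:
        Free-form provenance (preprocessing steps applied, generator
        config, ...).  Not considered in equality checks.
    """

    grid: WavenumberGrid
    intensities: np.ndarray
    labels: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        X = np.asarray(self.intensities, dtype=float)
        if X.ndim != 2:
            raise ConsistencyError("intensities must be a 2-D matrix")
        if X.shape[0] == 0:
            raise ConsistencyError("dataset must contain at least one spectrum")
        if X.shape[1] != len(self.grid):
            raise ConsistencyError(
                f"{X.shape[1]} channels but grid has {len(self.grid)} points"
            )
        if not isinstance(self.labels, pd.DataFrame):
            raise ConsistencyError("labels must be a DataFrame")
        missing = [c for c in LABEL_COLUMNS if c not in self.labels.columns]
        if missing:
            raise ConsistencyError(f"label table missing columns: {missing}")
        if len(self.labels) != X.shape[0]:
            raise ConsistencyError(
                f"{X.shape[0]} spectra but {len(self.labels)} label rows"
            )
        ids = self.labels["cell_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ConsistencyError(f"duplicate cell_id {dup!r}")
        ok = set(STAGES) | {STAGE_UNKNOWN}
        bad = set(self.labels["stage"].unique()) - ok
        if bad:
            raise ConsistencyError(
                f"unknown stage labels {sorted(bad)}; expected one of {sorted(ok)}"
            )
        self.intensities = X
        self.labels = self.labels.reset_index(drop=True)

    # -- convenience ----------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def subset(self, index) -> "SpectraDataset":
        """Row subset (boolean mask or integer positions), order preserved."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectraDataset(
            grid=self.grid,
            intensities=self.intensities[idx].copy(),
            labels=self.labels.iloc[idx].reset_index(drop=True),
            meta=dict(self.meta),
        )

    def with_intensities(self, X: np.ndarray, grid: WavenumberGrid | None = None,
                         meta: dict | None = None) -> "SpectraDataset":
        """Copy with replaced intensities (and optionally grid/meta)."""
        return SpectraDataset(
            grid=self.grid if grid is None else grid,
            intensities=np.asarray(X, dtype=float),
            labels=self.labels.copy(),
            meta=dict(self.meta) if meta is None else meta,
        )

    def equals(self, other: "SpectraDataset") -> bool:
        return (
            self.grid == other.grid
            and np.array_equal(self.intensities, other.intensities)
            and self.labels[list(LABEL_COLUMNS)].equals(
                other.labels[list(LABEL_COLUMNS)]
            )
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_matrix(ds: SpectraDataset, path, labels_path) -> None:
    """Write the CSV intensity matrix and TSV label table.

    Inverse of :func:`read_matrix`; floats survive the round trip exactly.
    """
    ds.validate()
    header = ["cell_id"] + [_FLOAT_FMT % w for w in ds.grid.values]
    df = pd.DataFrame(ds.intensities, columns=header[1:])
    df.insert(0, "cell_id", ds.labels["cell_id"].to_numpy())
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    ds.labels[list(LABEL_COLUMNS)].to_csv(labels_path, sep="\t", index=False)


def read_matrix(path, labels_path) -> SpectraDataset:
    """Read a CSV matrix + TSV label table back into a validated dataset.

    Rows are returned in label-table order; any cell_id mismatch between the
    two files raises :class:`ConsistencyError`.
    """
    mat = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if mat.shape[1] < 3 or mat.columns[0] != "cell_id":
        raise FormatError("matrix file must start with a cell_id column")
    try:
        wavenumbers = np.array([float(c) for c in mat.columns[1:]])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber header: {exc}") from exc
    grid = WavenumberGrid(wavenumbers)

    labels = pd.read_csv(
        labels_path, sep="\t", dtype=str, keep_default_na=False
    )
    missing = [c for c in LABEL_COLUMNS if c not in labels.columns]
    if missing:
        raise FormatError(f"label table missing columns: {missing}")

    mat_ids = mat["cell_id"].to_numpy()
    lab_ids = labels["cell_id"].to_numpy()
    if set(mat_ids) != set(lab_ids) or len(mat_ids) != len(lab_ids):
        only_m = sorted(set(mat_ids) - set(lab_ids))[:3]
        only_l = sorted(set(lab_ids) - set(mat_ids))[:3]
        raise ConsistencyError(
            f"cell_id mismatch between matrix and labels "
            f"(matrix-only: {only_m}, labels-only: {only_l})"
        )
    # order matrix rows as in the label file
    order = pd.Index(mat_ids).get_indexer(lab_ids)
    X = mat.iloc[order, 1:].to_numpy(dtype=float)
    return SpectraDataset(grid=grid, intensities=X, labels=labels)


def read_two_column(directory) -> SpectraDataset:
    """Stack per-spectrum two-column text files (wavenumber, intensity).

    All files must share an identical grid; differing grids are rejected
    with instructions to resample first.  The file stem becomes the
    cell_id; taxonomy/stage labels are set to the unknown sentinel.
    """
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in {".txt", ".tsv", ".csv", ".dat", ""}
    ) if directory.is_dir() else []
    if not directory.is_dir():
        raise FormatError(f"not a directory: {directory}")
    if not files:
        raise FormatError(f"no spectrum files found in {directory}")

    grid = None
    rows, ids = [], []
    for p in files:
        try:
            arr = np.loadtxt(p, delimiter=None if p.suffix != ".csv" else ",")
        except Exception as exc:
            raise FormatError(f"cannot parse {p.name}: {exc}") from exc
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise FormatError(f"{p.name}: expected two columns (wavenumber, intensity)")
        g = WavenumberGrid(arr[:, 0])
        if grid is None:
            grid = g
        elif g != grid:
            raise FormatError(
                f"{p.name}: wavenumber grid differs from {files[0].name}; "
                "resample spectra onto a shared grid "
                "(ramantax.preprocess.resample) before assembly"
            )
        rows.append(arr[:, 1])
        ids.append(p.stem)

    labels = pd.DataFrame(
        {
            "cell_id": ids,
            "strain": STAGE_UNKNOWN,
            "genus": STAGE_UNKNOWN,
            "phylum": STAGE_UNKNOWN,
            "stage": STAGE_UNKNOWN,
        }
    )
    return SpectraDataset(grid=grid, intensities=np.vstack(rows), labels=labels)
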