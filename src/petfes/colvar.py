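"""COLVAR-dialect tabular I/O.

The dialect used by metadynamics engines: whitespace-delimited float
columns, first line ``#! FIELDS <name> <name> ...``, further ``#!``
lines carrying metadata as ``#! SET key value``.  Reading and writing
round-trip values exactly at the printed decimal representation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ColvarFormatError
from .fes_analysis import CVTrajectory, FESGrid

__all__ = [
    "ColvarTable",
    "read_colvar",
    "write_colvar",
    "trajectory_to_table",
    "table_to_trajectory",
    "write_fes",
    "write_bias_checkpoint",
    "read_bias_checkpoint",
]

def _fmt(v: float) -> str:
    """Shortest decimal that round-trips the float exactly."""
    return repr(float(v))


@dataclass
class ColvarTable:
    """Named float columns plus ``#! SET`` metadata."""

    fields: tuple
    rows: np.ndarray            # (n, len(fields))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fields = tuple(self.fields)
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if self.rows.size == 0:
            self.rows = self.rows.reshape(0, len(self.fields))
        if self.rows.shape[1] != len(self.fields):
            raise ColvarFormatError(
                f"rows have {self.rows.shape[1]} columns for "
                f"{len(self.fields)} fields")

    def column(self, name: str) -> np.ndarray:
        try:
            return self.rows[:, self.fields.index(name)]
        except ValueError:
            raise ColvarFormatError(
                f"no field {name!r}; available: {list(self.fields)}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(self.fields))


def read_colvar(path) -> ColvarTable:
    """Parse a COLVAR-dialect file."""
    path = Path(path)
    fields: Optional[tuple] = None
    metadata: dict = {}
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#!"):
                parts = line[2:].split()
                if parts and parts[0] == "FIELDS":
                    if fields is not None:
                        raise ColvarFormatError(
                            f"{path}:{lineno}: duplicate FIELDS header")
                    fields = tuple(parts[1:])
                    if not fields:
                        raise ColvarFormatError(
                            f"{path}:{lineno}: FIELDS header names no columns")
                elif parts and parts[0] == "SET" and len(parts) >= 3:
                    metadata[parts[1]] = " ".join(parts[2:])
                continue
            if fields is None:
                raise ColvarFormatError(
                    f"{path}:{lineno}: data before '#! FIELDS' header")
            cells = line.split()
            if len(cells) != len(fields):
                raise ColvarFormatError(
                    f"{path}:{lineno}: row has {len(cells)} cells, "
                    f"expected {len(fields)}")
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ColvarFormatError(
                    f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if fields is None:
        raise ColvarFormatError(f"{path}: missing '#! FIELDS' header")
    arr = np.array(rows) if rows else np.empty((0, len(fields)))
    return ColvarTable(fields=fields, rows=arr, metadata=metadata)


def write_colvar(table: ColvarTable, path) -> None:
    """Write a COLVAR-dialect file (lossless at the printed precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(table.fields) + "\n")
        for key, value in table.metadata.items():
            fh.write(f"#! SET {key} {value}\n")
        for row in table.rows:
            fh.write(" ".join(_fmt(v) for v in row) + "\n")


def trajectory_to_table(traj: CVTrajectory) -> ColvarTable:
    """CVTrajectory -> ColvarTable, metadata carried as SET lines."""
    meta = {k: v for k, v in traj.metadata.items()
            if isinstance(v, (str, int, float, bool))}
    return ColvarTable(fields=tuple(traj.data.columns),
                       rows=traj.data.to_numpy(dtype=float), metadata=meta)


def table_to_trajectory(table: ColvarTable) -> CVTrajectory:
    meta = {}
    for k, v in table.metadata.items():
        try:
            meta[k] = float(v) if "." in v or "e" in v.lower() else int(v)
        except ValueError:
            meta[k] = v
    return CVTrajectory(table.to_frame(), metadata=meta)


def write_fes(fes: FESGrid, path) -> None:
    """Write a 1D or 2D FES as a table of bin centers, F and error."""
    names = list(fes.cv_names) or [f"cv{i}" for i in range(len(fes.edges))]
    if len(fes.edges) == 1:
        c = fes.centers(0)
        err = (fes.errors if fes.errors is not None
               else np.zeros_like(fes.values))
        rows = np.column_stack([c, fes.values, err])
        table = ColvarTable(fields=(names[0], "free_energy", "error"),
                            rows=rows,
                            metadata={"normalization": fes.normalization})
    else:
        c0, c1 = fes.centers(0), fes.centers(1)
        g0, g1 = np.meshgrid(c0, c1, indexing="ij")
        err = (fes.errors if fes.errors is not None
               else np.zeros_like(fes.values))
        rows = np.column_stack([g0.ravel(), g1.ravel(),
                                fes.values.ravel(), err.ravel()])
        table = ColvarTable(fields=(names[0], names[1], "free_energy", "error"),
                            rows=rows,
                            metadata={"normalization": fes.normalization})
    write_colvar(table, path)


def write_bias_checkpoint(bias, path) -> None:
    """Write the kernel history (centers, widths, heights, index)."""
    centers, widths, heights = bias.kernel_arrays()
    d = centers.shape[1] if centers.ndim == 2 else 1
    fields = ([f"center_{c}" for c in bias.cv_names]
              + [f"sigma_{c}" for c in bias.cv_names]
              + ["height", "deposit_index"])
    rows = np.column_stack([
        centers.reshape(-1, d), widths.reshape(-1, d), heights,
        np.arange(len(heights), dtype=float)]) if len(heights) else \
        np.empty((0, 2 * d + 2))
    table = ColvarTable(fields=tuple(fields), rows=rows, metadata={
        "cv_names": ",".join(bias.cv_names),
        "bias_factor": repr(bias.bias_factor),
        "pace": str(bias.pace)})
    write_colvar(table, path)


def read_bias_checkpoint(path):
    """Round-trip counterpart of `write_bias_checkpoint`."""
    from .enhanced_sampling import MetadBias

    table = read_colvar(path)
    cv_names = tuple(table.metadata["cv_names"].split(","))
    d = len(cv_names)
    bias = MetadBias(cv_names,
                     bias_factor=float(table.metadata["bias_factor"]),
                     pace=int(table.metadata["pace"]))
    if len(table.rows):
        order = np.argsort(table.column("deposit_index"))
        centers = table.rows[order, :d]
        widths = table.rows[order, d:2 * d]
        heights = table.rows[order, 2 * d]
        bias._centers = centers.copy()
        bias._widths = widths.copy()
        bias._heights = heights.copy()
    return bias
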