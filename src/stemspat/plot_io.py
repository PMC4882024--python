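"""Plot geometry, stem tables, point patterns, raster surfaces and their text I/O.

Coordinates are plot-local metres, origin at the south-west corner. All
gridded structures use a half-open cell convention ``[x0, x0+cell) x
[y0, y0+cell)`` so every in-window point maps to exactly one cell.

File formats:

* stem tables / soil tables: comma- or tab-delimited text with a header
  (dialect auto-detected from the header line);
* rasters: ESRI ASCII grid (``ncols/nrows/xllcorner/yllcorner/cellsize``).
"""

from __future__ import annotations

import json
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROWTH_FORMS = ("canopy", "subcanopy", "shrub")

STEM_COLUMNS = ("tag", "sp", "gf", "gx", "gy", "dbh")
SOIL_COLUMNS = ("x", "y", "totalC", "totalN", "totalP", "pH")


class FormatError(ValueError):
    """Malformed input file (missing columns, bad header)."""


@dataclass(frozen=True)
class PlotWindow:
    """Rectangular observation window, half-open in both axes."""

    x_extent: float = 500.0
    y_extent: float = 400.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.x_extent > 0 and self.y_extent > 0):
            raise ValueError("window extents must be strictly positive")

    @property
    def area(self) -> float:
        return self.x_extent * self.y_extent

    @property
    def xrange(self) -> tuple[float, float]:
        return (self.origin[0], self.origin[0] + self.x_extent)

    @property
    def yrange(self) -> tuple[float, float]:
        return (self.origin[1], self.origin[1] + self.y_extent)

    def contains(self, x, y):
        """Vectorised membership test under the half-open convention."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        (x0, x1), (y0, y1) = self.xrange, self.yrange
        return (x >= x0) & (x < x1) & (y >= y0) & (y < y1)


@dataclass
class PointPattern:
    """A planar point pattern observed in a rectangular window."""

    x: np.ndarray
    y: np.ndarray
    window: PlotWindow

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if self.n and not bool(np.all(self.window.contains(self.x, self.y))):
            raise ValueError("all points must lie inside the window")

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def intensity(self) -> float:
        return self.n / self.window.area

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class RasterSurface:
    """Regular-grid scalar field covering the window exactly.

    ``values[iy, ix]`` is the cell whose lower-left corner is
    ``(origin[0] + ix*cell_size, origin[1] + iy*cell_size)`` -- row 0 is the
    southern row. ASCII-grid I/O flips rows to the ESRI top-down layout.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"surface {self.name!r} contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def window(self) -> PlotWindow:
        ny, nx = self.values.shape
        return PlotWindow(nx * self.cell_size, ny * self.cell_size, self.origin)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map points to (iy, ix) cell indices; raises if any point is outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.window.contains(x, y)
        if not bool(np.all(inside)):
            bad = np.argwhere(~np.atleast_1d(inside)).ravel()
            raise ValueError(f"point(s) outside window at index {bad[:5].tolist()}")
        ix = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        iy = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        return iy, ix

    def value_at(self, x, y):
        iy, ix = self.cell_index(x, y)
        return self.values[iy, ix]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened x and y coordinates of every cell center (C order)."""
        ny, nx = self.values.shape
        cx = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        cy = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        gx, gy = np.meshgrid(cx, cy)
        return gx.ravel(), gy.ravel()


def surface_value_at(surface: RasterSurface, x, y):
    """Value of the cell containing (x, y) under the half-open convention."""
    return surface.value_at(x, y)


@dataclass
class StemTable:
    """Validated stem census table plus per-row rejection diagnostics."""

    data: pd.DataFrame
    window: PlotWindow
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.data)

    def species(self) -> list[str]:
        return sorted(self.data["sp"].unique())

    def pattern(self, sp: str | None = None, mask: pd.Series | None = None) -> PointPattern:
        df = self.data
        if sp is not None:
            df = df[df["sp"] == sp]
        if mask is not None:
            df = df[mask.reindex(df.index, fill_value=False)]
        return PointPattern(df["gx"].to_numpy(), df["gy"].to_numpy(), self.window)


def _sniff_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_delimited(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a comma/tab-delimited table, checking the required columns exist."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = _sniff_sep(header)
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    return df


def read_stem_table(path: str | Path, window: PlotWindow | None = None) -> StemTable:
    """Read and validate a stem census file.

    Rows with non-numeric coordinates/DBH, coordinates outside the window, or
    DBH below the 1 cm census threshold are dropped and reported in
    ``StemTable.rejected`` as ``(line_number, reason)`` (line numbers count
    from 1 at the header).
    """
    window = window or PlotWindow()
    raw = read_delimited(path, STEM_COLUMNS)
    rejected: list[tuple[int, str]] = []
    rows = []
    for pos, row in enumerate(raw.itertuples(index=False)):
        line = pos + 2  # header is line 1
        rec = dict(zip(raw.columns, row))
        try:
            gx, gy = float(rec["gx"]), float(rec["gy"])
            dbh = float(rec["dbh"])
        except (TypeError, ValueError):
            rejected.append((line, "non-numeric coordinate or dbh"))
            continue
        if not bool(window.contains(gx, gy)):
            rejected.append((line, f"coordinates ({gx}, {gy}) outside window"))
            continue
        if dbh < 1.0:
            rejected.append((line, f"dbh {dbh} below 1 cm census threshold"))
            continue
        gf = str(rec["gf"]).strip()
        if gf not in GROWTH_FORMS:
            rejected.append((line, f"unknown growth form {gf!r}"))
            continue
        rows.append(
            {"tag": str(rec["tag"]).strip(), "sp": str(rec["sp"]).strip(),
             "gf": gf, "gx": gx, "gy": gy, "dbh": dbh}
        )
    data = pd.DataFrame(rows, columns=list(STEM_COLUMNS))
    return StemTable(data=data, window=window, rejected=rejected)


def write_stem_table(table: StemTable | pd.DataFrame, path: str | Path) -> None:
    df = table.data if isinstance(table, StemTable) else table
    df.to_csv(path, index=False, float_format="%.6f")


def read_soil_table(path: str | Path) -> pd.DataFrame:
    df = read_delimited(path, SOIL_COLUMNS)
    return df[list(SOIL_COLUMNS)].astype(float)


def read_ascii_grid(path: str | Path, name: str = "") -> RasterSurface:
    """Read an ESRI ASCII grid into a RasterSurface (rows re-ordered south-up)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"{path.name}: missing ASCII-grid header field {key}")
    body = np.loadtxt(lines[i:], dtype=float)
    body = np.atleast_2d(body)
    if body.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError(
            f"{path.name}: grid body {body.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return RasterSurface(
        values=body[::-1],  # ESRI rows run north->south
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        name=name or path.stem,
    )


def write_ascii_grid(surface: RasterSurface, path: str | Path) -> None:
    ny, nx = surface.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {surface.origin[0]:.6f}\n")
        fh.write(f"yllcorner {surface.origin[1]:.6f}\n")
        fh.write(f"cellsize {surface.cell_size:.6f}\n")
        np.savetxt(fh, surface.values[::-1], fmt="%.8g")


SPECIES_RESULT_COLUMNS = [
    "sp", "stage", "n", "habitat_associated", "positive_habitats",
    "dispersal_limited", "h_selected", "d_retained", "process_class",
    "pve", "pvd",
]


def write_results(species_table: pd.DataFrame, summary_table: pd.DataFrame,
                  outdir: str | Path, manifest: dict | None = None) -> dict[str, Path]:
    """Write the per-species x stage table, the community summary and a run
    manifest (config echo, seed, library versions) to ``outdir``.

    Returns the mapping of logical name -> written path. Empty tables produce
    header-only files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "species": outdir / "species_results.csv",
        "summary": outdir / "stage_summary.csv",
        "manifest": outdir / "manifest.json",
    }
    sp = species_table if not species_table.empty else pd.DataFrame(
        columns=SPECIES_RESULT_COLUMNS)
    sp.to_csv(paths["species"], index=False, float_format="%.6f")
    summary_table.to_csv(paths["summary"], index=False, float_format="%.6f")
    info = {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    info.update(manifest or {})
    with open(paths["manifest"], "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True, default=str)
    return paths
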