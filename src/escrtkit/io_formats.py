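"""File formats used by the pipeline: MRC rasters, STAR coordinate tables, CSV traces.

Conventions
-----------
* Coordinates are physical, in Angstrom, with the origin at the centre of the
  top-left pixel; ``x`` increases along columns, ``y`` along rows.  STAR files
  store pixel coordinates; conversion happens at this boundary.
* Coordinate tables are plain :class:`pandas.DataFrame` objects with the
  columns listed in :data:`COORD_COLUMNS`.  Within one ``edge_id`` rows are
  ordered by arc length ``s_A``.
* Kinetic traces travel as CSV with columns ``t_s, intensity,
  concentration_uM, replicate`` (schema version 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger("escrtkit")

__all__ = [
    "FormatError",
    "Micrograph",
    "COORD_COLUMNS",
    "make_coord_table",
    "validate_coord_table",
    "read_mrc",
    "write_mrc",
    "read_star_coords",
    "write_star_coords",
    "read_traces_csv",
    "write_traces_csv",
]


class FormatError(ValueError):
    """Raised when a file does not conform to the expected format."""


# ---------------------------------------------------------------------------
# Micrograph
# ---------------------------------------------------------------------------

@dataclass
class Micrograph:
    """A 2D intensity raster with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Real-valued image.  Stored as float32.
    pixel_size_A : float
        Angstrom per pixel, > 0.
    name : str
        Identifier (usually the source file stem).
    """

    pixels: np.ndarray
    pixel_size_A: float
    name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype not in (np.float32, np.float64):
            self.pixels = self.pixels.astype(np.float32)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise FormatError("micrograph raster must be 2D with >= 2 rows and columns")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("micrograph contains non-finite pixels")
        if not (self.pixel_size_A > 0):
            raise FormatError(f"pixel size must be positive, got {self.pixel_size_A}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_mrc(path) -> Micrograph:
    """Read a 2D MRC map.

    The pixel size is taken from the header cell dimensions; a non-positive
    value falls back to 1.0 A with a logged warning.  A map with more than one
    section (a 3D volume) or a non-real data mode is rejected.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except FileNotFoundError:
        raise
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"not a valid MRC map: {path}: {exc}") from exc
    mode = ccp4.header_i32(4)
    if mode not in (0, 1, 2):  # signed ints and float32 are real rasters
        raise FormatError(f"unsupported MRC mode {mode} (complex/packed data)")
    grid = ccp4.grid
    arr = np.array(grid, copy=True)  # axes (nu, nv, nw) = (x, y, z)
    if arr.shape[2] != 1:
        raise FormatError(f"expected a single-section 2D map, got nz={arr.shape[2]}")
    pixels = arr[:, :, 0].T  # -> (rows=y, cols=x)
    px = grid.unit_cell.a / grid.nu if grid.nu else 0.0
    if not (px > 0) or not math.isfinite(px):
        logger.warning("MRC header of %s lacks a positive pixel size; assuming 1.0 A", path)
        px = 1.0
    name = str(path).rsplit("/", 1)[-1]
    if name.endswith(".mrc"):
        name = name[:-4]
    return Micrograph(pixels=pixels, pixel_size_A=float(px), name=name)


def write_mrc(micrograph: Micrograph, path) -> None:
    """Write a :class:`Micrograph` as a single-section float32 MRC map."""
    rows, cols = micrograph.shape
    ccp4 = gemmi.Ccp4Map()
    data = np.ascontiguousarray(micrograph.pixels.T[:, :, None], dtype=np.float32)
    ccp4.grid = gemmi.FloatGrid(data)
    px = micrograph.pixel_size_A
    ccp4.grid.unit_cell = gemmi.UnitCell(cols * px, rows * px, px, 90, 90, 90)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Coordinate tables
# ---------------------------------------------------------------------------

#: Canonical column order of a coordinate table (positions in Angstrom).
COORD_COLUMNS = ["x_A", "y_A", "edge_id", "s_A", "psi_deg", "micrograph_name"]

#: STAR labels used for the extra per-pick columns.
_STAR_LABELS = {
    "x_A": "_rlnCoordinateX",
    "y_A": "_rlnCoordinateY",
    "edge_id": "_rlnHelicalTubeID",
    "s_A": "_rlnHelicalTrackLengthAngst",
    "psi_deg": "_rlnAnglePsi",
    "micrograph_name": "_rlnMicrographName",
}


def make_coord_table(x_A, y_A, edge_id=0, s_A=np.nan, psi_deg=np.nan,
                     micrograph_name="") -> pd.DataFrame:
    """Assemble a coordinate table; scalars broadcast over rows."""
    df = pd.DataFrame({
        "x_A": np.asarray(x_A, dtype=float),
        "y_A": np.asarray(y_A, dtype=float),
    })
    df["edge_id"] = edge_id
    df["s_A"] = s_A
    df["psi_deg"] = psi_deg
    df["micrograph_name"] = micrograph_name
    return validate_coord_table(df)


def validate_coord_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check invariants: finite positions, per-edge ordering by arc length."""
    missing = [c for c in COORD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"coordinate table lacks columns {missing}")
    if len(df):
        if not np.all(np.isfinite(df["x_A"])) or not np.all(np.isfinite(df["y_A"])):
            raise FormatError("coordinate positions must be finite")
        for eid, grp in df.groupby("edge_id", sort=False):
            s = grp["s_A"].to_numpy(dtype=float)
            if np.all(np.isfinite(s)) and len(s) > 1 and not np.all(np.diff(s) > 0):
                raise FormatError(f"edge {eid}: rows not strictly ordered by s_A")
    return df[COORD_COLUMNS].reset_index(drop=True)


def _parse_star_loop(lines):
    """Parse the first ``loop_`` block of a STAR file into (labels, rows)."""
    labels: list[str] = []
    rows: list[list[str]] = []
    in_loop = in_header = False
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "loop_":
            in_loop, in_header = True, True
            continue
        if not in_loop:
            continue
        if line.startswith("_"):
            if not in_header:  # a second loop begins; stop at the first
                break
            labels.append(line.split()[0])
            continue
        if line.startswith("data_"):
            if labels:
                break
            in_loop = in_header = False
            continue
        in_header = False
        rows.append(line.split())
    return labels, rows


def read_star_coords(path, pixel_size_A: float) -> pd.DataFrame:
    """Read a STAR particle-coordinate file into a coordinate table (Angstrom).

    Missing edge/arc-length/angle columns are filled with sentinel values
    (edge_id -1, NaN) and flagged with a warning.
    """
    if not (pixel_size_A > 0):
        raise FormatError("pixel_size_A must be positive")
    with open(path, "r", encoding="utf-8") as fh:
        labels, rows = _parse_star_loop(fh)
    if "_rlnCoordinateX" not in labels or "_rlnCoordinateY" not in labels:
        raise FormatError(f"STAR file {path} lacks particle X/Y coordinate columns")
    cols = {lab: [r[i] for r in rows] for i, lab in enumerate(labels)}
    n = len(rows)
    out = pd.DataFrame({
        "x_A": np.asarray(cols["_rlnCoordinateX"], dtype=float) * pixel_size_A,
        "y_A": np.asarray(cols["_rlnCoordinateY"], dtype=float) * pixel_size_A,
    })
    sentinels = {"edge_id": -1, "s_A": np.nan, "psi_deg": np.nan}
    for key in ("edge_id", "s_A", "psi_deg", "micrograph_name"):
        lab = _STAR_LABELS[key]
        if lab in cols:
            if key == "edge_id":
                out[key] = np.asarray(cols[lab], dtype=int)
            elif key == "micrograph_name":
                out[key] = cols[lab]
            else:
                out[key] = np.asarray(cols[lab], dtype=float)
        else:
            if key == "micrograph_name":
                out[key] = ""
            else:
                out[key] = sentinels[key]
                logger.warning("STAR file %s lacks %s; filled with sentinel", path, lab)
    return validate_coord_table(out) if n else out.reindex(columns=COORD_COLUMNS)


def write_star_coords(table: pd.DataFrame, path, pixel_size_A: float) -> None:
    """Write a coordinate table as a STAR particle loop (coordinates in pixels)."""
    if not (pixel_size_A > 0):
        raise FormatError("pixel_size_A must be positive")
    table = validate_coord_table(table) if len(table) else table
    keys = COORD_COLUMNS
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\ndata_particles\n\nloop_\n")
        for i, key in enumerate(keys, start=1):
            fh.write(f"{_STAR_LABELS[key]} #{i}\n")
        for _, row in table.iterrows():
            x_px = row["x_A"] / pixel_size_A
            y_px = row["y_A"] / pixel_size_A
            name = row["micrograph_name"] or '""'
            fh.write(f"{x_px:.6f} {y_px:.6f} {int(row['edge_id'])} "
                     f"{row['s_A']:.6f} {row['psi_deg']:.6f} {name}\n")


# ---------------------------------------------------------------------------
# Kinetic-trace CSV (schema v1: t_s, intensity, concentration_uM, replicate)
# ---------------------------------------------------------------------------

TRACE_COLUMNS = ["t_s", "intensity", "concentration_uM", "replicate"]


def write_traces_csv(traces, path) -> None:
    """Write one or more kinetic traces to a single CSV file."""
    frames = []
    for tr in np.atleast_1d(traces):
        frames.append(pd.DataFrame({
            "t_s": tr.times,
            "intensity": tr.intensities,
            "concentration_uM": tr.concentration_uM,
            "replicate": tr.replicate,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path) -> list:
    """Read kinetic traces from CSV, one trace per (concentration, replicate)."""
    from .kinetics import KineticTrace  # deferred: avoid import cycle

    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trace CSV lacks columns {missing}")
    traces = []
    for (conc, rep), grp in df.groupby(["concentration_uM", "replicate"], sort=True):
        grp = grp.sort_values("t_s")
        traces.append(KineticTrace(
            times=grp["t_s"].to_numpy(dtype=float),
            intensities=grp["intensity"].to_numpy(dtype=float),
            concentration_uM=float(conc),
            replicate=int(rep),
        ))
    return traces
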