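"""Localization-table I/O and preprocessing.

Single-molecule localization data arrive as flat CSV tables (one row per
detected emitter, with frame index, position and an estimated localization
precision).  This module reads such tables from the common header dialects,
normalizes everything to nanometre units, and applies the two standard
preprocessing steps used for dSTORM data of synaptic structures:

* merging of localizations that persist over consecutive frames (one
  blinking event of a fluorophore yields several rows; they are collapsed
  into a single precision-weighted localization), and
* a hard cutoff on localization precision (default 15 nm) so that only
  well-determined emitters enter the downstream geometry.

Conventions: coordinates are nm, origin top-left, y pointing down (image
convention); frame indices are 0-based; all region boundaries are closed
(points on an edge are inside).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "Dialect",
    "Roi",
    "RoiSet",
    "read_localizations",
    "write_localizations",
    "merge_consecutive",
    "precision_filter",
    "crop_to_roi",
]

#: canonical column order of a localization table
COLUMNS = ["frame", "x", "y", "precision", "channel"]


class FormatError(ValueError):
    """A mandatory column is missing or a cell cannot be parsed."""


@dataclass(frozen=True)
class Dialect:
    """Column-name and unit mapping for a localization CSV flavour.

    ``columns`` maps canonical names (``frame``, ``x``, ``y``,
    ``precision``) to the header names used in the file.  ``unit`` is the
    length unit of the position/precision columns (``"nm"``, ``"um"`` or
    ``"px"``); for pixel units ``pixel_size_nm`` must be given.
    """

    columns: Mapping[str, str] = field(
        default_factory=lambda: {"frame": "frame", "x": "x", "y": "y", "precision": "precision"}
    )
    unit: str = "nm"
    pixel_size_nm: float | None = None

    def scale(self) -> float:
        if self.unit == "nm":
            return 1.0
        if self.unit == "um":
            return 1000.0
        if self.unit == "px":
            if self.pixel_size_nm is None:
                raise ValueError("pixel unit requires pixel_size_nm")
            return float(self.pixel_size_nm)
        raise ValueError(f"unknown unit {self.unit!r}")


#: header map for ThunderSTORM-style exports
THUNDERSTORM = Dialect(
    columns={"frame": "frame", "x": "x [nm]", "y": "y [nm]", "precision": "uncertainty [nm]"},
    unit="nm",
)


@dataclass(frozen=True)
class Roi:
    """Axis-aligned rectangular or circular region of interest (nm)."""

    center: tuple[float, float]
    width: float | None = None
    height: float | None = None
    radius: float | None = None
    label: str = "roi"

    def __post_init__(self) -> None:
        if self.radius is None and (self.width is None or self.height is None):
            raise ValueError("Roi needs either radius or width+height")
        for v in (self.width, self.height, self.radius):
            if v is not None and v <= 0:
                raise ValueError("Roi sizes must be > 0")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        if self.radius is not None:
            return (x - cx) ** 2 + (y - cy) ** 2 <= self.radius**2
        return (
            (np.abs(x - cx) <= self.width / 2.0)
            & (np.abs(y - cy) <= self.height / 2.0)
        )


@dataclass
class RoiSet:
    rois: list[Roi]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise ValueError("Roi labels must be unique")

    def to_json(self, path: str | Path) -> None:
        import json

        records = []
        for r in self.rois:
            rec: dict = {"center": list(r.center), "label": r.label}
            if r.radius is not None:
                rec["radius"] = r.radius
            else:
                rec["width"], rec["height"] = r.width, r.height
            records.append(rec)
        Path(path).write_text(json.dumps({"rois": records}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiSet":
        import json

        data = json.loads(Path(path).read_text())
        rois = [
            Roi(
                center=tuple(rec["center"]),
                width=rec.get("width"),
                height=rec.get("height"),
                radius=rec.get("radius"),
                label=rec.get("label", f"roi{i}"),
            )
            for i, rec in enumerate(data["rois"])
        ]
        return cls(rois=rois)


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by frame within channel, stable, and order columns."""
    cols = [c for c in COLUMNS if c in df.columns]
    out = df[cols].copy()
    out = out.sort_values(
        ["channel", "frame"] if "channel" in out else ["frame"], kind="stable"
    ).reset_index(drop=True)
    return out


def read_localizations(
    path: str | Path,
    dialect: Dialect | None = None,
    channel: str | None = None,
) -> pd.DataFrame:
    """Read a localization CSV into the canonical nm-unit table.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Column/unit mapping; default assumes canonical headers in nm.
    channel
        Channel label to assign if the file has no ``channel`` column.
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path)
    rename = {v: k for k, v in dialect.columns.items() if v in df.columns}
    df = df.rename(columns=rename)
    for col in ("frame", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    for col in ("frame", "x", "y", "precision"):
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"non-numeric value in column {col!r} at row {row}")
        df[col] = vals
    s = dialect.scale()
    df["x"] = df["x"] * s
    df["y"] = df["y"] * s
    if "precision" in df.columns:
        df["precision"] = df["precision"] * s
    if "channel" not in df.columns:
        df["channel"] = channel if channel is not None else "ch0"
    df["frame"] = df["frame"].astype(int)
    if (df["frame"] < 0).any():
        raise FormatError("negative frame index")
    return _canonical(df)


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical table as CSV (nm units, canonical headers)."""
    cols = [c for c in COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


def merge_consecutive(
    table: pd.DataFrame,
    merge_radius: float = 30.0,
    max_gap_frames: int = 0,
) -> pd.DataFrame:
    """Collapse blinking runs into single localizations (idempotent).

    The single-pass collapse is iterated to a fixed point, so applying
    the operation twice gives the same table as applying it once.
    """
    out = _merge_once(table, merge_radius, max_gap_frames)
    while len(out) < len(table):
        table, out = out, _merge_once(out, merge_radius, max_gap_frames)
    return out


def _merge_once(
    table: pd.DataFrame,
    merge_radius: float,
    max_gap_frames: int = 0,
) -> pd.DataFrame:
    """One collapse pass over blinking runs.

    Localizations of the same channel that appear in consecutive frames
    within ``merge_radius`` (nm) of each other are linked into a run
    (connected components of the frame-adjacency proximity graph, so the
    result is independent of row order); each run is replaced by one
    localization at the precision-weighted mean position, with ``frame``
    set to the first frame of the run and ``precision`` set to the pooled
    SD ``1/sqrt(sum 1/sigma_i^2)``.

    ``max_gap_frames`` optionally closes short dark gaps inside a run
    (0 = strictly consecutive frames, the default).
    """
    from scipy.spatial import cKDTree

    if merge_radius <= 0:
        raise ValueError("merge_radius must be > 0")
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    has_prec = "precision" in table.columns
    out_rows: list[tuple] = []
    for channel, sub in table.groupby("channel", sort=False, observed=True):
        frames = sub["frame"].to_numpy()
        xy = sub[["x", "y"]].to_numpy(float)
        prec = sub["precision"].to_numpy(float) if has_prec else np.zeros(len(sub))
        n = len(sub)
        parent = np.arange(n)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

        unique_frames = np.unique(frames)
        idx_by_frame = {f: np.flatnonzero(frames == f) for f in unique_frames}
        trees = {f: cKDTree(xy[idx_by_frame[f]]) for f in unique_frames}
        for f in unique_frames:
            for gap in range(1, max_gap_frames + 2):
                g = f + gap
                if g not in trees:
                    continue
                pairs = trees[f].query_ball_tree(trees[g], merge_radius)
                ia, ib = idx_by_frame[f], idx_by_frame[g]
                for i, neighbors in enumerate(pairs):
                    for j in neighbors:
                        union(ia[i], ib[j])
        roots = np.array([find(i) for i in range(n)])
        for root in np.unique(roots):
            m = np.flatnonzero(roots == root)
            sig = prec[m]
            if len(m) == 1:  # exact passthrough keeps the operation idempotent
                k = m[0]
                out_rows.append(
                    (int(frames[k]), float(xy[k, 0]), float(xy[k, 1]))
                    + ((float(sig[0]),) if has_prec else ())
                    + (channel,)
                )
                continue
            if has_prec and np.all(sig > 0):
                w = 1.0 / sig**2
                mx, my = np.average(xy[m], axis=0, weights=w)
                pooled = float(1.0 / np.sqrt(w.sum()))
            else:
                mx, my = xy[m].mean(axis=0)
                pooled = float(sig.mean()) if has_prec else 0.0
            row = (int(frames[m].min()), float(mx), float(my))
            out_rows.append(row + ((pooled,) if has_prec else ()) + (channel,))
    cols = ["frame", "x", "y"] + (["precision"] if has_prec else []) + ["channel"]
    out = pd.DataFrame(out_rows, columns=cols)
    return _canonical(out)


def precision_filter(table: pd.DataFrame, cutoff: float = 15.0) -> pd.DataFrame:
    """Keep localizations with precision <= cutoff (nm, boundary inclusive)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if "precision" not in table.columns:
        raise ValueError("table has no precision column")
    return table[table["precision"] <= cutoff].reset_index(drop=True)


def crop_to_roi(table: pd.DataFrame, roi: Roi) -> pd.DataFrame:
    """Rows whose position lies inside the closed ROI."""
    mask = roi.contains(table["x"].to_numpy(float), table["y"].to_numpy(float))
    return table[mask].reset_index(drop=True)
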