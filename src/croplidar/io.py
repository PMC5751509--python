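"""Readers and writers for the pipeline's on-disk formats.

Point clouds travel as ASCII PLY or PCD (or bare XYZ CSV), parcel
polygons as GeoJSON with an explicit ``crs`` property, treatment tables
and parcel summaries as CSV, canopy rasters as ESRI ASCII grid with a
JSON sidecar, voxel grids as sparse CSV with a JSON header, and pose
streams as CSV.  All formats are plain text and round-trip losslessly at
their declared precision.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import ParcelPolygon, PointCloud, VoxelGrid
from .geo import GeoCoordinate, Pose, wgs84_to_utm
from .grid import PixelGrid

__all__ = [
    "ParseError",
    "FormatError",
    "SchemaError",
    "read_point_cloud",
    "write_point_cloud",
    "read_polygons",
    "write_polygons",
    "read_treatments",
    "write_treatments",
    "read_pixel_grid",
    "write_pixel_grid",
    "read_voxel_grid",
    "write_voxel_grid",
    "read_pose_stream",
    "write_pose_stream",
    "write_summaries",
]


class ParseError(ValueError):
    """Malformed file content; the message names the offending line."""


class FormatError(ValueError):
    """Unknown or unsupported file format."""


class SchemaError(ValueError):
    """Tabular input violates the expected schema."""


_FLOAT_FMT = "%.8f"


def _format_of(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("ply", "pcd", "xyz", "csv"):
        return "xyz" if suffix == "csv" else suffix
    if suffix in ("las", "laz"):
        raise FormatError(
            "LAS/LAZ are binary formats and not supported; convert to ASCII PLY or PCD"
        )
    raise FormatError(f"unknown point cloud format {path.suffix!r}")


# -- point clouds -----------------------------------------------------------


def write_point_cloud(cloud: PointCloud, path, fmt: str | None = None) -> None:
    """Write a cloud as ASCII PLY, PCD or XYZ; format from the extension."""
    path = Path(path)
    fmt = _format_of(path, fmt)
    pts = cloud.points
    with open(path, "w") as fh:
        if fmt == "ply":
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"comment frame {cloud.frame}\n")
            fh.write(f"element vertex {len(pts)}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write("end_header\n")
            np.savetxt(fh, pts, fmt=_FLOAT_FMT)
        elif fmt == "pcd":
            fh.write("# .PCD v0.7 - Point Cloud Data file format\n")
            fh.write("VERSION 0.7\nFIELDS x y z\nSIZE 8 8 8\nTYPE F F F\nCOUNT 1 1 1\n")
            fh.write(f"WIDTH {len(pts)}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\n")
            fh.write(f"POINTS {len(pts)}\nDATA ascii\n")
            np.savetxt(fh, pts, fmt=_FLOAT_FMT)
        else:  # xyz
            fh.write("x,y,z\n")
            np.savetxt(fh, pts, fmt=_FLOAT_FMT, delimiter=",")


def _read_ply(path: Path, frame: str) -> PointCloud:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ParseError(f"{path}: line 1: missing 'ply' magic")
    n = None
    props: list[str] = []
    body_start = None
    for i, line in enumerate(lines[1:], start=2):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format" and tok[1] != "ascii":
            raise ParseError(f"{path}: line {i}: only ASCII PLY is supported")
        if tok[0] == "element":
            if tok[1] != "vertex":
                raise ParseError(f"{path}: line {i}: only vertex elements are supported")
            n = int(tok[2])
        elif tok[0] == "property":
            props.append(tok[-1])
        elif tok[0] == "comment" and len(tok) >= 3 and tok[1] == "frame":
            frame = tok[2]
        elif tok[0] == "end_header":
            body_start = i
            break
    if n is None or body_start is None:
        raise ParseError(f"{path}: header missing 'element vertex' or 'end_header'")
    for axis in ("x", "y", "z"):
        if axis not in props:
            raise ParseError(f"{path}: vertex element lacks property {axis!r}")
    body = [ln for ln in lines[body_start:] if ln.strip()]
    if len(body) < n:
        raise ParseError(
            f"{path}: truncated at line {body_start + len(body) + 1}: "
            f"expected {n} vertices, found {len(body)}"
        )
    if n == 0:
        return PointCloud(np.empty((0, 3)), frame)
    try:
        data = np.array([[float(v) for v in ln.split()] for ln in body[:n]])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric vertex data: {exc}") from exc
    cols = [props.index(a) for a in ("x", "y", "z")]
    return PointCloud(data[:, cols], frame)


def _read_pcd(path: Path, frame: str) -> PointCloud:
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = None
    fields: list[str] = []
    body_start = None
    for i, line in enumerate(lines, start=1):
        tok = line.split()
        if not tok or tok[0].startswith("#"):
            continue
        if tok[0] == "FIELDS":
            fields = tok[1:]
        elif tok[0] == "POINTS":
            n = int(tok[1])
        elif tok[0] == "DATA":
            if tok[1] != "ascii":
                raise ParseError(f"{path}: line {i}: only DATA ascii is supported")
            body_start = i
            break
    if n is None or body_start is None:
        raise ParseError(f"{path}: header missing POINTS or DATA line")
    for axis in ("x", "y", "z"):
        if axis not in fields:
            raise ParseError(f"{path}: FIELDS lacks {axis!r}")
    body = [ln for ln in lines[body_start:] if ln.strip()]
    if len(body) < n:
        raise ParseError(
            f"{path}: truncated at line {body_start + len(body) + 1}: "
            f"expected {n} points, found {len(body)}"
        )
    if n == 0:
        return PointCloud(np.empty((0, 3)), frame)
    try:
        data = np.array([[float(v) for v in ln.split()] for ln in body[:n]])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric point data: {exc}") from exc
    cols = [fields.index(a) for a in ("x", "y", "z")]
    return PointCloud(data[:, cols], frame)


def read_point_cloud(path, fmt: str | None = None, frame: str = "local") -> PointCloud:
    """Read an ASCII PLY, PCD or XYZ-CSV cloud; format from the extension."""
    path = Path(path)
    fmt = _format_of(path, fmt)
    if fmt == "ply":
        return _read_ply(path, frame)
    if fmt == "pcd":
        return _read_pcd(path, frame)
    df = pd.read_csv(path)
    for axis in ("x", "y", "z"):
        if axis not in df.columns:
            raise ParseError(f"{path}: XYZ CSV lacks column {axis!r}")
    return PointCloud(df[["x", "y", "z"]].to_numpy(dtype=float), frame)


# -- polygons ---------------------------------------------------------------


def write_polygons(polygons: list[ParcelPolygon], path, crs: str | None = None) -> None:
    """Write parcel rings as a GeoJSON FeatureCollection with a crs property."""
    features = []
    for p in polygons:
        ring = np.vstack([p.vertices, p.vertices[:1]])
        features.append(
            {
                "type": "Feature",
                "properties": {"parcel_id": p.parcel_id},
                "geometry": {"type": "Polygon", "coordinates": [ring.tolist()]},
            }
        )
    doc = {
        "type": "FeatureCollection",
        "crs": crs if crs is not None else (polygons[0].frame if polygons else "local"),
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def read_polygons(path, anchor=None, frame: str | None = None) -> list[ParcelPolygon]:
    """Read parcel rings from GeoJSON.

    A geographic ``crs`` ("EPSG:4326" / "WGS84") triggers conversion of
    each lon/lat vertex to UTM; ``anchor`` (easting, northing) is then
    subtracted so coordinates match the pipeline's relative-UTM frame.
    Any other crs string is treated as an already-projected frame name.
    """
    doc = json.loads(Path(path).read_text())
    crs = doc.get("crs", "EPSG:4326")
    if isinstance(crs, dict):  # legacy GeoJSON crs object
        crs = crs.get("properties", {}).get("name", "EPSG:4326")
    geographic = str(crs).upper() in ("EPSG:4326", "WGS84", "CRS84", "OGC:CRS84")
    out = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise SchemaError(f"{path}: unsupported geometry type {geom.get('type')!r}")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        pid = str(feat.get("properties", {}).get("parcel_id", len(out)))
        if geographic:
            utm = [wgs84_to_utm(GeoCoordinate.from_degrees(lat, lon)) for lon, lat in ring[:, :2]]
            ring = np.array([[u.easting, u.northing] for u in utm])
        if anchor is not None:
            ring = ring - np.asarray(anchor, dtype=float)[:2]
        out.append(ParcelPolygon(ring, pid, frame or ("utm" if geographic else str(crs))))
    ids = [p.parcel_id for p in out]
    if len(set(ids)) != len(ids):
        raise SchemaError(f"{path}: duplicated parcel ids")
    return out


# -- tables -----------------------------------------------------------------

_TREATMENT_COLS = ("parcel_id", "n_applied_kg_ha")


def read_treatments(path) -> pd.DataFrame:
    """Read a treatment table CSV (parcel_id, n_applied_kg_ha[, mean_height_m])."""
    df = pd.read_csv(path)
    for col in _TREATMENT_COLS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    df["parcel_id"] = df["parcel_id"].astype(str)
    if df["parcel_id"].duplicated().any():
        dupes = df.loc[df["parcel_id"].duplicated(), "parcel_id"].tolist()
        raise SchemaError(f"{path}: duplicated parcel ids {dupes}")
    if (df["n_applied_kg_ha"] < 0).any():
        raise SchemaError(f"{path}: negative nitrogen doses")
    return df


def write_treatments(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_summaries(summaries, path) -> None:
    """Write parcel summaries as CSV."""
    pd.DataFrame(
        {
            "parcel_id": [s.parcel_id for s in summaries],
            "mean_height_m": [s.mean_height for s in summaries],
            "volume_m3": [s.volume for s in summaries],
            "n_pixels": [s.n_pixels for s in summaries],
            "interp_fraction": [s.interpolated_fraction for s in summaries],
        }
    ).to_csv(path, index=False, float_format="%.6f")


# -- rasters ----------------------------------------------------------------


def write_pixel_grid(grid: PixelGrid, path, nodata: float = -9999.0) -> None:
    """Write a raster as ESRI ASCII grid plus a JSON sidecar.

    The sidecar (``<path>.json``) carries the frame, origin and resolution
    (ESRI headers only hold a single square cell size).
    """
    if not math.isclose(grid.resolution[0], grid.resolution[1]):
        raise FormatError("ESRI ASCII grids require square cells")
    path = Path(path)
    nx, ny = grid.values.shape
    vals = np.where(grid.valid, grid.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\nnrows {ny}\n")
        fh.write(f"xllcorner {grid.origin[0]:.8f}\nyllcorner {grid.origin[1]:.8f}\n")
        fh.write(f"cellsize {grid.resolution[0]:.8f}\nNODATA_value {nodata}\n")
        for j in range(ny - 1, -1, -1):  # top row first
            fh.write(" ".join(_FLOAT_FMT % v for v in vals[:, j]) + "\n")
    sidecar = {"frame": grid.frame, "origin": list(map(float, grid.origin)),
               "resolution": list(grid.resolution)}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_pixel_grid(path) -> PixelGrid:
    path = Path(path)
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        rows = np.loadtxt(fh, ndmin=2)
    nx, ny = int(header["ncols"]), int(header["nrows"])
    if rows.shape != (ny, nx):
        raise ParseError(f"{path}: grid body {rows.shape} does not match header ({ny}, {nx})")
    vals = rows[::-1].T.astype(float)  # back to [i, j] with j increasing north
    vals[vals == header["nodata_value"]] = np.nan
    frame = "local"
    res = (header["cellsize"], header["cellsize"])
    origin = (header["xllcorner"], header["yllcorner"])
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        frame = meta.get("frame", frame)
        res = tuple(meta.get("resolution", res))
        origin = tuple(meta.get("origin", origin))
    return PixelGrid(vals, res, np.asarray(origin), frame)


# -- voxel grids ------------------------------------------------------------


def write_voxel_grid(grid: VoxelGrid, path) -> None:
    """Sparse voxel CSV (i, j, k, count, mean_z) with a JSON header sidecar."""
    path = Path(path)
    pd.DataFrame(
        {
            "i": grid.indices[:, 0],
            "j": grid.indices[:, 1],
            "k": grid.indices[:, 2],
            "count": grid.counts,
            "mean_z": grid.mean_z,
        }
    ).to_csv(path, index=False, float_format="%.8f")
    meta = {
        "origin": list(map(float, grid.origin)),
        "resolution": list(grid.resolution),
        "frame": grid.frame,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta))


def read_voxel_grid(path) -> VoxelGrid:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return VoxelGrid(
        tuple(meta["resolution"]),
        np.asarray(meta["origin"]),
        df[["i", "j", "k"]].to_numpy(dtype=np.int64),
        df["count"].to_numpy(dtype=np.int64),
        df["mean_z"].to_numpy(dtype=float),
        meta.get("frame", "local"),
    )


# -- pose streams -----------------------------------------------------------


def write_pose_stream(poses: list[Pose], path) -> None:
    """Pose CSV: timestamp, x, y, z (frame metres), qw, qx, qy, qz."""
    rows = []
    for p in poses:
        x, y, z = p.position
        qx, qy, qz, qw = p.quaternion
        rows.append((p.timestamp, x, y, z, qw, qx, qy, qz))
    pd.DataFrame(rows, columns=["timestamp", "x", "y", "z", "qw", "qx", "qy", "qz"]).to_csv(
        path, index=False, float_format="%.10f"
    )


def read_pose_stream(path, anchor=None) -> list[Pose]:
    """Read a pose CSV.

    Accepts either projected columns (x, y, z) or geodetic ones
    (lat, lon, alt in degrees), which are converted through the UTM
    projection with ``anchor`` (easting, northing) subtracted.
    """
    df = pd.read_csv(path)
    for col in ("timestamp", "qw", "qx", "qy", "qz"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    poses = []
    geographic = "lat" in df.columns and "lon" in df.columns
    if not geographic and not {"x", "y", "z"} <= set(df.columns):
        raise SchemaError(f"{path}: needs either x/y/z or lat/lon/alt columns")
    for row in df.itertuples(index=False):
        if geographic:
            u = wgs84_to_utm(GeoCoordinate.from_degrees(row.lat, row.lon, getattr(row, "alt", 0.0)))
            pos = np.array([u.easting, u.northing, u.altitude])
            if anchor is not None:
                pos[:2] -= np.asarray(anchor, dtype=float)[:2]
        else:
            pos = np.array([row.x, row.y, row.z])
        q = np.array([row.qx, row.qy, row.qz, row.qw])
        q = q / np.linalg.norm(q)  # renormalise against CSV rounding
        poses.append(Pose(float(row.timestamp), pos, q))
    return poses
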