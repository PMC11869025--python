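"""GNSS-fused yield mapping: join per-plant counts to trunk coordinates
and interpolate a bunch-count surface by inverse distance weighting.

Trunk positions come from an RTK-grade GNSS survey in a projected CRS
(defaults to ETRS89 / UTM 29N, EPSG:25829, the zone of the vineyards the
package models), so distances are plain Euclidean meters. The IDW value
at a cell center is

    z(c) = sum_i d_i^-p * z_i / sum_i d_i^-p

over the k nearest populated plants, with exact interpolation at data
points (a cell center within 1e-9 m of a plant takes that plant's count;
coinciding plants are averaged). Defaults p = 2, k = 12, 1 m cells follow
common geostatistical practice; none is prescribed by the survey design
and all are configurable.

The module performs no reprojection: all inputs must share one CRS
(checked), conversion is the caller's job.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .synthetic_scene import DEFAULT_CRS, TrunkRecord

NODATA = -9999.0


@dataclasses.dataclass
class YieldRaster:
    """Georeferenced grid of interpolated per-cell bunch counts.

    ``origin`` is the lower-left corner (ESRI convention); row 0 of
    ``values`` is the northernmost row.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    nodata: float = NODATA
    crs: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        vals = np.asarray(self.values, dtype=float)
        bad = ~np.isfinite(vals) & (vals != self.nodata)
        if bad.any():
            raise ValueError("raster values must be finite or nodata")
        self.values = vals

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nx) + 0.5) * self.cell_size
        ys = y0 + (ny - np.arange(ny) - 0.5) * self.cell_size  # row 0 = north
        return xs, ys


@dataclasses.dataclass
class JoinReport:
    matched: int
    unmatched_images: list[str]
    excluded_replants: list[str]


def join_counts(
    trunks: Sequence[TrunkRecord],
    counts: Mapping[str, int],
    link: Mapping[str, str],
) -> tuple[list[TrunkRecord], JoinReport]:
    """Attach per-image bunch counts to trunk records via an image->plant map.

    Replant-flagged plants (young vines not in full production) are
    excluded from the populated output; image ids without a known plant
    are reported, not silently dropped. Two images linked to one plant is
    an error.
    """
    plant_targets = list(link.values())
    dupes = {p for p in plant_targets if plant_targets.count(p) > 1}
    if dupes:
        raise ValueError(f"duplicate image->plant links for plants: {sorted(dupes)}")
    by_id = {t.plant_id: t for t in trunks}
    populated: list[TrunkRecord] = []
    unmatched: list[str] = []
    excluded: list[str] = []
    for image_id, count in counts.items():
        plant_id = link.get(image_id)
        if plant_id is None or plant_id not in by_id:
            unmatched.append(image_id)
            continue
        trunk = by_id[plant_id]
        if trunk.replant_flag:
            excluded.append(plant_id)
            continue
        populated.append(dataclasses.replace(trunk, count=int(count)))
    report = JoinReport(
        matched=len(populated),
        unmatched_images=sorted(unmatched),
        excluded_replants=sorted(excluded),
    )
    return populated, report


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Target grid: lower-left origin, cell size, and cell counts."""

    origin: tuple[float, float]
    cell_size: float
    nx: int
    ny: int

    @classmethod
    def covering(
        cls, eastings: Iterable[float], northings: Iterable[float],
        cell_size: float = 1.0, padding: float = 2.0,
    ) -> "GridSpec":
        e = np.asarray(list(eastings))
        n = np.asarray(list(northings))
        x0, y0 = e.min() - padding, n.min() - padding
        nx = int(np.ceil((e.max() + padding - x0) / cell_size))
        ny = int(np.ceil((n.max() + padding - y0) / cell_size))
        return cls(origin=(x0, y0), cell_size=cell_size, nx=max(nx, 1), ny=max(ny, 1))


_COINCIDENCE_EPS = 1e-9  # meters; exact-interpolation rule at data points


def idw_interpolate(
    points: Sequence[TrunkRecord],
    grid: GridSpec,
    power: float = 2.0,
    neighbors: int = 12,
) -> YieldRaster:
    """Inverse-distance-weighted bunch-count surface on ``grid``."""
    if neighbors < 1:
        raise ValueError("neighbors must be >= 1")
    populated = [p for p in points if p.count is not None]
    if not populated:
        raise ValueError("no populated points to interpolate")
    crss = {p.crs for p in populated}
    if len(crss) > 1:
        raise ValueError(f"points mix CRSs: {sorted(crss)}")
    xy = np.array([(p.easting, p.northing) for p in populated])
    z = np.array([float(p.count) for p in populated])
    tree = cKDTree(xy)
    k = min(neighbors, len(populated))

    raster = YieldRaster(
        origin=grid.origin,
        cell_size=grid.cell_size,
        values=np.full((grid.ny, grid.nx), NODATA),
        crs=populated[0].crs,
    )
    xs, ys = raster.cell_centers()
    cx, cy = np.meshgrid(xs, ys)
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    gx0, gy0 = grid.origin
    gx1 = gx0 + grid.nx * grid.cell_size
    gy1 = gy0 + grid.ny * grid.cell_size
    if (
        gx0 > xy[:, 0].min() or gx1 < xy[:, 0].max()
        or gy0 > xy[:, 1].min() or gy1 < xy[:, 1].max()
    ):
        import warnings

        warnings.warn("interpolation grid does not cover all data points", stacklevel=2)
    dist, idx = tree.query(centers, k=k)
    dist = np.atleast_2d(dist.reshape(len(centers), k))
    idx = np.atleast_2d(idx.reshape(len(centers), k))
    values = np.empty(len(centers))
    coincident = dist[:, 0] < _COINCIDENCE_EPS
    for row in np.nonzero(coincident)[0]:
        hit = dist[row] < _COINCIDENCE_EPS
        values[row] = z[idx[row][hit]].mean()
    free = ~coincident
    if free.any():
        w = dist[free] ** (-power)
        values[free] = (w * z[idx[free]]).sum(axis=1) / w.sum(axis=1)
    raster.values = values.reshape(grid.ny, grid.nx)
    return raster


# ---------------------------------------------------------------------------
# exports


def export_raster(raster: YieldRaster, path: Path | str) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    ny, nx = raster.values.shape
    header = (
        f"ncols {nx}\n"
        f"nrows {ny}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {raster.nodata:.6f}\n"
    )
    body = "\n".join(
        " ".join(f"{v:.6f}" for v in row) for row in raster.values
    )
    Path(path).write_text(header + body + "\n")


def read_raster(path: Path | str, crs: str = DEFAULT_CRS) -> YieldRaster:
    """Read an ESRI ASCII grid written by :func:`export_raster`."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    values = np.array([[float(v) for v in line.split()] for line in lines[body_start:] if line.strip()])
    return YieldRaster(
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        values=values,
        nodata=header.get("nodata_value", NODATA),
        crs=crs,
    )


def export_points_csv(records: Sequence[TrunkRecord], path: Path | str) -> None:
    rows = [
        {
            "plant_id": r.plant_id,
            "easting": r.easting,
            "northing": r.northing,
            "count": r.count,
            "esca": int(r.esca_flag),
            "replant": int(r.replant_flag),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_points_csv(path: Path | str, crs: str = DEFAULT_CRS) -> list[TrunkRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        count = row.get("count")
        records.append(
            TrunkRecord(
                plant_id=str(row["plant_id"]),
                easting=float(row["easting"]),
                northing=float(row["northing"]),
                crs=crs,
                count=None if pd.isna(count) else int(count),
                esca_flag=bool(row.get("esca", 0)),
                replant_flag=bool(row.get("replant", 0)),
            )
        )
    return records


def export_points_geojson(records: Sequence[TrunkRecord], path: Path | str) -> None:
    """GeoJSON FeatureCollection of trunk points, CRS tagged by name."""
    crs = records[0].crs if records else DEFAULT_CRS
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [r.easting, r.northing]},
            "properties": {
                "plant_id": r.plant_id,
                "count": r.count,
                "esca": r.esca_flag,
                "replant": r.replant_flag,
            },
        }
        for r in records
    ]
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs}},
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_points_geojson(path: Path | str) -> list[TrunkRecord]:
    doc = json.loads(Path(path).read_text())
    crs = doc.get("crs", {}).get("properties", {}).get("name", DEFAULT_CRS)
    records = []
    for feat in doc["features"]:
        x, y = feat["geometry"]["coordinates"]
        props = feat["properties"]
        count = props.get("count")
        records.append(
            TrunkRecord(
                plant_id=str(props["plant_id"]),
                easting=float(x),
                northing=float(y),
                crs=crs,
                count=None if count is None else int(count),
                esca_flag=bool(props.get("esca", False)),
                replant_flag=bool(props.get("replant", False)),
            )
        )
    return records
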