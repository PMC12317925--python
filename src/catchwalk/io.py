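"""Export of walks and batch products to GIS and tabular formats.

Walks go to a GeoPackage with two layers: ``points`` (one feature per
visited cell centre, attributed with run id and step index) and ``lines``
(one polyline per walk, attributed with run id, termination status and the
distance/direction statistics).  The GeoPackage container is written
directly over ``sqlite3`` following the OGC GeoPackage 1.3 layout
(``gpkg_spatial_ref_sys`` / ``gpkg_contents`` / ``gpkg_geometry_columns``
plus standard GPKG binary geometry blobs wrapping WKB), so the files open
in QGIS or any OGR-based stack.  Density grids go to GeoTIFF aligned
bit-exactly to the input raster, statistics and rose bins to CSV, and the
full run configuration to a JSON manifest.
"""

from __future__ import annotations

import json
import sqlite3
import struct
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import from_wkb, to_wkb
from shapely.geometry import LineString, Point

from .batch import BatchResult
from .lattice import CostSurface
from .surfaces import write_geotiff
from .walker import Walk
from . import walkstats

__all__ = [
    "export_walks",
    "read_gpkg_layer",
    "export_density",
    "export_stats",
    "export_rose_bins",
    "write_manifest",
]

_GPKG_APPLICATION_ID = 0x47504B47  # 'GPKG'
_GPKG_USER_VERSION = 10300  # GeoPackage 1.3


def _srs_id(crs_id: str | None) -> int:
    if crs_id and crs_id.upper().startswith("EPSG:"):
        try:
            return int(crs_id.split(":", 1)[1])
        except ValueError:
            return -1
    return -1  # undefined cartesian SRS


def _gpkg_blob(geom, srs_id: int) -> bytes:
    # GPKG binary header: magic 'GP', version 0, flags (little-endian, no
    # envelope), srs_id; then little-endian WKB.
    return (
        b"GP" + bytes([0, 0b00000001]) + struct.pack("<i", srs_id)
        + to_wkb(geom, byte_order=1)
    )


def _parse_gpkg_blob(blob: bytes):
    if blob[:2] != b"GP":
        raise ValueError("not a GeoPackage geometry blob")
    flags = blob[3]
    envelope_sizes = {0: 0, 1: 32, 2: 48, 3: 48, 4: 64}
    env = envelope_sizes[(flags >> 1) & 0b111]
    return from_wkb(bytes(blob[8 + env :]))


def _init_gpkg(conn: sqlite3.Connection, srs_id: int, crs_id: str | None) -> None:
    conn.execute(f"PRAGMA application_id = {_GPKG_APPLICATION_ID}")
    conn.execute(f"PRAGMA user_version = {_GPKG_USER_VERSION}")
    conn.execute(
        """CREATE TABLE gpkg_spatial_ref_sys (
             srs_name TEXT NOT NULL, srs_id INTEGER PRIMARY KEY,
             organization TEXT NOT NULL, organization_coordsys_id INTEGER NOT NULL,
             definition TEXT NOT NULL, description TEXT)"""
    )
    conn.execute(
        "INSERT INTO gpkg_spatial_ref_sys VALUES "
        "('Undefined cartesian', -1, 'NONE', -1, 'undefined', NULL)"
    )
    conn.execute(
        "INSERT INTO gpkg_spatial_ref_sys VALUES "
        "('Undefined geographic', 0, 'NONE', 0, 'undefined', NULL)"
    )
    if srs_id > 0:
        conn.execute(
            "INSERT INTO gpkg_spatial_ref_sys VALUES (?, ?, 'EPSG', ?, 'undefined', ?)",
            (crs_id, srs_id, srs_id, f"CRS read from source raster: {crs_id}"),
        )
    conn.execute(
        """CREATE TABLE gpkg_contents (
             table_name TEXT NOT NULL PRIMARY KEY, data_type TEXT NOT NULL,
             identifier TEXT UNIQUE, description TEXT DEFAULT '',
             last_change DATETIME NOT NULL DEFAULT '2000-01-01T00:00:00.000Z',
             min_x DOUBLE, min_y DOUBLE, max_x DOUBLE, max_y DOUBLE,
             srs_id INTEGER)"""
    )
    conn.execute(
        """CREATE TABLE gpkg_geometry_columns (
             table_name TEXT NOT NULL, column_name TEXT NOT NULL,
             geometry_type_name TEXT NOT NULL, srs_id INTEGER NOT NULL,
             z TINYINT NOT NULL, m TINYINT NOT NULL,
             PRIMARY KEY (table_name, column_name))"""
    )


def _register_layer(
    conn: sqlite3.Connection,
    name: str,
    geom_type: str,
    srs_id: int,
    bounds: tuple[float, float, float, float],
) -> None:
    conn.execute(
        "INSERT INTO gpkg_contents (table_name, data_type, identifier, "
        "min_x, min_y, max_x, max_y, srs_id) VALUES (?, 'features', ?, ?, ?, ?, ?, ?)",
        (name, name, *bounds, srs_id),
    )
    conn.execute(
        "INSERT INTO gpkg_geometry_columns VALUES (?, 'geom', ?, ?, 0, 0)",
        (name, geom_type, srs_id),
    )


def export_walks(
    walks: list[Walk], path: str | Path, crs_id: str | None = None
) -> None:
    """Write walks to a two-layer GeoPackage (``points`` and ``lines``).

    ``points``: one feature per visited cell centre with run id and step
    index.  ``lines``: one polyline per walk (single-cell walks get a
    degenerate zero-length two-point line) with run id, status, total and
    resultant distance, deviation percentage and azimuth.
    """
    if not walks:
        raise ValueError("export_walks requires at least one walk")
    path = Path(path)
    if path.exists():
        path.unlink()
    srs = _srs_id(crs_id)
    allc = np.vstack([w.centres for w in walks])
    bounds = (
        float(allc[:, 0].min()), float(allc[:, 1].min()),
        float(allc[:, 0].max()), float(allc[:, 1].max()),
    )
    conn = sqlite3.connect(path)
    try:
        with conn:
            _init_gpkg(conn, srs, crs_id)
            _register_layer(conn, "points", "POINT", srs, bounds)
            _register_layer(conn, "lines", "LINESTRING", srs, bounds)
            conn.execute(
                """CREATE TABLE points (
                     fid INTEGER PRIMARY KEY AUTOINCREMENT, geom BLOB,
                     run_id INTEGER, step_index INTEGER)"""
            )
            conn.execute(
                """CREATE TABLE lines (
                     fid INTEGER PRIMARY KEY AUTOINCREMENT, geom BLOB,
                     run_id INTEGER, status TEXT, total_distance DOUBLE,
                     resultant_distance DOUBLE, deviation_pct DOUBLE,
                     azimuth_deg DOUBLE)"""
            )
            for run_id, walk in enumerate(walks):
                for step, (x, y) in enumerate(walk.centres):
                    conn.execute(
                        "INSERT INTO points (geom, run_id, step_index) VALUES (?, ?, ?)",
                        (_gpkg_blob(Point(x, y), srs), run_id, step),
                    )
                coords = [tuple(c) for c in walk.centres]
                if len(coords) == 1:
                    coords = coords * 2  # degenerate zero-length line
                s = walkstats.walk_distances(walk)
                conn.execute(
                    "INSERT INTO lines (geom, run_id, status, total_distance, "
                    "resultant_distance, deviation_pct, azimuth_deg) "
                    "VALUES (?, ?, ?, ?, ?, ?, ?)",
                    (
                        _gpkg_blob(LineString(coords), srs), run_id, walk.status,
                        s.total_distance, s.resultant_distance, s.deviation_pct,
                        s.azimuth_deg,
                    ),
                )
    finally:
        conn.close()


def read_gpkg_layer(path: str | Path, layer: str) -> list[tuple[object, dict]]:
    """Read a feature layer back: list of (shapely geometry, attributes)."""
    conn = sqlite3.connect(path)
    try:
        cur = conn.execute(f"SELECT * FROM {layer} ORDER BY fid")  # noqa: S608
        cols = [d[0] for d in cur.description]
        out = []
        for row in cur.fetchall():
            rec = dict(zip(cols, row))
            geom = _parse_gpkg_blob(rec.pop("geom"))
            out.append((geom, rec))
        return out
    finally:
        conn.close()


def export_density(
    density: np.ndarray, surface: CostSurface, path: str | Path
) -> None:
    """Write a walk-density grid as GeoTIFF aligned to ``surface``."""
    write_geotiff(density.astype(np.int32), surface, path)


def export_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats.to_csv(path, index=False)


def export_rose_bins(
    azimuths: list[float], bin_width: float, path: str | Path
) -> pd.DataFrame:
    """Compute and write sqrt-scaled rose bins; returns the table written."""
    heights = walkstats.rose_bins(azimuths, bin_width)
    table = pd.DataFrame(
        {
            "bin_start_deg": np.arange(len(heights)) * bin_width,
            "bin_end_deg": (np.arange(len(heights)) + 1) * bin_width,
            "count": np.round(heights**2).astype(int),
            "sqrt_height": heights,
        }
    )
    table.to_csv(path, index=False)
    return table


def write_manifest(config: dict, path: str | Path) -> None:
    from . import __version__

    manifest = {"software": "catchwalk", "version": __version__, **config}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def export_batch(
    result: BatchResult,
    surface: CostSurface,
    outdir: str | Path,
    rose_bin_width: float = 15.0,
) -> dict[str, Path]:
    """Write all batch products into ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "walks": outdir / "walks.gpkg",
        "density": outdir / "density.tif",
        "stats": outdir / "stats.csv",
        "rose_bins": outdir / "rose_bins.csv",
    }
    if result.walks:
        export_walks(result.walks, paths["walks"], crs_id=surface.crs_id)
    export_density(result.density, surface, paths["density"])
    export_stats(result.stats_table, paths["stats"])
    az = [
        a for a in result.stats_table["azimuth_deg"].tolist()
        if a is not None and not (isinstance(a, float) and np.isnan(a))
    ]
    export_rose_bins(az, rose_bin_width, paths["rose_bins"])
    return paths
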