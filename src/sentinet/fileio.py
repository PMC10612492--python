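"""Readers and writers: rasters, park vectors, node tables, results.

Rasters travel as ESRI ASCII grids (``.asc``, the 6-line-header text
format with a NODATA_value sentinel) or as TIFF via :mod:`tifffile`, with
cell size, origin and CRS carried in a JSON ImageDescription tag.  Park
layers are GeoJSON FeatureCollections.  Pairwise resistances are written
both as a Circuitscape-style 3-column text file and as a square CSV matrix
keyed by park id.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .circuit import NodePixel, PairwiseResult
from .cost_surface import CostRaster, Park, ParkLayer

__all__ = [
    "read_grid",
    "write_raster",
    "read_cost_raster",
    "read_parks_geojson",
    "write_parks_geojson",
    "write_nodes_csv",
    "read_nodes_csv",
    "write_resistances",
]

_ASC_NODATA = -9999.0


# ---------------------------------------------------------------------------
# rasters


def _read_asc(path: Path) -> CostRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(val)
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value", _ASC_NODATA)
    mask = data == nodata
    return CostRaster.unchecked(
        data,
        mask,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )


def _write_asc(raster: CostRaster, path: Path) -> None:
    nrows, ncols = raster.shape
    data = np.where(raster.nodata_mask, _ASC_NODATA, raster.grid)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]:.10g}\n")
        fh.write(f"yllcorner {raster.origin[1]:.10g}\n")
        fh.write(f"cellsize {raster.cell_size:.10g}\n")
        fh.write(f"NODATA_value {_ASC_NODATA:g}\n")
        np.savetxt(fh, data, fmt="%.17g")


def _read_tif(path: Path) -> CostRaster:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    nodata = meta.get("nodata", _ASC_NODATA)
    mask = (data == nodata) | np.isnan(data)
    return CostRaster.unchecked(
        data,
        mask,
        cell_size=meta.get("cell_size", 1.0),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        crs=meta.get("crs"),
    )


def _write_tif(raster: CostRaster, path: Path) -> None:
    import tifffile

    meta = {
        "cell_size": raster.cell_size,
        "origin": list(raster.origin),
        "crs": raster.crs,
        "nodata": _ASC_NODATA,
    }
    data = np.where(raster.nodata_mask, _ASC_NODATA, raster.grid)
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_grid(path: str | Path) -> CostRaster:
    """Read a raster (.asc or .tif/.tiff) without cost-positivity checks.

    Current-density maps, which legitimately contain zeros, go through
    this; masked cells carry a placeholder value of 1 under the mask.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    if path.suffix.lower() in (".asc", ".txt"):
        return _read_asc(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_tif(path)
    raise ValueError(f"unsupported raster format: {path.suffix!r} (use .asc or .tif)")


def read_cost_raster(path: str | Path) -> CostRaster:
    """Read a cost raster, rejecting non-positive values outside NoData."""
    r = read_grid(path)
    bad = np.argwhere(~r.nodata_mask & ~(np.isfinite(r.grid) & (r.grid > 0)))
    if len(bad):
        raise ValueError(
            f"{path}: non-positive cost outside NoData at cells "
            f"{[(int(a), int(b)) for a, b in bad[:10]]}" + ("..." if len(bad) > 10 else "")
        )
    return r


def write_raster(raster_or_array, path: str | Path, template: CostRaster | None = None) -> None:
    """Write a CostRaster, or a bare array georeferenced from a template.

    Arrays may contain nan (written as NoData); that is how current maps
    are saved.
    """
    path = Path(path)
    if isinstance(raster_or_array, CostRaster):
        raster = raster_or_array
    else:
        arr = np.asarray(raster_or_array, dtype=float)
        mask = np.isnan(arr)
        if template is not None and template.shape == arr.shape:
            mask = mask | template.nodata_mask
        raster = CostRaster.unchecked(
            np.where(mask, 1.0, arr),
            mask,
            cell_size=template.cell_size if template else 1.0,
            origin=template.origin if template else (0.0, 0.0),
            crs=template.crs if template else None,
        )
    if path.suffix.lower() in (".asc", ".txt"):
        _write_asc(raster, path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        _write_tif(raster, path)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r} (use .asc or .tif)")


# ---------------------------------------------------------------------------
# parks and nodes


def read_parks_geojson(path: str | Path) -> ParkLayer:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parks file not found: {path}")
    with open(path) as fh:
        fc = json.load(fh)
    parks = []
    for i, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties", {}) or {}
        geom = shape(feat["geometry"])
        parks.append(
            Park(
                park_id=str(props.get("id", props.get("park_id", f"park-{i + 1:03d}"))),
                geometry=geom,
                designation=props.get("designation", "Provincial Park"),
                area_km2=props.get("area_km2"),
                is_island=bool(props.get("is_island", False)),
            )
        )
    return ParkLayer(parks)


def write_parks_geojson(parks: ParkLayer, path: str | Path) -> None:
    feats = []
    for p in parks:
        if p.geometry is None:
            raise ValueError(f"park {p.park_id!r} has no geometry to serialize")
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(shapely.set_precision(p.geometry, 1e-6)),
                "properties": {
                    "id": p.park_id,
                    "designation": p.designation,
                    "area_km2": p.area_km2,
                    "is_island": p.is_island,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_nodes_csv(
    nodes: list[NodePixel], path: str | Path, template: CostRaster, zones: dict[str, str] | None = None
) -> None:
    rows = []
    for nd in nodes:
        x, y = template.cell_center(nd.row, nd.col)
        rows.append(
            {
                "park_id": nd.park_id,
                "zone": (zones or {}).get(nd.park_id, ""),
                "row": nd.row,
                "col": nd.col,
                "x": x,
                "y": y,
                "cost_at_node": nd.cost,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_nodes_csv(path: str | Path) -> list[NodePixel]:
    df = pd.read_csv(path)
    return [
        NodePixel(str(r.park_id), int(r.row), int(r.col), float(r.cost_at_node))
        for r in df.itertuples()
    ]


def write_resistances(result: PairwiseResult, stem: str | Path) -> tuple[Path, Path]:
    """Write pairwise resistances in both interchange layouts.

    ``<stem>_resistances_3col.txt`` is Circuitscape-style (node_id_1,
    node_id_2, resistance); ``<stem>_resistances.csv`` is the square matrix
    with park ids as headers.  Unreachable pairs serialize as ``inf``.
    """
    stem = Path(stem)
    ids = [nd.park_id for nd in result.nodes]
    n = len(ids)
    three = stem.parent / (stem.name + "_resistances_3col.txt")
    with open(three, "w") as fh:
        for i in range(n):
            for j in range(i + 1, n):
                fh.write(f"{ids[i]} {ids[j]} {result.resistances[i, j]:.12g}\n")
    square = stem.parent / (stem.name + "_resistances.csv")
    pd.DataFrame(result.resistances, index=ids, columns=ids).to_csv(square)
    return three, square
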