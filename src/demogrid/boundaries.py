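"""Administrative boundary sets: polygons with joinable attributes.

A thin container over shapely geometries plus a per-unit attribute table,
read and written as GeoJSON (WGS84 lon/lat).  Polygon order is preserved:
rasterisation assigns ties (a cell center exactly on a shared edge) to the
first polygon in file order, so order is part of the contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


@dataclass
class AdminBoundarySet:
    """Ordered polygons keyed by ``unit_id`` with an attribute table.

    ``attributes`` is indexed by ``unit_id`` (one row per polygon, same
    order as ``geometries``) and carries whatever fields are to be joined
    or rasterised, e.g. ``admin1_id`` or the standardised proportions.
    """

    geometries: list[BaseGeometry]
    attributes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.attributes.empty and self.geometries:
            self.attributes = pd.DataFrame(index=range(len(self.geometries)))
        if len(self.geometries) != len(self.attributes):
            raise ValueError("one attribute row per geometry required")
        if self.attributes.index.has_duplicates:
            raise ValueError("unit_id index must be unique")
        for geom in self.geometries:
            if not geom.is_valid:
                raise ValueError(f"invalid geometry: {geom.wkt[:80]}")

    @property
    def unit_ids(self) -> list:
        return list(self.attributes.index)

    def __len__(self) -> int:
        return len(self.geometries)

    def join(self, table: pd.DataFrame, on: str | None = None) -> "AdminBoundarySet":
        """Join attribute columns from ``table`` by unit id (index join)."""
        joined = self.attributes.join(
            table.set_index(on) if on else table, how="left"
        )
        return AdminBoundarySet(self.geometries, joined)

    def to_geojson(self, path: str | Path) -> None:
        features = []
        for (uid, row), geom in zip(self.attributes.iterrows(), self.geometries):
            props = {"unit_id": uid, **{k: _jsonable(v) for k, v in row.items()}}
            features.append(
                {"type": "Feature", "properties": props, "geometry": mapping(geom)}
            )
        doc = {
            "type": "FeatureCollection",
            "crs": {"type": "name", "properties": {"name": "urn:ogc:def:crs:OGC:1.3:CRS84"}},
            "features": features,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "AdminBoundarySet":
        doc = json.loads(Path(path).read_text())
        geoms, rows, ids = [], [], []
        for feat in doc["features"]:
            geoms.append(shape(feat["geometry"]))
            props = dict(feat.get("properties", {}))
            ids.append(props.pop("unit_id"))
            rows.append(props)
        attrs = pd.DataFrame(rows, index=pd.Index(ids, name="unit_id"))
        return cls(geoms, attrs)


def _jsonable(v):
    if hasattr(v, "item"):
        return v.item()
    return v
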