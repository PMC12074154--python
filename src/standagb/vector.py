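"""GeoJSON I/O for species-attributed stand polygons (shapely geometries)."""

from __future__ import annotations

import json
from pathlib import Path

from shapely.geometry import mapping, shape

__all__ = ["read_stands", "write_stands"]


def write_stands(stands, path) -> None:
    """Write ``(polygon, species)`` pairs as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "properties": {"id": i, "species": species},
            "geometry": mapping(geom),
        }
        for i, (geom, species) in enumerate(stands)
    ]
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(fc))


def read_stands(path):
    """Read a FeatureCollection back into ``[(polygon, species), ...]``."""
    fc = json.loads(Path(path).read_text())
    out = []
    for feat in fc["features"]:
        props = feat.get("properties") or {}
        if "species" not in props:
            raise ValueError("stand feature lacks a 'species' property")
        out.append((shape(feat["geometry"]), props["species"]))
    return out
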