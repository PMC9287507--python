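"""GeoJSON FeatureCollection and CSV helpers.

Geometry I/O is deliberately thin: GeoJSON is plain JSON with shapely's
mapping/shape round-trip; thematic attributes travel as feature properties.
All files are UTF-8; floats are serialised with repr so coordinates
round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

from shapely.geometry import mapping, shape


def write_feature_collection(
    path: Path | str,
    geometries: Sequence,
    properties: Sequence[Mapping] | None = None,
) -> None:
    props = properties if properties is not None else [{}] * len(geometries)
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": dict(p)}
        for g, p in zip(geometries, props)
    ]
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))


def read_feature_collection(path: Path | str) -> tuple[list, list[dict]]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    geoms, props = [], []
    for feat in doc.get("features", []):
        geoms.append(shape(feat["geometry"]))
        props.append(feat.get("properties") or {})
    return geoms, props
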