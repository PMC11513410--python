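"""Plain-text serialisation: GeoJSON polygons, YAML configs, manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import shapely
from shapely.geometry import mapping, shape
import yaml


def write_geojson(path, geometries, properties: list[dict] | None = None) -> None:
    """Write shapely geometries as a GeoJSON FeatureCollection."""
    feats = []
    for k, geom in enumerate(geometries):
        props = properties[k] if properties else {}
        feats.append({"type": "Feature", "geometry": mapping(geom), "properties": props})
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_geojson(path) -> tuple[list[shapely.Geometry], list[dict]]:
    data = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in data["features"]]
    props = [f.get("properties", {}) for f in data["features"]]
    return geoms, props


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _builtin(obj):
    """Recursively convert numpy scalars/arrays and tuples to plain types."""
    import numpy as np

    if isinstance(obj, dict):
        return {k: _builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_builtin(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def dump_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_builtin(obj), fh, sort_keys=False)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, stage: str, inputs: list, config: dict, seed: int) -> None:
    """Record provenance of a stage's outputs: inputs' checksums, the
    config echo, the seed, and the package version."""
    from . import __version__

    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": seed,
        "inputs": {str(p): file_checksum(p) for p in inputs if Path(p).exists()},
        "config": config,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
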