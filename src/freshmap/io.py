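"""Plain-text readers/writers for scenes, rasters and training sets.

Rasters travel as CSV grids (one row per raster row) with a small JSON
sidecar holding the legend / band names and nodata code; polygons are
GeoJSON; training sets are CSV. These formats keep every artefact
human-inspectable and diff-able.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .types import FEATURE_NAMES, FeatureImage, LabelImage, TrainingSet


def write_label_image(path: str | Path, image: LabelImage) -> None:
    path = Path(path)
    np.savetxt(path, image.labels, fmt="%d", delimiter=",")
    sidecar = {
        "legend": {str(k): v for k, v in image.legend.items()},
        "nodata": image.nodata,
        "transform": list(image.transform),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_label_image(path: str | Path) -> LabelImage:
    path = Path(path)
    labels = np.loadtxt(path, dtype=int, delimiter=",", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    legend = {int(k): v for k, v in meta["legend"].items()}
    return LabelImage(labels, legend, meta["nodata"], tuple(meta["transform"]))


def write_feature_image(path: str | Path, image: FeatureImage) -> None:
    """One CSV per feature band inside a directory, plus a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(image.band_names):
        band = np.where(image.nodata_mask, np.nan, image.data[..., i])
        np.savetxt(path / f"{name}.csv", band, delimiter=",", fmt="%.6f")
    manifest = {
        "bands": list(image.band_names),
        "transform": list(image.transform),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    np.savetxt(path / "n_valid.csv", image.n_valid, fmt="%d", delimiter=",")


def read_feature_image(path: str | Path) -> FeatureImage:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    bands = [
        np.loadtxt(path / f"{name}.csv", delimiter=",", ndmin=2)
        for name in manifest["bands"]
    ]
    data = np.stack(bands, axis=-1)
    nodata = ~np.isfinite(data).all(axis=2)
    n_valid = np.loadtxt(path / "n_valid.csv", dtype=int, delimiter=",", ndmin=2)
    return FeatureImage(data, nodata, n_valid, tuple(manifest["transform"]))


def write_polygons(path: str | Path, polygons, properties: list[dict] | None = None) -> None:
    feats = []
    for i, poly in enumerate(polygons):
        props = properties[i] if properties else {"id": i}
        feats.append({"type": "Feature", "geometry": mapping(poly), "properties": props})
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_polygons(path: str | Path):
    doc = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in doc["features"]]
    props = [f.get("properties", {}) for f in doc["features"]]
    return geoms, props


def write_training_set(path: str | Path, training: TrainingSet) -> None:
    training.to_frame().to_csv(path, index=False)


def read_training_set(path: str | Path) -> TrainingSet:
    frame = pd.read_csv(path)
    return TrainingSet(
        X=frame[list(FEATURE_NAMES)].to_numpy(),
        y=frame["class"].to_numpy(),
        stratum=frame["stratum"].to_numpy(),
        rows=frame["row"].to_numpy(),
        cols=frame["col"].to_numpy(),
        reliable=frame["reliable"].to_numpy(dtype=bool),
        post_ci_filter=frame["post_ci_filter"].to_numpy(dtype=bool),
    )
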