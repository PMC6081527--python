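"""On-disk formats: multi-page TIFF + JSON sidecar, NPZ archive, CSV.

An image series is written as a 16-bit multi-page TIFF (one page per
frame) next to a ``<stem>.json`` sidecar holding timestamps, pixel size,
geometry and provenance metadata.  A compact single-file ``.npz`` archive
of the same content is provided for tests and scripting.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .config import PhantomGeometry
from .imaging import ImageSeries
from .tdc import TimeDensityCurve

__all__ = [
    "write_tiff_series",
    "read_tiff_series",
    "write_npz_series",
    "read_npz_series",
    "tdcs_to_csv",
]


def _sidecar_dict(series: ImageSeries) -> dict:
    return {
        "timestamps": series.timestamps.tolist(),
        "pixel_size": series.pixel_size,
        "origin": list(series.origin),
        "geometry": dataclasses.asdict(series.geometry),
        "meta": _jsonable(series.meta),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _series_from_parts(frames, sidecar) -> ImageSeries:
    geometry = PhantomGeometry(**sidecar["geometry"])
    return ImageSeries(
        timestamps=np.asarray(sidecar["timestamps"], dtype=float),
        frames=frames,
        pixel_size=float(sidecar["pixel_size"]),
        origin=tuple(sidecar["origin"]),
        geometry=geometry,
        meta=dict(sidecar.get("meta", {})),
    )


def write_tiff_series(series: ImageSeries, path: str | Path) -> Path:
    """Write frames as multi-page 16-bit TIFF with a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, series.frames.astype(np.uint16), photometric="minisblack")
    path.with_suffix(".json").write_text(json.dumps(_sidecar_dict(series), indent=1))
    return path


def read_tiff_series(path: str | Path) -> ImageSeries:
    """Read a TIFF + JSON sidecar pair written by :func:`write_tiff_series`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return _series_from_parts(frames.astype(np.uint16), sidecar)


def write_npz_series(series: ImageSeries, path: str | Path) -> Path:
    """Compact single-archive format (frames + metadata in one .npz)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        frames=series.frames.astype(np.uint16),
        sidecar=np.frombuffer(json.dumps(_sidecar_dict(series)).encode(), dtype=np.uint8),
    )
    return path


def read_npz_series(path: str | Path) -> ImageSeries:
    with np.load(path) as data:
        sidecar = json.loads(bytes(data["sidecar"].tobytes()).decode())
        frames = data["frames"]
    return _series_from_parts(frames, sidecar)


def tdcs_to_csv(tdcs: list[TimeDensityCurve], path: str | Path) -> Path:
    """Write TDCs as tidy CSV (columns: time_s, roi_label, value)."""
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = [
        pd.DataFrame(
            {"time_s": tdc.times, "roi_label": tdc.roi.label, "value": tdc.values}
        )
        for tdc in tdcs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path
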