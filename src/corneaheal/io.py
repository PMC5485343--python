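"""Reading and writing volumes, photos and measurement tables.

Volumes go to multi-page TIFF (one page per en face z-slice) with a JSON
sidecar carrying the scan geometry, cornea model, wound specification and
seed; photos to 8-bit PNG with a sidecar carrying the ground-truth scale and
wound geometry; tables to plain CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .geometry import CorneaModel, ScanSpec, WoundSpec
from .synthetic import NoiseSpec, OCTVolume, Photo

__all__ = [
    "write_volume",
    "read_volume",
    "write_photo",
    "read_photo",
    "write_series",
    "read_series",
]

SERIES_COLUMNS = [
    "animal_id",
    "arm",
    "timepoint_h",
    "true_area_mm2",
    "oct_area_mm2",
    "fluoro_area_mm2",
]


def _encode(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = dataclasses.asdict(obj)
        d["__type__"] = type(obj).__name__
        return d
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


_TYPES = {"CorneaModel": CorneaModel, "ScanSpec": ScanSpec, "WoundSpec": WoundSpec, "NoiseSpec": NoiseSpec}


def _decode(d: dict):
    if "__type__" in d:
        cls = _TYPES.get(d.pop("__type__"))
        if cls is not None:
            kwargs = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d.items()
                if k in {f.name for f in dataclasses.fields(cls)}
            }
            return cls(**kwargs)
    return d


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(path: str | Path, volume: OCTVolume) -> Path:
    """Write a volume as multi-page TIFF (pages = z-slices, each (ny, nx)) + JSON sidecar."""
    path = Path(path)
    # (nx, ny, nz) -> (nz, ny, nx) so each TIFF page is one en face slice
    pages = np.transpose(volume.intensity, (2, 1, 0)).astype(np.float32)
    tifffile.imwrite(path, pages)
    meta = {"scan": volume.scan, "axis_order": "zyx", **volume.metadata}
    _sidecar(path).write_text(json.dumps(meta, default=_encode, indent=1))
    return path


def read_volume(path: str | Path, extent: tuple[float, float, float] | None = None) -> OCTVolume:
    """Read a TIFF volume; scan geometry from the sidecar or an explicit ``extent``."""
    path = Path(path)
    pages = tifffile.imread(path)
    intensity = np.transpose(np.asarray(pages, dtype=np.float32), (2, 1, 0))
    side = _sidecar(path)
    meta: dict = {}
    if side.exists():
        meta = json.loads(side.read_text(), object_hook=_decode)
    scan = meta.pop("scan", None)
    if scan is None:
        if extent is None:
            raise ValueError(f"{path}: no sidecar scan geometry; pass extent=(x, y, z) in mm")
        scan = ScanSpec(extent=tuple(extent), samples=tuple(intensity.shape))
    meta.pop("axis_order", None)
    return OCTVolume(intensity=intensity, scan=scan, metadata=meta)


def write_photo(path: str | Path, photo: Photo) -> Path:
    """Write an 8-bit RGB PNG + JSON sidecar with ground-truth scale and geometry."""
    path = Path(path)
    iio.imwrite(path, photo.rgb)
    _sidecar(path).write_text(json.dumps(photo.metadata, default=_encode, indent=1))
    return path


def read_photo(path: str | Path) -> Photo:
    path = Path(path)
    rgb = np.asarray(iio.imread(path))
    if rgb.ndim == 3 and rgb.shape[2] == 4:
        rgb = rgb[..., :3]
    side = _sidecar(path)
    meta = json.loads(side.read_text(), object_hook=_decode) if side.exists() else {}
    if isinstance(meta.get("ruler_region"), list):
        meta["ruler_region"] = tuple(meta["ruler_region"])
    return Photo(rgb=rgb, metadata=meta)


def write_series(path: str | Path, series: pd.DataFrame) -> Path:
    """Write a measurement series as CSV with the canonical column order first."""
    path = Path(path)
    cols = [c for c in SERIES_COLUMNS if c in series.columns]
    cols += [c for c in series.columns if c not in cols]
    series[cols].to_csv(path, index=False)
    return path


def read_series(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
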