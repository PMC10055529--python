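"""Multi-page TIFF + JSON sidecar I/O.

Movies and volume series travel as multi-page TIFFs (one page per frame or
z-slice) with a JSON sidecar describing axis order, channel schedule, voxel
or pixel size and timestamps.  Writers are deterministic: identical arrays
and sidecars produce identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile


def write_stack(path, array: np.ndarray, sidecar: dict | None = None) -> Path:
    """Write a 2D/3D/4D array as a multi-page TIFF (+ ``.json`` sidecar).

    4D input (t, z, y, x) is flattened page-wise in t-then-z order, as
    recorded in the sidecar.
    """
    path = Path(path)
    arr = np.asarray(array)
    if arr.ndim == 4:
        arr = arr.reshape((-1,) + arr.shape[2:])
    tifffile.imwrite(path, arr)
    if sidecar is not None:
        write_json(path.with_suffix(".json"), sidecar)
    return path


def read_stack(path, with_sidecar: bool = True):
    path = Path(path)
    arr = tifffile.imread(path)
    if not with_sidecar:
        return arr
    sidecar_path = path.with_suffix(".json")
    sidecar = read_json(sidecar_path) if sidecar_path.exists() else None
    if sidecar and "shape" in sidecar:
        arr = arr.reshape(sidecar["shape"])
    return arr, sidecar


def write_json(path, obj: dict) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return path


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
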