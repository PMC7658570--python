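"""File I/O: multi-channel TIFF stacks with a JSON metadata sidecar.

Images travel as multi-page TIFF in (channel, z, y, x) page order, with a
``<stem>.meta.json`` sidecar recording voxel size (microns per z/y/x) and
channel names. Label volumes are single-channel integer TIFFs with the
same sidecar convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from aavfish.volumes import ImageVolume, LabelVolume


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_image(vol: ImageVolume, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(vol.data), photometric="minisblack")
    meta = {
        "axes": "CZYX",
        "voxel_size_um": list(vol.voxel_size),
        "channels": list(vol.channels),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_image(
    path: str | Path,
    channels: list[str] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> ImageVolume:
    """Read a multi-channel TIFF stack.

    Voxel size and channel names come from the sidecar unless overridden.
    If the file has no channel axis, a single channel is assumed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    names = channels or meta.get("channels")
    vs = voxel_size or meta.get("voxel_size_um")
    if vs is None:
        raise ValueError(
            f"{path}: voxel size not in sidecar and not overridden"
        )
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"{path}: cannot interpret shape {data.shape} as (c, z, y, x)")
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    if len(names) != data.shape[0]:
        raise ValueError(
            f"{path}: {data.shape[0]} channels in file but "
            f"{len(names)} channel names declared ({names})"
        )
    return ImageVolume(data, tuple(vs), tuple(names))


def write_labels(labels: LabelVolume, path: str | Path) -> None:
    path = Path(path)
    data = labels.data
    dtype = np.uint16 if data.max(initial=0) < 2**16 else np.uint32
    tifffile.imwrite(path, data.astype(dtype))
    meta = {"axes": "ZYX", "voxel_size_um": list(labels.voxel_size)}
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_labels(
    path: str | Path, voxel_size: tuple[float, float, float] | None = None
) -> LabelVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    vs = voxel_size or meta.get("voxel_size_um")
    if vs is None:
        raise ValueError(f"{path}: voxel size not in sidecar and not overridden")
    return LabelVolume(np.asarray(data).astype(np.int32), tuple(vs))


def write_mask(mask: np.ndarray, voxel_size, path: str | Path) -> None:
    write_labels(LabelVolume(mask.astype(np.int32), tuple(voxel_size)), path)


def read_mask(path: str | Path) -> np.ndarray:
    return read_labels(path).data > 0
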