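"""Reading and writing stacks, label volumes and object tables.

Stacks are written as OME-TIFF with voxel sizes (``PhysicalSizeX/Y/Z``, um)
and the channel name embedded; camera exposure, which OME-TIFF planes do
not carry in this minimal layout, travels in a small JSON sidecar next to
the image.  Cell masks are 16-bit label TIFFs; object tables are plain CSV.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import tifffile

from .errors import GeometryError
from .stack import VoxelStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_label_volume",
    "read_label_volume",
    "write_object_table",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_stack(stack: VoxelStack, path: str | Path) -> Path:
    """Write one channel as OME-TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path,
        np.asarray(stack.intensities, dtype=np.float32),
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": stack.dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.dz,
            "PhysicalSizeZUnit": "µm",
        },
    )
    _sidecar(path).write_text(
        json.dumps(
            {
                "channel_name": stack.channel_name,
                "exposure_ms": stack.exposure_ms,
                "dx_um": stack.dx,
                "dy_um": stack.dy,
                "dz_um": stack.dz,
            },
            indent=1,
        )
    )
    return path


def _voxel_sizes_from_ome(xml: str) -> dict[str, float]:
    out = {}
    for axis in "XYZ":
        m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', xml or "")
        if m:
            out[axis.lower()] = float(m.group(1))
    return out


def read_stack(
    path: str | Path,
    voxel_size_um: tuple[float, float, float] | None = None,
    channel_name: str | None = None,
    exposure_ms: float | None = None,
) -> VoxelStack:
    """Read a stack written by :func:`write_stack` (or any TIFF z-stack).

    Voxel sizes come from the OME metadata; ``voxel_size_um = (dx, dy, dz)``
    overrides or supplies them when the file has none.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            ome = tif.ome_metadata
    except Exception as exc:  # corrupt / truncated file
        raise OSError(f"could not read TIFF stack {path}: {exc}") from exc
    if data.size == 0 or data.ndim not in (2, 3):
        raise OSError(f"could not read TIFF stack {path}: no image data (truncated?)")
    if data.ndim == 2:
        data = data[np.newaxis]

    meta = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    sizes = _voxel_sizes_from_ome(ome) if ome else {}
    if voxel_size_um is not None:
        dx, dy, dz = voxel_size_um
    elif sizes.keys() >= {"x", "y", "z"}:
        dx, dy, dz = sizes["x"], sizes["y"], sizes["z"]
    elif {"dx_um", "dy_um", "dz_um"} <= meta.keys():
        dx, dy, dz = meta["dx_um"], meta["dy_um"], meta["dz_um"]
    else:
        raise GeometryError(
            f"{path} carries no voxel-size metadata; pass voxel_size_um=(dx, dy, dz) "
            "or the --voxel-size override on the command line"
        )
    return VoxelStack(
        intensities=data,
        dx=dx, dy=dy, dz=dz,
        channel_name=channel_name if channel_name is not None else meta.get("channel_name", path.stem),
        exposure_ms=exposure_ms if exposure_ms is not None else meta.get("exposure_ms", 1.0),
    )


def write_label_volume(labels: np.ndarray, path: str | Path) -> Path:
    """Write a 3-D label volume as a 16-bit (or 32-bit if needed) TIFF."""
    path = Path(path)
    labels = np.asarray(labels)
    dtype = np.uint16 if labels.max() < 2**16 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))
    return path


def read_label_volume(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_object_table(objects, path: str | Path) -> Path:
    """Write a LabeledObjectSet as the standard object CSV."""
    path = Path(path)
    objects.to_dataframe().to_csv(path, index=False, float_format="%.9g")
    return path
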