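"""Voxel volume container and TIFF-stack I/O.

A :class:`Volume` is a 3-D grid of intensities (or attenuation
coefficients) together with its physical voxel size in micrometres.
Axis order is ``(z, y, x)`` with 0-based indices; the physical position
of a voxel centre is ``index * voxel_size``.

Volumes are stored on disk as multi-page TIFF stacks (one page per z
slice) with a JSON sidecar (``<name>.json`` next to the TIFF) carrying
the physical metadata, because TIFF resolution tags are dialect-ridden
across tomography software.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError, ValidationError

__all__ = ["Volume", "read_volume", "write_volume"]


@dataclass
class Volume:
    """A 3-D image with isotropic physical voxel size.

    Parameters
    ----------
    data
        Voxel intensities, shape ``(nz, ny, nx)``.
    voxel_size
        Edge length of a voxel in micrometres (μm).
    """

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"volume must be 3-D, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValidationError(f"voxel_size must be > 0 μm, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel in mm³."""
        return (self.voxel_size * 1e-3) ** 3

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Volume):
            return NotImplemented
        return (
            self.voxel_size == other.voxel_size
            and self.data.shape == other.data.shape
            and self.data.dtype == other.data.dtype
            and bool(np.array_equal(self.data, other.data))
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write *volume* as a multi-page TIFF plus JSON metadata sidecar.

    Returns the path of the sidecar file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.data, photometric="minisblack")
    sidecar = _sidecar_path(path)
    meta = {
        "voxel_size_um": volume.voxel_size,
        "shape": list(volume.data.shape),
        "dtype": str(volume.data.dtype),
        "axis_order": "zyx",
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_volume(path: str | Path) -> Volume:
    """Read a TIFF stack written by :func:`write_volume`.

    Raises
    ------
    FormatError
        If the file cannot be parsed, the sidecar is missing/invalid, or
        the array shape disagrees with the recorded metadata.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF volume {path}: {exc}") from exc
    if data.ndim == 2:  # single-page stack
        data = data[None]
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
        voxel_size = float(meta["voxel_size_um"])
        shape = tuple(meta["shape"])
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"invalid sidecar {sidecar}: {exc}") from exc
    if tuple(data.shape) != shape:
        raise FormatError(
            f"shape mismatch for {path}: TIFF has {data.shape}, sidecar says {shape}"
        )
    return Volume(data=data, voxel_size=voxel_size)
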