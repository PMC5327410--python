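"""Flat/dark-field correction and parallel-beam filtered back projection.

The correction follows the standard Beer–Lambert normalization

    p = -ln( (I - D̄) / (F̄ - D̄) )

with F̄/D̄ the pixelwise means of the flat (beam, no sample) and dark
(beam off) frames, and a small transmittance floor keeping the log
finite.  Reconstruction is slice-by-slice filtered back projection with
a Ram-Lak ramp filter (optionally Hann-apodized), the textbook analytic
inversion for parallel-beam geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import iradon

from .errors import DataError, ValidationError
from .volume import Volume

__all__ = [
    "SinogramSet",
    "AttenuationProjections",
    "correct_projections",
    "fbp_reconstruct",
    "effective_pixel",
    "TRANSMITTANCE_FLOOR",
]

#: transmittance values are clamped here before the log
TRANSMITTANCE_FLOOR = 1e-6


@dataclass
class SinogramSet:
    """Raw counts of one tomographic scan.

    ``projections`` has shape ``(n_angles, nz, n_det)``; ``flats`` and
    ``darks`` are stacks of frames of shape ``(nz, n_det)``.
    """

    projections: np.ndarray
    flats: np.ndarray
    darks: np.ndarray
    angles: np.ndarray  # radians, strictly increasing in [0, pi)
    detector_pixel: float = 6.5  # μm
    magnification: float = 1.0

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections, dtype=float)
        self.flats = np.atleast_3d(np.asarray(self.flats, dtype=float))
        self.darks = np.atleast_3d(np.asarray(self.darks, dtype=float))
        self.angles = np.atleast_1d(np.asarray(self.angles, dtype=float))
        frame = self.projections.shape[1:]
        if self.flats.shape[1:] != frame or self.darks.shape[1:] != frame:
            raise ValidationError("projections, flats and darks must share frame shape")
        if len(self.angles) != self.projections.shape[0]:
            raise ValidationError("one projection per angle required")
        if len(self.angles) > 1 and not np.all(np.diff(self.angles) > 0):
            raise ValidationError("angles must be strictly increasing")
        if np.any(self.angles < 0) or np.any(self.angles >= np.pi):
            raise ValidationError("angles must lie in [0, pi)")


@dataclass
class AttenuationProjections:
    """Per-angle line-integral images (unitless optical depth)."""

    projections: np.ndarray  # (n_angles, nz, n_det)
    angles: np.ndarray  # radians
    detector_pixel: float = 6.5
    magnification: float = 1.0

    @property
    def effective_pixel_um(self) -> float:
        return effective_pixel(self.detector_pixel, self.magnification)


def effective_pixel(detector_pixel: float, magnification: float) -> float:
    """Effective sample-plane pixel size, μm.

    A 6.5 μm CCD pixel behind a 2× (4×) lens resolves 3.25 μm
    (1.625 μm) at the sample.
    """
    if detector_pixel <= 0 or magnification <= 0:
        raise ValidationError("detector_pixel and magnification must be > 0")
    return detector_pixel / magnification


def correct_projections(
    s: SinogramSet, floor: float = TRANSMITTANCE_FLOOR
) -> AttenuationProjections:
    """Flat/dark-normalize raw counts into optical depths.

    Raises
    ------
    DataError
        If the mean flat does not exceed the mean dark at every pixel.
    """
    flat_mean = s.flats.mean(axis=0)
    dark_mean = s.darks.mean(axis=0)
    bad = flat_mean <= dark_mean
    if np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise DataError(
            f"mean flat <= mean dark at pixel {idx} "
            f"(flat={flat_mean[idx]:g}, dark={dark_mean[idx]:g})"
        )
    transmittance = (s.projections - dark_mean) / (flat_mean - dark_mean)
    p = -np.log(np.clip(transmittance, floor, None))
    return AttenuationProjections(
        projections=p,
        angles=s.angles,
        detector_pixel=s.detector_pixel,
        magnification=s.magnification,
    )


def fbp_reconstruct(
    p: AttenuationProjections,
    out_shape: tuple[int, int, int],
    voxel_size: float,
    filter_name: str = "ramlak",
) -> Volume:
    """Slice-by-slice filtered back projection.

    Parameters
    ----------
    p
        Corrected line integrals, shape ``(n_angles, nz, n_det)``.
    out_shape
        Output grid ``(nz, ny, nx)`` with ``ny == nx`` (in-plane
        reconstruction is square).
    voxel_size
        Voxel edge in μm; output values are attenuation in mm⁻¹.
    filter_name
        ``"ramlak"`` for the plain ramp filter or ``"hann"`` for a
        Hann-apodized ramp.
    """
    proj = np.asarray(p.projections, dtype=float)
    if proj.ndim != 3:
        raise ValidationError("projections must have shape (n_angles, nz, n_det)")
    if proj.shape[0] != len(p.angles):
        raise ValidationError(
            f"{proj.shape[0]} projections but {len(p.angles)} angles"
        )
    if len(p.angles) < 2:
        raise ValidationError("FBP needs at least 2 angles")
    if not np.all(np.isfinite(proj)):
        raise ValidationError("projections contain non-finite values")
    nz, ny, nx = out_shape
    if ny != nx:
        raise ValidationError("in-plane output must be square (ny == nx)")
    if proj.shape[1] != nz:
        raise ValidationError(f"projections have {proj.shape[1]} rows, expected nz={nz}")
    skimage_filter = {"ramlak": "ramp", "hann": "hann"}.get(filter_name)
    if skimage_filter is None:
        raise ValidationError(f"unknown filter {filter_name!r}")
    theta_deg = np.degrees(p.angles)
    voxel_mm = voxel_size * 1e-3
    out = np.empty(out_shape, dtype=np.float32)
    for z in range(nz):
        sino = proj[:, z, :].T  # (n_det, n_angles)
        rec = iradon(
            sino,
            theta=theta_deg,
            output_size=nx,
            filter_name=skimage_filter,
            circle=False,
        )
        out[z] = rec / voxel_mm  # undo the pixel-step path scaling
    return Volume(data=out, voxel_size=voxel_size)
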