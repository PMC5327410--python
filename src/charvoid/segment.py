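"""Seed envelope extraction and interior void morphometry.

The seed is segmented by intensity threshold (Otsu by default), keeping
the largest connected material object.  The *envelope* — material plus
every enclosed cavity — is obtained by a small morphological closing
(which caps narrow channels open to the outside) followed by cavity
filling; it is the "whole bean" volume used as the normalization
divisor downstream.  Voids are the connected components of
``envelope AND NOT material`` and are characterized by voxel count,
physical volume, centroid and the principal semi-axes of their
second-moment (inertia) tensor.

Classification mirrors how charred-seed CT analyses exclude artefacts:
components smaller than ``n_min`` voxels are unresolvable *outliers*;
very large or exterior-connected planar components are cotyledon
*breaks*; thin planar components are *cracks*; everything else is a
*hole*.  Only holes enter quantification (cracks that evade the
planarity threshold are reported as contamination, expected below 1%).

Connectivity: voids are 6-connected, material 26-connected — the
standard complementary pair that avoids topological paradoxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .errors import NoSeedFound, ValidationError
from .phantom import GroundTruth
from .volume import Volume

__all__ = [
    "ClassifierRules",
    "SeedMask",
    "HoleComponent",
    "segment_seed",
    "extract_void_components",
    "classify_component",
    "classify_components",
    "crack_contamination",
    "match_ground_truth",
]

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class ClassifierRules:
    """Thresholds of the void classification rules.

    n_min
        Minimum voxel count; smaller components are unresolvable
        outliers.
    tau_crack
        Planarity (c/a) below which an interior component is a crack.
    tau_break
        Planarity below which an exterior-connected component is a
        break.
    f_break
        Fraction of the envelope volume above which any component is a
        break (cotyledon separation).
    """

    n_min: int = 10
    tau_crack: float = 0.15
    tau_break: float = 0.3
    f_break: float = 0.05


@dataclass
class SeedMask:
    """Binary segmentation of one seed."""

    envelope: np.ndarray  # bool, material + enclosed voids
    material: np.ndarray  # bool
    voxel_size: float  # μm
    envelope_volume: float = field(init=False)  # mm³
    material_volume: float = field(init=False)  # mm³

    def __post_init__(self) -> None:
        voxel_mm3 = (self.voxel_size * 1e-3) ** 3
        self.envelope_volume = float(self.envelope.sum()) * voxel_mm3
        self.material_volume = float(self.material.sum()) * voxel_mm3


@dataclass
class HoleComponent:
    """One connected void region and its descriptors."""

    label: int
    voxel_count: int
    volume: float  # mm³
    centroid: tuple[float, float, float]  # (z, y, x) voxels
    semi_axes_um: tuple[float, float, float]  # a >= b >= c, from moments
    planarity: float  # c / a
    touches_exterior: bool
    klass: str = "hole"


def segment_seed(
    v: Volume,
    threshold: str | float = "otsu",
    closing_radius: int = 2,
) -> SeedMask:
    """Threshold, keep the largest object, and close the envelope.

    Parameters
    ----------
    v
        Input volume (reconstructed or ideal).
    threshold
        ``"otsu"`` or an explicit intensity value; material is every
        voxel strictly above it.
    closing_radius
        Radius (voxels) of the ball used to cap narrow openings before
        cavity filling; 0 disables closing.
    """
    data = np.asarray(v.data)
    if threshold == "otsu":
        if data.min() == data.max():
            raise NoSeedFound("volume is constant; nothing to segment")
        thr = float(threshold_otsu(data))
    else:
        thr = float(threshold)
    material = data > thr
    if not material.any():
        raise NoSeedFound(f"no voxels above threshold {thr:g}")
    labels, n = ndimage.label(material, structure=STRUCT_26)
    if n > 1:
        sizes = ndimage.sum_labels(material, labels, index=np.arange(1, n + 1))
        material = labels == (1 + int(np.argmax(sizes)))
    closed = material
    if closing_radius > 0:
        closed = ndimage.binary_closing(material, structure=ball(closing_radius))
    envelope = _fill_cavities(closed) | material
    return SeedMask(envelope=envelope, material=material, voxel_size=v.voxel_size)


def _fill_cavities(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 6-connected to the array border."""
    bg_labels, _ = ndimage.label(~mask, structure=STRUCT_6)
    border = np.zeros(mask.shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[ax] = edge
            border[tuple(sl)] = True
    exterior_ids = np.unique(bg_labels[border & ~mask])
    exterior = np.isin(bg_labels, exterior_ids[exterior_ids > 0])
    return ~exterior


def _principal_semi_axes(
    coords: np.ndarray, voxel_size: float
) -> tuple[float, float, float]:
    """Semi-axes (μm) of the equivalent ellipsoid from second moments.

    For a solid ellipsoid the coordinate covariance eigenvalues are
    ``axis² / 5``; a ``1/12`` per-voxel variance term accounts for the
    finite voxel extent (so a one-voxel-thin plate gets a sub-voxel,
    not zero, thickness).
    """
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / coords.shape[0] + np.eye(3) / 12.0
    eigvals = np.linalg.eigvalsh(cov)  # ascending
    axes_vox = np.sqrt(5.0 * np.clip(eigvals, 0.0, None))
    a, b, cc = axes_vox[::-1] * voxel_size
    return float(a), float(b), float(cc)


def extract_void_components(
    mask: SeedMask, return_labels: bool = False
) -> list[HoleComponent] | tuple[list[HoleComponent], np.ndarray]:
    """Label the voids of *mask* and compute per-component descriptors.

    Components 6-adjacent to the exterior (outside the envelope) are
    flagged ``touches_exterior``.  A solid seed yields an empty list.
    """
    voids = mask.envelope & ~mask.material
    labels, n = ndimage.label(voids, structure=STRUCT_6)
    comps: list[HoleComponent] = []
    if n > 0:
        exterior_neighbors = ndimage.binary_dilation(
            ~mask.envelope, structure=STRUCT_6
        )
        touching = np.unique(labels[exterior_neighbors & voids])
        touching_set = {int(t) for t in touching if t > 0}
        voxel_mm3 = (mask.voxel_size * 1e-3) ** 3
        objects = ndimage.find_objects(labels)
        for lab in range(1, n + 1):
            sl = objects[lab - 1]
            sub = labels[sl] == lab
            coords = np.argwhere(sub).astype(float)
            coords += [s.start for s in sl]
            count = coords.shape[0]
            a, b, c = _principal_semi_axes(coords, mask.voxel_size)
            comps.append(
                HoleComponent(
                    label=lab,
                    voxel_count=count,
                    volume=count * voxel_mm3,
                    centroid=tuple(coords.mean(axis=0)),
                    semi_axes_um=(a, b, c),
                    planarity=float(c / a) if a > 0 else 1.0,
                    touches_exterior=lab in touching_set,
                )
            )
    if return_labels:
        return comps, labels
    return comps


def classify_component(
    c: HoleComponent,
    rules: ClassifierRules = ClassifierRules(),
    envelope_volume: float | None = None,
) -> str:
    """Apply the exclusion rules to one component; returns its class.

    Order: outlier (too small) → break (too large, or exterior-connected
    and planar) → crack (planar) → hole.
    """
    if c.voxel_count < rules.n_min:
        return "outlier"
    if envelope_volume is not None and c.volume > rules.f_break * envelope_volume:
        return "break"
    if c.touches_exterior and c.planarity < rules.tau_break:
        return "break"
    if c.planarity < rules.tau_crack:
        return "crack"
    return "hole"


def classify_components(
    comps: list[HoleComponent],
    mask: SeedMask,
    rules: ClassifierRules = ClassifierRules(),
) -> list[HoleComponent]:
    """Classify every component in place (and return the list)."""
    for c in comps:
        c.klass = classify_component(c, rules, mask.envelope_volume)
    return comps


def match_ground_truth(
    labels: np.ndarray, truth: GroundTruth
) -> dict[int, str]:
    """Map void-component labels to the generating void's true class.

    Each ground-truth void is matched to the component containing its
    centre voxel (sub-voxel voids usually match nothing).  Returns
    ``{component label: true class}``.
    """
    out: dict[int, str] = {}
    for h in truth.holes:
        idx = tuple(int(round(x)) for x in h.center_voxel)
        if all(0 <= i < s for i, s in zip(idx, labels.shape)):
            lab = int(labels[idx])
            if lab > 0:
                out[lab] = h.klass
    return out


def crack_contamination(
    comps: list[HoleComponent], true_classes: dict[int, str] | None = None
) -> float | None:
    """Fraction of retained "holes" that are actually cracks.

    With ground truth (``{label: true class}`` from
    :func:`match_ground_truth`) the numerator counts true cracks
    classified as holes; without it, nothing can be a known crack and
    the fraction is 0.  Returns ``None`` (flagged null) when no
    component was retained as a hole.
    """
    retained = [c for c in comps if c.klass == "hole"]
    if not retained:
        return None
    if true_classes is None:
        return 0.0
    n_bad = sum(1 for c in retained if true_classes.get(c.label) == "crack")
    return n_bad / len(retained)
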