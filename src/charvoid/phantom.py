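"""Synthetic charred-seed phantoms with known internal hole populations.

Charred soybean cotyledons contain spheroidal/ellipsoidal voids
("holes") tens to hundreds of micrometres across whose abundance tracks
seed composition: oil content drives the number of small holes, protein
content the number of large holes, charring at 300 °C (vs 275 °C)
halves the small-hole count, and water-saturated seeds develop no small
holes at all.  This module generates voxel phantoms that encode those
effects with full ground truth, so every downstream stage
(reconstruction, segmentation, quantification, statistics) can be
validated against known answers.

Hole abundance model
--------------------
Expected hole counts per seed are Poisson means, log-linear in
composition (percent dry mass):

    lambda_small  = exp(A0 + A1 * oil)
    lambda_medium = exp(C0 + C1 * (oil + protein) / 2)
    lambda_large  = exp(B0 + B1 * protein)

Charring at 300 °C multiplies ``lambda_small`` by exactly 0.5; water
saturation forces ``lambda_small = lambda_medium = 0`` and enlarges the
seed envelope by a linear factor of 1.4.  The coefficients below are
documented model constants, chosen so that the three reference
cultivars (protein/oil 48.7/19.2, 42.5/15, 33.9/23.6) reproduce the
qualitative category orderings seen in charred-seed CT data.

Hole sizes are drawn so that each hole's volume, normalized by the seed
envelope volume, is log-uniform within its category's decade:
Small = [1e-7, 1e-6), Medium = [1e-6, 1e-5), Large = [1e-5, 1e-4).
For a default-geometry seed (~25 mm³) this puts equivalent-sphere radii
between roughly 8 and 85 μm — tens of micrometres, as observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ValidationError
from .volume import Volume

__all__ = [
    "PhantomSpec",
    "HoleRates",
    "GroundTruthHole",
    "GroundTruth",
    "hole_rate_model",
    "draw_hole_population",
    "generate_seed_phantom",
    "simulate_projections",
    "CATEGORY_BINS",
]

# log-linear Poisson-rate coefficients (documented model constants)
RATE_A0, RATE_A1 = 0.6, 0.115  # small holes ~ oil %
RATE_B0, RATE_B1 = -2.0, 0.092  # large holes ~ protein %
RATE_C0, RATE_C1 = 0.4, 0.06  # medium holes ~ mean(oil, protein) %

TEMP_SMALL_FACTOR_300C = 0.5  # small-hole rate at 300 °C relative to 275 °C
SATURATION_LINEAR_SCALE = 1.4  # linear envelope enlargement of soaked seeds

#: normalized-volume decade bins (lower edge inclusive)
CATEGORY_BINS: dict[str, tuple[float, float]] = {
    "Small": (1e-7, 1e-6),
    "Medium": (1e-6, 1e-5),
    "Large": (1e-5, 1e-4),
}

# hole shape: semi-axis ratios b/a, c/a drawn uniform in this range,
# keeping holes clearly non-planar (planarity >> crack threshold)
HOLE_AXIS_RATIO_RANGE = (0.6, 1.0)

# cracks: thin plates, largest semi-axis log-uniform (μm), thickness
# ratio c/a fixed well below any crack-classification threshold.
# Charred-seed cracks are very small fracture voids — smaller than the
# holes themselves — which is why the few that evade the planarity rule
# cannot be isolated from holes
CRACK_EXTENT_RANGE_UM = (50.0, 150.0)
CRACK_THICKNESS_RATIO = 0.05

CHAR_INTENSITY = 1.0  # attenuation assigned to char material (mm^-1)


@dataclass(frozen=True)
class HoleRates:
    """Expected (Poisson-mean) hole counts per seed, by size category."""

    lambda_small: float
    lambda_medium: float
    lambda_large: float

    def __post_init__(self) -> None:
        for name in ("lambda_small", "lambda_medium", "lambda_large"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one synthetic charred seed.

    Parameters
    ----------
    protein_pct, oil_pct
        Composition in percent dry mass; their sum may not exceed 100.
    char_temp
        Charring temperature, 275 or 300 °C.
    water_saturated
        Seed soaked before charring: no small/medium holes, envelope
        enlarged by a 1.4 linear factor.
    semi_axes
        Dry-seed ellipsoid semi-axes in mm, ordered (z, y, x).
    voxel_size
        Voxel edge in μm.
    crack_count
        Number of thin planar cracks to add.
    break_flag
        Add a cotyledon-separation break (planar gap through the seed).
    rng_seed
        Seed of the generator; identical specs yield identical output.
    """

    protein_pct: float = 33.9
    oil_pct: float = 23.6
    char_temp: float = 275.0
    water_saturated: bool = False
    semi_axes: tuple[float, float, float] = (1.5, 1.6, 2.5)  # mm, (z, y, x)
    voxel_size: float = 60.0  # μm
    crack_count: int = 0
    break_flag: bool = False
    rng_seed: int = 0
    rate_override: HoleRates | None = None  # bypass the composition model

    def __post_init__(self) -> None:
        if not (0 <= self.protein_pct <= 100 and 0 <= self.oil_pct <= 100):
            raise ValidationError("protein_pct and oil_pct must lie in [0, 100]")
        if self.protein_pct + self.oil_pct > 100:
            raise ValidationError("protein_pct + oil_pct must not exceed 100")
        if any(a <= 0 for a in self.semi_axes):
            raise ValidationError("semi_axes must be positive")
        if self.voxel_size <= 0:
            raise ValidationError("voxel_size must be positive")
        if self.crack_count < 0:
            raise ValidationError("crack_count must be >= 0")

    @property
    def effective_semi_axes_mm(self) -> tuple[float, float, float]:
        """Seed semi-axes after any saturation enlargement."""
        s = SATURATION_LINEAR_SCALE if self.water_saturated else 1.0
        return tuple(a * s for a in self.semi_axes)  # type: ignore[return-value]

    @property
    def envelope_volume_mm3(self) -> float:
        a, b, c = self.effective_semi_axes_mm
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass(frozen=True)
class GroundTruthHole:
    """One generated void: analytic geometry plus its class label."""

    center_voxel: tuple[float, float, float]  # (z, y, x), voxel units
    semi_axes_um: tuple[float, float, float]  # a >= b >= c
    klass: str  # "hole", "crack" or "break"
    category: str | None  # Small/Medium/Large for holes, None otherwise
    volume_mm3: float  # analytic 4/3 pi abc
    normalized_volume: float  # volume / envelope volume


@dataclass
class GroundTruth:
    """Emitted truth for one phantom seed."""

    holes: list[GroundTruthHole]
    seed_envelope_volume: float  # mm³, analytic
    expected_counts: HoleRates  # the Poisson means used
    category_counts: dict[str, int] = field(default_factory=dict)

    def holes_of_class(self, klass: str) -> list[GroundTruthHole]:
        return [h for h in self.holes if h.klass == klass]


def hole_rate_model(
    protein_pct: float,
    oil_pct: float,
    char_temp: float = 275.0,
    water_saturated: bool = False,
) -> HoleRates:
    """Expected per-seed hole counts for a given composition and treatment.

    The small-hole rate increases with oil content, the large-hole rate
    with protein content; charring at 300 °C halves the small-hole
    rate, and water saturation removes small and medium holes entirely.
    """
    if not (0 <= protein_pct <= 100 and 0 <= oil_pct <= 100):
        raise ValidationError("percentages must lie in [0, 100]")
    if char_temp not in (275, 300):
        raise ValidationError(f"char_temp must be 275 or 300 °C, got {char_temp}")
    lam_small = math.exp(RATE_A0 + RATE_A1 * oil_pct)
    lam_medium = math.exp(RATE_C0 + RATE_C1 * (oil_pct + protein_pct) / 2.0)
    lam_large = math.exp(RATE_B0 + RATE_B1 * protein_pct)
    if char_temp == 300:
        lam_small *= TEMP_SMALL_FACTOR_300C
    if water_saturated:
        lam_small = 0.0
        lam_medium = 0.0
    return HoleRates(lam_small, lam_medium, lam_large)


def _draw_hole_semi_axes(
    rng: np.random.Generator, category: str, envelope_volume_mm3: float
) -> tuple[tuple[float, float, float], float, float]:
    """Draw ellipsoid semi-axes (μm, a>=b>=c) for one hole.

    The normalized volume is log-uniform within the category decade, so
    equivalent radii are log-uniform over the matching range.
    """
    lo, hi = CATEGORY_BINS[category]
    v = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    volume_mm3 = v * envelope_volume_mm3
    r_lo, r_hi = HOLE_AXIS_RATIO_RANGE
    qb = rng.uniform(r_lo, r_hi)
    qc = rng.uniform(r_lo, qb)
    # a * (qb a) * (qc a) * 4pi/3 = volume
    a_mm = (volume_mm3 * 3.0 / (4.0 * math.pi * qb * qc)) ** (1.0 / 3.0)
    axes_um = (a_mm * 1e3, a_mm * qb * 1e3, a_mm * qc * 1e3)
    return axes_um, volume_mm3, v


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _place_center(
    rng: np.random.Generator,
    semi_axes_vox: np.ndarray,
    max_extent_vox: float,
    center_vox: np.ndarray,
) -> np.ndarray:
    """Uniform position inside the seed with the void strictly interior."""
    # shrink the allowed normalized radius so the whole void plus a
    # one-voxel pad fits inside the envelope
    pad = (max_extent_vox + 1.0) / float(np.min(semi_axes_vox))
    rmax = max(1.0 - pad, 0.05)
    while True:
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.dot(u, u) <= 1.0:
            break
    return center_vox + u * semi_axes_vox * rmax


def draw_hole_population(spec: PhantomSpec) -> GroundTruth:
    """Draw the analytic hole/crack/break population for *spec*.

    This is the generative half of :func:`generate_seed_phantom`; it is
    exposed separately because the population itself (counts and
    analytic volumes) is what the category statistics consume, while
    voxel painting is only needed when an image volume is required.
    """
    rng = np.random.default_rng(spec.rng_seed)
    rates = spec.rate_override or hole_rate_model(
        spec.protein_pct, spec.oil_pct, spec.char_temp, spec.water_saturated
    )
    env_vol = spec.envelope_volume_mm3
    semi_axes_mm = np.array(spec.effective_semi_axes_mm)
    semi_axes_vox = semi_axes_mm * 1e3 / spec.voxel_size
    shape = np.ceil(2 * semi_axes_vox).astype(int) + 8
    center_vox = (shape - 1) / 2.0

    counts = {
        "Small": int(rng.poisson(rates.lambda_small)),
        "Medium": int(rng.poisson(rates.lambda_medium)),
        "Large": int(rng.poisson(rates.lambda_large)),
    }
    holes: list[GroundTruthHole] = []
    for category in ("Large", "Medium", "Small"):  # biggest first
        for _ in range(counts[category]):
            axes_um, vol_mm3, v = _draw_hole_semi_axes(rng, category, env_vol)
            c = _place_center(
                rng, semi_axes_vox, axes_um[0] / spec.voxel_size, center_vox
            )
            holes.append(
                GroundTruthHole(
                    center_voxel=tuple(c),
                    semi_axes_um=axes_um,
                    klass="hole",
                    category=category,
                    volume_mm3=vol_mm3,
                    normalized_volume=v,
                )
            )
    for _ in range(spec.crack_count):
        a_um = math.exp(rng.uniform(*map(math.log, CRACK_EXTENT_RANGE_UM)))
        b_um = a_um * rng.uniform(0.5, 0.9)
        c_um = a_um * CRACK_THICKNESS_RATIO
        vol_mm3 = 4.0 / 3.0 * math.pi * a_um * b_um * c_um * 1e-9
        c = _place_center(rng, semi_axes_vox, a_um / spec.voxel_size, center_vox)
        holes.append(
            GroundTruthHole(
                center_voxel=tuple(c),
                semi_axes_um=(a_um, b_um, c_um),
                klass="crack",
                category=None,
                volume_mm3=vol_mm3,
                normalized_volume=vol_mm3 / env_vol,
            )
        )
    if spec.break_flag:
        # cotyledon-separation break: a thick plate across the seed
        # mid-plane covering ~95% of the cross-section, leaving the two
        # halves attached at the rim (as in real partly-split seeds)
        a_um = 0.95 * semi_axes_mm[2] * 1e3
        b_um = 0.95 * semi_axes_mm[1] * 1e3
        c_um = 2.5 * spec.voxel_size
        vol_mm3 = 4.0 / 3.0 * math.pi * a_um * b_um * c_um * 1e-9
        holes.append(
            GroundTruthHole(
                center_voxel=tuple(center_vox),
                semi_axes_um=(a_um, b_um, c_um),
                klass="break",
                category=None,
                volume_mm3=vol_mm3,
                normalized_volume=vol_mm3 / env_vol,
            )
        )
    return GroundTruth(
        holes=holes,
        seed_envelope_volume=env_vol,
        expected_counts=rates,
        category_counts=counts,
    )


def _paint_ellipsoid(
    data: np.ndarray,
    center: np.ndarray,
    semi_axes_vox: np.ndarray,
    rotation: np.ndarray | None,
    value: float,
) -> None:
    """Set voxels inside an (optionally rotated) ellipsoid to *value*."""
    extent = float(np.max(semi_axes_vox)) + 1.0
    lo = np.maximum(np.floor(center - extent).astype(int), 0)
    hi = np.minimum(np.ceil(center + extent).astype(int) + 1, data.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        *(np.arange(lo[i], hi[i]) - center[i] for i in range(3)), indexing="ij"
    )
    pts = np.stack([zz, yy, xx])
    if rotation is not None:
        pts = np.einsum("ij,jzyx->izyx", rotation.T, pts)
    q = sum((pts[i] / semi_axes_vox[i]) ** 2 for i in range(3))
    sub = data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub[q <= 1.0] = value


def generate_seed_phantom(
    spec: PhantomSpec, shape: tuple[int, int, int] | None = None
) -> tuple[Volume, GroundTruth]:
    """Voxelize a charred-seed phantom with its ground truth.

    The seed is an ellipsoid of char material (intensity
    ``CHAR_INTENSITY``) on zero background; every generated void is
    carved back to background intensity.  Voids smaller than a voxel
    may not survive voxelization but are still listed in the ground
    truth with their analytic volumes.

    Parameters
    ----------
    spec
        Generative parameters (composition, treatment, geometry, seed).
    shape
        Grid shape ``(nz, ny, nx)``; default fits the seed with a
        4-voxel background margin on every side.
    """
    truth = draw_hole_population(spec)
    semi_axes_vox = (
        np.array(spec.effective_semi_axes_mm) * 1e3 / spec.voxel_size
    )
    auto_shape = np.ceil(2 * semi_axes_vox).astype(int) + 8
    if shape is None:
        shape = tuple(int(n) for n in auto_shape)
    shape_arr = np.array(shape, dtype=int)
    if np.any(2 * semi_axes_vox > shape_arr - 4):
        raise GeometryError(
            f"seed of {2 * semi_axes_vox} voxels does not fit grid {shape} "
            "with a 2-voxel margin"
        )
    data = np.zeros(tuple(shape_arr), dtype=np.float32)
    center = (shape_arr - 1) / 2.0
    _paint_ellipsoid(data, center, semi_axes_vox, None, CHAR_INTENSITY)

    # carve voids; the drawn centres were placed on the auto grid, so
    # shift them if a custom grid was requested
    offset = center - (auto_shape - 1) / 2.0
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 1]))
    shifted_holes = []
    for h in truth.holes:
        c = np.array(h.center_voxel) + offset
        axes_vox = np.array(h.semi_axes_um) / spec.voxel_size
        if h.klass == "break":
            # plate with its thin axis along z: per-axis semi-axes (z, y, x)
            _paint_ellipsoid(data, c, axes_vox[::-1], None, 0.0)
        else:
            rot = _random_rotation(rng)
            _paint_ellipsoid(data, c, axes_vox, rot, 0.0)
        shifted_holes.append(
            GroundTruthHole(tuple(c), h.semi_axes_um, h.klass, h.category,
                            h.volume_mm3, h.normalized_volume)
        )
    truth.holes = shifted_holes
    return Volume(data=data, voxel_size=spec.voxel_size), truth


def simulate_projections(
    volume: Volume,
    angles,
    flux: float = 5e4,
    rng_seed: int | None = 0,
    n_flats: int = 5,
    n_darks: int = 5,
    dark_level: float = 20.0,
    poisson_noise: bool = True,
    detector_pixel: float | None = None,
    magnification: float = 1.0,
):
    """Parallel-beam forward projection to detector counts.

    Volume values are linear attenuation coefficients in mm⁻¹; rays run
    in-slice (rotation axis = z).  Each projection is
    ``Poisson(flux * exp(-line integral) + dark_level)``; flat frames
    are beam-only (``flux + dark_level``) and dark frames beam-off
    (``dark_level``), mirroring a standard flat/dark acquisition.

    Returns a :class:`charvoid.recon.SinogramSet`.
    """
    from skimage.transform import radon

    from .recon import SinogramSet

    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        raise ValidationError("angle list must be non-empty")
    if flux <= 0:
        raise ValidationError("flux must be > 0")
    theta_deg = np.degrees(angles)
    voxel_mm = volume.voxel_size * 1e-3
    nz = volume.data.shape[0]
    sinos = []
    for z in range(nz):
        s = radon(volume.data[z].astype(float), theta=theta_deg, circle=False)
        sinos.append(s * voxel_mm)  # pixel-step sums -> optical depth
    path = np.stack(sinos, axis=0)  # (nz, n_det, n_angles)
    path = np.moveaxis(path, 2, 0)  # (n_angles, nz, n_det)

    rng = np.random.default_rng(rng_seed)
    expected = flux * np.exp(-path) + dark_level
    flat_expected = np.full(expected.shape[1:], flux + dark_level)
    dark_expected = np.full(expected.shape[1:], dark_level)
    if poisson_noise:
        projections = rng.poisson(expected).astype(float)
        flats = rng.poisson(
            np.broadcast_to(flat_expected, (n_flats, *flat_expected.shape))
        ).astype(float)
        darks = rng.poisson(
            np.broadcast_to(dark_expected, (n_darks, *dark_expected.shape))
        ).astype(float)
    else:
        projections = expected
        flats = np.broadcast_to(flat_expected, (n_flats, *flat_expected.shape)).copy()
        darks = np.broadcast_to(dark_expected, (n_darks, *dark_expected.shape)).copy()
    return SinogramSet(
        projections=projections,
        flats=flats,
        darks=darks,
        angles=angles,
        detector_pixel=detector_pixel or volume.voxel_size,
        magnification=magnification,
    )
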