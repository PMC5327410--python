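"""Normalized hole metrics, decade size categories and rank curves.

The core metric is the *normalized hole volume* v = V_hole / V_seed,
where V_seed is the whole-seed envelope volume (material plus enclosed
voids).  Normalization makes seeds of different sizes comparable and is
scale invariant: rescaling the voxel size leaves every v unchanged.

Holes are binned into half-open decade categories of v with inclusive
lower edges:

    Small  = [1e-7, 1e-6)
    Medium = [1e-6, 1e-5)
    Large  = [1e-5, 1e-4)

v < 1e-7 is ``below_range`` (too small to differentiate, excluded from
statistics) and v >= 1e-4 is ``above_range`` (flagged rather than
silently kept).  The *rank curve* plots v against descending rank
(holes sorted large to small); its tail encodes small-hole abundance
(high oil) and its head large-hole abundance (high protein).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .phantom import CATEGORY_BINS

__all__ = [
    "HoleTable",
    "SeedMetrics",
    "normalize_holes",
    "categorize",
    "seed_metrics",
    "rank_curve",
    "dimension_product",
]

CATEGORIES = ("Small", "Medium", "Large")
BELOW = "below_range"
ABOVE = "above_range"


@dataclass
class HoleTable:
    """Per-seed table of retained holes, sorted descending by v.

    ``data`` columns: ``label`` (component id), ``volume_mm3``, ``v``
    (normalized volume), ``category``.
    """

    seed_id: str
    v_seed: float  # mm³
    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class SeedMetrics:
    """Summary metrics of one seed."""

    seed_id: str
    v_seed: float  # mm³
    normalized_count: float  # retained holes per mm³ of seed
    total_normalized_volume: float  # unitless porosity, sum of v
    category_counts: dict[str, int]  # Small/Medium/Large
    excluded_below_small: int
    flagged_above_large: int


def categorize(v: float) -> str:
    """Decade category of one normalized volume."""
    if not v > 0:
        raise ValidationError(f"normalized volume must be > 0, got {v}")
    if v < CATEGORY_BINS["Small"][0]:
        return BELOW
    for name in CATEGORIES:
        lo, hi = CATEGORY_BINS[name]
        if lo <= v < hi:
            return name
    return ABOVE


def normalize_holes(holes, v_seed: float, seed_id: str = "seed") -> HoleTable:
    """Build a :class:`HoleTable` from hole volumes and the seed volume.

    Parameters
    ----------
    holes
        Either a sequence of ``HoleComponent``-like objects (attributes
        ``label`` and ``volume``, class ``hole``) or a plain sequence
        of volumes in mm³.
    v_seed
        Envelope volume in mm³ (the normalization divisor).
    """
    if not v_seed > 0:
        raise ValidationError(f"v_seed must be > 0 mm³, got {v_seed}")
    labels, volumes = [], []
    for i, h in enumerate(holes):
        if hasattr(h, "volume"):
            if getattr(h, "klass", "hole") != "hole":
                raise ValidationError(
                    f"component {h.label} has class {h.klass!r}; "
                    "only retained holes may be normalized"
                )
            labels.append(h.label)
            volumes.append(h.volume)
        else:
            labels.append(i + 1)
            volumes.append(float(h))
    df = pd.DataFrame({"label": labels, "volume_mm3": volumes})
    df["v"] = df["volume_mm3"] / v_seed
    df["category"] = [categorize(v) for v in df["v"]]
    # descending by v, ties broken by component label (stable)
    df = df.sort_values(["v", "label"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    return HoleTable(seed_id=seed_id, v_seed=v_seed, data=df)


def seed_metrics(table: HoleTable) -> SeedMetrics:
    """Per-seed summary: normalized count, porosity, category counts."""
    df = table.data
    in_range = df[df["category"].isin(CATEGORIES)]
    counts = {c: int((in_range["category"] == c).sum()) for c in CATEGORIES}
    return SeedMetrics(
        seed_id=table.seed_id,
        v_seed=table.v_seed,
        normalized_count=len(in_range) / table.v_seed,
        total_normalized_volume=float(in_range["v"].sum()),
        category_counts=counts,
        excluded_below_small=int((df["category"] == BELOW).sum()),
        flagged_above_large=int((df["category"] == ABOVE).sum()),
    )


def rank_curve(table: HoleTable) -> pd.DataFrame:
    """Rank–size curve: v against descending rank (1 = largest hole).

    Includes every retained hole; an empty table yields an empty curve.
    """
    df = table.data
    return pd.DataFrame(
        {"rank": np.arange(1, len(df) + 1), "v": df["v"].to_numpy()}
    )


def dimension_product(length: float, width: float, thickness: float) -> float:
    """Product of the three seed dimensions (mm), one-decimal rounded.

    A crude size proxy: e.g. 5.1 × 2.5 × 2.4 mm → 30.6.
    """
    if length <= 0 or width <= 0 or thickness <= 0:
        raise ValidationError("seed dimensions must be positive")
    return round(length * width * thickness, 1)
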