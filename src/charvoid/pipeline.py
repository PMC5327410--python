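"""Configuration, the stage-chaining driver, and experiment suites.

``run_pipeline`` chains phantom → (optional) projection/reconstruction →
segmentation → quantification for one seed and returns everything a
caller needs (volume, mask, components, metrics).  The experiment
suites reproduce the three charred-seed study designs on synthetic
seeds:

* cultivar suite — three compositions (protein/oil 48.7/19.2, 42.5/15,
  33.9/23.6), seven seeds each, charred at 275 °C; ANOVA + post-hoc on
  per-category normalized hole counts;
* temperature suite — the high-oil composition charred at 275 vs
  300 °C, six seeds each, two-tailed t-tests per category;
* water-saturation run — a soaked seed, expected to retain no hole
  below 1e-5 normalized volume.

Category statistics in the suites are computed from the generator's
analytic hole populations: a hole in the Small decade (v ~ 1e-7)
occupies ≥ 10 voxels only on grids with ≥ 1e8 envelope voxels, far
beyond routine grid sizes, so voxel segmentation cannot resolve the
two lower decades at the default geometry.  Segmentation accuracy is
established separately on fixtures whose voids are voxel-resolvable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantom, quantify, segment, stats
from .errors import CharvoidError, ValidationError
from .volume import Volume, read_volume, write_volume

log = logging.getLogger("charvoid")

__all__ = [
    "RunConfig",
    "run_pipeline",
    "seed_category_counts",
    "cultivar_suite",
    "temperature_suite",
    "water_saturation_run",
    "CULTIVARS",
]

#: the three reference cultivars: label -> (protein %, oil %)
CULTIVARS: dict[str, tuple[float, float]] = {
    "P48.7O19.2": (48.7, 19.2),
    "P42.5O15": (42.5, 15.0),
    "P33.9O23.6": (33.9, 23.6),
}


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with documented defaults.

    Round-trips losslessly through YAML (`save`/`load`).
    """

    # stage toggles
    do_phantom: bool = True
    do_recon: bool = False
    do_segment: bool = True
    do_quantify: bool = True
    # phantom
    protein_pct: float = 33.9
    oil_pct: float = 23.6
    char_temp: float = 275.0
    water_saturated: bool = False
    semi_axes: tuple[float, float, float] = (1.5, 1.6, 2.5)
    voxel_size: float = 60.0
    crack_count: int = 0
    break_flag: bool = False
    # recon
    n_angles: int = 180
    flux: float = 5e4
    fbp_filter: str = "ramlak"
    # segment
    threshold: str | float = "otsu"
    closing_radius: int = 2
    n_min: int = 10
    tau_crack: float = 0.15
    tau_break: float = 0.3
    f_break: float = 0.05
    # stats
    alpha: float = 0.05
    # io
    input_volume: str | None = None
    out_dir: str | None = None
    rng_seed: int = 0

    def rules(self) -> segment.ClassifierRules:
        return segment.ClassifierRules(
            n_min=self.n_min,
            tau_crack=self.tau_crack,
            tau_break=self.tau_break,
            f_break=self.f_break,
        )

    def spec(self) -> phantom.PhantomSpec:
        return phantom.PhantomSpec(
            protein_pct=self.protein_pct,
            oil_pct=self.oil_pct,
            char_temp=self.char_temp,
            water_saturated=self.water_saturated,
            semi_axes=self.semi_axes,
            voxel_size=self.voxel_size,
            crack_count=self.crack_count,
            break_flag=self.break_flag,
            rng_seed=self.rng_seed,
        )

    def save(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["semi_axes"] = list(d["semi_axes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValidationError(f"config {path} is not a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "semi_axes" in d:
            d["semi_axes"] = tuple(d["semi_axes"])
        return cls(**d)


@dataclass
class PipelineResult:
    """Bundle returned by :func:`run_pipeline`."""

    volume: Volume
    truth: phantom.GroundTruth | None
    mask: segment.SeedMask | None
    components: list[segment.HoleComponent]
    table: quantify.HoleTable | None
    metrics: quantify.SeedMetrics | None
    log_records: list[dict] = field(default_factory=list)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the enabled stages in order for a single seed.

    Raises the first failing stage's error, annotated with the stage
    name; with ``out_dir`` set, writes the volume, component table and
    metrics (plus a run log echoing all parameters).
    """
    records: list[dict] = []

    def record(stage: str, **info) -> None:
        records.append({"stage": stage, "time": time.time(), **info})
        log.info("stage %s: %s", stage, info)

    truth = None
    if config.do_phantom:
        vol, truth = phantom.generate_seed_phantom(config.spec())
        record("phantom", shape=list(vol.shape), n_voids=len(truth.holes),
               rng_seed=config.rng_seed)
    elif config.input_volume:
        path = Path(config.input_volume)
        if not path.exists():
            raise FileNotFoundError(f"input volume not found: {path}")
        vol = read_volume(path)
        record("load", path=str(path), shape=list(vol.shape))
    else:
        raise ValidationError("either enable the phantom stage or give input_volume")

    if config.do_recon:
        try:
            from .recon import correct_projections, fbp_reconstruct

            angles = np.linspace(0, np.pi, config.n_angles, endpoint=False)
            sino = phantom.simulate_projections(
                vol, angles, flux=config.flux, rng_seed=config.rng_seed
            )
            proj = correct_projections(sino)
            nz = vol.shape[0]
            n = max(vol.shape[1], vol.shape[2])
            vol = fbp_reconstruct(
                proj, (nz, n, n), vol.voxel_size, filter_name=config.fbp_filter
            )
            record("recon", n_angles=config.n_angles, filter=config.fbp_filter)
        except CharvoidError as exc:
            raise type(exc)(f"recon stage failed: {exc}") from exc

    mask = None
    components: list[segment.HoleComponent] = []
    table = None
    metrics = None
    if config.do_segment:
        mask = segment.segment_seed(
            vol, threshold=config.threshold, closing_radius=config.closing_radius
        )
        components = segment.extract_void_components(mask)
        segment.classify_components(components, mask, config.rules())
        record("segment", n_components=len(components),
               envelope_mm3=mask.envelope_volume)

    if config.do_quantify and mask is not None:
        holes = [c for c in components if c.klass == "hole"]
        table = quantify.normalize_holes(
            holes, mask.envelope_volume, seed_id=f"seed{config.rng_seed}"
        )
        metrics = quantify.seed_metrics(table)
        record("quantify", n_holes=len(table),
               porosity=metrics.total_normalized_volume)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_volume(vol, out / "volume.tif")
        if components:
            pd.DataFrame(
                [
                    {
                        "label": c.label,
                        "voxels": c.voxel_count,
                        "volume_mm3": c.volume,
                        "centroid_z": c.centroid[0],
                        "centroid_y": c.centroid[1],
                        "centroid_x": c.centroid[2],
                        "a_um": c.semi_axes_um[0],
                        "b_um": c.semi_axes_um[1],
                        "c_um": c.semi_axes_um[2],
                        "planarity": c.planarity,
                        "touches_exterior": c.touches_exterior,
                        "klass": c.klass,
                    }
                    for c in components
                ]
            ).to_csv(out / "components.csv", index=False)
        if table is not None:
            table.data.to_csv(out / "holes.csv", index=False)
            quantify.rank_curve(table).to_csv(out / "rank_curve.csv", index=False)
        config.save(out / "config.yaml")
        (out / "run_log.json").write_text(json.dumps(records, indent=2))
    return PipelineResult(vol, truth, mask, components, table, metrics, records)


def seed_category_counts(spec: phantom.PhantomSpec) -> dict[str, float]:
    """Normalized per-category hole counts (mm⁻³) of one phantom seed.

    Computed from the analytic hole population: every generated hole is
    normalized by the envelope volume, categorized by decade, counted,
    and divided by the envelope volume — the per-seed quantity the
    group statistics consume.
    """
    truth = phantom.draw_hole_population(spec)
    holes = [h.volume_mm3 for h in truth.holes_of_class("hole")]
    table = quantify.normalize_holes(holes, truth.seed_envelope_volume)
    m = quantify.seed_metrics(table)
    return {
        cat: m.category_counts[cat] / truth.seed_envelope_volume
        for cat in quantify.CATEGORIES
    }


def _suite_frame(specs: dict[str, list[phantom.PhantomSpec]]) -> pd.DataFrame:
    rows = []
    for group, spec_list in specs.items():
        for i, spec in enumerate(spec_list):
            counts = seed_category_counts(spec)
            for cat, val in counts.items():
                rows.append(
                    {"group": group, "seed_id": f"{group}-{i}", "category": cat,
                     "value": val}
                )
    return pd.DataFrame(rows)


def cultivar_suite(
    rng_seed: int, n_seeds: int = 7, mc_draws: int = 20_000
) -> dict:
    """One replicate of the three-cultivar comparison (275 °C).

    Returns the tidy per-seed frame, the per-category
    :class:`~charvoid.stats.GroupComparison`, and the ordering checks:
    is the Small-category mean greatest for the high-oil cultivar and
    the Large-category mean greatest for the high-protein one, each
    with ANOVA p < 0.05?
    """
    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.generate_state(len(CULTIVARS) * n_seeds) % (2**31)
    specs = {}
    i = 0
    for label, (protein, oil) in CULTIVARS.items():
        specs[label] = []
        for _ in range(n_seeds):
            specs[label].append(
                phantom.PhantomSpec(
                    protein_pct=protein, oil_pct=oil, char_temp=275.0,
                    rng_seed=int(seeds[i]),
                )
            )
            i += 1
    df = _suite_frame(specs)
    comparisons = {}
    means = {}
    for cat in quantify.CATEGORIES:
        groups = stats.groups_from_tidy(df, cat)
        comparisons[cat] = stats.compare_groups(groups, mc_draws=mc_draws)
        means[cat] = {g.label: float(g.values.mean()) for g in groups}
    small_ok = (
        max(means["Small"], key=means["Small"].get) == "P33.9O23.6"
        and comparisons["Small"].p_anova < 0.05
    )
    large_ok = (
        max(means["Large"], key=means["Large"].get) == "P48.7O19.2"
        and comparisons["Large"].p_anova < 0.05
    )
    return {
        "frame": df,
        "comparisons": comparisons,
        "means": means,
        "small_ordering_ok": bool(small_ok),
        "large_ordering_ok": bool(large_ok),
    }


def temperature_suite(rng_seed: int, n_seeds: int = 6) -> dict:
    """One replicate of the 275 vs 300 °C contrast (high-oil cultivar).

    Two-tailed t-tests per category; the expected pattern is a
    significant Small-category reduction at 300 °C and no significant
    Medium/Large difference.
    """
    protein, oil = CULTIVARS["P33.9O23.6"]
    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.generate_state(2 * n_seeds) % (2**31)
    frames = {}
    for gi, temp in enumerate((275.0, 300.0)):
        per_cat: dict[str, list[float]] = {c: [] for c in quantify.CATEGORIES}
        for i in range(n_seeds):
            spec = phantom.PhantomSpec(
                protein_pct=protein, oil_pct=oil, char_temp=temp,
                rng_seed=int(seeds[gi * n_seeds + i]),
            )
            for cat, val in seed_category_counts(spec).items():
                per_cat[cat].append(val)
        frames[temp] = per_cat
    tests = {}
    for cat in quantify.CATEGORIES:
        t, p = stats.t_test_two_tailed(frames[275.0][cat], frames[300.0][cat])
        tests[cat] = {
            "t": t,
            "p": p,
            "mean_275": float(np.mean(frames[275.0][cat])),
            "mean_300": float(np.mean(frames[300.0][cat])),
        }
    pattern_ok = (
        tests["Small"]["p"] < 0.05
        and tests["Small"]["mean_300"] < tests["Small"]["mean_275"]
        and tests["Medium"]["p"] >= 0.05
        and tests["Large"]["p"] >= 0.05
    )
    return {"tests": tests, "pattern_ok": bool(pattern_ok), "data": frames}


def crack_contamination_suite(rng_seed: int, n_seeds: int = 20) -> dict:
    """Pooled crack contamination over a mixed phantom suite.

    Each seed is a fine-voxel phantom (10 μm voxels on a small seed, so
    Large-decade holes and cracks are voxel-resolvable) carrying two
    thin cracks; the suite reports the fraction of retained "holes"
    that are really cracks, expected below 1%.
    """
    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.generate_state(n_seeds) % (2**31)
    n_retained = n_crack_as_hole = 0
    rules = segment.ClassifierRules()
    for s in seeds:
        spec = phantom.PhantomSpec(
            protein_pct=60.0, oil_pct=5.0, semi_axes=(0.6, 0.65, 0.8),
            voxel_size=10.0, crack_count=2, rng_seed=int(s),
        )
        vol, truth = phantom.generate_seed_phantom(spec)
        mask = segment.segment_seed(vol, threshold=0.5)
        comps, labels = segment.extract_void_components(mask, return_labels=True)
        segment.classify_components(comps, mask, rules)
        true_classes = segment.match_ground_truth(labels, truth)
        retained = [c for c in comps if c.klass == "hole"]
        n_retained += len(retained)
        n_crack_as_hole += sum(
            1 for c in retained if true_classes.get(c.label) == "crack"
        )
    frac = n_crack_as_hole / n_retained if n_retained else None
    return {
        "n_retained": n_retained,
        "n_crack_as_hole": n_crack_as_hole,
        "fraction": frac,
    }


def water_saturation_run(rng_seed: int) -> dict:
    """Full voxel pipeline on one water-saturated seed.

    The generator gives soaked seeds no Small/Medium holes, so every
    retained hole should sit at or above 1e-5 normalized volume.
    """
    cfg = RunConfig(water_saturated=True, rng_seed=rng_seed)
    res = run_pipeline(cfg)
    assert res.table is not None
    v = res.table.data["v"].to_numpy()
    return {
        "n_retained": int(len(v)),
        "n_below_1e5": int((v < 1e-5).sum()),
        "min_v": float(v.min()) if len(v) else None,
        "truth_min_v": min(
            (h.normalized_volume for h in res.truth.holes), default=None
        )
        if res.truth
        else None,
    }
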