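# Methods

This note documents the models, conventions and numerical choices
behind `charvoid`, in the spirit of a methods appendix: what each
stage assumes, which knobs matter, and what the synthetic data do and
do not establish about real specimens.

## Synthetic seed phantoms

A phantom seed is an axis-aligned ellipsoid of "char" material
(uniform attenuation, 1.0 mm⁻¹ by convention) on zero background, with
semi-axes in mm (defaults 1.5 × 1.6 × 2.5 mm, a typical soybean) and a
stated voxel size in μm. Internal voids are carved back to background
intensity. The grid is sized to fit the seed with a 4-voxel margin
unless a shape is given.

### Hole abundance

Per-seed hole counts are Poisson with log-linear means in composition
(percent dry mass):

| rate | form | coefficients | default-cultivar values |
|---|---|---|---|
| λ_small | exp(a₀ + a₁·O) | a₀ = 0.6, a₁ = 0.115 | 27.5 / 10.2 / 16.6 |
| λ_medium | exp(c₀ + c₁·(O+P)/2) | c₀ = 0.4, c₁ = 0.06 | 8.4 / 8.4 / 11.4 |
| λ_large | exp(b₀ + b₁·P) | b₀ = −2.0, b₁ = 0.092 | 3.1 / 6.8 / 11.9 |

(values for oil/protein = 23.6/33.9, 15/42.5, 19.2/48.7). The
log-linear form is the simplest strictly monotone model that
reproduces the qualitative contrasts the charred-seed literature
reports: small-hole abundance rises with oil, large-hole abundance
with protein. Charring at 300 °C multiplies λ_small by exactly 0.5 —
"about half" made exact for testability. Water saturation sets
λ_small = λ_medium = 0 and enlarges the envelope by a 1.4 linear
factor; whether the reported ~1.4× enlargement of soaked beans is
linear or volumetric is not stated anywhere we know of, so linear was
chosen and is flagged here as an interpretation.

Known limitation: with the medium rate driven by (O+P)/2, two
compositions with equal mean composition (e.g. 15/42.5 and 23.6/33.9)
get identical λ_medium, so the model cannot separate them in the
Medium category. The Small/Large contrasts, the temperature halving
and the saturation effect — the claims the test suites check — are
unaffected.

### Hole geometry

Each hole's normalized volume v is drawn log-uniform within its
category decade (Small [1e-7, 1e-6), Medium [1e-6, 1e-5), Large
[1e-5, 1e-4)), which makes equivalent radii log-uniform over the
matching range — roughly 8–85 μm for the default ~25 mm³ envelope,
i.e. tens of micrometres. Shape: semi-axis ratios b/a, c/a uniform in
[0.6, 1], random orientation (QR-based uniform rotation). Centres are
uniform in the seed with the whole void kept strictly interior.

Cracks are thin plates: largest semi-axis log-uniform in 50–150 μm,
thickness ratio c/a = 0.05. They are deliberately *small* — in real
charred seeds cracks are fracture voids smaller than the holes, which
is exactly why the few that evade planarity screening cannot be told
apart from holes. Breaks (cotyledon separation) are modelled as a
2.5-voxel-thick plate across the seed mid-plane covering 95% of the
cross-section, leaving the halves attached at the rim.

Determinism: a `PhantomSpec` (including `rng_seed`) maps to
bit-identical volume and ground truth.

### Voxel-resolution budget

A hole at normalized volume v occupies v × (envelope voxels) voxels.
With the 10-voxel outlier floor, Small-decade holes (v ~ 1e-7) are
resolvable only on grids with ≥ 1e8 envelope voxels (~580³); at the
~100³ scale used for routine suites only the Large decade survives
voxelization. The category *statistics* therefore run on the
generator's analytic hole populations (phantom → quantify → stats),
while segmentation fidelity is established separately on fine-voxel
fixtures (10 μm voxels on a 0.6–0.8 mm seed, ~1.2e6 envelope voxels)
whose Large-decade holes and cracks are well resolved. Passing suites
show that the statistical machinery recovers the generative contrasts
at realistic sample sizes; they do not show that a given scanner
resolution suffices for real seeds — that is set by the physical
voxel size against the 1e-7 decade.

## Projection simulation and reconstruction

The forward model is parallel-beam Beer–Lambert attenuation: per
slice, line integrals via the Radon transform (pixel-step sums scaled
by the voxel size), detector counts Poisson(flux·e^(−p) + dark).
Flat frames are beam-only, dark frames beam-off; five of each by
default, averaged pixelwise for correction. No phase contrast, beam
hardening or detector PSF is modelled.

Correction: p = −ln((I − D̄)/(F̄ − D̄)), with transmittance clamped at
1e-6 before the log so zero-count pixels stay finite; a mean flat not
exceeding the mean dark anywhere is a data error naming the offending
pixel. Reconstruction is slice-by-slice filtered back projection with
a Ram-Lak ramp filter (Hann apodization optional). On a noiseless
uniform disk the interior mean is recovered to ≪1%; a full
simulate → correct → reconstruct roundtrip on a ~64³ seed phantom at
180 views and 5e4 counts/pixel correlates > 0.99 with ground truth.
Effective pixel size is detector pixel / magnification (6.5 μm at
2×/4× → 3.25/1.625 μm).

## Segmentation and classification

Material = voxels above an Otsu (or explicit) threshold, largest
26-connected component. The envelope — the "whole bean" including
enclosed voids — is the material after a morphological closing
(ball radius 2, capping narrow openings) and cavity filling
(background regions not 6-connected to the border). Voids are the
6-connected components of envelope ∧ ¬material; the 6/26 pair is the
standard complementary choice avoiding topological paradoxes. Void
voxel counts, material and envelope volumes add up exactly.

Per-component shape comes from the second-moment (inertia) tensor of
voxel centres, with a 1/12-per-voxel variance term for finite voxel
extent; semi-axes are √(5λᵢ) as for a solid ellipsoid, scaled per
axis so anisotropic voxels are supported. Planarity is c/a.

Classification rules (all thresholds overridable):

* **outlier** — fewer than n_min = 10 voxels (unresolvable);
* **break** — volume > 5% of the envelope, or exterior-connected with
  planarity < 0.3 (cotyledon separation);
* **crack** — planarity < 0.15;
* **hole** — everything else; only holes enter quantification.

On the default mixed suite (20 fine-voxel seeds, two cracks each) the
fraction of retained "holes" that are really cracks measures
0.3–0.7%, consistent with the < 1% contamination expected of this
screening. The normalization divisor V_seed is the *envelope* volume
(material plus enclosed voids): the natural reading of "whole bean
volume", and insensitive to internal porosity itself; a
material-volume divisor would couple the metric to the quantity being
measured.

## Quantification conventions

Decade categories are half-open with inclusive lower edges — the only
convention making the three bins exhaustive and disjoint. v < 1e-7 is
excluded (the outlier rule restated in normalized units); v ≥ 1e-4 is
flagged rather than silently kept. Normalized hole number is reported
in mm⁻³. Rank curves sort retained holes descending, ties broken by
component label (stable); all retained holes are included. The seed
dimension product L×W×T is rounded to one decimal, matching how such
measurements are reported.

## Statistics

One-way fixed-effects ANOVA; the post-hoc family is gated by Levene's
test (mean-centered, α = 0.05) — the conventional SPSS-style
homogeneity criterion, since no specific gate is canonical. Fisher's
LSD uses the pooled within-group mean square on N−k df; Dunnett's T3
uses per-pair Welch statistics with Welch–Satterthwaite df, adjusted
against the studentized maximum modulus over all pairs, whose tail is
evaluated by seeded Monte Carlo (100 000 draws by default; fixed
internal seed so adjusted p-values are reproducible) rather than
quantile tables — exact at arbitrary fractional df. Both post-hoc
families are always computed so either can be inspected; all tests
report mean differences, standard errors and confidence intervals.
Calibration under simulated nulls: ANOVA type-I error 0.04–0.06 at
α = 0.05 (3 groups × 7, 2000 reps), T3 family-wise error ≈ 0.03–0.05
under an unequal-variance null.

## Problem sizes

Routine suites use 7 seeds/group for the three-cultivar comparison
and 6/group for the temperature contrast, matching the study designs
being emulated; suite-level fractions are estimated over 20 (cultivar)
and 200–400 (temperature) seeded replicates — the temperature pattern
includes two true-null α = 0.05 checks, so its joint per-suite
propensity sits near 0.90 by construction and the per-check fractions
(~99.7% / ~95%) are the robust quantities. Voxel suites use ~100³
grids (60 μm voxels) for whole-seed runs and ~130–170³ grids (10 μm
voxels, small seeds) where individual voids must be resolved.

## Known limitations

* The composition→rate coefficients are calibrated to reproduce
  orderings, not absolute counts; group means are plot-level, not
  measured, quantities.
* Uniform char attenuation: no density gradients, surface texture or
  scan artefacts (rings, beam hardening), so segmentation thresholds
  face an easier task than on real reconstructions.
* Merged voids are not split (no watershed); two overlapping
  generated holes segment as one component.
* Equally-sloped tomography, phase retrieval and cone-beam geometry
  are out of scope; the reconstruction path is parallel-beam FBP only.
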