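# charvoid

Micro-CT void analysis of charred seeds: synthetic phantoms, filtered
back projection, hole segmentation, normalized porosity metrics, and
group statistics.

## The problem

Charred (carbonized) soybean cotyledons are porous: they contain
spheroidal/ellipsoidal internal voids — *holes* — tens to hundreds of
micrometres across, visible in synchrotron X-ray CT. Hole structure
carries compositional information: a high oil content favours many
small holes, a high protein content favours larger holes, charring at
300 °C rather than 275 °C roughly halves the number of small holes,
and water-saturated seeds lose their small holes entirely. This makes
the hole-size signature of a charred seed a non-destructive proxy for
oil/protein content — of interest to archaeobotanists studying crop
domestication and to anyone quantifying internal porosity of small
biological specimens from CT volumes.

`charvoid` implements the full analysis chain as a tested library, and
— because the original specimens are not publicly deposited — ships a
first-class synthetic-data generator so every stage can be validated
against known ground truth.

## The model

For a seed with envelope (whole-bean) volume $V_{\mathrm{seed}}$, each
retained hole of volume $V_i$ contributes a **normalized hole volume**

$$v_i = V_i / V_{\mathrm{seed}},$$

binned into half-open decades: Small $[10^{-7}, 10^{-6})$, Medium
$[10^{-6}, 10^{-5})$, Large $[10^{-5}, 10^{-4})$; $v < 10^{-7}$ is
excluded as unresolvable, $v \ge 10^{-4}$ is flagged. Per-seed category
counts (normalized by $V_{\mathrm{seed}}$, units mm⁻³) are compared
across groups with one-way ANOVA, a Levene variance gate selecting
Fisher's LSD (equal variances) or Dunnett's T3 (unequal variances,
studentized-maximum-modulus adjustment by Monte Carlo), and two-tailed
t-tests for two-group contrasts. The *rank curve* — $v$ against
descending rank — summarizes a seed's hole population: a long tail of
small holes signals oil, a heavy head of large holes signals protein.

The phantom generator encodes the composition effects as log-linear
Poisson hole-count rates

$$\lambda_{\mathrm{small}} = e^{a_0 + a_1 O},\quad
\lambda_{\mathrm{large}} = e^{b_0 + b_1 P},\quad
\lambda_{\mathrm{medium}} = e^{c_0 + c_1 (O+P)/2},$$

with $O$, $P$ the oil/protein percentages, an exact ×0.5 factor on
$\lambda_{\mathrm{small}}$ at 300 °C, and
$\lambda_{\mathrm{small}} = \lambda_{\mathrm{medium}} = 0$ plus a 1.4×
linear envelope enlargement for water-saturated seeds. See
`docs/methods.md` for coefficients, assumptions and limitations.

## Worked example

Generate a fine-voxel phantom of a high-protein seed, segment it, and
quantify its holes:

```python
import charvoid as cv

spec = cv.PhantomSpec(protein_pct=48.7, oil_pct=19.2,
                      semi_axes=(0.6, 0.65, 0.8), voxel_size=10.0,
                      rng_seed=1)
vol, truth = cv.generate_seed_phantom(spec)
mask = cv.segment_seed(vol)
comps = cv.classify_components(cv.extract_void_components(mask), mask)
holes = [c for c in comps if c.klass == "hole"]
table = cv.normalize_holes(holes, mask.envelope_volume, seed_id="demo")
m = cv.seed_metrics(table)
```

This prints (via the obvious `print` calls):

```
grid (128, 138, 168), envelope 1.307 mm^3
component classes: {'hole': 12, 'outlier': 21}
category counts: {'Small': 0, 'Medium': 0, 'Large': 12}
normalized count 9.18 mm^-3, porosity 4.07e-04
```

Twelve voids were retained as holes, all in the Large decade (at this
grid size only Large-decade holes exceed the 10-voxel outlier
threshold; 21 smaller voids were excluded as outliers), giving a
porosity of 4.1 × 10⁻⁴.

Comparing the three reference cultivars (7 synthetic seeds each,
charred at 275 °C) on analytic hole populations:

```python
from charvoid.pipeline import cultivar_suite
suite = cultivar_suite(1)
```

```
Small  P33.9O23.6=1.251  P42.5O15=0.387  P48.7O19.2=0.631   (mm^-3)
Large  P33.9O23.6=0.142  P42.5O15=0.273  P48.7O19.2=0.495
Small: F=55.58, p=1.98e-08   Large: F=13.71, p=2.41e-04
```

The high-oil cultivar (P33.9O23.6) dominates the Small category and
the high-protein cultivar (P48.7O19.2) the Large category, both highly
significant — the oil-vs-protein hole signature.

A command-line interface mirrors the library:
`charvoid simulate|reconstruct|segment|quantify|compare|run --help`.

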