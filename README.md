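# mosaiq

Quantitative analysis of **mosaic self-patterning in human iPSC
colonies**: when a CRISPRi-silenced subpopulation (reported by mCherry,
red channel) is mixed with wild-type GFP cells (green channel) inside one
colony, knockdown of mechanical regulators such as ROCK1 (cortical
tension) or CDH1 (E-cadherin adhesion) drives the two populations to
sort into reproducible spatial patterns. `mosaiq` implements the
image-based, biophysical and expression statistics used to quantify
those experiments, together with synthetic-data generators that provide
known ground truth for every stage:

* **Radial segregation score** — from a multi-channel colony image,
  binary masks are built per channel (threshold, remove small objects,
  fill small holes); the nuclear (blue) mask defines the colony's
  centroid and equivalent-area radius *r*; the score compares each
  population's area inside the inner band (≤ ¼ *r*) against the outer
  band (≥ ¾ *r*) and averages the red ratio with the inverse green
  ratio.  Edge-sorted CRISPRi cells score < 1, center-sorted > 1,
  well-mixed ≈ 1.
* **Differentiation co-emergence** — marker-positive (PAX6/EOMES) area
  fraction per population and the CRISPRi-over-WT enrichment ratio.
* **AFM elasticity** — Hertz spherical-indenter model
  *F* = (4/3)·*E*/(1−ν²)·√*R*·δ^(3/2) fitted to force curves with joint
  contact-point estimation; force maps (6×6 rasters) summarised into
  per-sample Young's moduli.
* **Comparative-C<sub>T</sub> expression statistics** — ΔΔCt fold
  changes (2^(−ΔΔCt)) against a housekeeping gene and reference group,
  the two-stage normalization to pure then mixed un-induced controls,
  and per-gene one-way ANOVA with Tukey HSD contrasts
  (mixing effect, knockdown effect, knockdown-within-mixed effect).

## Worked example

Score a synthetic colony whose red population was planted entirely at
the colony edge (`radial_edge`, strength 1):

```python
from mosaiq import RadialSegregation
from mosaiq.synthetic import ColonySpec, generate_colony_image

image, truth = generate_colony_image(
    ColonySpec(mode="radial_edge", strength=1.0, n_cells=200, seed=4))
print(RadialSegregation(image).fit().summary())
```

```
Radial segregation score
--------------------------
density_normalized (primary):
  ratio_red   : 0.01351
  ratio_green : 1.235
  combined    : 0.4116
literal_area:
  ratio_red   : 0.001249
  ratio_green : 0.1142
  combined    : 4.379
areas (px): dapi=115883 inner_band=5545 outer_band=59960
```

The red population's inner/outer density ratio is ~0.014 (almost no red
area near the colony center), the green ratio is slightly above 1, and
the combined score 0.41 ≪ 1 reports strong edge sorting.  A well-mixed
colony scores ≈ 1 under the density-normalized variant.

Fitting a noisy synthetic force curve recovers the planted modulus:

```python
from mosaiq import HertzModel
from mosaiq.synthetic import ForceCurveSpec, generate_force_curve

curve = generate_force_curve(ForceCurveSpec(E_true=1000.0, noise_sd=0.2, seed=0))
print(HertzModel(curve).fit().summary())
```

```
Hertz spherical-indentation fit
---------------------------------
converged        : True
Young's modulus E: 994.281 Pa
contact point    : 1 um
RSS              : 7.37512 nN^2
post-contact n   : 133
tip radius       : 2.5 um
Poisson ratio    : 0.5
```

And a Ct table with a planted 2.5-cycle knockdown in both induced arms
yields the expected contrasts:

```python
from mosaiq import ComparativeCt
from mosaiq.synthetic import CtDesign, generate_ct_table

effect = {("geneX", "pure_kd"): -2.5, ("geneX", "mixed_kd"): -2.5}
table = generate_ct_table(CtDesign(effect=effect, seed=0))
print(ComparativeCt(table).fit().summary())
```

```
Comparative-CT analysis
------------------------
samples        : 12
genes          : 2
housekeeping   : 18S
reference group: pure_uninduced
contrasts      : 2/6 significant at alpha=0.05
  geneX d1 kd_effect: log2FC=+2.60 p=1.05e-05
  geneX d1 kd_in_mixed_effect: log2FC=+2.70 p=7.79e-06
```

The knockdown contrast and the knockdown-within-mixed contrast are
flagged; the mixing-only contrast is (correctly) not.

## Command line

Every stage is also exposed as a `mosaiq` subcommand operating on files
(16-bit multi-channel TIFF images, CSV tables) and writing CSV/JSON
artifacts plus a run manifest:

```bash
mosaiq simulate --kind colony --mode radial_edge --strength 1 --n 10 --seed 0 --out sim/
mosaiq score    --images 'sim/*.tif' --out scores.csv
mosaiq afm-fit  --curves 'afm/*.csv' --tip-radius 2.5 --poisson 0.5 --out fits.csv
mosaiq qpcr     --ct ct_table.csv --out qpcr/
```

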