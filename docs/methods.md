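# Methods

## The measurement problem

A mosaic colony contains two genetically distinct but initially
well-mixed hiPSC populations: CRISPRi cells reporting induction with
mCherry (red) and wild-type cells expressing GFP (green), over a nuclear
stain (blue) that marks the whole colony.  Knockdown of mechanical
regulators can make the subpopulation sort toward the colony edge,
toward the center, or into discrete islands.  The package quantifies
(i) that spatial sorting from 2-D fluorescence images, (ii) lineage
marker co-emergence after directed differentiation, (iii) cell
elasticity from AFM force curves, and (iv) knockdown-induced expression
changes from qPCR Ct tables.  All four analyses are area- or
scalar-based; none require per-cell instance segmentation or tracking.

## Mask construction

Each channel is thresholded (Otsu by default; a fixed threshold can be
configured), 8-connected foreground components smaller than
`min_object_px` are removed, and enclosed background components smaller
than `min_hole_px` are filled.  A "hole" is a background component that
does not touch the image border; hole filling is implemented directly
(component labelling + area census) so this definition holds exactly.
Defaults `min_object_px = min_hole_px = 64` are package choices — they
are below the area of any rendered cell (≥ 314 px) and above plausible
speckle noise; both are configurable.  A constant channel under Otsu
raises an explicit degenerate-input error rather than returning an
empty mask.  Masking is idempotent on binary input, and raising a fixed
threshold can only shrink the mask.

## Radial segregation score

From the nuclear mask the colony gets a centroid (mean of mask pixel
coordinates) and an **equivalent-area radius** r = √(area/π).  This
radius definition is robust to ragged borders; a max-distance radius
would be dominated by single protruding cells.  The inner band is the
nuclear mask within ¼·r of the centroid, the outer band beyond ¾·r; the
middle band is deliberately unused, which makes the statistic sensitive
to the extremes of the radial distribution.  Each population's ratio is
computed in two variants:

* `density_normalized` (default): share of nuclear area occupied by the
  population in the inner band divided by the same share in the outer
  band.  A uniformly mixed population scores exactly 1, so the combined
  average with the inverse green ratio is self-consistent.
* `literal_area`: raw inner/outer population area quotient.  A uniform
  population scores the band-area ratio (1/7 in the continuum limit:
  (r/4)²π versus (1−9/16)πr²); per-population total-area normalization
  cancels in this quotient and is therefore only recorded.

The combined score is the arithmetic mean of the red ratio and the
inverse of the green ratio.  Note this combination is *not* exactly
inversion-symmetric under a red/green channel swap — 1/mean(r, 1/g)
equals mean(g, 1/r) only when r·g ≈ 1; what does hold exactly is that a
channel swap exchanges the two population ratios, and the test suite
asserts that form.  Zero denominators produce an infinity sentinel,
0/0 produces a missing value with a logged warning; batch scoring never
aborts on one degenerate colony.  Both variants are reported for every
colony.  Whether ratios are averaged per colony or areas pooled across
colonies is a genuine choice; per-colony scoring is used, matching how
replicate colonies are treated as statistical units downstream.

### Calibration and its limits

With ~200 cells per colony at a 1:3 red:green ratio, the inner band
(radius ¼·r) contains only ~12 cells, ~3 of them red.  The per-colony
combined score under the null therefore has an intrinsic spread of
σ ≈ 0.3 — hypergeometric label-sampling noise, not an imaging artifact
— and its per-colony distribution is right-skewed (the long-run mean is
≈ 1.05, the median ≈ 1.02).  A small additional upward component comes
from coverage multiplicity: at the colony fringe, pixels are covered by
a single cell rather than several, which raises both populations' inner
densities relative to outer and partially cancels in the combined
average.  Consequences drawn here: calibration checks estimate the
expected batch mean over 200 seeded colonies (Monte-Carlo error ≈ 0.02)
rather than a single 20-colony batch whose mean fluctuates by ±0.07,
and monotonicity checks across planted bias strengths use 50 colonies
per level.

## Synthetic colony generator

Cell centers are sampled uniformly in the colony disk; labels follow the
placement mode: `mixed` draws the red quota uniformly; `radial_edge`
uses sampling weight (1−s) + s·ρ/r and `radial_center` its mirror, with
strength s interpolating from uniform mixing to full bias;
`islands` plants n seed points and colors the cells nearest to any seed
(ties broken by cell index) until the quota is met, reproducing discrete
knockdown islands.  Cells are rendered as hard disks so that noise-free
masks are exactly recoverable by thresholding — segmentation accuracy
can be asserted as IoU = 1 rather than approximately.

Defaults are the study conditions: ~100 cells per colony, fraction_red
0.25 (the 1:3 CRISPRi:WT mix), 512-px frames with a 200-px colony
radius.  The cell radius default is 20 px so that a 100-cell colony is
*confluent* (cell diameter ≈ colony diameter/√n): hiPSC colonies are
confluent epithelial sheets, and sparse-dot rendering demonstrably
mis-calibrates the density-normalized score (long-run null mean 1.15 at
~40% coverage versus 1.05 confluent).  No pixel size is implied; an
optional µm-per-pixel field is metadata only.  What the generator does
*not* emulate: cell-shape irregularity, intensity gradients and
vignetting, z-stacking of populations, and any sorting *dynamics* — it
paints end-state patterns only.  Passing tests therefore validate the
measurement pipeline, not a mechanistic model of sorting.

## Lineage co-emergence

After directed differentiation the blue channel reports PAX6 or EOMES
rather than a nuclear stain.  The marker-positive fraction of a
population is area(population ∧ marker)/area(population); the
enrichment ratio divides the CRISPRi fraction by the WT fraction.  The
marker channel is masked with the same recipe as the population
channels (no separate recipe is warranted for nuclear transcription
factors in an area-based analysis).  Fractions are bounded in [0, 1] by
construction; 0/0 enrichment is reported missing.

## Hertz force-curve fitting

The forward model for a spherical tip of radius R on an incompressible
elastic half-space is F = (4/3)·E/(1−ν²)·√R·δ^(3/2).  Units are µm/nN
at the interface (so F[nN] = 10⁻³·(4/3)·E[Pa]/(1−ν²)·√(R[µm])·δ[µm]^1.5)
with E in Pa.  Defaults: R = 2.5 µm (5 µm-diameter sphere), ν = 0.5,
spring constant 0.05 N/m, 4 nN maximum force.  Raw (piezo z, deflection
d) input is converted by F = k·d, δ = z − d, leaving the pre-contact
baseline in place.

The contact point δ₀ is unknown and estimated jointly with E by grid
search over the curve's own sample positions: at each candidate the
model is zero before contact and c·(δ−δ₀)^{3/2} after, the amplitude
c ≥ 0 has a closed-form least-squares solution, and the candidate with
minimal total residual sum of squares wins (ties resolved to the
earliest contact point).  This is deterministic, needs no smoothing
hyperparameters, and recovers noise-free synthetic curves to machine
precision with the contact point exact on the grid.  Fits with fewer
than 5 post-contact samples, or with a non-positive amplitude (e.g. an
all-zero curve), are flagged non-converged with E missing.  Exact
consequences of linearity: scaling all forces by c scales E by c, and
refitting with a different ν rescales E by (1−ν²)new/(1−ν²)old.  Only
the approach segment is modelled; no Sneddon/JKR/viscoelastic variants.
A configurable maximum-indentation cutoff exists and is off by default.
Force maps (nominally 6×6, 5 µm spacing) are summarised by mean,
median and SD of the converged moduli; both mean and median are emitted
because either may be the preferred per-area statistic.

## Comparative-C_T statistics

Technical replicates are averaged per (sample, gene); ΔCt subtracts the
housekeeping gene (18S rRNA by default); fold change is 2^(−ΔΔCt)
against the day-matched mean ΔCt of the reference group (PCR efficiency
fixed at 2, the standard comparative-threshold assumption).  The
mixed-colony design adds a two-stage normalization: divide by the
day-matched pure un-induced control mean, then by the (stage-1)
mixed un-induced control mean, so that expression changes caused merely
by mixing two cell lines cancel before knockdown effects are assessed.
Both stages are retained in the output.

Significance per gene/day uses a one-way ANOVA across the four arms
(pure/mixed × un-induced/induced) on per-sample −ΔCt (log2 expression
relative to housekeeping; group contrasts on this scale are log2 fold
differences), followed by Tukey HSD.  Three named contrasts are read
off: mixing effect (mixed vs pure un-induced), knockdown effect (pure
induced vs pure un-induced), and knockdown-within-mixed (mixed induced
vs mixed un-induced).  Entries with adjusted p ≥ α are masked — the
grey cells of a rendered heat map.  Masking is monotone in α.  No
correction is applied across genes (per-gene reporting); biological
replicates (n = 3 by default) are the ANOVA units.  A caveat for
oracle comparisons: Tukey's adjusted p is guaranteed no smaller than
the *pooled-variance* (Fisher LSD) pairwise t-test p, but can undercut
a two-sample-only t-test when the other groups' variance is small,
because Tukey pools the mean-square error across all groups.

The synthetic Ct generator draws Ct = baseline + effect + N(0, σ) with
σ = 0.3 cycles and n = 3 biological replicates per arm.  Planted
knockdowns used in power checks are −2.5 cycles (≈ 18% residual mRNA),
inside the 1.7–3.3-cycle range corresponding to the knockdown
efficiencies this assay design targets; note the ΔCt noise is √2·σ
because the housekeeping measurement contributes equally.

## Problem sizes and numerical choices

Calibration and ordering checks use 200-cell colonies (200 seeds for
the null mean, 50 per bias strength); segmentation checks use 5
colonies noise-free and 5 at 5% intensity noise; Hertz recovery uses
100 curves at 5% force noise; error control uses 200 null Ct tables and
100 planted ones.  These sizes put Monte-Carlo error well below each
check's tolerance while keeping the full run around a minute.  Ties in
the contact-point search go to the earliest candidate; infinities and
0/0 in ratio computations become sentinels/missing values rather than
exceptions; all generators draw from a single seeded NumPy generator
per call, so identical spec + seed is bit-identical output.

## Known limitations

The generator's end-state painting cannot probe time-resolved sorting;
the segregation score saturates once a population vacates a band (the
ratio hits 0 or the sentinel); area-based lineage scoring counts
overlap pixels toward both populations, which dilutes extreme
enrichments in dense colonies; and the four-arm one-way ANOVA treats
the design as unstructured groups rather than a 2×2 factorial, so
interaction effects are only accessible through the named pairwise
contrasts.
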