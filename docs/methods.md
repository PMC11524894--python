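# Methods

This note documents the models, conventions and numerical choices behind
`lungquant`, and what the synthetic-data tests do and do not demonstrate
about real whole-slide images.

## Data model

A tissue mask is a 2-D integer raster (0-based, row-major `(row, col)`)
bound to a class legend. The working legend has 12 entries: 11 tissue
classes plus slide background (`BACK`, id 0, so zero-initialized rasters
are background). Ids are contiguous from 0, names unique, and exactly
one class carries the `background` group. Areas are exact:
`area_µm² = pixel_count × mpp²` with `mpp` the microns-per-pixel
resolution (1.0 µm/px ≈ 10× magnification is the working default).
Background is excluded from every density denominator.

The pre-merge annotation scheme is also modeled: 14 tissue classes in
which non-tumor stroma is split into connective tissue, fat, muscle and
vessels; `merge_classes` collapses those four into `STROMA`, yielding the
11-class working scheme, and returns an id map for converting rasters.

RGB color-coded masks are ingested through the legend's color table;
pixel colors absent from the legend are an error, never guessed.

## Tiling and inference

Grids are exact covers by non-overlapping tiles of at most 512 px per
side, with ragged edge tiles rather than padding. Tile outputs are
placed verbatim: no smoothing, overlap blending or post-filtering of any
kind. Consequently, for any deterministic per-pixel segmenter the tiled
result is bit-identical to whole-image application — an invariant the
tests assert exactly, not approximately. Label rescaling between
resolutions uses nearest-neighbor only (center-of-pixel mapping,
`src[floor((i+0.5)/scale)]`), because any interpolation of class ids
fabricates classes; a rescale can therefore never introduce an id absent
from the source.

The segmenter seam accepts any callable from an image tile to a label
tile of the same height/width over the legend's ids. Two stand-ins ship
with the package: an identity pass-through for label rasters and an
intensity-binning toy. They exercise the harness end-to-end; they are
not segmentation models.

## Dice evaluation

Per class, `D_c = 2|T_c∩P_c| / (|T_c|+|P_c|)` over the evaluated region
(the annotated-region raster when given, the full frame otherwise).
A class with zero support in both masks has no defined Dice and is
excluded from the macro average — scoring it 1.0 would inflate reports
on sparsely annotated validation sets, scoring it 0 would punish them.
A pooled (micro) variant — intersections and supports summed over
classes before the ratio — is reported alongside, since an "overall"
Dice can reasonably mean either.

## Subtyping

Subtype labels (LUAD/LUSC plus tumor stroma, necrosis, mucin,
background) are interpreted **only** where the main mask found
epithelial tumor; subtype pixels elsewhere are ignored, never
reassigned. The slide call is the argmax of
`pct_LUAD = 100·LUAD/(LUAD+LUSC)` over that support, so
`pct_LUAD + pct_LUSC = 100` whenever evaluable tumor exists. The
borderline flag uses the closed interval [40 %, 60 %] on the winning
percentage — endpoints included, erring toward review. An exact 50/50
tie is called LUAD deterministically, flagged borderline and logged;
the flag routes such slides to immunohistochemistry regardless of which
label the tie-break picks. A slide with no evaluable tumor returns an
explicit `NO_TUMOR` outcome rather than raising.

The mucin fraction `100·mucin/(mucin + LUAD + LUSC + tumor stroma)` is
tallied over the same epithelial-tumor support, consistent with the rule
that the subtype layer is undefined outside it. The percentage is
reported without a mucinous-subtype call: no threshold is established,
and the value is meant for a pathologist's judgement.

Case aggregation pools raw pixel counts across slides (area weighting)
and classifies the pooled tallies exactly like a slide. Pooling is
invariant to slide order and to how a tumor is split across blocks, and
reduces to the slide call for a single slide; averaging slide
percentages would have neither property.

## Prognostic parameters

Objects are connected components of the TLS or necrosis class under
8-neighborhood connectivity (4 is available; 8 is the default because
thin diagonal structures at 1 µm/px would otherwise fragment). **No size
filtering is applied at any stage** — single-pixel components count.

Qualification measures each object's minimum Euclidean distance (via an
exact distance transform, scaled to µm) to the tumor region — the union
of epithelial tumor, tumor stroma, necrosis and mucin, minus the
object's own class so that a necrosis object can never qualify against
itself. An object is *intratumoral* when that distance is within
√2·mpp (8-neighbor touching), *peritumoral* when within the
"immediate peritumoral" threshold, and *non-tumor-associated* otherwise
(excluded from all densities). The threshold defaults to 250 µm — a
choice on the scale of a few alveolar diameters, not an established
constant — and is exposed in the configuration and recorded in every
run log.

Densities divide qualified areas by the epithelial tumor + **tumor**
stroma area (non-tumor stroma is deliberately excluded: these are tumor
densities). `T/NR` is the raw TLS/necrosis area ratio with no further
normalization; it is *undefined* (not 0, not ∞) when qualified necrosis
is absent, and such cases are excluded from T/NR dichotomization while
keeping their other parameters. Stored values are raw ratios; any
display upscaling (×1,000 for readability of small densities) is
presentation-only and never enters stored or computed values.

The cumulative T+NR classifier maps the two dichotomized densities to
three groups: PG1 = TLS-high & necrosis-low (both favorable), PG3 =
TLS-low & necrosis-high (both adverse), PG2 = the two mixed
combinations. Treating the two discordant combinations as one middle
group is the natural reading of a three-level scheme built from two
binary factors, but it is a design choice, not an established fact.

### Optimal cutoff

Candidate cutoffs are the cohort percentiles 10–90 in steps of 2.5; at
each candidate the cohort splits at `value ≤ c` vs `> c` and the
two-group log-rank χ² is computed; the maximizer wins subject to each
group keeping at least 10 % of the cohort (and ≥ 2 cases), ties broken
toward the smaller cutoff. The full statistic trace is part of the
result: maximally selected statistics are famously optimistic, and no
multiplicity correction is applied internally — users who need honest
p-values for the *cutoff itself* must correct downstream. The cutoff is
found once on a primary endpoint and reused across endpoints.

## Survival machinery

Kaplan–Meier and the two-group log-rank test are implemented natively —
the cutoff scan calls log-rank once per grid candidate, so its inner
loop must not drag in a fitting framework — and are verified in the
tests against both hand-computed product-limit tables and lifelines.
Log-rank uses the standard pooled risk-table O−E/V form with the
hypergeometric variance; a zero-variance table with zero O−E scores 0.
Cox models delegate to lifelines (Efron tie handling, the conventional
default). pT/pN enter as dummy variables with the lowest category as
reference; an ordinal-trend encoding would be equally defensible but
assumes linearity across stages. Degenerate designs (constant
covariate, fewer events than covariates, separation) raise a fit error
with the reason, caught and logged per-model by the pipeline.

## Synthetic data

The generator reproduces the *geometry the analysis depends on*, not
histology: smooth tumor blobs (unions of random disks, textured into
epithelial tumor vs tumor stroma by a thresholded Gaussian random
field), necrosis and mucin carved strictly inside the tumor, TLS disks
placed intratumorally, peritumorally (center distance chosen so the
object's minimum distance falls inside the 200 µm placement band) or
distantly (beyond 300 µm), and a benign surround with a background
margin. Planted fractions are solved against the **final** tumor +
tumor-stroma denominator (carving shrinks it), and disks are trimmed to
exact pixel counts, so planted densities are recovered essentially
exactly; the ±10 % recovery tolerance in the tests absorbs residual
discretization at small canvases. Every object's planted placement
category is recorded, giving the qualification tests a by-construction
oracle. Infeasible requests — fractions summing past 0.8, distant
placement on a canvas with no room beyond the association distance —
raise a spec error rather than silently degrading.

Survival cohorts draw exponential event times with log-hazard linear in
the planted densities (TLS protective, necrosis adverse; hazard ratios
are parameterized per 0.05 density units, roughly the planted spread),
independent exponential censoring capped at 120 months, three endpoints
(OS/CSS/PFS) with different baselines, and pT/pN categories sampled from
latents positively associated with necrosis density. The cutoff-recovery
cohort instead plants a hazard *step* at a known value. Default study
conditions for the recovery analyses: 1024² masks at 1 µm/px for density
recovery; 50 cohorts of n = 200 with hazard ratio 3 for cutoff recovery;
n = 500 with hazard ratio 2 for Cox recovery.

**What passing tests do not show:** the generator's blobs are smooth and
its classes noiseless, so the tests validate the *quantification layer*
— areas, components, distances, statistics — under a known truth. They
say nothing about segmentation accuracy on real H&E slides, about
stain/scanner variation, or about clinical effect sizes; those require
trained models and patient cohorts, which are outside this package.

## Known limitations

* The "immediate peritumoral" 250 µm threshold and the PG2 composition
  are package choices where the field has no fixed convention; both are
  configurable/auditable rather than asserted.
* The pipeline is single-process; slide-level parallelism is the
  caller's concern.
* Pyramidal WSI formats are not read directly; masks arrive as plain
  rasters (PNG/TIFF/npy) at the working resolution.
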