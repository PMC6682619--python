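# Methods

This note documents the models, defaults and design choices behind
thromboquant, in the spirit of a methods appendix: what the pipeline
assumes, which knobs matter, and what the synthetic benchmarks do and do
not demonstrate.

## Image model and background correction

Brightfield thrombus micrographs from flow chambers carry three dominant
artifacts: slowly varying illumination, periodic striping from the camera
readout, and pixel noise. The pipeline treats them separately.

The bandpass step is a Gaussian-weighted high-pass applied in the frequency
domain with transfer function

```
H(f) = 1 − exp(−(f · L)²)
```

where `f` is radial spatial frequency (cycles/pixel) and `L` the
large-structure cutoff in pixels (default 60 for brightfield, 65 for
fluorescence). Structure with wavelength ≫ `L` is removed almost entirely
(a period-200 px wave survives at <9 % of its amplitude with `L = 60`),
while a 3×3 spot keeps ≥99 % of its contrast. We parameterize the Gaussian
by the cutoff wavelength directly rather than by a spatial σ: the
equivalent spatial scale is σ ≈ 0.225·L, chosen so that "structures larger
than L pixels" are in the stop band — a σ as large as L/2 would leave more
than a third of a period-200 illumination wave in place, defeating the
correction. The output is re-offset to the input mean and clipped to the
bit-depth range. Small-structure smoothing (`bandpass_small_px`) exists but
is off by default because sub-platelet texture carries signal.

Strictly columnar striping lives on the zero-vertical-frequency line of the
2-D spectrum, so the filter can optionally zero that line
(`suppress_stripes="vertical"`, the default; "horizontal" and "none" are
available). A compact object only loses its column-mean contribution —
a few percent of its energy — while a row-constant artifact is removed
exactly. This matters because the grayscale closing that follows can only
bridge stripes *between* objects: a stripe trough crossing a platelet
smaller than the structuring element cannot be repaired by morphology, and
without spectral suppression such pixels fall below the threshold and bias
coverage low by 2–3 %SAC under 10–15 % striping.

## Grayscale morphology

The brightfield clean-up applies, in order: grayscale closing with a
diamond of radius 4 px, closing with a disc of radius 2 px, and dilation
with a disc of radius 1 px (all configurable; the invariant
large > medium > small ≥ 1 is enforced). The closings fill dark gaps
narrower than their footprints and round shapes; both are idempotent and
verified pixel-for-pixel against a brute-force sliding min/max oracle in
the tests. The final dilation is extensive — it grows bright objects by one
pixel — so the measurement path erodes the thresholded mask by the same
disc before counting pixels. The net effect on the mask is a binary
closing: holes are filled, no systematic size bias is introduced. The
dilate radius is deliberately exposed because it is the step users of the
original interactive tooling were expected to adjust per dataset.

## Thresholding

Thresholds may be set manually (they are always recorded and logged) or
resolved by Otsu's criterion. Otsu always splits a histogram, including a
unimodal one, so an automatic threshold on an object-free frame would
report noise as platelets; the guard declares a frame empty when the
inter-class mean separation is below 2.5 pooled within-class standard
deviations. After the clean-up chain an object-free frame sits near 2.1
and even a 10-platelet frame above 2.7, so the guard is not a sensitive
dial. Brightfield polarity (platelets brighter or darker than background)
is configurable with `auto` assigning the minority pixel class to the
foreground.

Aggregate coverage (P2) has no standard pixel-level definition in
brightfield; we use a two-criterion rule: a connected component of the
platelet mask counts as an aggregate when (i) its area is at least 80 px
and (ii) at least 10 % of its pixels pass a second, more stringent
intensity threshold (default: Otsu over foreground pixels only) capturing
the denser multilayered core. Both criteria are configurable; a stringent
threshold that is not stricter than the primary one is a configuration
error. By construction P2 ≤ P1.

## Parameters, averaging and inclusion

Parameter values from the (typically three) images of one experiment are
averaged; a parameter present in only some images is averaged over the
available ones with a warning rather than discarding the experiment, since
fluorescence panels are often partial. Visual scores P3–P5 are accepted in
0.5 increments within their ranges (0–5, 0–3, 0–3) and multiple observers
of an image are averaged. Strain summaries report mean, sample SD (n−1
denominator) and n per parameter; the inclusion rule (≥3 animals per
modified group, ≥4 per wild-type cohort) is enforced by default and raises
a named exclusion error.

## Scaling, subtraction and the relevance filter

Scaling is univariate per (surface, parameter) column: anchored at 0
(every parameter's natural range starts at zero) with the observed maximum
across *all* strains in the run — wild-type and modified jointly — mapped
to 10. Anchors are recorded so later data can be scaled consistently.

The subtraction heatmap is scaled modified minus scaled wild-type, paired
by wild-type database cohort. "Composite mean ± SD" is realized as the
root-mean-square of the two group SDs on the scaled axis,
`sqrt((SD²_mod + SD²_wt)/2)`; the more conservative `max(SD_mod, SD_wt)`
is available via `sd_mode="max"`. SDs are compared on the scaled axis
(scaling first, then filtering) and variance is not pooled across
parameters. Under a planted null with n = 4 per group, the |Δ| > composite
SD rule flags ~22–24 % of cells — it is a salience filter, not a
significance test, and p-values are deliberately not attached to it.

Kendall's tau-b (tie-corrected; exact enumeration for small untied
samples, tie-corrected normal approximation otherwise) is used for the
parameter correlation matrix on pairwise-complete observations; raw
p-values are reported without multiple-testing correction. Rankings sort
ascending by the summed scaled P2–P5 delta (thrombus signature) or the P1
delta, ties broken alphabetically by strain id; "none" instead orders rows
by agglomerative hierarchical clustering with complete linkage on
Euclidean distances, missing cells pairwise-excluded and distances
rescaled by `sqrt(k / k_valid)`.

Concordance with in vivo phenotypes classifies each strain by the sign of
its summed relevant P1–P5 change at the collagen surface and cross-tabulates
against the packaged literature labels (thrombosis: decreased / unchanged /
increased; bleeding: prolonged / unchanged / shortened; "nd" tabulated
separately). One packaged row carries a compound unchanged-to-prolonged
bleeding token; it is mapped to "prolonged", the flagged direction.

## MCODE

The clustering is the original two-stage molecular-complex-detection
scheme. Stage 1 weights each vertex by `k · density(highest k-core of its
closed neighborhood)`, with vertices under the degree cutoff (2) scored
zero. Stage 2 grows clusters breadth-first from the highest-weighted
unvisited seed, admitting neighbors with weight ≥ seed weight × (1 − 0.2),
up to depth 100; a 1e−9 tolerance on the comparison absorbs floating-point
ties of exactly-rational weights. Post-processing: the 2-core haircut (on),
then fluff (on): boundary neighbors whose closed-neighborhood density
exceeds 0.1 are admitted and may belong to several clusters. Two choices
deviate from the historical defaults and are deliberate: vertices removed
by the haircut are *not* consumed, so a vertex dragged across a spurious
inter-complex edge remains available to its true complex; and fluff is on
by default because members of a dense complex whose vertex weight falls
just outside the 20 % seed window are otherwise lost — with fluff off,
planted 8-node blocks (within-block edge probability 0.9, between 0.05)
are jointly recovered in only ~75 of 100 graphs, with it in ≥96. Clusters
must contain a 2-core; the score is density × node count; ordering is by
score, then size, then seed symbol. Edge confidences are parsed from both
STRING dialects (0–1000 integers and 0–1 floats, auto-detected), filtered
at 0.40 by default.

Live STRING queries, shell-interactor expansion and pathway enrichment are
out of scope; the module consumes pre-exported edge lists.

## Synthetic data: what it does and does not show

The brightfield generator places non-overlapping bright discs (platelets,
radius 2–4 px; intensity 0.65 of range on a 0.40 background) and larger
aggregate blobs (radius 14 px, rim 0.70, core 0.85) on 256×256 frames,
then adds a period-8 px vertical sinusoidal stripe (default amplitude 10 %
of range), a linear vertical illumination gradient (default 15 %) and
Gaussian noise (default 3 %). Separation margins (≥10 px) keep distinct
objects from merging under the morphology so component-level truth stays
meaningful. Truth masks and percentages are exact by construction. The
benchmark sweep spans stripe amplitudes 5–15 % and gradients 8–20 %.

The strain-table generator plants effects on the 0–10 scaled axis with the
top of each parameter's observed range as the nominal anchor, draws
replicates from truncated normals (group SD in scaled units, default 0.5),
rounds visual scores to half steps, and clamps P2 ≤ P1 per replicate —
planted effect combinations must respect that physical coupling. The graph
generator produces planted-partition graphs with uniform confidences in
the 0.40–0.99 band.

Passing these benchmarks shows the measurement chain is unbiased under the
modelled artifacts and that the statistical machinery recovers effects of
the planted size; it does not validate against real stained thrombi (no
out-of-focus light, debris, uneven staining, or platelet shape variation),
and the printed correlation coefficients of any particular historical
cohort are not reproducible without that cohort's raw per-strain data.

## Numerical and reproducibility choices

All intermediate images are floating point, clipped and rounded only at
file output. Coordinates are row-major, origin top-left. All generators
and every pipeline stage are seed-deterministic; identical configuration
and inputs yield bit-identical output manifests (SHA-256 per artifact).
Every resolved threshold and scaling anchor is logged, since the manual
threshold choices of the interactive workflow are the main reproducibility
hazard this package is designed to remove. Problem sizes in the shipped
benchmarks (50 images, 500 strain tables, 100 graphs) were chosen to give
stable rates while keeping a full verification run around a minute on one
CPU.
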