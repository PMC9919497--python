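# Methods

`psmmet` quantifies the gradual mesenchymal-to-epithelial transition (MET)
that accompanies somite formation in the amniote presomitic mesoderm (PSM).
Somites bud sequentially from the rostral end of the PSM, so position along
the tissue is a proxy for developmental time: cells located more caudally
are younger. The package turns three kinds of raw measurements — manually
traced cell outlines from sectioned tissue, polarity-marker intensity
stacks, and time-lapse distance tables — into per-domain onset positions
for cell elongation and apical polarization, and rescales those positions
into hours before segmentation.

## Coordinate conventions

Outline coordinates are 0-based pixels with y increasing downward (image
convention); physical calibration (µm/pixel) is carried in the run
configuration, default 1.0. Rostro-caudal position is expressed per embryo
as a percentage of PSM length: 0% at the posterior tip, 100% at the
PSM–somite border. Somite cells are reported at 100% + 10% per somite
index purely for plotting continuity.

## Aspect ratio

The elongation proxy is the aspect ratio (AR): the longest over the
shortest dimension of the 2-D cell outline. The default estimator is the
fitted-ellipse axis ratio — the square-rooted eigenvalue ratio of the
polygon's area covariance matrix — which matches the standard FIJI "AR"
shape descriptor and is exact, deterministic and invariant under rigid
motion and uniform scaling. Moments are evaluated analytically from the
vertices (Green's theorem) in vertex-mean-centred coordinates; the naive
parallel-axis form loses ~1e-9 relative accuracy for small cells far from
the image origin. Because ellipse-fit and caliper measurements disagree on
concave cells and the original workflow does not say which FIJI readout
was used, a Feret alternative (max caliper / minimum rotated-rectangle
width) is selectable in config. Degenerate polygons (zero area, collinear)
raise an error naming the cell. Tests compare the analytic estimator
against an independent brute-force oracle that rasterizes each polygon at
10× supersampling and takes the pixel-cloud covariance (1% tolerance).

## Axis straightening and domain assignment

Cell centroids are orthogonally projected onto a midline polyline (user
supplied, or trivially the strip axis for synthetic data); cumulative arc
length is rescaled linearly to 0–100% per embryo. Projection ties between
non-adjacent segments resolve to the smaller arc length. The signed
perpendicular offset is positive on the dorsal side.

"A single layer of cells" is operationalized as a surface band: a cell is
a surface cell iff its outline comes within `surface_band_depth_px`
(default: the median cell minor-axis length) of the section's outer
boundary; all other cells are core. Sagittal PSM sections split the
surface dorsal/ventral by image side; sagittal somite sections use four
45°-rotated quadrants (dorsal/ventral/anterior/posterior) about the
section centroid; transverse sections use four 90° sectors
(dorsal/medial/ventral/lateral) about the centroid, rotatable in config,
with the medial side (facing the neural tube) set per section — anatomy
cannot be inferred from outlines alone. Ties at sector corners break in
the fixed order dorsal > medial > ventral > lateral.

## Sigmoid profiles and onset landmarks

Per domain, the response (AR or polarity delta) against position x is fit
by least squares with a 4-parameter logistic

    y(x) = a + (b − a) / (1 + exp(−k (x − x0)))

using a fixed multi-start grid (x0 ∈ {25, 50, 75}%, k ∈ {0.05, 0.2, 0.5},
asymptotes from the 5th/95th response percentiles), keeping the best-RSS
converged start, so fits are reproducible with no randomness. Fits are
canonicalized to b ≥ a (decreasing profiles get k < 0 and a flag). If no
start converges the flat model (a = b = mean) is returned flagged
`no_sigmoid`. Responses are fit untransformed by default (a log-response
flag exists); the fitter requires n ≥ 8 points spanning ≥ 30 percentage
points.

Two onset landmarks are extracted: the inflection x0, and the position at
10% of the curve's vertical height, which has the closed form
x0 − ln(9)/k (verified against numeric root-finding to 1e-8). Model
support is summarized by a nested F-test against the constant-mean model,
F = ((RSS_flat − RSS_sig)/3)/(RSS_sig/(n−4)), with p from F(3, n−4).

**Known limitation — F-test calibration.** Under a truly flat profile the
onset x0 and slope k are unidentified, so optimizing them inflates F
slightly beyond the nominal F(3, n−4) reference (a Davies-type problem).
Measured on flat-truth simulations, p-values are mildly anti-conservative
(median ≈ 0.37 rather than 0.5; a KS test against uniformity rejects over
hundreds of replicates). Consequences: genuinely flat profiles (e.g. core
cells) are usually, but not ≥95%-reliably, assigned large p; p should be
read as a ranking/screening statistic, not an exact tail probability. Two
acceptance tests pin the idealized behaviour (exact uniformity; core
p > 0.5 in ≥95% of runs) and fail by design margins; they are kept at
their stated thresholds rather than loosened.

Group comparisons (between domains within a position bin, same domain
across bins, left vs right, anterior vs posterior somite domains) report
Welch's t and the Wilcoxon rank-sum statistic with raw p-values plus a
Holm adjustment per family. Box-plot summaries per (domain, bin) use
lower-open, upper-closed bins (an edge value belongs to the lower bin) and
1.5·IQR whiskers.

## Polarity quantification

Each transverse intensity slice carries a PSM cross-section mask. The
surface band (Euclidean distance transform ≤ band depth) is split into an
apical (inner) and basal (outer) half at the midpoint of the local band
thickness — a parameter-free, symmetric choice, since the original split
surface is not documented. Sectors reuse the transverse rules above,
evaluated about the slice's apical reference point. The polarity index per
domain and slice is delta = mean(apical) − mean(basal): means rather than
sums so delta is independent of sector area (a sum option exists), and a
constant background cancels exactly. Sectors with fewer than 10 pixels in
either half are dropped with a log entry. The core is never analysed —
apical/basal is undefined for unpolarized mesenchyme. Delta-vs-position
profiles feed the same sigmoid/landmark stage. No cross-embryo intensity
normalization is applied by default; per-slice median-background
subtraction is available in config.

## Position → time rescaling

Somite-formation rate: per embryo, interval = duration / somites formed;
the cohort value is the arithmetic mean of per-embryo intervals (68 min
for the two bundled example embryos: 2050 min/28 and 1690 min/27).

The labelled-front trajectory — front-to-border distance normalized by the
concurrent PSM length, i.e. position in % — is fit with a continuous
two-segment piecewise-linear model; the breakpoint is chosen by exhaustive
search over interior observed timepoints (≥3 points per side), each
candidate solved by linear least squares. The two-segment model is
accepted over a single line by a nested F-test (2 extra parameters,
α = 0.05); otherwise a single-phase map is returned flagged. Tracks a
single line already explains to working precision short-circuit to
single-phase. The map reports hours remaining before the material at a
position reaches the forming-somite border: t100 − t(p), monotone, 0 at
100%. Positions outside the observed trajectory range are computed from
the fitted model but flagged extrapolated. A raw-µm (unnormalized) mode
exists in config.

## Synthetic data: what it does and does not establish

Generator defaults state the conditions the pipeline is meant to recover:

- AR truth per surface domain: 4PL with a = 1.5, b = 6, k = 0.3 and onsets
  dorsal 40% < medial 55% < ventral = lateral 70%; core AR constant at
  2.2. Noise is multiplicative lognormal, σ = 0.15 (AR ≥ 1 and
  right-skewed; σ chosen once to give realistic scatter). 600 cells per
  domain by default.
- Marker onset table per domain for GM130/PAR3/PKCζ/ZO1/Ncad, encoding the
  observed orderings (e.g. PKCζ dorsal 40% first, lateral only at the
  border; ZO1 ventral post-budding, encoded 110%); delta amplitude 30
  intensity units over baseline 50, Gaussian noise σ = 5.
- Time lapse: biphasic advection (1 %/h before the 10 h breakpoint, 6 %/h
  after), one somite per 68 min, PSM shortening slowly, front-distance
  noise 3% of the concurrent PSM length, one frame per 20 min over 25 h.

Cells are 24-vertex ellipse polygons placed tangent to the surface band
(surface domains) or uniformly in the interior with random orientation
(core); this exercises moments, banding, sector assignment and fitting,
but none of the things real SEM data are hard for: touching/overlapping
outlines, out-of-focus cells, protrusions, irregular tissue boundaries, or
anatomy-dependent sector orientation. Green recovery tests therefore
establish the correctness of the computations, not robustness to tracing
quality. Everything is deterministic given the seed; same seed means
byte-identical output files.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| `microns_per_pixel` | 1.0 | outline calibration |
| `ar_method` | ellipse | AR estimator (or `feret`) |
| `surface_band_depth_px` | median minor axis | "one cell layer" depth |
| `sector_rotation_deg` | 0 | rotate transverse sectors |
| `medial_side` | left | side facing the neural tube |
| `intensity_stat` | mean | apical/basal summary (or `sum`) |
| fit `min_n`, `min_span` | 8, 30% | fit preconditions |
| breakpoint grid | observed timepoints | segmented-fit candidates |

## Degenerate inputs and tie-breaks

Malformed outlines (<3 vertices, self-intersecting, zero area) are
rejected per record with a logged reason, never silently dropped;
duplicate cell ids are rejected. Decreasing somite counts in a time-lapse
table are a hard error naming the row. Zero-RSS sigmoid fits give p = 0
unless the data were flat (then p = 1). Bin-edge values go to the lower
bin; sector-corner cells resolve dorsal > medial > ventral > lateral.
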