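# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `orgrowth`, in the spirit of a methods appendix. It
states no result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic recordings

**What is emulated.** Cystic organoids in brightfield appear as bright
luminal interiors surrounded by a darker epithelial rim. The generator
renders each organoid as a radially symmetric profile built from two erf
edge steps (lumen disk of radius r, rim of configurable thickness, default
5–6 µm), composited additively onto a uniform background, with:

- **Growth law** — luminal area A(t) = A(0)·exp(g(1 − η)t), with base rate
  g = ln(2.3)/48 h⁻¹ (an untreated culture grows 2.3× in area over 48 h)
  and per-condition inhibition η ∈ [0, 1]. Radii are deterministic given
  the initial draw: ground-truth log-areas are exactly linear in time, so
  closed-form recovery checks are exact. Initial radii are lognormal
  (median 20 µm, log-sd 0.12 by default).
- **Optics** — each organoid has a focal plane at one of the acquired z
  positions; the edge softness grows linearly with defocus
  (σ = 0.8 px + 0.03 px/µm·|Δz|). No other point-spread modeling.
- **Illumination and noise** — a multiplicative linear gradient of random
  orientation (default amplitude 8%) and additive Gaussian noise (default
  sd 300 counts on a 10 000-count background).
- **Acquisition geometry** — tiles are crops of one rendered mosaic scene at
  the nominal integer-pixel grid (pitch = tile·(1 − overlap), rounded).
  Overlapping tile regions therefore carry identical pixels, which makes
  "stitching reproduces the reference" an exact property. Independent
  per-tile noise or stage jitter are not simulated.
- **Dropout** — an organoid can be undetectable in a frame with fixed
  probability (omitted from rendering, flagged invisible in ground truth),
  to exercise the completeness filter.
- **Placement** — rejection sampling of centers, rejecting pairs closer
  than `placement_margin` (default 1.05) times the sum of projected *final*
  outer radii; infeasible densities raise an explicit packing error naming
  the fill factor.

**What is not emulated** (and hence what passing tests do not show about
real data): organoid fusion, collapse or morphological change; debris and
out-of-well artifacts; spatially varying focus drift; camera fixed-pattern
noise; realistic intensity statistics. The default contrast and noise were
chosen once so that segmentation operates in a realistic-but-comfortable
regime; they are synthetic conveniences, not measurements. One seeded
generator drives placement, focal planes, illumination orientation, noise
and dropout, so identical configs give bit-identical recordings.

## Preprocessing

Average-intensity z-projection is the default (max available); integer
inputs are accumulated in float64 and rounded back. Stitching refinement
maximizes the Pearson correlation of the shared overlap strip over integer
shifts within ± half the overlap; a degenerate strip (zero variance) falls
back to the nominal offset with a logged warning. Because areas, not
positions, are the readout, sub-pixel registration is deliberately omitted.
Offsets are estimated on the first frame and reused (the stage does not move
between frames); per-frame estimation is available by flag. Overlaps are
blended by linear feathering; with consistent overlap pixels any convex
blend is exact.

## Segmentation

Per frame: Gaussian smoothing (σ 2 px) → morphological gradient (disk
radius 2 px) → extended-minima markers → Meyer priority-flood watershed →
filtering. Extended minima are computed by morphological reconstruction
(by erosion, of gradient + h over gradient) followed by regional minima,
i.e. the definition of the h-minima transform, rather than a shortcut mask.

The watershed is implemented in the package (numba kernel) with fully
specified semantics: pixels are queued once, flooded in ascending
(gradient value, insertion order), neighbors visited in fixed raster order,
and pixels where two labels meet become watershed-line pixels (label 0)
that do not propagate. This pins down plateau and tie behavior exactly, so
a brute-force priority-flood oracle reproduces the labels pixel for pixel
on arbitrary fixtures; library watersheds leave these conventions
unspecified. skimage's watershed serves as an independent cross-check on
basins with well-defined boundaries.

Filtering: the background basin is identified as any region containing a
mosaic corner; border-touching regions are dropped by default; regions
below `min_area_um2` (default 500 µm²; 250 µm² in the scaled-down benchmark,
whose synthetic organoids are smaller than real ones) are removed; survivors
are relabeled 1..n by descending area (ties by topmost, then leftmost
centroid).

Defaults (σ = 2 px, radius = 2 px, h = 500 intensity counts, 4-connectivity)
were calibrated once on simulator fixtures so each lumen seeds exactly one
marker; downstream conclusions depend only on recovery tolerances, not on
these exact values. Segmenting on the gradient is one of two modes of the
morphological-segmentation tools this stage emulates; object-intensity mode
is not implemented.

**Known bias.** Watershed-line pixels are excluded from areas, so a region
loses a ≈1-px annulus at its boundary: a relative area bias of about
−2/R per pixel radius R (−15% at R ≈ 12 px, −2% at R ≈ 60 px). The bias is
shared by numerator and denominator of NPA and largely cancels in relative
sizes; the end-to-end benchmark recovers a 49% contrast at 47%.

## Morphometry

Area = pixel count · pixel size²; centroid = mean of pixel centers;
perimeter = 4-connected crack length (a 10×10 square has perimeter 40 px),
chosen for its exact hand-computable semantics; the estimator is pluggable
(`perimeter_fn`) since tools differ (e.g. Crofton-based estimators).
Circularity = 4πA/P² under the declared estimator; digital disks converge
to π²/16 ≈ 0.617, not 1.

## Tracking

Greedy one-to-one matching between each frame's regions and every open
track's most recent detected footprint, by descending IoU (computed on
pixels), gated by `min_iou` (default 0.3) and a maximum centroid shift
(default 50 µm); ties break by (higher IoU, smaller track id, smaller
label). Undetected tracks record MISSING entries but stay open and may
re-link later. When two tracks claim one region the higher-IoU track wins
and the loser goes MISSING — consistent with the conservative spirit of the
completeness rule, which excludes any track not detected in all frames (and
therefore every track born after frame 1). This linker is the package's
principal departure from the original manual identity bookkeeping it
replaces; it is a stand-in, not a reconstruction.

## Growth analysis

NPA normalization window: 5 frames (the first 2 h at 0.5 h intervals), per
the established protocol. Median across organoids uses the midpoint
convention for even counts. Relative sizes are integer percentages rounded
half away from zero, computed from full-precision final medians;
`relative_sizes` applied to already-rounded two-decimal display values can
therefore differ by one percentage point from tables computed before
display rounding (two such cells — 70 vs 71 and 75 vs 76 — are documented
in the tests rather than matched). Dose ratios (high vs low dose) and
signed differences vs 100 are emitted alongside.

## Statistics

- Shapiro–Wilk gate: nonparametric route at p < 0.05; constant data are an
  error (W undefined).
- Two-sample t: pooled variance by default (Welch selectable); zero pooled
  variance with equal means yields t = 0, p = 1, with unequal means a
  degenerate flag.
- Mann–Whitney U: exact null distribution when both n ≤ 8 (default) and no
  ties, else tie-corrected normal approximation with continuity correction.
  When applied to the two 97-point median NPA series, time points are
  treated as observations — reproducing the established procedure — and the
  serial-correlation caveat is recorded in the result metadata rather than
  "corrected".
- Kruskal–Wallis: tie-corrected H, χ² reference with k − 1 df; identical
  data give H = 0.
- Post-hoc "Bonferroni": interpreted as Dunn's pooled-rank z-test with
  Bonferroni multiplication (the behavior of mainstream statistical
  suites); plain pairwise Mann–Whitney is selectable. Adjusted p = min(1,
  m·raw) never falls below raw.
- Display: ***, **, * at p < 0.001, 0.01, 0.05.

MTS normalization divides by the untreated-control mean; Ki67 quantification
is percent positive per visual field, analyzed by Kruskal–Wallis + post-hoc.
Absolute biological effect sizes from patient-derived material (e.g. a
specific percent inhibition of Ki67) depend on the recordings and are not
reproduced by synthetic data; only the procedures are.

## Benchmark and problem sizes

The shipped recovery benchmark uses 256 × 256 px tiles (2 × 2, 15% overlap),
3 z-planes, the full 97 half-hour frames, and 42 organoids per condition
(inside the observed 41–139 per-culture range), with initial lumen radii
lognormal(median 15 µm, log-sd 0.12) and a 5 µm rim — a deliberately
reduced field so a full two-well experiment (simulation through statistics)
completes in about a minute on one CPU while keeping several hundred pixels
per organoid. The treated condition's η is derived from the target final
ratio: η = −ln(ratio)/ln(2.3).

## Determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; pipeline re-runs with the same config are
bit-identical, and stage manifests record parameters, seed and package
version (no timestamps) to make that checkable.
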