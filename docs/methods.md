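# Methods

## The measurement

The quantity of interest is, per nucleus, the Pearson correlation
coefficient *R* of raw pixel intensities between a query-protein
channel and a nucleolar-marker channel, evaluated over the pixels of
the nucleus mask only. *R* captures spatial coincidence of the two
signals: if the query protein concentrates in the same sub-nuclear
structure the marker labels, bright marker pixels are also bright query
pixels and *R* → 1; if the query is excluded from that structure (as
DNA counterstain is from nucleoli), *R* < 0. The statistic is invariant
to channel gain and offset, so it does not depend on illumination or
detector settings — but not to pixel *selection*, which is why three
policies are fixed throughout:

* **mask pixels only, never the bounding-box crop** — background pixels
  in the crop are dark in both channels and would manufacture positive
  correlation;
* **raw intensities** — no background subtraction, filtering or
  rescaling before the coefficient;
* **undefined is a value, not an error** — masks with fewer than
  `min_pixels` (default 20) pixels or zero variance in either channel
  yield an undefined coefficient with a machine-readable reason, and
  undefined cells are excluded listwise from group statistics with
  their counts reported.

Saturated pixels (at the bit-depth maximum) are retained, consistent
with the raw-data policy; their per-cell fraction is exported as a QC
column so heavily clipped cells can be audited downstream.

## Synthetic fields and what they emulate

`simgen` renders the statistical structure the analysis assumes: fields
of non-overlapping elliptical nuclei (semi-axes drawn from
`nucleus_axes_range`, default 14–22 px, with a smooth low-order radial
boundary jitter of 5%), each containing `nucleoli_per_nucleus` disks
(default 2) totalling a fraction `nucleolar_area_fraction` (default
0.12) of the nuclear area. Channels are piecewise constant plus noise,
on an 8-bit scale:

| channel | outside nucleus | nucleoplasm | nucleolus | default levels |
|---------|----------------|-------------|-----------|----------------|
| dapi    | background     | `dapi_level` | 40% of `dapi_level` | 8 / 180 / 72 |
| marker  | background     | `m0`        | `m1`      | 8 / 30 / 150 |
| query   | background     | `q0`        | `q0 + f·Δq` | 8 / 80 / 80+f·80 |
| pcna    | 0              | homogeneous or foci | — | 120 base, +110 foci |

DAPI is rendered at 40% (not zero) inside nucleoli so the negative
control is clearly negative without being an unrealistic −1. The
per-cell enrichment *f* ∈ [0, 1] is the simulator's ground-truth dial
for nucleolar localization. Bleed-through β adds β × (clean marker
signal) to the query *before* noise, so the two channels' noise stays
independent and crosstalk appears purely as shared structure; its
default is 0, matching sequential-illumination acquisition. Noise is
additive Gaussian per channel (default σ = 8 grey levels, a plausible
magnitude for 8-bit confocal data; the source study reports no noise
statistics, so this is a calibration-free choice), optionally preceded
by Poisson resampling; intensities are then rounded and clipped to the
bit range. A single seed drives named per-stage streams with
per-nucleus sub-streams, so outputs are bit-identical across runs.

Features of real data the generator deliberately omits: point-spread
blur, uneven illumination, autofluorescence gradients, partial-volume
edge pixels, nucleolar substructure (fibrillar centers vs granular
component), and touching/overlapping nuclei. Passing tests therefore
demonstrate correctness of the *computation* under the stated model,
not robustness to every acquisition artifact.

## The closed-form oracle

For a mask in which a fraction *p* of pixels (the nucleolus) raises the
query by Δq_eff = f·Δq and the marker by Δm, with independent additive
noise σ_q, σ_m, the population coefficient is

    R = p(1−p)·Δq_eff·Δm /
        sqrt[(p(1−p)·Δq_eff² + σ_q²) · (p(1−p)·Δm² + σ_m²)]

(the two-level indicator has variance p(1−p), and covariance only
arises through it). The implementation validates this form against
brute-force simulation of 10⁶ independent two-level noisy pixels, and
the empirical mean of per-cell coefficients is checked against it on a
3 × 3 grid of (f, σ) settings with ≥ 200 simulated cells per setting,
using each cell's *realized* nucleolar pixel fraction. In those
comparisons the oracle's σ includes the quantization variance 1/12
added by rounding to integer grey levels.

## Segmentation

The DAPI channel is binarized at a per-pixel Otsu threshold computed in
a sliding disk (`local_window_radius`, default 50 px). Pure local Otsu
is unstable wherever the window contains a single intensity class — in
background-only windows the histogram has no bimodality and the
"threshold" splits noise — so the local threshold is gated by the
global Otsu level of the whole image. Both thresholds are
histogram-relative, preserving invariance to constant intensity
offsets. Holes are filled *before* morphological opening (a dim
nucleolus near the nuclear rim would otherwise be turned from an
enclosed hole into a boundary bay by the opening), the mask is opened
with a 2 px disk and re-filled, and 8-connected components are filtered
on area (200–20 000 px²), solidity (≥ 0.85), eccentricity (≤ 0.95) and
border contact. The source analysis reports only that "size and shape
criteria" were applied; these cut-offs are this package's explicit,
config-exposed defaults, sized for nuclei of roughly 15–25 px radius.
Touching nuclei are not watershed-split: clusters fail the shape
filters and are excluded, which biases toward well-isolated cells
rather than corrupted masks.

## Phase classification

Replication foci are detected as white top-hat responses (disk radius
3 px) exceeding mean + 2 SD within the nucleus; connected responses
smaller than 4 px are ignored, and intensity peaks (minimum separation
2 px) are counted within the surviving blobs so that adjacent foci do
not merge into one count. The mid-S zone is the union of a peripheral
ring (width 15% of the equivalent nuclear radius) and an equally wide
dilation of the nucleolus submask. Rules: **mid_S** requires ≥ 5 foci
with ≥ 60% of them in the zone; **non_S** requires ≤ 2 foci and a
coefficient of variation ≤ 0.3; everything else is **discarded**,
mirroring the conventional exclusion of cells transitioning between
phases. All thresholds are explicit surrogates for what is normally a
manual call, and are config-exposed.

## Nucleolar call

Published "percent nucleolar-localized" figures rarely state an
operational rule. The rule here is explicit: the nucleolus submask is
the global-Otsu partition of the marker within the nucleus, and a cell
is called nucleolar-localized when mean query intensity inside the
submask is at least τ (default 1.5) times the mean over the remaining
nucleoplasm. Degenerate submasks (< `min_pixels` on either side) give
an undefined call.

## Statistics

Welch's unequal-variance *t* is the two-group default (the pooled
Student variant is available by flag) with two-sided p-values
throughout. Multi-group designs use one-way ANOVA followed by
Dunnett's many-to-one procedure (adjusted p-values from the
equicorrelated multivariate-t distribution, seeded for
reproducibility) or Tukey's HSD. Reported adjusted p-values are
clamped to be at least the raw per-contrast p (the procedures pool
variance across all groups, which with differing degrees of freedom
can otherwise nudge an adjusted value fractionally below the raw one).
Star annotations follow the usual figure-legend convention
(*, **, ***, **** for p ≤ 0.05, 0.01, 0.001, 0.0001). Both procedures'
type-I error is verified by null simulation (10 000 two-group
replicates; 5 000 four-group families) to lie in [0.04, 0.06] at
α = 0.05.

Cells, not fields, are the statistical unit, matching how n is usually
reported for this kind of imaging panel. This ignores field-level
nesting (pseudo-replication): cells within a field share illumination
and focus, so per-cell p-values are anti-conservative for
field-to-field effects. Hierarchical models are out of scope; treat
strongly significant per-cell p-values on few fields with caution.

## Validation problem sizes

The test suite exercises: oracle agreement on a 3 × 3 (f, σ) grid with
200 cells per setting; ordering of mean coefficients across five
enrichment levels with 200 cells each; segmentation on 512 × 512 fields
of 12 nuclei (noise-free exactness plus ten moderate-noise seeds);
phase classification on 60 nuclei per noise regime across ten seeds;
and the null-simulation calibrations above. Most unit tests run on
256 × 256 fields of 5–10 nuclei.

## Known limitations

* Two-level piecewise-constant truth is idealized; real nucleoli have
  internal structure and soft edges, which lower attainable *R*.
* No optics model: segmentation accuracy on simulated fields
  overstates accuracy on blurred, unevenly illuminated images.
* The nucleolar call depends on a marker-derived submask; a marker that
  itself delocalizes (e.g. after polymerase-I inhibition) degrades the
  submask, and the per-cell coefficient is then the more trustworthy
  readout.
* Phase thresholds were designed against the simulator's foci model;
  applying them to real PCNA images will likely require retuning
  `PhaseParams`.
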