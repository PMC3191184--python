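# Methods

This note records the models, conventions and numerical choices behind
`punctacoloc`, in the order data flows through the package.

## Image and ROI conventions

Pixel coordinates are 0-based with x = column and y = row; the centre of
pixel (row r, col c) is the point (c, r). A pixel belongs to a polygon ROI
when its centre is inside or on the boundary (boundary inclusive — the
semantics of a traced perimeter); to a polyline ROI when its centre is
within `line_width_px / 2` of the path (inclusive). ROI pixels are
enumerated row-major, so paired extractions from two channels are
positionally identical by construction. The polyline default width is 1 px
and is configurable, since the width of a hand-drawn "line ROI" is a
free choice of the analyst. Geometry predicates are delegated to shapely;
the test suite checks them against brute-force ray-casting and
point-to-segment-distance oracles.

## Preprocessing

The fixed order is: 16→8-bit conversion, then background subtraction; both
steps are optional and the coefficients can be run on raw images.

- **Bit-depth conversion** is a linear min–max rescale to [0, 255] with
  round-half-up; a constant image maps to all zeros. Min–max rescaling
  preserves intensity ordering, which is all the rank-free coefficients
  below need; it does change Mander's support only via the subsequent
  background threshold.
- **Background subtraction** estimates a threshold T = mean + k·SD from
  the pixels of a user-drawn background polygon and clamps
  `max(0, pixel − T)`, re-quantized to the integer range. The SD is the
  sample (n−1) SD — the contract is stated explicitly because plugin
  implementations differ. k defaults to 2.0; k = 0.5 is the documented
  setting for in situ hybridization images, whose diffuse probe signal
  would be erased by a 2-SD cut.

## Colocalization coefficients

All four coefficients are evaluated on the *same* pixel pairs, sharing N,
Ā and B̄, which are computed over the ROI only (the analysis is per
dendritic segment, not per field of view).

- Pearson's Rr is the standard product-moment correlation; a constant
  channel raises `ConstantChannelError` rather than silently returning 0.
- Mander's M1/M2 use the "> 0" support rule on background-subtracted
  intensities: subtraction is what defines "no signal", so no extra
  threshold parameter is introduced.
- ICQ counts strictly positive mean-centred products; a product of exactly
  0 (a pixel sitting at either channel mean) stays in the denominator but
  not the numerator. This makes the +0.5 / −0.5 endpoints exact for a
  channel paired with itself / its inversion whenever no pixel attains the
  mean.
- The PDM image stores (Aᵢ − Ā)(Bᵢ − B̄) on the ROI support; its sum equals
  N times the population covariance (an identity the tests assert). The
  displayed positive mask requires Aᵢ > Ā *and* Bᵢ > B̄, excluding the
  below-both-means pixels whose positive products merely reflect shared
  background.

**Zero-inflation sensitivity.** After background subtraction a sparse ROI
is dominated by (0, 0) pixels. These sit below both means, so their
products are positive and ICQ approaches +0.5 even for independent
channels — the very artifact the above-the-mean display rule exists to
avoid. Measured on sparse synthetic scenes with no co-positioning, ICQ is
≈ 0.44 after subtraction but 0.01 on the raw images. ICQ therefore
discriminates *changes* in co-positioning (it is monotone in the planted
fraction either way) but its absolute value on subtracted sparse images
should not be read against the "≈ 0 means random" yardstick; that reading
applies to ROIs whose pixels carry signal or independent noise in both
channels. All ROI pixels always enter N; no zero-pixel exclusion option is
offered, to keep the statistic's definition fixed.

## Cluster detection and % colocalized clusters

Clusters are particles of the thresholded protein channel: Otsu's
threshold computed within the ROI by default (an explicit numeric
threshold is accepted), 8-connected labeling, particles under
`min_area_px = 4` discarded. Neither the connectivity nor the minimum area
is canonical in the field's plugin lore, so both are parameters and are
recorded on the returned `ClusterSet`. Positive-PDM particles use the
positive mask directly as the binary image (threshold at 0), with an
optional Otsu cut on the positive PDM values for stricter definitions. A
cluster "contains correlated signal" when its pixel set overlaps ≥ 1 pixel
of any positive-PDM particle — pixel overlap rather than centroid
containment, the closest reading of counting clusters that contain
colocalized signal. The percentage is 100 × colocalized / total; an empty
cluster set is signaled, not returned as 0.

## Spine-location scoring

A centroid outside every traced total perimeter is `shaft`; inside a total
perimeter it is `head` or `base_neck` by the head polygon, or `all` for a
stubby spine with no traced head. `all` is kept as its own category rather
than split between head and base/neck, since the head and base/neck
fractions of real tracings need not sum to 1 and the residual is best left
explicit. The centroid rule (rather than any-pixel overlap) makes scoring
deterministic; overlapping tracings are resolved to the nearest perimeter
centroid with a warning. Scoring reads only geometry — never the protein
channel's intensities — mirroring the blinding of manual tracing to the
cluster channel. Summaries (density per µm, % spines occupied, category
fractions) are exact counts; there is no noise stage, and the tests demand
bit-exact recovery of planted plans.

## Synthetic scenes

The generator emulates two-channel immunofluorescence of dendrites:
cluster centres are a Poisson process along a dendrite polyline (default
0.67 clusters/µm, the observed density of overexpressed protein clusters
in CA1 dendrites) with uniform lateral jitter (±2 px); a fraction f of
channel-A clusters receives a channel-B partner offset uniformly on the
unit disc (≤ 1 px, sub-resolution); the remaining channel-B clusters are
an independent Poisson process of rate (1−f)·λ so both channels keep the
same expected density. Spots are isotropic 2-D Gaussians — the pre-blur
punctum (σ = radius/2) convolved with a Gaussian PSF (default σ = 1.3 px)
— rendered additively, then constant background, optional Poisson photon
noise, Gaussian read noise, clipping and round-half-up integer
quantization. Pixel size defaults to 0.11 µm/px, typical 60×/1.25 NA
sampling; no magnification calibration is modelled, so all µm-based
defaults are conventions surfaced in `SceneParams`.

What the generator does *not* emulate: spectral bleed-through, chromatic
offsets, 3-D defocus, uneven illumination, autofluorescent debris, or
clustered-on-structure backgrounds. Passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not robustness
to every real-microscope artifact.

Spine scenarios place mushroom spines (neck rectangle ∪ head disc, with a
slightly inset head polygon) and stubby spines (disc, no head) alternating
along a straight shaft, and plant cluster centroids to realize a requested
per-category plan exactly; every planted centroid is verified against the
classifier at generation time.

## Summary statistics

Confidence intervals are percentile bootstraps of the mean over individual
cells (dendrites are averaged within a cell first; resampling dendrites
directly is possible by passing them as observations). Percentile rather
than BCa is the simplest defensible method when only "bootstrapping" is
specified; `method="basic"` is available. Default 10,000 resamples, seed
mandatory in the result object. Percent colocalization across cultures is
summarized as the mean of per-culture means with SE = SD(culture means,
n−1)/√(#cultures); a single culture yields SE = NaN, printed "N/A".
Densitometry divides band by loading-control intensity per timepoint and
expresses the ratio as a percentage of the earliest timepoint, which is
100 by definition.

## Problem sizes used in the checks

The parameter-recovery suite uses sparse scenes chosen a priori: a 500 µm
straight dendrite (4545 px at 0.11 µm/px) at 0.03 clusters/µm (~15 per
channel per scene), amplitude 180 ± 20 on an 8-count background, PSF
σ = 1.2 px, 10 seeds per fraction f ∈ {0, 0.25, 0.5, 0.75, 1}. Sparsity
keeps chance juxtaposition of independent puncta — which is real signal
for this estimator, not an artifact — down to a few percent (a 1-D
encounter-rate estimate predicts ~3–7%, and the measured f = 0 baseline is
5.3%), so the estimate's response to f is isolated. The study-condition
default density (0.67/µm) is unchanged by this choice. Bootstrap coverage
is checked with 500 replicate datasets of n = 38 cells from N(0.63, 0.1²)
at 2,000 resamples per CI — enough replicates to resolve the 93–97% band
while keeping the whole suite around twenty seconds.

## Known limitations

- No Costes randomization or thresholded Mander's variants; no watershed
  splitting of touching clusters, so merged puncta undercount particles at
  high density.
- The ROI text schema is this package's own; ImageJ `.roi` binaries are
  not parsed.
- ICQ on background-subtracted sparse ROIs carries the zero-inflation bias
  described above; compare like with like.
- Whole-image (rather than per-ROI) coefficient mode simply means passing
  an image-spanning polygon; means are always taken over the analyzed
  region.
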