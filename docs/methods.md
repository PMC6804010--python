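# Methods

This note records the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic generator does and does
not emulate, and the known limitations.

## Image standardization

Exported three-channel rasters are reduced to one channel by per-pixel
summation in widened integers, then a linear rescale of [0, 765] onto
[0, 255] with round-half-up (exact integer arithmetic, so the operation
is invariant under channel permutation and never clips before the
rescale). Grids are row-major with the origin at the top-left pixel; the
physical position of pixel *(r, c)* is its center,
*((c + ½)·px, (r + ½)·px)* with *px* the pixel size in µm. Inputs deeper
than 8 bits are rejected rather than silently rescaled.

## IsoData thresholding

The intermeans map `T ← round((μ_{≤T} + μ_{>T})/2)` is computed on the
full 256-bin histogram (no extreme-bin exclusion) and iterated from the
midpoint of the occupied intensity range; half-integer means round toward
the smaller level, and after convergence the threshold descends through
any contiguous plateau of fixed points, so all ties resolve toward the
smaller T. On unimodal (noise-like) histograms every fixed point lies in
one plateau and the result equals the globally smallest fixed point,
which is the property the test suite checks by exhaustive search. The
globally smallest fixed point is deliberately **not** used as the
definition: when a histogram carries a large background mode and a small
bright population, a spurious fixed point exists inside the background
mode, and selecting it would split background noise instead of
separating the two phases. Midpoint initialization keeps the
between-modes solution, which is also what the interactive tools this
chain mirrors produce.

Foreground is *strictly greater than* the threshold. Connected
components use 8-connectivity (the particle-analysis default of those
tools). No minimum particle size is applied unless requested
(`min_size_um2`, default 0).

In the pipeline, a thresholded ion map whose foreground exceeds 25% of
the field is scored as having no distinct spots: that situation arises
exactly when the threshold fell inside a single intensity mode (e.g. a
channel with no aggregates at all), where "particles" would be noise
percolation artifacts. The same guard applies to the dark phase in
excavation detection.

## Surface metrics

*Entropy.* Intensities are normalized to [0, 1] and binned into 64 equal
widths Δ; the plug-in differential entropy is Ĥ = −Σ pᵢ ln(pᵢ/Δ) in
nats. The *deficit* is H_ref − Ĥ with H_ref = ½ln(2πeσ̂²), the maximum
entropy attainable at the image's variance; amorphous deposits push the
intensity distribution away from Gaussian and enlarge the deficit. Bin
count is a reported, configurable convention — absolute entropies are
estimator-specific and are compared only within a run. For genuinely
Gaussian images the deficit can be marginally negative (discretization
bias of order Δ²/24σ²).

*Roughness/waviness.* A Gaussian low-pass with 50% amplitude
transmission at the cutoff wavelength (σ = cutoff·√(ln 2 / 2)/π; cutoff
default 8 µm, above fibril diameters but below lattice wavelengths)
splits the intensity surface into waviness and a roughness residual:
Ra = mean |residual|, Rq = RMS residual, Wa = mean |waviness − mean|.
These are intensity-scale quantities (0–255), not nanometer topography.

*Periodicity.* The image is tiled into windows (default 12.5 µm, ≥3
expected periods); a window is periodic when its normalized
autocorrelation, sampled along 24 directions through the origin, shows a
secondary peak with prominence ≥ 0.3. The area fraction is the percent
of periodic windows.

*Excavations.* Dark blobs below the IsoData threshold with circularity
4πA/P² ≥ 0.5 are counted, normalized per 100×100 µm², with mean
equivalent radius and a *depth proxy* (background mean minus blob mean
intensity). Depth is never reported in nm: that would require calibrated
depth profiling, which exported images do not carry.

## Mixture discriminant analysis

Each pretreatment's feature distribution is a Gaussian mixture of R
subclasses (default R = 3, the customary default of MDA
implementations) sharing one covariance across all subclasses and
classes. With class labels known, EM reduces to per-class mixture
responsibilities (E-step) and weighted means/weights plus a pooled
covariance (M-step); the log-likelihood is non-decreasing and iteration
stops at a gain below 1e-8 or 500 iterations. Subclass means initialize
from within-class k-means seeded deterministically from the run seed. The
covariance always receives a ridge ε = 1e-6·trace(Σ)/q. When parameters
outnumber what the within-class scatter can support (p > n − K), the
data are first projected onto their principal subspace and the
projection is stored in the model; with R = 1 the model is exactly
linear discriminant analysis, which the tests exploit as an oracle. A
class with fewer rows than R gets one subclass per row.

*String and neighbor matrix.* Class centroids are whitened by the shared
covariance and projected on the principal axes of the between-class
scatter; the 1-D order along the first axis (ties by the second) is the
similarity string, canonicalized to the lexicographically smaller of
itself and its reverse. Each consecutive pair in the string receives a 1
in the binary neighbor matrix. With gating enabled, every treatment pair
is tested for centroid separation by a permutation test (999 label
permutations, α = 0.05) on leave-one-out nearest-centroid accuracy under
an inverse pooled-within-variance diagonal metric (shrunk by 1% of the
mean within-variance). Pairs that fail are merged: merged groups sit
contiguously in the string and only within-group neighbors receive a 1.
The diagonal metric is the p ≫ n analogue of the model's shared
covariance — training accuracy of a full refit is always 100% in that
regime and carries no information, and an unweighted distance is
dominated by uninformative columns. The pipeline runs the string, matrix,
tree and jackknife on the *ionic* feature block: the anatomical
parameters group the pretreatments along a different axis (loss of
periodicity pairs the alkali and steam treatments) and are reported
separately.

*Tree.* The element-wise mean of binary neighbor matrices is a
similarity S ∈ [0, 1]; the tree is average-linkage clustering of 1 − S.

*Jackknife.* For each parameter group (per-ion count/area/mean-size,
plus Li-on-OH coverage in the lithium group) the model is refitted
without the group and the importance is 100·(full − reduced)/full of the
discrimination score, with a misclassification-count variant reported
alongside. The score is training accuracy by default and stratified
5-fold cross-validated accuracy in the pipeline, where parameters
outnumber observations. The attribution share depends on this choice;
only ranks should be compared across settings.

## Saccharification curves

Replicate reducing-sugar series are smoothed with a penalized cubic
regression spline: uniform knots (default df = min(10, distinct times)),
second-order difference penalty (linear trends unpenalized, so exact
linear data are reproduced to numerical precision), smoothing parameter
by GCV over a 29-point log grid, pointwise standard errors from the
sandwich covariance at the chosen penalty.

Curve equality uses an extra-sum-of-squares F-test between a pooled
single-curve fit and separate per-curve fits on a *common unpenalized*
cubic B-spline basis (df = 8) over the overlap of the time ranges — a
nested linear model, so the test is exact under iid Gaussian noise; its
measured type-I error is 4–5% at α = 0.05. Treatments are partitioned
into connected components of the pairwise "statistically same" relation.
Fold changes are ratios of the smoothed curves at 10 h (the assay's
reporting interval). A post-10 h decay is flagged when the smoothed
derivative is negative over a contiguous ≥20% span of (10 h, 48 h].

The ion-in-solution table (salts × enzymes, control = 100%) is ingested
and summarized as activator (>100) / inhibitor (<100) flags only; no
kinetic modeling is attempted.

## The synthetic generator

The generator produces the *structure* of the study with known ground
truth; it does not simulate mass spectra, sputter physics, or 3-D depth.

*Ion maps.* Aggregates are non-overlapping discs (Gaussian edge blur
σ = 0.5 px, additive Gaussian intensity noise, default background 30,
foreground 200 on a 256² grid for a 100 µm field) placed by one of three
point processes: homogeneous random, Thomas-process clusters, or
`fibril_periodic` — aggregates strung along parallel, gently sinusoidal
ridges whose spacing is the planted period (recoverable by FFT). Dense
cluster recipes spill over to uniform placement before raising a
placement error. Co-location pairs render the ion exactly on the
distance-transform cores of the site foreground, so a requested coverage
fraction is planted to pixel precision.

*Treatment suite.* Five pretreatments × (8 ion channels + –OH + a
carbohydrate-texture channel). Lithium carries the discriminating
signal: planted counts follow the reference particle table
(353/320/88/63/16 per 100×100 µm² for control / organosolv / steam /
microwave / alkali), radii follow the table's mean aggregate sizes,
placement is fibril-periodic where fibrils are intact (control,
organosolv), random after steam/microwave, clustered after alkali, and
the probability of seeding a Li disc on an –OH site is higher for
control/organosolv (coverage ordering). The other metal/anion channels
are treatment-independent background chemistry — their only structure is
placement noise — with two qualitative exceptions stated by the study:
the alkali pretreatment enriches Na and F 1.73-fold, and the DDA
fragment is absent from the untreated control. The texture channel
carries striped (periodic) ordering over the planted fraction of the
field (1.0/0.90/0.47/0.972/0.087) and, for microwave:acid only, 72
circular pits of radius 0.72 µm per field. Replicate observations are
16 tiles of 25×25 µm² per treatment — the instrument's smallest analysis
field — which gives the permutation gate usable resolution (4 quadrants
leave the smallest attainable p-values too coarse).

*Curves.* Without decay, release is Michaelis-type saturating
(plateau 6 mg/mL, half-saturation 6 h); with decay, a smooth gamma-type
pulse peaking exactly at 10 h. Both take the value fold × control(10 h)
at 10 h, so planted folds are exact there by construction; the study
recipes plant 2.04 (alkali), 1.74 (steam, microwave), 0.9 (organosolv,
with decay; the reported "1.1-fold decrease" is encoded as ratio 0.9)
and decay for control and organosolv, with three replicates of iid
Gaussian noise (σ = 0.15 mg/mL) on a 2 h grid over 0–48 h.

What passing tests show: that every stage recovers *planted* truth under
these conditions — thresholds, counts, coverage, periods, fold effects,
the Li-driven cluster structure. What they do not show: robustness to
real ToF-SIMS artifacts (topographic shading, detector saturation,
charging, overlapping isobaric fragments), to touching aggregates
(no watershed splitting), or to non-Gaussian assay noise. Because
pairwise gating runs at α = 0.05, a minority of generator seeds split
the control/organosolv pair; that is the expected operating
characteristic of the test, not a failure of recovery.

## Reproducibility

Every random draw descends from one integer seed through spawn-key
stream splitting, so a fixed seed gives bit-identical images, features
and reports; every output table embeds the seed and a hash of the run
configuration in a header comment.

## Known limitations

- Absolute entropy values depend on the binning convention and are not
  comparable across estimators; only within-run contrasts are meaningful.
- Excavation depth is an intensity proxy, never a length.
- The jackknife attribution share depends on the chosen score
  functional; ranks are the robust output.
- The neighbor-matrix construction encodes only adjacency (row sums
  ≤ 2); gradations of similarity enter through averaging matrices across
  analyses, not within one.
- No vendor raw formats (ITM/ITA); the chain starts from exported 8-bit
  images, as the analysis it reproduces did.
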