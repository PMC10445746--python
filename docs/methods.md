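# Methods notes

This note records the models, parameter choices and numerical conventions
behind each analysis stage, the assumptions the synthetic-data generators
make, and what the validation studies do and do not demonstrate.

## Image primitives

**Calibration.** Every spatial operation converts µm to pixels through the
image's `pixel_size_um`, with round-half-up and a minimum of 1 px, so
results are bit-reproducible for a given calibration. The default pixel
size of 0.1 µm/px is typical of a 100×/1.47 TIRF system with an sCMOS
camera.

**Background correction** subtracts a scalar offset and clips at zero
(downstream entropy thresholding assumes non-negative intensities).
With a cell mask, the offset defaults to the *median* of the extracellular
pixels: under the camera model (noise-free electronic offset + Gaussian
read noise outside the cell) the median is unbiased and robust to hot
pixels, whereas an extreme lower-order statistic such as the 1st percentile
underestimates the offset by ≈ 2.3 read-noise standard deviations, a bias
that propagates directly into depletion residuals. Without a mask the 1st
percentile of the full frame is used, since the lower tail then best
approximates the dark level. A constant mode covers traces without imagery.

**Median filtering** uses a disk structuring element and edge replication.
Replication avoids the dark rim a zero pad would produce, which the
high-pass difference step would otherwise turn into spurious bright borders.

**Cell segmentation** (Otsu on a lightly smoothed copy, largest component,
holes filled) is deliberately simple: the TIRF footprint of a single
adherent cell is high-contrast, and the analyses only need a consistent
footprint to normalize against. Multi-cell fields are out of scope.

**Line profiles** sample at 1 px spacing with bilinear interpolation;
positions are arc length in µm. Mean normalization makes profiles from
different channels comparable regardless of gain.

## Cluster sectioning

The difference image D = max(I − median_r(I), 0) isolates structures
smaller than the 0.9 µm filter radius as positive excursions. Before
filtering, extracellular pixels are replaced by the within-cell median so
the dark surround does not drag the local median down at the cell edge;
without this fill, a noise-free uniform membrane would grow a spurious
bright rim and edge clusters.

D restricted to the cell footprint is histogrammed into 256 equal bins over
[0, max(D)] and thresholded by Rényi entropy. "Local" thresholding is
interpreted as per-cell (one histogram per cell footprint) — the natural
reading for single-cell TIRF fields, avoiding tile seams.

The threshold selects t maximizing H^α_b(t) + H^α_f(t). Two points that
matter numerically:

- Suffix sums (foreground class) are computed by reversed cumulative sums.
  Computing them as `total − cumsum` cancels catastrophically in sparse
  histogram tails and can hand `argmax` a NaN.
- Ties are broken toward the lowest maximizing bin. On histograms whose
  two classes are far apart the objective can be flat across the whole
  inter-class region to ~1e-10; any bin within the plateau is an equally
  valid separation, and tests assert separation rather than an exact bin.

The default `sahoo_combined` method computes the α = 1/2, 1, 2 thresholds,
sorts them, and combines them with the cumulative-probability β-weight rule
of Sahoo, Wilkins & Yeager (1997) (β triples (1,2,1), (0,1,3), (3,1,0),
(1,2,1) selected by whether adjacent sorted thresholds differ by ≤ 5 gray
levels) — the same rule as the widely used ImageJ auto-threshold
implementation. `single_alpha` (default α → 1, the Shannon maximum-entropy
criterion) is kept as a simpler audited fallback.

Components smaller than 4 px at 8-connectivity are discarded (single-pixel
shot noise). Coverage is cluster pixels / cell pixels; density is cluster
count / cell area (cell-mask area, not the full imaged field). Time-series
aggregation averages per-frame metrics over the first 10 frames and reports
the across-frame s.e.m.; the per-cell mean is the unit that should enter any
cross-cell statistics. A flat difference image yields an empty cluster map
with a warning, not an error.

The bulk-membrane mask keeps cell pixels whose Euclidean distance to the
nearest cluster pixel is ≥ 1.8 µm. Note that at the reference cluster
density (0.66 µm⁻²) *no* pixel is that far from a cluster; a bulk region at
this exclusion distance only exists in sparsely clustered cells, which is
why the depletion-scene generator defaults to a sparser condition (below).

## Colocalization

Pearson's coefficient is computed over the masked pixel pairs without any
intensity thresholding — the plain whole-mask coefficient. Thresholded
variants (and Manders/Costes analyses) are intentionally out of scope. The
mask for two-channel work is the intersection of the per-channel footprints
(pixels informative in both channels). A minimum of 16 masked pixels is
enforced; constant channels make the correlation undefined and raise.

The membrane index finds the two highest marker-profile maxima separated by
≥ 25% of the profile length (peak prominence ≥ 20% of the dynamic range),
averages the reporter at those positions ±1 sample, and divides by the mean
reporter intensity over the central 50% of the inter-peak span.

## Kinetics

FRAP fitting normalizes to the pre-bleach mean and fits
F(t) = f∞ − (f∞ − f0) e^{−t/τ} to the post-bleach samples by least squares
(initialization: f0 from the first post-bleach sample, f∞ from the last 10%
of samples, τ from the half-recovery time / ln 2; bounds keep all
parameters positive). Mobile fraction = (f∞ − f0)/(1 − f0), clamped to
[0, 1] with the raw value kept in metadata. τ outside
(frame interval / 10, 100 × trace duration) is reported as unidentifiable;
a flat post-bleach trace yields mobile fraction 0 with the unidentifiable
flag instead of an error. No acquisition-bleaching correction is applied by
default; an optional reference trace divides it out. This is a reaction-
dominant single-exponential description — diffusion-model FRAP
(Soumpasis/Axelrod) is out of scope.

Depletion analysis expects a background-corrected stack, averages intensity
per frame inside the cluster and bulk masks, normalizes each trace to its
pre-activation baseline, and reports the mean over the last 3 frames
(≈ 12 s at the 4 s cadence) of the activation period — near steady state
while still averaging noise.

## Binding-trajectory statistics

"Integration of the distance population up to a cutoff" is implemented as
direct frame counting (fraction of frames with distance ≤ cutoff), which is
exactly the integral of the normalized histogram without binning artifacts.
Default cutoffs: 2.25 nm (tubbyCT), 2.0 nm (PLCδ1 PH). Histograms are
density-normalized with right-open bins (default width 0.05 nm).

The compartment-B population per replica is n_B / (n_A + n_B) from the
paired bound counts; frames bound to neither compartment are excluded
(simultaneous binding to both leaflets is sterically excluded, so counts
are disjoint). For a symmetric setup (both leaflets at the same lipid
concentration) the replica value is replaced by the average of the two
leaflet populations. Replicas with no bound frames are dropped with a
warning; the replica mean ± s.e.m. is reported (3 replicas is the typical
design).

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed); a single seed fans
out to child seeds via `numpy.random.SeedSequence.generate_state`.

**TIRF scenes** place non-overlapping disk clusters uniformly inside an
elliptical cell (semi-axes 18 × 13 µm ≈ 735 µm², of the order of a spread
CHO footprint), identical across frames (clusters are immobile on the
minutes time scale), on a uniform membrane with a linear illumination tilt
(±5%). Defaults realize the reference condition: density 0.66 µm⁻² and
coverage 10.5%, giving r = √(c/(π·d)) ≈ 0.225 µm; the stated cluster radius
is the root-mean-square of the lognormal radius distribution so expected
coverage is exact regardless of spread. Disk edges keep a ≥ 2 px gap so
rasterized components never merge at 8-connectivity. Intensities follow the
standard camera model — Poisson shot noise on the signal, noise-free
electronic offset (100 counts), Gaussian read noise (σ = 2) — with bulk
membrane at 250 counts and 2× cluster enrichment, i.e. cluster SNR ≈ 11.
Not modeled: the optical PSF and evanescent-field depth, membrane
topography, cluster substructure, intensity variation between clusters, and
cell-edge ruffling. Recovery tolerances achieved on these scenes therefore
bound algorithmic error, not total error on real data, where PSF blur and
heterogeneous enrichment will loosen them.

**Colocalization pairs** mix two standardized Gaussian fields
(B ∝ ρ·z₁ + √(1−ρ²)·z₂) and map them affinely to positive intensity ranges,
so the expected sample Pearson equals ρ exactly. Real image pairs have
spatial autocorrelation, which widens the sampling distribution of r at
fixed pixel count but does not bias it.

**FRAP traces** follow the monoexponential model exactly, plus white
Gaussian noise, at the 0.1 s cadence typical of such experiments; the
generator and the fit share the model by construction, so these tests
verify estimator correctness and noise robustness, not model adequacy.

**Depletion stacks** decay cluster and bulk intensities exponentially
(τ = 6 s) from baseline to distinct residuals after onset, at the 4 s
imaging cadence with a 60 s activation window. The default scene uses
0.08 clusters/µm² with 0.4 µm radii so that a 1.8 µm-exclusion bulk region
exists (see above).

**Distance trajectories** are two-state Markov chains: bound frames draw
from a truncated normal (1.5 ± 0.15 nm, well below the cutoff), unbound
frames from a uniform band (3–6 nm, well above). The initial state is drawn
from the stationary distribution p_ub/(p_ub + p_bu), so the expected bound
fraction is stationary at every length. Successive frames are correlated
(decorrelation factor 1 − p_ub − p_bu), which the tolerance of any
finite-length test must account for. Not modeled: the continuous approach/
departure kinetics visible in real distance histograms between the modes.

## Validation study sizes

The recovery studies use 20 scenes (512×512 px, 10 frames each) for
coverage/density, 10 pairs (512×512) for Pearson recovery, 50 traces per τ
∈ {0.5, 2, 8} s for FRAP, and 10⁴-frame trajectories for binding
statistics; these sizes put the sampling error of each study well below the
tolerance it asserts.

## Known limitations

- Per-cell (not tiled) thresholding assumes roughly uniform illumination
  across the footprint after background correction; strong vignetting would
  call for the tiled variant, which is not implemented.
- The sectioning algorithm cannot separate clusters closer than the
  rasterization gap; merged adjacent domains count as one.
- Density normalization uses cell-mask area; if a different footprint
  definition is used upstream, densities shift proportionally.
- `mobile_fraction` is undefined when the post-bleach start exceeds the
  baseline (f0 ≥ 1); the raw value is preserved in fit metadata.
- The trajectory analysis assumes distances are pre-extracted; parsing
  binary trajectory formats is out of scope.
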