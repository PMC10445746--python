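# pmdomains

Quantitative analysis of plasma-membrane (PM) microdomains from live-cell
fluorescence microscopy, plus the post-processing statistics for
membrane-binding simulation trajectories.

Lipid biosensors such as the tubby C-terminal domain (tubbyCT) segregate
into micrometer-scale clusters at ER–PM contact sites when imaged by TIRF
microscopy. Quantifying that behavior requires a reproducible chain of
measurements: detecting the clusters, measuring how much of the cell they
cover, asking which markers they colocalize with, how mobile the protein is
inside versus outside them (FRAP), how tightly it stays bound when its lipid
ligand is acutely depleted, and — on the simulation side — how often a
protein's lipid-binding pocket sits on the membrane. This package implements
that chain as a tested library with a thin CLI, together with seeded
synthetic-data generators that provide exact ground truth for every stage.

## Methods at a glance

- **Cluster sectioning.** A background-corrected frame is median-filtered
  with a disk of physical radius r = 0.9 µm and subtracted from itself; the
  positive difference image is thresholded by maximizing the summed
  background/foreground **Rényi entropies**
  H^α_b(t) + H^α_f(t), with H^α = (1/(1−α)) ln Σ (p_i/P)^α
  (α → 1 gives the Shannon maximum-entropy criterion). The default combines
  the α = 1/2, 1, 2 thresholds with the Sahoo–Wilkins–Yeager β-weight rule.
  Connected components ≥ 4 px become cluster ROIs; coverage (cluster
  pixels / cell pixels), density (clusters / µm² of cell area) and mean
  cluster area are aggregated over the first 10 frames of a time series.
  Bulk (non-clustered) membrane is everything ≥ 1.8 µm from any cluster.
- **Colocalization.** Pixel-wise Pearson correlation over the cell mask, no
  intensity thresholding; paired mean-normalized line profiles; and a
  membrane/cytosol localization index from wide-field line profiles.
- **Kinetics.** FRAP traces are normalized to the pre-bleach mean and fit
  with F(t) = f∞ − (f∞ − f0)·exp(−t/τ); the mobile fraction is
  (f∞ − f0)/(1 − f0). Depletion responses report the residual normalized
  intensity in cluster vs bulk regions over the final activation window.
- **Binding trajectories.** The membrane-bound fraction is the fraction of
  frames with pocket-to-PO4-plane distance ≤ 2.25 nm (tubbyCT; 2.0 nm for
  the PLCδ1 PH domain), and the compartment-B population is
  P_B = bound_B / (bound_A + bound_B), averaged over replicas.

## Worked example

```python
import pmdomains as pm

spec = pm.SceneSpec(seed=1)  # CHO-like footprint: 10.5% coverage, 0.66/µm²
stack, cell, truth = pm.synth_tirf_scene(spec)
frame = pm.background_correct(stack.frames[0], cell=cell)
clusters = pm.detect_clusters(frame, cell)
m = pm.cluster_metrics(clusters)
print(f"truth:    coverage {truth.coverage_fraction:.3f}, density {truth.density_per_um2:.3f} /um^2")
print(f"detected: coverage {m.coverage_fraction:.3f}, density {m.density_per_um2:.3f} /um^2, "
      f"{m.n_clusters} clusters, mean area {m.mean_cluster_area_um2:.3f} um^2")

fit = pm.fit_frap(pm.synth_frap_trace(tau_s=2.0, mobile_fraction=0.8, f0=0.2, sigma=0.01, seed=1))
print(f"FRAP: tau = {fit.tau_s:.2f} s, mobile fraction = {fit.mobile_fraction:.2f}")

a, b, mask = pm.synth_coloc_pair(rho=0.3, seed=1)
print(f"Pearson r = {pm.pearson_coefficient(a, b, mask).pearson_r:.3f}")
```

Output:

```
truth:    coverage 0.103, density 0.660 /um^2
detected: coverage 0.105, density 0.660 /um^2, 485 clusters, mean area 0.158 um^2
FRAP: tau = 2.01 s, mobile fraction = 0.80
Pearson r = 0.302
```

The generated scene places 485 non-overlapping clusters in a ~735 µm²
elliptical cell; the sectioning pipeline recovers the realized coverage to
within a few percent and the density almost exactly. The FRAP fit recovers
the generating time constant and mobile fraction, and the measured Pearson
coefficient matches the mixing coefficient of the two-channel generator.

## Command line

Subcommands over the same library: `pmdomains detect-clusters`,
`pmdomains coloc`, `pmdomains frap-fit`, `pmdomains depletion`,
`pmdomains md-bound` and `pmdomains simulate` (synthetic data with a
`truth.json` manifest). Each writes CSV tables, TIFF masks/labels and a JSON
manifest carrying the config hash and seed. See `pmdomains --help`.

## Layout

- `src/pmdomains/imaging.py` — calibrated image primitives
- `src/pmdomains/sectioning.py` — cluster detection and metrics
- `src/pmdomains/coloc.py` — Pearson / line profiles / membrane index
- `src/pmdomains/kinetics.py` — FRAP and depletion kinetics
- `src/pmdomains/mdbinding.py` — trajectory binding statistics
- `src/pmdomains/synth.py` — seeded ground-truth generators
- `src/pmdomains/workflows.py` — end-to-end pipelines
- `src/pmdomains/io.py`, `cli.py` — formats, config, CLI
- `docs/methods.md` — modeling choices, parameters and limitations
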