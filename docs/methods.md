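# Methods

`cytotomo` implements, end to end, a label-free single-cell
classification pipeline for tomographic phase imaging flow cytometry
(TPI-FC): cells flowing through a microfluidic channel rotate under the
shear of the laminar flow, a holographic microscope records a quantitative
phase map (QPM) of each cell at hundreds of rolling angles, the 3D
refractive-index (RI) tomogram is reconstructed by filtered back
projection, and a hierarchical machine-learning classifier decides first
whether a cell is a monocyte-like white blood cell (MC) or a tumor cell,
and then whether a tumor cell is neuroblastoma-like (NB) or
ovarian-cancer-like (OC). Because no real tomographic recordings ship
with the package, every experiment runs on synthetic phantoms whose class
structure emulates the biophysical contrasts the method exploits.

## Optical model and geometry

Axes are fixed throughout: `z` is the optical axis (the projection
direction), `y` the flow direction, `x` the rotation axis. The medium RI
is n₀ = 1.334, the wavelength λ = 0.532 µm, and the object-space sampling
0.1125 µm/voxel (a 4.5 µm camera pitch behind a 40× objective); the paper
never states the tomogram's metric pitch, so this derived value is the
package default. Tomograms are cubes, 201³ voxels by default.

The forward model is the straight-ray approximation:

    φ_θ(x, y) = (2π/λ) Σ_z Δn_θ(x, y, z) · pitch,

with Δn = n − n₀ ≥ 0 the RI contrast and Δn_θ the volume rotated by the
rolling angle θ about x (trilinear interpolation, rotation about the
exact volume center). Diffraction is deliberately ignored: the 2D
baseline uses the same straight-ray model, and the filtered
back-projection inverse assumes it. Consequences: phase scales linearly
with Δn, and Σφ·pitch² = (2π/λ)·ΣΔn·pitch³ at every angle — both are
regression-tested conservation laws.

## Phantoms

A phantom is an ellipsoidal cell body (semi-axes r_eq·(a₁,a₂,a₃) with
unit geometric mean, so r_eq is the equal-volume sphere radius) holding

* a concentric nucleus occupying a volume fraction f (linear scale
  f^{1/3}) with an RI offset,
* a few spherical inclusions (organelle-scale RI peaks) at uniform
  positions within 80 % of the body,
* a Gaussian random field band-limited to a correlation length ℓ,
  scaled to a chosen amplitude and clipped so Δn stays ≥ 10 % of the
  cytoplasm contrast.

Δn is exactly 0 off the support and strictly positive on it — the regime
every augmentation bound relies on — and capped at 0.12 RIU
(physiological ceiling).

Class-conditional defaults encode only the orderings the study reports,
not absolute histograms (no per-class numerical summaries are published):
MC are nearly spherical (axis ratios ∈ [0.94, 1.06]) while NB/OC are
elongated (major ratio up to 1.55), placing the tumor sphericity
distribution left of MC; OC mean contrast (0.026 ± 0.0015) sits right of
NB (0.019 ± 0.0015) with MC between (0.022); texture amplitude and
correlation length differ per class (MC weak/medium, NB strong/short,
OC strongest/long), separating the co-occurrence statistics. Radii
(4.2–5.8 µm) are cell-line-plausible for monocytes and tumor lines. A
single `radius_scale` knob shrinks all linear parameters together for
smaller grids without touching the separations.

What the generator does *not* emulate: real intracellular organization
(nucleoli, membranes), flow-induced deformation, reconstruction artifacts
of real data (limited-angle streaks, phase-unwrapping errors), or
biological overlap between classes. Passing benchmarks therefore
demonstrate the pipeline's correctness and its sensitivity to the encoded
contrasts — not clinical performance.

## Tomographic reconstruction

Rolling angles are unknown in flow; the package estimates them under the
quasi-uniform-rotation assumption. The period T is the lag (≥ `t_min`,
default 30 frames) at which the Pearson similarity between frame 0 and
frame k returns to its maximum; angles are θ_k = 360·k/T. Numerical
choices that matter: the half-turn frame is the mirror image of frame 0
and can correlate above 0.99 for nearly symmetric cells, so the detector
takes the *global* similarity maximum (earliest among numerical ties)
rather than the first local peak, and requires it to exceed 0.995; a
sequence whose similarity never leaves 1 (a spherically symmetric cell
produces identical frames) is rejected as having no rotation signature.
Over 20 seeded phantoms with angular speeds drawn in [2°, 6°]/frame the
period is recovered exactly in ≥ 18 (regression-tested). This uniform
estimator is an explicit simplification of full holographic-tracking
angle recovery, which needs the microfluidic velocity model.

Reconstruction is classical slice-wise FBP: for each x-slice the QPM rows
(rescaled by λ/2π·pitch to line integrals of Δn) form a sinogram over
angles, inverted with a Ram-Lak (ramp) filter and linear back-projection
interpolation (`skimage.transform.iradon`); angles are wrapped to
[0, 360) and duplicates averaged; negative excursions are clipped since
Δn ≥ 0 by construction. On a homogeneous Δn = 0.02 sphere sampled at 180
angles the median reconstructed RI over the eroded support is within
5×10⁻⁴ of truth, and voxel RMSE inside textured cells is < 2×10⁻³ RIU.

Support segmentation thresholds Δn > α·max Δn with α = 0.1 (config
knob), keeps the largest connected component, fills holes and applies one
binary closing. Published isolevels of 0.6/0.75·max are display choices,
far too aggressive for support extraction.

## 3D data augmentation

Three successive operations per training tomogram, with parameters drawn
per copy: intensity scaling (Δn × a, a ~ U(0.9, 1.1)), intensity
shifting (Δn + b on the support, b ~ U(−min Δn⁽¹⁾/2, +min Δn⁽¹⁾/2) — the
bound uses the *post-scaling* minimum, so positivity is guaranteed), and
morphological alteration (the volume resampled to (L+cₓ)×(L+c_y)×(L+c_z),
c ~ U{−20..20}, cubic interpolation, intensities not rescaled, background
clamped back to n₀ to kill ringing). The resample is computed on the
support's neighborhood and re-embedded — the field is exactly zero
elsewhere, so this equals the full-grid resize on the support up to
sub-voxel placement. "9× augmented" means 9 new copies plus the retained
original (200 originals → 2000 records), matching the published counts;
multiplicities are 9/3/3 for MC/NB/OC and the test split is never
augmented.

## Features (44 per cell, 3D and 2D flavors)

* 11 intensity statistics over the support: mean, median, mode, max,
  std, skewness, entropy (bits), excess kurtosis, 0.25/0.75 quantiles,
  dry mass. Dry mass uses the specific refraction increment
  α = 0.19 mL/g (the standard protein value; config knob):
  m = (1/α)ΣΔn·pitch³ in picograms, and in 2D
  m = λ/(2πα)·Σφ·pitch². Statistics are support-only (the Δn = 0
  background would otherwise dominate). Constant distributions use the
  conventions std = skew = excess kurtosis = entropy = 0. Mode and
  entropy come from a 32-bin min–max histogram.
* 9 morphology values. 3D: volume, convex volume (voxels inside the
  support's convex hull, the regionprops convention — a hull of voxel
  centers alone pushes solidity above 1), sphericity
  π^{1/3}(6V)^{2/3}/A with the surface area from marching cubes on a
  lightly smoothed mask (σ = 1.2 voxels; a raw binary surface inflates
  the area ≈ 8 % by staircasing), extent, solidity, three principal-axis
  lengths 2√5·√eig(cov) (solid-ellipsoid moment equivalence), and the
  centroid-to-RI-weighted-centroid distance normalized by the equivalent
  radius. 2D: area, extent, solidity, circularity 4πA/P² with P the
  contour length of the smoothed mask (the 2D analogue of the smoothed
  surface; pixel-count perimeter estimators miss either the disk or the
  square closed form by > 3 %), eccentricity, max/min Feret diameters
  (hull diameter / rotating calipers), major-axis length 4√λ₁, and the
  normalized centroids' distance.
* 24 texture values: gray levels from min–max quantization over the
  support into P = 32 bins (affine-invariant); symmetric co-occurrence
  matrices over the 13 unique 3D directions (4 in 2D) at offsets of
  0.5 µm and 1 µm (rounded to voxels: 4 and 9 at the 0.1125 µm pitch,
  which the scaled benchmark keeps); 12 Haralick statistics per matrix,
  averaged over directions per distance. "Contrast" and "inertia" are
  both listed in the canonical feature set though their standard
  formulas coincide — the duplicated column is kept under both names so
  the vector keeps its stated length and naming. Every formula is
  regression-tested to 1e-12 against brute-force enumeration.

## Hierarchical classification

Stage A separates MC from tumor on all cells; stage B separates NB from
OC and sees only cells stage A routed to it, so stage-A errors propagate
and the hierarchical MC recall equals stage-A MC recall exactly (asserted
on every evaluation). For 3D features both stages are shallow networks —
44 inputs, one ReLU hidden layer (100 nodes for A, 10 for B), sigmoid
output, threshold 0.5 with ties positive — with z-score standardization
frozen at fit time. The 2D baseline replaces the stages with logistic
regression (A) and a linear discriminant (B), sharing all other code.

Training protocol: Adam on cross-entropy, learning rate 0.01, stopping
when the training loss plateaus (tol 1e-4 over 10 epochs, at most 500).
Early stopping on a held-out validation *score* was evaluated and
rejected: at these per-stage sample sizes the validation accuracy
saturates within a few epochs and freezes the optimizer long before the
loss converges (measured 95.8 % training accuracy on trivially separable
data). All fits are seeded and deterministic.

## Metrics

Rows of a confusion matrix are true classes. The report carries accuracy,
recall/TPR, specificity/TNR, precision/PPV, NPV, balanced accuracy, F1,
Matthews correlation (×100) and the Fowlkes–Mallows index, each as a
percentage rounded half-up to one decimal (0.9375 → 93.8; banker's
rounding would print 93.7). N-class matrices report overall accuracy
(trace/total) plus one-vs-rest statistics per class. Zero-denominator
statistics are reported as undefined with a reason, never silently 0.
`cm_from_recalls` reconstructs the unique binary matrix consistent with
printed recalls and class sizes (TP = recall·n/100 rounded half away from
zero, residual off-diagonal) — the bridge between published per-class
rates and full metric tables.

## Benchmark problem sizes

The default release-gate benchmark (`pipeline.benchmark_config`, also run
by `scripts/acceptance.py`) keeps the study's structure — class
separations, 9×/3×/3× augmentation, the 47/122/60 test split — with the
phantom geometry scaled by half onto a 100³ grid and the training
originals reduced to 30/40/40 (→ 300/160/160 training rows after
augmentation). These sizes keep one full run in the minutes range on a
single core; the full-size configuration (201³, 200/250/250 →
2000/1000/1000) is the `ExperimentConfig` default for users with the
hours to spend. The pipeline streams cell by cell, so peak memory is a
few volumes regardless of dataset size.

## Known limitations

* The straight-ray model ignores diffraction; strongly scattering or
  large cells would need Rytov/Born diffraction tomography.
* The uniform-rotation angle estimator assumes quasi-constant angular
  speed over one turn and a full turn present in the sequence.
* The holography layer handles clean synthetic interferograms
  (hard circular band-pass, no aberration compensation, no windowed
  Fourier denoising); real holograms need the cited preprocessing.
* Synthetic class separations are generous by construction; benchmark
  accuracies say nothing about real cell lines.
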