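# Methods

`sinuct` is a desk-scale re-creation of a synchrotron imaging study of
cavernous hemangioma of the liver (CHL): dilated hepatic sinusoids are
imaged with in-line phase-contrast CT, reconstructed, segmented and
measured. Because no real beamline data are available, the package starts
from a synthetic-tissue generator with exact ground truth, which turns the
whole chain into a measurable parameter-recovery experiment.

## Phantoms

A sample is a cylinder of parenchyma (inscribed in the voxel grid, as a
tissue block sealed in a cylindrical holder) containing sinusoid lumina:
unions of randomly oriented ellipsoids and capsules. Capsules supply the
tortuous, canaliform shapes seen in dilated sinusoids; ellipsoids the
saccular ones. Minimum-axis diameters are drawn uniformly from a
configurable range (study default 120–400 µm at 9 µm voxels, matching the
scale of dilated CHL sinusoids, which reach several hundred µm against a
normal 20–30 µm).

Severity grades control packing:

* **mild** — single-primitive lumina, pairwise separated by at least six
  voxels of parenchyma ("almost isolated" lacunae with resolvable walls);
* **moderate** — chains of 2–4 overlapping primitives, contact between
  lumina allowed (touching lumina merge into one 26-connected label);
* **severe** — long chains grown and topped up until the lumina occupy
  more than half of the tissue cylinder.

Lumina keep a six-voxel margin from the cylinder wall: lacunae are
embedded in tissue, and the margin also keeps them clear of the strong
wall-fringe band in the reconstruction. A thrombus is added to a lumen as
its deepest-EDT (concentric) voxel set, hitting the requested volume
fraction to within one voxel by randomized tie-breaking on the outermost
shell.

Optical constants at 16 keV (refractive index n = 1 − δ + iβ) default to
parenchyma δ = 4.0e-7 / β = 2.0e-10, lumen (formalin/plasma) 3.0e-7 /
1.5e-10, thrombus 4.5e-7 / 2.5e-10. These are plausible soft-tissue
magnitudes, not measured values; only the ordering and the existence of
contrast matter to the pipeline, and they are configurable.

## Forward model

The beam is ideal: monochromatic, parallel, fully coherent. Projection is
a rotation of the δ/β volumes about the z axis (linear interpolation)
followed by summation along the beam, giving the exit-wave maps
B = (2π/λ)∫β dz and φ = −(2π/λ)∫δ dz (φ ≤ 0 for δ > 0). Near-field
propagation to the detector at distance z uses the weak-object transfer
function,

    Î_z(u,v) = δ_D(u,v) − 2 B̂ cos χ + 2 φ̂ sin χ,   χ = πλz(u² + v²),

implemented as I = exp(−2B) − 2F⁻¹[B̂(cos χ − 1)] + 2F⁻¹[φ̂ sin χ]. Keeping
the exact contact term exp(−2B) rather than its linearisation 1 − 2B makes
the z = 0 image exactly the absorption image and preserves the mean
intensity exactly (flux conservation); it is identical to the plain
transfer function to first order in B. The sign of the phase term is fixed
by consistency with the transport-of-intensity limit

    I_z ≈ exp(−2B)(1 − (λz/2π)∇²φ),

under the φ ≤ 0 convention: a dense object then shows the physical dark
rim just inside its boundary and bright rim outside. The TIE Laplacian is
the 5-point stencil at detector pitch. Padding before the frequency-domain
product is edge-replicating (2× by default), so constant fields propagate
unchanged and compact-support fields are zero-extended.

The TIE and Fresnel operators agree to second order in z on smooth
objects. Note that at 9 µm pitch the difference between the 5-point and
the spectral Laplacian (a discretisation effect, linear in z) dominates
the z³ physics term; the convergence-order check therefore runs at 2 µm
pitch, where λz exceeds the pixel area and the z-nonlinearity is the
leading term.

Virtual acquisition mirrors the reference protocol: 16 keV (λ ≈ 0.7749 Å),
9×9 µm² pixels, z = 1 m, 1200 projections over 180° (scaled down to 300 in
the bundled studies), 20 flat fields, 10 dark fields. Counts are
gain × flat_counts × I + dark_offset with Poisson counting noise plus
rounded Gaussian read noise (σ = 2 counts); darks carry offset and read
noise only. The unspecified photon flux is represented by `flat_counts`
(default 5000 photons/pixel). An optional smooth ±5% gain map emulates
flat-field structure.

## Preprocessing and reconstruction

Flat/dark correction is pixelwise: T = (P − D̄)/(F̄ − D̄), with dead pixels
(flat-minus-dark below 1e-6 of the flat dynamic range) repaired from the
valid 3×3 neighbourhood. Projection smoothing is an in-plane Gaussian
(default σ = 1.5 px in the study configuration — strong enough to bring
the reconstruction noise below the weak lumen/parenchyma absorption
contrast at 5000 counts, narrow enough to leave 120 µm lumina intact).
Ring suppression removes the angle-stationary per-column bias (pixelwise
mean over angles minus its median-filtered column trend, window 15,
re-centred so projection means are preserved exactly). Unsharp-mask edge
enhancement is available for display volumes but is off in the measurement
path, where it would bias boundaries.

Reconstruction is parallel-beam FBP: −ln of transmission (clamped at
1e-6), Ram–Lak filtering via the exact DFT of the band-limited spatial
kernel (Shepp–Logan and Hann apodisations available), linear-interpolation
back projection about column (cols−1)/2 — the same centre the projector
rotates about. No phase retrieval is applied, matching the reference
processing: interfaces reconstruct with bright/dark rims, and large
cavities acquire a cupped (near-parenchyma) interior from the filtered
rims and the −ln nonlinearity. These artifacts are treated as features of
the data by the segmentation stage.

## Segmentation

The reference workflow segmented interactively; here the replacement is
deterministic:

1. 3³ median filter.
2. Tissue region: the caller passes a cylindrical ROI (the analogue of the
   operator-selected region of interest; the reconstruction of the wall
   fringes shifts the apparent air level unpredictably — it can land
   between the lumen and parenchyma levels — so an intensity-based
   air/tissue split is unreliable for contained samples). Without an ROI a
   geometric fallback estimates air from the volume border and tissue from
   the central bulk.
3. Lumen threshold: Otsu on the interior histogram (tails trimmed at the
   2nd/95th percentiles so boundary-rim and thrombus tails cannot capture
   the split), refined to the midpoint of the two class medians — an
   unbiased 50% edge placement regardless of class populations.
4. Hysteresis shell repair: a looser threshold (75% of the way to the
   parenchyma median) completes weak stretches of the dark boundary shell
   of large cupped lumina; only cavities *enclosed* by the loose shell are
   added, so the outer boundary geometry stays at the strict threshold and
   clean two-valued volumes segment voxel-exactly.
5. Hole filling, 26-connected labelling, rejection of components smaller
   than `min_voxels` and (when an ROI is given) of components touching the
   ROI edge, which are wall-fringe residue.

Thrombus detection uses a physical criterion instead of histogram shape
statistics (intraluminal rim tails make every lumen histogram skewed and
nominally "bimodal"): a thrombus is denser than parenchyma, so its voxels
reconstruct brighter than the local parenchyma level, estimated as the
median ± MAD of a ring 2–5 voxels outside the lumen. Seeds exceed that
level by 4 robust standard deviations; the final boundary is re-thresholded
midway between the plasma and thrombus medians. Plasma-only cavities yield
an empty mask because no interior voxel rises above parenchyma.

## Morphometry

Per lumen: volume = voxel count × voxel³; surface area = marching-cubes
isosurface (0.5 level) of the Gaussian-smoothed mask (σ = 1 voxel; raw
mode available), avoiding the ≈1.5× staircase overestimate of raw voxel
surfaces; minimum diameter = 2 × (max EDT − 0.5) — the largest inscribed
ball, with the half-voxel correction from voxel centres to the physical
boundary; maximum diameter = maximum Feret diameter over convex-hull
surface voxels; thrombus fraction = thrombus voxels as a percentage of the
full cavity (the thrombus counts as part of the sinusoid interior).
Summaries report the arithmetic mean and sample (n−1) SD per descriptor,
rendered "mean±SD" to two decimals. All measures scale exactly with
voxel_size because the physical factor is applied after voxel-domain
computation.

## Study configurations and what they show

The bundled recovery study (20 mild-grade lumina, 120–400 µm, 160³ grid at
9 µm, 300 views, 5000 photons/pixel) recovers every lumen with Dice ≥ 0.9
and descriptor errors within 10% (volume, diameters) / 15% (surface area).
The problem sizes are scaled-down choices that keep a full study at
desk scale; the 1200-view full protocol is the geometry default and runs
identically, only longer. `min_voxels` is raised to 500 in the study
configurations (the smallest plausible lumen — a 120 µm sphere — is
≈1150 voxels, and noise blobs reach a few hundred; the library default of
27 only rejects speckle).

The generator emulates geometry, x-ray contrast and counting statistics,
not histology: no cell cords, no wall texture, no partial coherence,
polychromaticity or detector blur, and lumina are smooth primitives rather
than anastomosing networks. Passing recovery tests therefore demonstrate
the internal consistency and artifact-robustness of the processing chain
under realistic noise — not segmentation performance on real stained
tissue, where boundary conventions and out-of-model structure dominate.

## Numerical notes and limitations

* Objects must fit inside the inscribed cylinder of the grid: the
  projector's in-place rotation crops corners, so corner material would
  receive inconsistent line integrals.
* The weak-object transfer function is not valid for |φ| ≫ 1; the
  simulator does not enforce weakness, and the strong cylinder-wall
  fringes are deliberately retained as realistic artifacts.
* Thrombus detection assumes the thrombus class exceeds the parenchyma
  level and covers at least `thrombus_min_voxels`; faint thrombi with
  δ at or below parenchyma would be missed.
* The hysteresis loose threshold assumes the bright tail (rims + thrombi)
  occupies well under half of the tissue histogram; extreme severe-grade
  volumes are better segmented with contact-allowed merging in mind (a
  merged conglutinate is a single label by design).
* Determinism: one global seed drives phantom packing, thrombus ties, and
  all detector noise; identical config + seed reproduces every CSV byte
  for byte.
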