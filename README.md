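# sinuct

Simulated in-line phase-contrast micro-CT of hepatic-sinusoid phantoms:
virtual acquisition, filtered back projection, segmentation and 3D
morphometry, with exact ground truth for every step.

## The problem

Cavernous hemangioma of the liver (CHL) is a benign tumour built from
abnormally dilated hepatic sinusoids — blood-filled lacunae that grow from
the normal 20–30 µm to hundreds of µm. Synchrotron in-line phase-contrast
CT (ILPCI-CT) can image these cavities in unstained, fixed tissue: the
x-ray refractive index n = 1 − δ + iβ makes phase contrast
(δ, up to ~10³ × β for soft tissue) visible as edge-enhancing Fresnel
fringes after free-space propagation, and tomographic reconstruction
yields a 3D map from which each sinusoid's diameters, surface area, volume
and thrombus content can be measured.

`sinuct` rebuilds that measurement chain end to end as testable software.
Since real beamline data cannot be redistributed, the package generates
CHL-like tissue phantoms with known labels, simulates the scan, and treats
the whole pipeline as a parameter-recovery experiment: every reported
morphometric number can be compared against the phantom's ground truth.

It is aimed at people developing or validating processing chains for
propagation-based phase-contrast CT of soft tissue: simulation, detector
corrections, reconstruction and vascular morphometry are all exposed as a
library (`sinuct.*` modules), a `sinuct` command-line tool, and one
configured pipeline.

## The model in brief

* **Exit wave** — B = (2π/λ)∫β dz, φ = −(2π/λ)∫δ dz (parallel beam).
* **Near field** — weak-object transfer function
  Î_z = δ_D − 2B̂ cos χ + 2φ̂ sin χ, χ = πλz(u²+v²), kept exact in the
  contact term exp(−2B); its z→0 limit is the transport-of-intensity form
  I ≈ exp(−2B)(1 − (λz/2π)∇²φ).
* **Acquisition** — 16 keV, 9 µm pixels, z = 1 m, 1200 views/180° (300 in
  the bundled studies), 20 flats, 10 darks, Poisson + read noise.
* **Reconstruction** — flat/dark correction, Gaussian smoothing, ring
  (column-bias) suppression, then Ram–Lak FBP of −ln T. No phase
  retrieval: boundary fringes reconstruct as bright/dark rims and are
  handled by the segmentation.
* **Morphometry** — per lumen: volume (voxel count), surface area
  (marching cubes), minimum diameter (largest inscribed ball via EDT),
  maximum diameter (max Feret over the convex hull), thrombus fraction
  (% of the cavity).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

A small noisy study — three mild-grade lumina of 90–160 µm in a 64³ grid
at 9 µm voxels, 90 views, 5000 photons/pixel:

```python
from sinuct import AcquisitionGeometry, RunConfig
from sinuct.config import PhantomConfig, SegmentConfig
from sinuct.pipeline import run_pipeline, compare_to_truth

config = RunConfig(
    phantom=PhantomConfig(grid_shape=(64, 64, 64), grade="mild",
                          n_sinusoids=3, diameter_range_um=(90.0, 160.0)),
    geometry=AcquisitionGeometry(n_angles=90, n_flats=5, n_darks=3,
                                 flat_counts=5000.0),
    segment=SegmentConfig(min_voxels=400),
    output_dir="demo_run",
    seed=7,
)
run_dir = run_pipeline(config)
print((run_dir / "measure" / "summary.txt").read_text())
report = compare_to_truth(run_dir)
print({k: round(v, 3) for k, v in report["median"].items()})
```

Output:

```
n = 3
min_diameter: 73.21±19.80 um
max_diameter: 177.86±27.98 um
surface_area: 68746.68±39564.82 um^2
volume: 1289115.00±650736.26 um^3
thrombus_fraction: 0.00±0.00 %

{'dice': 0.971, 'volume_rel_err': 0.035, 'min_diameter_rel_err': 0.022,
 'max_diameter_rel_err': 0.049, 'surface_area_rel_err': 0.027}
```

The summary lines are cohort mean±SD (sample SD, n−1) of each descriptor
over the recovered sinusoids; the report shows that each lumen was
re-identified with a median Dice of 0.97 and that volumes and diameters
were recovered to within ~5% of the generator's ground truth. The run
directory holds every intermediate artifact (phantom TIFFs + ground-truth
CSV, raw projections/flats/darks, normalized sinograms, reconstructed
volume, label volumes, per-sinusoid and summary CSVs), each stage with a
JSON manifest of its parameters and input/output hashes.

The same run from the shell:

```bash
sinuct run -c demo.yaml -o demo_run --seed 7
sinuct compare demo_run
```

where `demo.yaml` is the YAML form of the config above (`RunConfig`
round-trips through `to_yaml`/`from_yaml`; a copy is written into every
run directory).

### Output tables

`measure/sinusoids.csv` has one row per sinusoid:

| column | meaning |
| --- | --- |
| `label_id` | lumen label in the segmentation volume |
| `min_diameter_um` | largest-inscribed-ball diameter (µm) |
| `max_diameter_um` | maximum Feret diameter (µm) |
| `surface_area_um2` | triangulated isosurface area (µm²) |
| `volume_um3` | voxel-count volume (µm³) |
| `thrombus_fraction_pct` | thrombus volume as % of the cavity |

`measure/summary.csv` is the long-format cohort summary (descriptor,
mean, sd, n) with the sample (n−1) standard deviation.
`phantom/ground_truth.csv` holds the same descriptors measured on the
true labels, for recovery scoring.

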