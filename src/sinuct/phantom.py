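"""Synthetic CHL-like tissue phantoms.

Cavernous hemangioma of the liver (CHL) is a benign tumour built from
abnormally dilated hepatic sinusoids: blood-filled lacunae whose diameters
reach hundreds of microns instead of the normal 20-30 um.  This module
generates 3D phantoms that emulate formalin-fixed CHL samples for a virtual
in-line phase-contrast CT experiment: paired volumes of the x-ray refractive
decrement ``delta`` and absorption index ``beta`` (complex refractive index
n = 1 - delta + i*beta), together with integer ground-truth labels for every
sinusoid lumen and an optional intraluminal thrombus mask.

Lumina are unions of randomly oriented ellipsoids and capsules (capsules
supply the tortuous, canaliform shapes) packed into a cylindrical tissue
sample.  The severity grade controls how much of the tissue the lacunae
occupy and whether distinct lumina may touch:

``mild``
    isolated single-primitive lumina, pairwise non-adjacent;
``moderate``
    short chains of primitives, contact between lumina allowed;
``severe``
    long chains grown until the lumina occupy more than half of the
    tissue cylinder, so the lacunae dominate the sample.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import PlacementError, UnknownLabelError

__all__ = [
    "OpticalConstants",
    "Phantom",
    "GroundTruthRecord",
    "make_sinusoid_phantom",
    "add_thrombus",
    "ground_truth_morphometry",
    "tissue_cylinder_mask",
    "write_phantom",
    "read_phantom",
]

#: 26-connectivity structuring element shared with the segmentation stage.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)

#: grade -> (primitives per lumen (lo, hi), target lumen fraction, contact allowed)
_GRADE_RULES = {
    "mild": ((1, 1), None, False),
    "moderate": ((2, 4), None, True),
    "severe": ((4, 8), 0.5, True),
}


@dataclass(frozen=True)
class OpticalConstants:
    """Refractive-index decrements and absorption indices at the working
    energy (default values are plausible soft-tissue magnitudes at 16 keV;
    only the existence of contrast between compartments matters)."""

    parenchyma_delta: float = 4.0e-7
    parenchyma_beta: float = 2.0e-10
    lumen_delta: float = 3.0e-7
    lumen_beta: float = 1.5e-10
    thrombus_delta: float = 4.5e-7
    thrombus_beta: float = 2.5e-10


@dataclass
class Phantom:
    """A labelled refractive-index phantom.

    Attributes
    ----------
    delta_volume, beta_volume:
        3D float fields of the refractive decrement and absorption index.
    label_volume:
        3D int field; 0 = parenchyma/background, k>0 = sinusoid lumen id.
        Labels are consecutive 1..K and each is one 26-connected component.
    thrombus_mask:
        3D bool field, a subset of the labelled lumina.
    voxel_size:
        isotropic voxel edge length in micrometres.
    grade:
        severity grade the phantom was generated with.
    """

    delta_volume: np.ndarray
    beta_volume: np.ndarray
    label_volume: np.ndarray
    thrombus_mask: np.ndarray
    voxel_size: float
    grade: str
    optics: OpticalConstants = field(default_factory=OpticalConstants)
    seed: int | None = None

    def __post_init__(self) -> None:
        shapes = {
            self.delta_volume.shape,
            self.beta_volume.shape,
            self.label_volume.shape,
            self.thrombus_mask.shape,
        }
        if len(shapes) != 1:
            raise ValueError("phantom fields must share one shape")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def n_labels(self) -> int:
        return int(self.label_volume.max())

    @property
    def lumen_fraction(self) -> float:
        """Lumen voxel count relative to the tissue cylinder volume."""
        tissue = tissue_cylinder_mask(self.label_volume.shape)
        return float((self.label_volume > 0).sum() / tissue.sum())

    def copy(self) -> "Phantom":
        return Phantom(
            self.delta_volume.copy(),
            self.beta_volume.copy(),
            self.label_volume.copy(),
            self.thrombus_mask.copy(),
            self.voxel_size,
            self.grade,
            self.optics,
            self.seed,
        )


@dataclass(frozen=True)
class GroundTruthRecord:
    """Reference morphometry of one lumen, measured on the true labels."""

    label_id: int
    true_min_diameter: float  # um
    true_max_diameter: float  # um
    true_surface_area: float  # um^2
    true_volume: float  # um^3
    true_thrombus_fraction: float  # fraction in [0, 1]


def tissue_cylinder_mask(shape: Sequence[int], margin: int = 2) -> np.ndarray:
    """Boolean mask of the cylindrical tissue sample inscribed in the grid.

    The cylinder axis is the z (slice) axis, mirroring a sample sealed in a
    cylindrical container on the rotation stage.  ``margin`` voxels are kept
    free at the cylinder wall and the axial faces.
    """
    nz, ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    radius = min(ny, nx) / 2.0 - margin
    yy, xx = np.mgrid[0:ny, 0:nx]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    mask = np.zeros(shape, dtype=bool)
    mask[margin : nz - margin] = disc
    return mask


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _rasterize_primitive(shape, kind, center, params, rotation, pad=2):
    """Rasterize one primitive; returns (slices, local boolean mask).

    ``kind`` is "ellipsoid" (params = three semi-axes, voxels) or "capsule"
    (params = (radius, half_length), voxels).  ``rotation`` maps local to
    grid coordinates.  ``pad`` is extra bounding-box margin (needed when a
    dilation of the mask is taken afterwards).
    """
    if kind == "ellipsoid":
        extent = float(np.max(params))
    else:
        radius, half_len = params
        extent = radius + half_len
    lo = np.maximum(np.floor(center - extent - pad).astype(int), 0)
    hi = np.minimum(np.ceil(center + extent + pad + 1).astype(int), shape)
    if np.any(hi <= lo):
        return None, None
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    rel = np.stack([g - c for g, c in zip(grids, center)], axis=-1)
    local = rel @ rotation  # rotation is orthonormal; inverse = transpose applied on right
    if kind == "ellipsoid":
        a, b, c = params
        q = (local[..., 0] / a) ** 2 + (local[..., 1] / b) ** 2 + (local[..., 2] / c) ** 2
        mask = q <= 1.0
    else:
        radius, half_len = params
        axial = np.clip(local[..., 0], -half_len, half_len)
        d2 = (local[..., 0] - axial) ** 2 + local[..., 1] ** 2 + local[..., 2] ** 2
        mask = d2 <= radius**2
    slc = tuple(slice(l, h) for l, h in zip(lo, hi))
    return slc, mask


def _sample_primitive(rng, diameter_range_vox):
    """Draw a primitive spec: (kind, params, rotation, extent in voxels)."""
    d = rng.uniform(*diameter_range_vox)
    r = d / 2.0
    rot = _random_rotation(rng)
    if rng.random() < 0.5:
        axes = np.array([r, r * rng.uniform(1.0, 2.5), r * rng.uniform(1.0, 2.5)])
        return "ellipsoid", axes, rot, float(axes.max())
    half_len = r * rng.uniform(1.0, 3.0)
    return "capsule", (r, half_len), rot, float(r + half_len)


def make_sinusoid_phantom(
    grid_shape: Sequence[int],
    voxel_size: float,
    grade: str,
    n_sinusoids: int,
    diameter_range: Sequence[float],
    seed: int,
    optical_constants: OpticalConstants | None = None,
    max_retries: int = 1000,
) -> Phantom:
    """Generate a CHL-like phantom with known ground-truth lumina.

    Parameters
    ----------
    grid_shape:
        (nz, ny, nx) voxel grid; z is the rotation axis.
    voxel_size:
        isotropic voxel edge length, micrometres.
    grade:
        "mild", "moderate" or "severe" (see module docstring).
    n_sinusoids:
        number of lumina to seed.  For moderate/severe grades lumina that
        grow into contact merge into a single 26-connected label.
    diameter_range:
        (lo, hi) of the minimum-axis diameter of each primitive, um.
    seed:
        RNG seed; identical arguments + seed give a bit-identical phantom.
    max_retries:
        rejection-sampling budget per primitive before PlacementError.
    """
    if grade not in _GRADE_RULES:
        raise ValueError(f"unknown grade {grade!r}")
    if n_sinusoids < 0:
        raise ValueError("n_sinusoids must be >= 0")
    lo_um, hi_um = float(diameter_range[0]), float(diameter_range[1])
    min_extent_um = min(grid_shape) * voxel_size
    if n_sinusoids > 0 and not (2 * voxel_size < lo_um <= hi_um < min_extent_um):
        raise ValueError(
            "diameter_range must lie within (2*voxel_size, min grid extent)"
        )
    optics = optical_constants or OpticalConstants()
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in grid_shape)
    tissue = tissue_cylinder_mask(shape)
    # lumina stay >= 6 voxels away from the sample wall: sinusoid lacunae
    # are embedded in parenchyma, never open to the container surface, and
    # the margin keeps them clear of the wall's phase-fringe band
    placement_region = ndimage.binary_erosion(tissue, iterations=6)
    lumen = np.zeros(shape, dtype=bool)
    # mild grade: voxels too close (< 6 voxel gap) to an accepted lumen;
    # maintained incrementally so rejection sampling stays cheap
    forbidden = np.zeros(shape, dtype=bool)
    diam_vox = (lo_um / voxel_size, hi_um / voxel_size)
    (chain_lo, chain_hi), target_fraction, contact_ok = _GRADE_RULES[grade]

    def try_place(center, spec, *, attach=False):
        kind, params, rot, _ = spec
        # O(1) pre-checks at the primitive centre before rasterizing
        c_idx = tuple(int(round(c)) for c in center)
        if any(not 0 <= i < s for i, s in zip(c_idx, shape)):
            return False
        if not attach and not placement_region[c_idx]:
            return False
        if not contact_ok and forbidden[c_idx]:
            return False
        slc, mask = _rasterize_primitive(shape, kind, center, params, rot)
        if slc is None or not mask.any():
            return False
        inside = placement_region[slc]
        if not attach and not inside[mask].all():
            return False  # keep whole primitive inside the tissue cylinder
        if not contact_ok:
            # mild: lumina keep >= 6 voxels of parenchyma between them —
            # "almost isolated" lacunae separated by resolvable walls
            if (forbidden[slc] & mask).any():
                return False
        lumen[slc] |= mask & inside
        if not contact_ok:
            # dilate in a wider bounding box so the forbidden zone extends
            # fully around the accepted primitive
            slc7, mask7 = _rasterize_primitive(shape, kind, center, params, rot, pad=7)
            forbidden[slc7] |= ndimage.binary_dilation(
                mask7 & placement_region[slc7],
                structure=CONNECTIVITY_26,
                iterations=5,
            )
        return True

    def random_center(extent):
        lo = extent + 2
        if any(dim - extent - 3 <= lo for dim in shape):
            return None  # primitive too large for this grid; resample
        return np.array([rng.uniform(lo, dim - extent - 3) for dim in shape])

    for _ in range(n_sinusoids):
        placed = False
        for _try in range(max_retries):
            spec = _sample_primitive(rng, diam_vox)
            center = random_center(spec[3])
            if center is not None and try_place(center, spec):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place lumen under grade={grade!r} constraints "
                f"after {max_retries} attempts"
            )
        # grow a chain of overlapping primitives for canaliform shapes
        n_chain = int(rng.integers(chain_lo, chain_hi + 1)) - 1
        prev_center, prev_extent = center, spec[3]
        for _ in range(n_chain):
            for _try in range(max_retries):
                spec2 = _sample_primitive(rng, diam_vox)
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                step = 0.6 * (prev_extent + spec2[3]) * rng.uniform(0.5, 1.0)
                center2 = prev_center + direction * step
                if try_place(center2, spec2, attach=True):
                    prev_center, prev_extent = center2, spec2[3]
                    break
            else:
                break  # chain growth exhausted; keep what we have

    if target_fraction is not None and n_sinusoids > 0:
        # severe: keep attaching primitives to existing lumina until the
        # lacunae dominate the tissue cylinder
        tissue_vox = tissue.sum()
        for _try in range(max_retries):
            if lumen.sum() / tissue_vox > target_fraction:
                break
            spec = _sample_primitive(rng, diam_vox)
            seeds = np.argwhere(lumen)
            anchor = seeds[rng.integers(len(seeds))]
            jitter = rng.standard_normal(3) * spec[3] * 0.5
            try_place(anchor + jitter, spec, attach=True)
        else:
            raise PlacementError(
                f"severe grade could not reach lumen fraction {target_fraction}"
            )

    labels, _ = ndimage.label(lumen, structure=CONNECTIVITY_26)
    delta = np.where(tissue, optics.parenchyma_delta, 0.0)
    beta = np.where(tissue, optics.parenchyma_beta, 0.0)
    delta[labels > 0] = optics.lumen_delta
    beta[labels > 0] = optics.lumen_beta
    return Phantom(
        delta_volume=delta,
        beta_volume=beta,
        label_volume=labels.astype(np.int32),
        thrombus_mask=np.zeros(shape, dtype=bool),
        voxel_size=float(voxel_size),
        grade=grade,
        optics=optics,
        seed=seed,
    )


def add_thrombus(
    phantom: Phantom, label_id: int, volume_fraction: float, seed: int = 0
) -> Phantom:
    """Return a copy of ``phantom`` with a concentric thrombus in one lumen.

    The thrombus occupies the deepest voxels of the lumen (largest Euclidean
    distance to the lumen boundary), so for a spherical lumen it is the
    concentric inner sphere.  The achieved voxel fraction matches
    ``volume_fraction`` to within the distance-transform tie shell; ties are
    broken with ``seed`` so the exact target count is hit when possible.
    """
    if not 0 <= volume_fraction < 1:
        raise ValueError("volume_fraction must be in [0, 1)")
    mask = phantom.label_volume == label_id
    n_lumen = int(mask.sum())
    if n_lumen == 0:
        raise UnknownLabelError(f"label {label_id} not present")
    out = phantom.copy()
    n_target = int(round(volume_fraction * n_lumen))
    if n_target == 0:
        return out
    edt = ndimage.distance_transform_edt(mask)
    depths = edt[mask]
    order = np.argsort(depths)[::-1]
    threshold = depths[order[n_target - 1]]
    core = mask & (edt > threshold)
    shell = mask & (edt == threshold)
    deficit = n_target - int(core.sum())
    if deficit > 0:
        shell_idx = np.argwhere(shell)
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(shell_idx), size=deficit, replace=False)
        core[tuple(shell_idx[pick].T)] = True
    out.thrombus_mask |= core
    out.delta_volume[core] = out.optics.thrombus_delta
    out.beta_volume[core] = out.optics.thrombus_beta
    return out


def ground_truth_morphometry(phantom: Phantom) -> list[GroundTruthRecord]:
    """Measure every true lumen with the morphometry operators.

    Values serve as recovery targets for the simulate->reconstruct->segment->
    measure pipeline.  They are voxel-oracle measurements on the phantom's
    own labels at phantom resolution (exact for volume; mesh/EDT-based for
    surface and diameters).
    """
    from .morphometry import measure_sinusoid
    from .segment import LabelVolume

    labels = LabelVolume(
        labels=phantom.label_volume,
        thrombus_mask=phantom.thrombus_mask,
        voxel_size=phantom.voxel_size,
    )
    records = []
    for label_id in range(1, phantom.n_labels + 1):
        rec = measure_sinusoid(labels, label_id)
        records.append(
            GroundTruthRecord(
                label_id=label_id,
                true_min_diameter=rec.min_diameter,
                true_max_diameter=rec.max_diameter,
                true_surface_area=rec.surface_area,
                true_volume=rec.volume,
                true_thrombus_fraction=rec.thrombus_fraction / 100.0,
            )
        )
    return records


def write_phantom(phantom: Phantom, directory: str | Path) -> Path:
    """Write the phantom as multipage TIFF stacks plus a JSON sidecar."""
    from . import io as _io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _io.write_stack(directory / "delta.tif", phantom.delta_volume.astype(np.float32))
    _io.write_stack(directory / "beta.tif", phantom.beta_volume.astype(np.float32))
    _io.write_stack(directory / "labels.tif", phantom.label_volume.astype(np.uint16))
    _io.write_stack(directory / "thrombus.tif", phantom.thrombus_mask.astype(np.uint8))
    sidecar = {
        "voxel_size_um": phantom.voxel_size,
        "grade": phantom.grade,
        "seed": phantom.seed,
        "optical_constants": dataclasses.asdict(phantom.optics),
    }
    (directory / "phantom.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def read_phantom(directory: str | Path) -> Phantom:
    """Read a phantom previously written by :func:`write_phantom`."""
    from . import io as _io

    directory = Path(directory)
    meta = json.loads((directory / "phantom.json").read_text())
    return Phantom(
        delta_volume=_io.read_stack(directory / "delta.tif").astype(np.float64),
        beta_volume=_io.read_stack(directory / "beta.tif").astype(np.float64),
        label_volume=_io.read_stack(directory / "labels.tif").astype(np.int32),
        thrombus_mask=_io.read_stack(directory / "thrombus.tif").astype(bool),
        voxel_size=float(meta["voxel_size_um"]),
        grade=meta["grade"],
        optics=OpticalConstants(**meta["optical_constants"]),
        seed=meta["seed"],
    )
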