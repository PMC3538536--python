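"""In-line phase-contrast forward model and virtual CT acquisition.

A monochromatic, fully coherent parallel beam traverses the phantom.  The
exit wave is described by the attenuation line integral B = (2*pi/lambda) *
integral(beta dz) and phase shift phi = -(2*pi/lambda) * integral(delta dz)
(phi <= 0 for delta > 0, since the refractive index of matter is n = 1 -
delta + i*beta < 1 for x rays).  Free-space propagation over the
sample-to-detector distance z turns phase gradients into measurable
intensity fringes; in the near field the recorded intensity is modelled
with the weak-object transfer function

    I_hat(u, v) = delta_D(u, v) - 2 B_hat cos(chi) + 2 phi_hat sin(chi),
    chi = pi * lambda * z * (u^2 + v^2),

whose z->0 / small-chi limit is the transport-of-intensity approximation

    I_z ~= exp(-2B) * (1 - (lambda z / 2 pi) * laplacian(phi)).

The implementation keeps the exact contact term exp(-2B) and applies the
transfer function to the deviations, so the z=0 image equals exp(-2B) to
machine precision and free-space propagation conserves the mean intensity.

The virtual acquisition mirrors a synchrotron micro-CT protocol: by default
16 keV, 9x9 um^2 detector pixels, z = 1 m, 1200 projections over 180
degrees, 20 flat-field and 10 dark-field frames, Poisson counting noise and
Gaussian read noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, GeometryError, ValidationError
from .phantom import Phantom

__all__ = [
    "HC_KEV_ANGSTROM",
    "AcquisitionGeometry",
    "ExitWave",
    "ProjectionSet",
    "project_refraction",
    "fresnel_propagate",
    "tie_intensity",
    "acquire_dataset",
]

#: h*c in keV * Angstrom; lambda[A] = HC_KEV_ANGSTROM / E[keV]
HC_KEV_ANGSTROM = 12.398419


@dataclass
class AcquisitionGeometry:
    """Beamline and scan geometry of a virtual acquisition.

    Defaults reproduce the reference protocol: 16 keV beam, 9 um detector
    pitch, 1 m sample-to-detector distance, 1200 uniformly spaced angles
    over 180 degrees, 20 flats, 10 darks.
    """

    energy_kev: float = 16.0
    sdd_m: float = 1.0
    pixel_size_um: float = 9.0
    n_angles: int = 1200
    angular_range_deg: float = 180.0
    flat_counts: float = 5000.0
    dark_offset: float = 20.0
    n_flats: int = 20
    n_darks: int = 10
    seed: int = 0
    noise: bool = True
    read_noise_sigma: float = 2.0
    gain_variation: float = 0.0

    def __post_init__(self) -> None:
        if self.energy_kev <= 0:
            raise ConfigurationError("energy must be positive")
        if self.sdd_m < 0:
            raise ConfigurationError("sample-to-detector distance must be >= 0")
        if self.n_angles < 1:
            raise ConfigurationError("n_angles must be >= 1")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if self.noise and self.flat_counts <= 0:
            raise ConfigurationError("Poisson noise requires flat_counts > 0")

    @property
    def wavelength_m(self) -> float:
        """lambda = hc / E, in metres (0.7749 A at 16 keV)."""
        return HC_KEV_ANGSTROM / self.energy_kev * 1e-10

    @property
    def pixel_size_m(self) -> float:
        return self.pixel_size_um * 1e-6

    @property
    def angles_deg(self) -> np.ndarray:
        """Uniformly spaced view angles in [0, angular_range)."""
        return np.arange(self.n_angles) * (self.angular_range_deg / self.n_angles)


@dataclass
class ExitWave:
    """Attenuation (B, dimensionless) and phase (phi, radians) maps of the
    wave leaving the sample, sampled at detector pitch."""

    B: np.ndarray
    phi: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.B.shape != self.phi.shape:
            raise ValidationError("B and phi must share one shape")


@dataclass
class ProjectionSet:
    """Raw detector frames of a CT scan: projections, flats, darks."""

    projections: np.ndarray  # (n_angles, rows, cols)
    flats: np.ndarray  # (n_flats, rows, cols)
    darks: np.ndarray  # (n_darks, rows, cols)
    angles: np.ndarray  # degrees
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        if self.projections.ndim != 3:
            raise ValidationError("projections must be (n_angles, rows, cols)")
        frame = self.projections.shape[1:]
        if self.flats.shape[1:] != frame or self.darks.shape[1:] != frame:
            raise ValidationError("flat/dark frame shape differs from projections")
        if len(self.angles) != self.projections.shape[0]:
            raise ValidationError("angle list length differs from projection count")


def project_refraction(
    phantom: Phantom, angle_deg: float, geometry: AcquisitionGeometry
) -> ExitWave:
    """Parallel-beam line integrals of delta and beta at one view angle.

    The phantom is rotated about the z (slice) axis and integrated along
    the beam; B = (2 pi / lambda) * integral(beta) and phi = -(2 pi /
    lambda) * integral(delta).  Detector rows map to phantom slices and
    columns to the axis perpendicular to the beam.
    """
    if not np.isfinite(angle_deg):
        raise ValidationError("angle must be finite")
    if abs(geometry.pixel_size_um - phantom.voxel_size) > 1e-9:
        raise GeometryError(
            f"detector pitch {geometry.pixel_size_um} um != voxel size "
            f"{phantom.voxel_size} um and resampling is not enabled"
        )
    stack = np.stack([phantom.delta_volume, phantom.beta_volume])
    if angle_deg % 360.0 != 0.0:
        stack = ndimage.rotate(
            stack,
            angle_deg,
            axes=(2, 3),
            reshape=False,
            order=1,
            mode="constant",
            cval=0.0,
            prefilter=False,
        )
    path = stack.sum(axis=2) * (phantom.voxel_size * 1e-6)  # (2, nz, nx)
    k = 2.0 * np.pi / geometry.wavelength_m
    return ExitWave(
        B=k * path[1], phi=-k * path[0], pixel_size_um=phantom.voxel_size
    )


def fresnel_propagate(
    wave: ExitWave, geometry: AcquisitionGeometry, pad_factor: int = 2
) -> np.ndarray:
    """Near-field intensity at distance z via the weak-object transfer
    function (relative units; 1 = unit incident beam).

    The maps are padded ``pad_factor``-fold (edge replication, so constant
    maps stay constant and compact-support maps are zero-extended) before
    the frequency-domain product to suppress wrap-around, and cropped back
    afterwards.  At z = 0
    the output is exactly exp(-2B); the spatial mean always equals the mean
    of exp(-2B) because cos(0) - 1 = sin(0) = 0 at zero frequency.
    """
    if not (np.isfinite(wave.B).all() and np.isfinite(wave.phi).all()):
        raise ValidationError("exit wave contains non-finite values")
    if wave.pixel_size_um <= 0:
        raise ValidationError("pixel size must be positive")
    rows, cols = wave.B.shape
    contact = np.exp(-2.0 * wave.B)
    if geometry.sdd_m == 0:
        return contact
    pr, pc = pad_factor * rows, pad_factor * cols
    u = np.fft.fftfreq(pr, d=geometry.pixel_size_m)
    v = np.fft.fftfreq(pc, d=geometry.pixel_size_m)
    chi = np.pi * geometry.wavelength_m * geometry.sdd_m * (
        u[:, None] ** 2 + v[None, :] ** 2
    )
    pad_spec = ((0, pr - rows), (0, pc - cols))
    B_hat = np.fft.fft2(np.pad(wave.B, pad_spec, mode="edge"))
    phi_hat = np.fft.fft2(np.pad(wave.phi, pad_spec, mode="edge"))
    absorb = np.fft.ifft2(B_hat * (np.cos(chi) - 1.0)).real[:rows, :cols]
    phase = np.fft.ifft2(phi_hat * np.sin(chi)).real[:rows, :cols]
    return contact - 2.0 * absorb + 2.0 * phase


def tie_intensity(wave: ExitWave, geometry: AcquisitionGeometry) -> np.ndarray:
    """Transport-of-intensity approximation of the near-field image:
    I = exp(-2B) * (1 - (lambda z / 2 pi) * laplacian(phi)), with the
    Laplacian evaluated by 5-point finite differences at detector pitch."""
    if not (np.isfinite(wave.B).all() and np.isfinite(wave.phi).all()):
        raise ValidationError("exit wave contains non-finite values")
    pix_m = wave.pixel_size_um * 1e-6
    lap = ndimage.laplace(wave.phi, mode="nearest") / pix_m**2
    factor = geometry.wavelength_m * geometry.sdd_m / (2.0 * np.pi)
    return np.exp(-2.0 * wave.B) * (1.0 - factor * lap)


def _gain_map(shape, geometry: AcquisitionGeometry, rng) -> np.ndarray:
    """Detector gain map: uniform 1.0, or a smooth +-gain_variation field."""
    if geometry.gain_variation == 0:
        return np.ones(shape)
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=8.0)
    peak = np.abs(raw).max()
    if peak == 0:
        return np.ones(shape)
    return 1.0 + geometry.gain_variation * raw / peak


def acquire_dataset(
    phantom: Phantom,
    geometry: AcquisitionGeometry,
    model: Literal["fresnel", "tie"] = "fresnel",
) -> ProjectionSet:
    """Simulate a full CT scan: projections at every angle plus flats/darks.

    Per angle: exit wave -> near-field intensity -> counts = gain *
    flat_counts * I + dark_offset, with Poisson counting noise and Gaussian
    read noise when ``geometry.noise`` is on.  Flats are beam-only frames,
    darks are offset + read noise only.  Deterministic per geometry.seed.
    """
    rng = np.random.default_rng(geometry.seed)
    propagate = fresnel_propagate if model == "fresnel" else tie_intensity
    angles = geometry.angles_deg
    nz = phantom.delta_volume.shape[0]
    nx = phantom.delta_volume.shape[2]
    gain = _gain_map((nz, nx), geometry, rng)

    projections = np.empty((geometry.n_angles, nz, nx))
    for i, angle in enumerate(angles):
        wave = project_refraction(phantom, angle, geometry)
        intensity = np.clip(propagate(wave, geometry), 0.0, None)
        signal = gain * geometry.flat_counts * intensity
        if geometry.noise:
            frame = rng.poisson(signal).astype(np.float64) + geometry.dark_offset
            frame += np.rint(rng.normal(0.0, geometry.read_noise_sigma, signal.shape))
            projections[i] = np.clip(frame, 0.0, None)
        else:
            projections[i] = signal + geometry.dark_offset

    beam = gain * geometry.flat_counts
    flats = np.empty((geometry.n_flats, nz, nx))
    for j in range(geometry.n_flats):
        if geometry.noise:
            frame = rng.poisson(beam).astype(np.float64) + geometry.dark_offset
            frame += np.rint(rng.normal(0.0, geometry.read_noise_sigma, beam.shape))
            flats[j] = np.clip(frame, 0.0, None)
        else:
            flats[j] = beam + geometry.dark_offset

    darks = np.empty((geometry.n_darks, nz, nx))
    for j in range(geometry.n_darks):
        if geometry.noise:
            frame = geometry.dark_offset + np.rint(
                rng.normal(0.0, geometry.read_noise_sigma, (nz, nx))
            )
            darks[j] = np.clip(frame, 0.0, None)
        else:
            darks[j] = np.full((nz, nx), geometry.dark_offset, dtype=np.float64)

    return ProjectionSet(
        projections=projections,
        flats=flats,
        darks=darks,
        angles=angles,
        geometry=geometry,
    )
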