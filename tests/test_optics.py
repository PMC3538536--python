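import numpy as np
import pytest

from sinuct.errors import ConfigurationError, GeometryError, ValidationError
from sinuct.optics import (
    AcquisitionGeometry,
    ExitWave,
    ProjectionSet,
    acquire_dataset,
    fresnel_propagate,
    project_refraction,
    tie_intensity,
)

from conftest import make_ball_phantom


def geometry(**kw):
    kw.setdefault("noise", False)
    return AcquisitionGeometry(**kw)


def gaussian_phase_wave(n=128, sigma_px=6.0, peak=-0.1, pixel_size_um=9.0):
    y, x = np.mgrid[0:n, 0:n] - (n - 1) / 2
    phi = peak * np.exp(-(x**2 + y**2) / (2 * sigma_px**2))
    return ExitWave(B=np.zeros_like(phi), phi=phi, pixel_size_um=pixel_size_um)


class TestGeometry:
    def test_wavelength_at_16_kev(self):
        g = geometry()
        assert abs(g.wavelength_m - 0.7749e-10) / 0.7749e-10 < 1e-4

    def test_defaults_mirror_acquisition_protocol(self):
        g = AcquisitionGeometry()
        assert g.energy_kev == 16.0
        assert g.pixel_size_um == 9.0
        assert g.sdd_m == 1.0
        assert (g.n_angles, g.angular_range_deg) == (1200, 180.0)
        assert (g.n_flats, g.n_darks) == (20, 10)

    def test_angles_uniform_in_half_turn(self):
        g = geometry(n_angles=10)
        assert np.allclose(np.diff(g.angles_deg), 18.0)
        assert g.angles_deg[0] == 0.0 and g.angles_deg[-1] < 180.0

    def test_noise_requires_positive_flux(self):
        with pytest.raises(ConfigurationError):
            AcquisitionGeometry(flat_counts=0.0, noise=True)


class TestProjectRefraction:
    def test_zero_beta_gives_zero_attenuation(self):
        ph = make_ball_phantom(10, 48)
        ph.beta_volume[:] = 0.0
        g = geometry()
        for angle in (0.0, 45.0, 90.0):
            wave = project_refraction(ph, angle, g)
            assert np.all(wave.B == 0.0)

    def test_ray_missing_material_is_zero(self):
        ph = make_ball_phantom(6, 48)
        ph.delta_volume[:] = 0.0
        ph.beta_volume[:] = 0.0
        ph.delta_volume[20:28, 20:28, 20:28] = 1e-7
        wave = project_refraction(ph, 0.0, geometry())
        assert wave.B[0, 0] == 0.0 and wave.phi[0, 0] == 0.0
        assert wave.phi.min() < 0  # rays through the cube do accumulate phase

    def test_central_ray_chord_length(self):
        """Phase of the central ray through a uniform ball equals the
        analytic chord integral -(2 pi/lambda) * delta * 2R within 1%."""
        radius_vox, grid = 32, 80
        ph = make_ball_phantom(radius_vox, grid)
        ph.delta_volume[:] = 0.0
        ball = ph.label_volume > 0
        delta0 = 3.0e-7
        ph.delta_volume[ball] = delta0
        g = geometry()
        wave = project_refraction(ph, 0.0, g)
        c = (grid - 1) // 2
        # interpolate the two central detector pixels (grid centre falls
        # between voxel centres for even grids)
        phi_centre = 0.5 * (wave.phi[c, c] + wave.phi[c + 1, c]) if grid % 2 == 0 else wave.phi[c, c]
        chord_m = 2 * radius_vox * ph.voxel_size * 1e-6
        expected = -2 * np.pi / g.wavelength_m * delta0 * chord_m
        assert abs(phi_centre - expected) / abs(expected) < 0.01

    def test_pixel_voxel_mismatch_raises(self):
        ph = make_ball_phantom(6, 32)
        with pytest.raises(GeometryError):
            project_refraction(ph, 0.0, geometry(pixel_size_um=13.0))


class TestFresnelPropagate:
    def test_contact_plane_equals_absorption_image(self):
        """z = 0 reduces exactly to the contact image exp(-2B)."""
        rng = np.random.default_rng(0)
        B = 0.01 * rng.random((64, 64))
        wave = ExitWave(B=B, phi=-0.1 * rng.random((64, 64)), pixel_size_um=9.0)
        out = fresnel_propagate(wave, geometry(sdd_m=0.0))
        assert np.array_equal(out, np.exp(-2 * B))

    def test_constant_wave_stays_uniform(self):
        B0 = 0.02
        wave = ExitWave(
            B=np.full((48, 48), B0), phi=np.full((48, 48), -0.3), pixel_size_um=9.0
        )
        for z in (0.1, 1.0, 3.0):
            out = fresnel_propagate(wave, geometry(sdd_m=z))
            assert np.allclose(out, np.exp(-2 * B0), atol=1e-12)

    def test_mean_intensity_preserved(self):
        """Free-space propagation conserves flux: the spatial mean equals
        the mean of the contact image."""
        wave = gaussian_phase_wave()
        wave.B += 0.01 * np.exp(-((np.arange(128) - 60) ** 2) / 200.0)[:, None]
        out = fresnel_propagate(wave, geometry(sdd_m=1.0))
        contact = np.exp(-2 * wave.B)
        assert abs(out.mean() - contact.mean()) / contact.mean() < 1e-6

    def test_non_finite_input_rejected(self):
        wave = gaussian_phase_wave(32)
        wave.phi[0, 0] = np.nan
        with pytest.raises(ValidationError):
            fresnel_propagate(wave, geometry())


class TestTieIntensity:
    def test_constant_phase_gives_contact_image(self):
        B = np.full((32, 32), 0.05)
        wave = ExitWave(B=B, phi=np.full((32, 32), -2.0), pixel_size_um=9.0)
        out = tie_intensity(wave, geometry(sdd_m=1.0))
        assert np.allclose(out, np.exp(-2 * B), atol=1e-12)

    def test_quadratic_phase_gives_uniform_defocus(self):
        """phi = a(x^2+y^2) has Laplacian 4a, so the interior intensity is
        uniformly 1 - (lambda z / 2 pi) * 4a."""
        n, pix_um = 64, 9.0
        g = geometry(sdd_m=1.0)
        y, x = (np.mgrid[0:n, 0:n] - (n - 1) / 2) * pix_um * 1e-6
        a = 1e4  # rad / m^2
        wave = ExitWave(B=np.zeros((n, n)), phi=a * (x**2 + y**2), pixel_size_um=pix_um)
        out = tie_intensity(wave, g)
        expected = 1.0 - g.wavelength_m * g.sdd_m / (2 * np.pi) * 4 * a
        interior = out[2:-2, 2:-2]  # one-sided stencil spoils the border
        assert np.allclose(interior, expected, rtol=1e-9)

    def test_agrees_with_fresnel_to_second_order(self):
        """Max TIE/Fresnel discrepancy on a smooth pure-phase object falls
        by >= 3.8x per halving of z (convergence order >= 1.9)."""
        wave = gaussian_phase_wave(n=256, sigma_px=4.0, pixel_size_um=2.0)
        discrepancies = []
        for z in (2.0, 1.0, 0.5):
            g = geometry(sdd_m=z, pixel_size_um=2.0)
            discrepancies.append(
                np.abs(tie_intensity(wave, g) - fresnel_propagate(wave, g)).max()
            )
        assert discrepancies[0] / discrepancies[1] >= 3.8
        assert discrepancies[1] / discrepancies[2] >= 3.8


class TestAcquireDataset:
    def test_zero_flux_noiseless_projections_are_offset_only(self):
        ph = make_ball_phantom(6, 32)
        g = geometry(n_angles=4, flat_counts=0.0, dark_offset=20.0)
        pset = acquire_dataset(ph, g)
        assert np.all(pset.projections == 20.0)
        assert np.all(pset.darks == 20.0)

    def test_stack_shapes_and_angles(self):
        ph = make_ball_phantom(6, 32)
        g = geometry(n_angles=5, n_flats=3, n_darks=2)
        pset = acquire_dataset(ph, g)
        assert pset.projections.shape == (5, 32, 32)
        assert pset.flats.shape == (3, 32, 32)
        assert pset.darks.shape == (2, 32, 32)
        assert np.allclose(pset.angles, g.angles_deg)

    def test_flat_field_mean_matches_poisson_expectation(self):
        """Mean of the flats approaches flat_counts + dark_offset within
        three standard errors of the Poisson + read-noise prediction."""
        ph = make_ball_phantom(4, 24)
        g = AcquisitionGeometry(
            n_angles=1, flat_counts=5000.0, dark_offset=20.0, n_flats=20, seed=123
        )
        pset = acquire_dataset(ph, g)
        n_samples = pset.flats.size
        se = np.sqrt((g.flat_counts + g.read_noise_sigma**2) / n_samples)
        assert abs(pset.flats.mean() - (g.flat_counts + g.dark_offset)) < 3 * se

    def test_counts_are_integer_valued_with_noise(self):
        ph = make_ball_phantom(4, 24)
        pset = acquire_dataset(ph, AcquisitionGeometry(n_angles=2, seed=5))
        for stack in (pset.projections, pset.flats, pset.darks):
            assert np.all(stack >= 0)
            assert np.array_equal(stack, np.rint(stack))

    def test_deterministic_per_seed(self):
        ph = make_ball_phantom(4, 24)
        a = acquire_dataset(ph, AcquisitionGeometry(n_angles=2, seed=11))
        b = acquire_dataset(ph, AcquisitionGeometry(n_angles=2, seed=11))
        assert np.array_equal(a.projections, b.projections)
        assert np.array_equal(a.flats, b.flats)
        assert np.array_equal(a.darks, b.darks)


@pytest.mark.parametrize("container", ["tiff", "hdf5"])
def test_projection_set_roundtrip(tmp_path, container):
    from sinuct import io as _io

    ph = make_ball_phantom(4, 24)
    pset = acquire_dataset(ph, AcquisitionGeometry(n_angles=3, seed=2))
    if container == "tiff":
        _io.write_projection_set(pset, tmp_path / "acq")
        back = _io.read_projection_set(tmp_path / "acq")
    else:
        _io.write_projection_set_hdf5(pset, tmp_path / "acq.h5")
        back = _io.read_projection_set_hdf5(tmp_path / "acq.h5")
    assert np.allclose(back.projections, pset.projections)
    assert np.allclose(back.flats, pset.flats)
    assert np.allclose(back.darks, pset.darks)
    assert np.allclose(back.angles, pset.angles)
    assert back.geometry.n_angles == pset.geometry.n_angles


def test_projection_set_validates_shapes():
    g = geometry(n_angles=2)
    with pytest.raises(ValidationError):
        ProjectionSet(
            projections=np.zeros((2, 8, 8)),
            flats=np.zeros((1, 4, 4)),
            darks=np.zeros((1, 8, 8)),
            angles=np.array([0.0, 90.0]),
            geometry=g,
        )
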