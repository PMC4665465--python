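"""Calibrated CCD imaging chain: rendering, noise, calibration, radiometry.

Includes an independent Monte-Carlo photon-transport oracle (isotropic
random walk at the reduced scattering coefficient, Fresnel boundary
transmission) against which the diffusion-based renderer's angular capture
profile is checked.
"""

import numpy as np
import pytest

from mblt import (
    MEDIA,
    CcdParameters,
    DetectorImage,
    PointSource,
    SceneModel,
    angular_capture_profile,
    apply_calibration,
    apply_ccd_noise,
    digitize,
    flat_field_calibrate,
    photon_energy_J,
    radiance_units,
    render_view,
    simulate_acquisition,
    surface_pixel_map,
    undo_calibration,
)
from mblt.acquisition import UNITS_PHOTONS, UNITS_W, bin_pixels
from mblt.geometry import CameraPose
from mblt.optics import _fresnel_unpolarized, air_irradiance

POWER = 1.4e10


# --------------------------------------------------------------------------- #
# rendering
# --------------------------------------------------------------------------- #

class TestRenderView:
    def test_centered_source_views_identical(self, phantom, lipid, poses):
        """A source on the rotation axis makes every view equivalent."""
        _, mesh, _ = phantom
        scene = SceneModel(mesh, lipid, [PointSource((0.0, 0.0, 0.0), POWER)])
        totals = [render_view(scene, poses[k], 60.0).total() for k in (0, 7, 13)]
        np.testing.assert_allclose(totals, totals[0], rtol=1e-6)

    def test_air_inverse_square(self, phantom, air):
        _, mesh, _ = phantom
        scene = SceneModel(mesh, air, [PointSource((0.0, 0.0, 0.0), POWER)])
        near = render_view(scene, CameraPose(position=(115.0, 0.0, 0.0)), 60.0)
        far = render_view(
            scene, CameraPose(position=(230.0, 0.0, 0.0), focus_distance_mm=230.0), 60.0
        )
        assert near.total() / far.total() == pytest.approx(4.0, rel=1e-3)

    def test_source_outside_mesh_rejected(self, phantom, lipid):
        _, mesh, _ = phantom
        with pytest.raises(ValueError):
            SceneModel(mesh, lipid, [PointSource((20.0, 0.0, 0.0), POWER)])

    def test_noiseless_pipeline_linear_in_power(self, phantom, lipid, poses):
        """Scaling every source power by c scales every calibrated image by c."""
        _, mesh, _ = phantom
        two = poses[:2]
        a = simulate_acquisition(
            SceneModel(mesh, lipid, [PointSource((5.0, 0.0, 0.0), POWER)]),
            two, exposure_s=60.0, noise=False,
        )
        b = simulate_acquisition(
            SceneModel(mesh, lipid, [PointSource((5.0, 0.0, 0.0), 3.7 * POWER)]),
            two, exposure_s=60.0, noise=False,
        )
        for ia, ib in zip(a.images, b.images):
            # bias subtraction limits absolute accuracy on empty pixels, so the
            # tolerance is taken relative to the image peak
            np.testing.assert_allclose(
                ib.pixels, 3.7 * ia.pixels, rtol=1e-10, atol=1e-10 * ia.pixels.max()
            )

    def test_air_photon_conservation_through_sphere(self):
        """Quadrature of the free-space irradiance over a closed sphere
        recovers the source power to 1%."""
        src = PointSource((0.3, -0.2, 0.1), POWER)
        r = 50.0
        th = np.linspace(0, np.pi, 201)
        ph = np.linspace(0, 2 * np.pi, 201)
        T, P = np.meshgrid(th, ph, indexing="ij")
        pts = np.stack(
            [r * np.sin(T) * np.cos(P), r * np.sin(T) * np.sin(P), r * np.cos(T)], -1
        )
        e = air_irradiance(src, pts.reshape(-1, 3)).reshape(T.shape)
        flux = np.trapezoid(
            np.trapezoid(e * r**2 * np.sin(T), ph, axis=1), th, axis=0
        )
        assert flux == pytest.approx(POWER, rel=0.01)


# --------------------------------------------------------------------------- #
# CCD noise chain
# --------------------------------------------------------------------------- #

class TestCcdNoise:
    def test_same_seed_identical(self):
        img = DetectorImage(np.full((64, 64), 1000.0), 60.0, units="electrons")
        ccd = CcdParameters()
        a = apply_ccd_noise(img, ccd, seed=42)
        b = apply_ccd_noise(img, ccd, seed=42)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        c = apply_ccd_noise(img, ccd, seed=43)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_zero_signal_zero_exposure_pure_read_noise(self):
        """Dark frame statistics: mean at the bias, spread = 5 e- RMS."""
        ccd = CcdParameters()
        img = DetectorImage(np.zeros((256, 256)), 0.0, units="electrons")
        out = apply_ccd_noise(img, ccd, seed=0)
        counts = out.pixels - ccd.bias_counts
        assert np.mean(counts) == pytest.approx(0.0, abs=0.05)
        read_in_counts = ccd.read_noise_e / ccd.electrons_per_count
        # digitization adds 1/12 count^2 of quantization variance
        expected_sd = np.sqrt(read_in_counts**2 + 1.0 / 12.0)
        assert np.std(counts) == pytest.approx(expected_sd, rel=0.05)

    def test_binning_sums_electrons_with_single_read(self):
        """4x4 binning: 16x the per-pixel signal, one read-noise draw per bin."""
        ccd4 = CcdParameters(binning=4)
        signal = 2000.0
        img = DetectorImage(np.full((256, 256), signal), 1.0, units="electrons")
        out = apply_ccd_noise(img, ccd4, seed=1)
        electrons = (out.pixels - ccd4.bias_counts) * ccd4.electrons_per_count
        expected = 16.0 * (signal + ccd4.dark_current_e_per_s)
        assert np.mean(electrons) == pytest.approx(expected, rel=0.005)
        # variance: 16 x Poisson + one read draw (not 16 read draws)
        var = np.var(electrons)
        expected_var = expected + ccd4.read_noise_e**2
        assert var == pytest.approx(expected_var, rel=0.1)
        # brute-force per-pixel summation oracle for the deterministic part
        det = digitize(img, ccd4)
        np.testing.assert_allclose(
            det.pixels - ccd4.bias_counts,
            bin_pixels(img.pixels, 4) / ccd4.electrons_per_count,
            rtol=1e-12,
        )

    def test_counts_clipped_to_adc_range(self):
        ccd = CcdParameters()
        img = DetectorImage(np.full((8, 8), 1e9), 1.0, units="electrons")
        out = apply_ccd_noise(img, ccd, seed=0)
        assert out.pixels.max() <= ccd.adc_max


# --------------------------------------------------------------------------- #
# flat-field calibration
# --------------------------------------------------------------------------- #

class TestFlatFieldCalibration:
    REF = 3.0e-7  # W/cm^2/sr

    def test_vignetted_flat_calibrates_to_reference(self, poses):
        """Imaging the known-radiance source and calibrating the same frame
        recovers a uniform field at the reference radiance."""
        from mblt.acquisition import render_flat_field

        ccd = CcdParameters()
        cam = poses[0]
        flat_e = render_flat_field(cam, ccd, self.REF, 10.0)
        # the raw flat is vignetted ...
        assert flat_e.pixels.min() < 0.97 * flat_e.pixels.max()
        flats = [apply_ccd_noise(flat_e, ccd, seed=s) for s in (1, 2, 3)]
        calib = flat_field_calibrate(flats, self.REF, ccd)
        cal = apply_calibration(flats[0], calib, ccd)
        # ... but the calibrated frame is flat at the reference within noise
        assert np.median(cal.pixels) == pytest.approx(self.REF, rel=1e-3)
        assert np.std(cal.pixels) / self.REF < 0.01

    def test_ideal_camera_constant_gain(self):
        flats = [DetectorImage(np.full((32, 32), 1100.0), 10.0)]
        ccd = CcdParameters()
        calib = flat_field_calibrate(flats, self.REF, ccd)
        np.testing.assert_allclose(calib.gain, calib.gain.flat[0])
        assert len(calib.dead_pixels) == 0

    def test_dead_pixels_flagged(self):
        px = np.full((16, 16), 1100.0)
        px[3, 5] = 100.0  # bias only: zero rate
        calib = flat_field_calibrate(
            [DetectorImage(px, 10.0)], self.REF, CcdParameters()
        )
        assert [3, 5] in calib.dead_pixels.tolist()
        assert calib.gain[3, 5] == 0.0

    def test_calibration_round_trip(self):
        rng = np.random.default_rng(0)
        ccd = CcdParameters()
        calib = flat_field_calibrate(
            [DetectorImage(100.0 + rng.uniform(500, 1500, (32, 32)), 10.0)],
            self.REF, ccd,
        )
        img = DetectorImage(100.0 + rng.uniform(0, 4e4, (32, 32)), 60.0)
        back = undo_calibration(apply_calibration(img, calib, ccd), calib, ccd)
        np.testing.assert_allclose(back.pixels, img.pixels, rtol=1e-12)


class TestRadianceUnits:
    def test_watts_to_photons_at_560nm(self):
        img = DetectorImage(np.ones((4, 4)), 60.0, units=UNITS_W)
        out = radiance_units(img, 560.0, UNITS_PHOTONS)
        assert out.pixels[0, 0] == pytest.approx(2.81911e18, rel=1e-5)

    def test_round_trip_identity(self):
        img = DetectorImage(np.random.default_rng(1).uniform(0, 1e-6, (8, 8)), 60.0,
                            units=UNITS_W)
        back = radiance_units(radiance_units(img, 560.0, UNITS_PHOTONS), 560.0, UNITS_W)
        np.testing.assert_allclose(back.pixels, img.pixels, rtol=1e-12)

    def test_photon_rate_doubles_with_wavelength(self):
        assert photon_energy_J(560.0) == pytest.approx(2.0 * photon_energy_J(1120.0) * 0.5 * 2)
        img = DetectorImage(np.ones((2, 2)), 1.0, units=UNITS_W)
        a = radiance_units(img, 560.0, UNITS_PHOTONS).pixels[0, 0]
        b = radiance_units(img, 1120.0, UNITS_PHOTONS).pixels[0, 0]
        assert b / a == pytest.approx(2.0, rel=1e-12)

    def test_unknown_units_rejected(self):
        img = DetectorImage(np.ones((2, 2)), 1.0, units="counts")
        with pytest.raises(ValueError):
            radiance_units(img, 560.0, UNITS_PHOTONS)


# --------------------------------------------------------------------------- #
# end-to-end acquisition
# --------------------------------------------------------------------------- #

class TestSimulateAcquisition:
    def test_bit_reproducible_under_seed(self, phantom, lipid, poses):
        _, mesh, _ = phantom
        scene = SceneModel(mesh, lipid, [PointSource((10.0, 0.0, 0.0), POWER)])
        two = poses[:2]
        a = simulate_acquisition(scene, two, exposure_s=60.0, seed=7, noise=True)
        b = simulate_acquisition(scene, two, exposure_s=60.0, seed=7, noise=True)
        for ia, ib in zip(a.counts, b.counts):
            np.testing.assert_array_equal(ia.pixels, ib.pixels)

    def test_calibrated_images_exposure_invariant(self, phantom, lipid, poses):
        """Radiance is per-second: doubling the exposure leaves calibrated
        images unchanged (noiseless)."""
        _, mesh, _ = phantom
        scene = SceneModel(mesh, lipid, [PointSource((10.0, 0.0, 0.0), POWER)])
        one = poses[:1]
        a = simulate_acquisition(scene, one, exposure_s=30.0, noise=False)
        b = simulate_acquisition(scene, one, exposure_s=60.0, noise=False)
        np.testing.assert_allclose(
            a.images[0].pixels, b.images[0].pixels,
            rtol=1e-9, atol=1e-9 * a.images[0].pixels.max(),
        )

    def test_zero_exposure_noise_images_still_calibratable(self, phantom, lipid, poses):
        _, mesh, _ = phantom
        scene = SceneModel(mesh, lipid, [PointSource((10.0, 0.0, 0.0), POWER)])
        vs = simulate_acquisition(scene, poses[:1], exposure_s=0.0, noise=True, seed=3)
        assert np.isfinite(vs.counts[0].pixels).all()


class TestAngularCaptureProfile:
    def test_centered_source_flat_profile(self, phantom, lipid, poses):
        _, mesh, _ = phantom
        scene = SceneModel(mesh, lipid, [PointSource((0.0, 0.0, 0.0), POWER)])
        vs = simulate_acquisition(scene, poses, exposure_s=60.0, noise=False)
        prof = angular_capture_profile(vs)
        assert prof.total_light.max() / prof.total_light.min() < 1.001

    def test_offaxis_air_small_modulation(self, offaxis_air_views):
        """A bare source shows only the lens-distance modulation."""
        prof = angular_capture_profile(offaxis_air_views)
        assert 1.0 < prof.total_light.max() / prof.total_light.min() < 2.0

    def test_offaxis_lipid_order_of_magnitude_variation(self, offaxis_lipid_views):
        """Scattering turns the flat profile into a near order-of-magnitude swing."""
        prof = angular_capture_profile(offaxis_lipid_views)
        ratio = prof.total_light.max() / prof.total_light.min()
        assert ratio > 10.0**0.5  # at least half an order of magnitude
        # proximal views brightest: maximum at the view facing the source
        assert prof.loc[prof.total_light.idxmax(), "angle_deg"] in (0.0, 18.0, 342.0)


# --------------------------------------------------------------------------- #
# Monte-Carlo transport oracle
# --------------------------------------------------------------------------- #

def _mc_surface_exitance(src, medium, radius, half_h, n_photons, seed,
                         n_az=72, n_zbins=27):
    """Isotropic-scattering random walk with Fresnel boundary escape.

    Returns the escaping power per side-wall bin (azimuth x z in
    [-half_h/3, half_h/3]) as a fraction of the source power.
    """
    rng = np.random.default_rng(seed)
    mu_s = medium.mu_s_prime
    mu_a = medium.mu_a
    n_rel = medium.refractive_index

    pos = np.tile(np.asarray(src.position, float), (n_photons, 1))
    w = np.ones(n_photons)
    # isotropic directions
    def iso_dirs(n):
        u = rng.uniform(-1, 1, n)
        ph = rng.uniform(0, 2 * np.pi, n)
        s = np.sqrt(1 - u**2)
        return np.column_stack([s * np.cos(ph), s * np.sin(ph), u])

    d = iso_dirs(n_photons)
    tally = np.zeros((n_az, n_zbins))
    z_lim = half_h / 3.0

    for _ in range(600):
        if len(w) == 0:
            break
        step = rng.exponential(1.0 / mu_s, len(w))
        new = pos + d * step[:, None]
        out_r = np.einsum("ij,ij->i", new[:, :2], new[:, :2]) > radius**2
        out_z = np.abs(new[:, 2]) > half_h
        crossed = out_r | out_z
        # interior moves: absorb along the step and rescatter
        idx_in = ~crossed
        pos_in = new[idx_in]
        w_in = w[idx_in] * np.exp(-mu_a * step[idx_in])

        # boundary hits: find the crossing, transmit/reflect
        if np.any(crossed):
            p0, d0, s0, w0 = pos[crossed], d[crossed], step[crossed], w[crossed]
            # distance to the cylinder wall along d0
            a = d0[:, 0] ** 2 + d0[:, 1] ** 2
            b = 2 * (p0[:, 0] * d0[:, 0] + p0[:, 1] * d0[:, 1])
            c = p0[:, 0] ** 2 + p0[:, 1] ** 2 - radius**2
            disc = np.sqrt(np.maximum(b**2 - 4 * a * c, 0.0))
            t_wall = np.where(a > 0, (-b + disc) / np.maximum(2 * a, 1e-30), np.inf)
            with np.errstate(divide="ignore"):
                t_cap = np.where(
                    d0[:, 2] > 0, (half_h - p0[:, 2]) / d0[:, 2],
                    np.where(d0[:, 2] < 0, (-half_h - p0[:, 2]) / d0[:, 2], np.inf),
                )
            t_hit = np.minimum(t_wall, t_cap)
            hit = p0 + d0 * t_hit[:, None]
            wall = t_wall <= t_cap
            nrm = np.zeros_like(hit)
            nrm[wall, :2] = hit[wall, :2] / radius
            nrm[~wall, 2] = np.sign(hit[~wall, 2])
            cos_i = np.einsum("ij,ij->i", d0, nrm)
            refl = _fresnel_unpolarized(np.clip(cos_i, 0, 1), n_rel, 1.0)
            w_hit = w0 * np.exp(-mu_a * t_hit)
            w_escape = w_hit * (1.0 - refl)
            # tally side-wall escapes in the central band
            az = np.floor((np.arctan2(hit[:, 1], hit[:, 0]) % (2 * np.pi))
                          / (2 * np.pi) * n_az).astype(int)
            zb = np.floor((hit[:, 2] + z_lim) / (2 * z_lim) * n_zbins).astype(int)
            ok = wall & (zb >= 0) & (zb < n_zbins)
            np.add.at(tally, (az[ok] % n_az, zb[ok]), w_escape[ok])
            # specular reflection of the remaining weight
            d_ref = d0 - 2 * cos_i[:, None] * nrm
            pos_ref = hit - 1e-9 * nrm
            w_ref = w_hit * refl
            pos_in = np.concatenate([pos_in, pos_ref])
            w_in = np.concatenate([w_in, w_ref])

        # roulette
        keep = w_in > 1e-4
        lucky = (~keep) & (rng.uniform(size=len(w_in)) < 0.1)
        w_in = np.where(lucky, w_in * 10.0, w_in)
        sel = keep | lucky
        pos = pos_in[sel]
        w = w_in[sel]
        d = iso_dirs(len(w))

    return tally / n_photons, z_lim


class TestMonteCarloOracle:
    def test_angular_profile_matches_transport(self, phantom, lipid, poses):
        """Diffusion-rendered view totals track a 1e6-photon Monte-Carlo
        transport simulation within 10% of the peak."""
        from mblt.optics import boundary_exitance, surface_fluence

        src = PointSource((10.0, 0.0, 0.0), 1.0)
        radius, half_h = 15.0, 20.25
        n_az, n_zb = 72, 27
        tally, z_lim = _mc_surface_exitance(
            src, lipid, radius, half_h, n_photons=1_000_000, seed=2024,
            n_az=n_az, n_zbins=n_zb,
        )
        # surface bins as pseudo-patches
        az = (np.arange(n_az) + 0.5) / n_az * 2 * np.pi
        zc = -z_lim + (np.arange(n_zb) + 0.5) / n_zb * 2 * z_lim
        AZ, ZC = np.meshgrid(az, zc, indexing="ij")
        cent = np.stack([radius * np.cos(AZ), radius * np.sin(AZ), ZC], -1).reshape(-1, 3)
        nrm = np.stack([np.cos(AZ), np.sin(AZ), np.zeros_like(AZ)], -1).reshape(-1, 3)
        bin_area = (2 * np.pi * radius / n_az) * (2 * z_lim / n_zb)
        # Lambertian radiance from the MC escaping power per bin
        l_mc = tally.reshape(-1) / bin_area / np.pi
        # diffusion-model radiance at the same patches
        phi = surface_fluence(src, cent, nrm, lipid)
        l_diff = boundary_exitance(phi, lipid)

        def view_totals(l_vals):
            out = []
            for pose in poses:
                to_cam = np.asarray(pose.position) - cent
                dist = np.linalg.norm(to_cam, axis=1)
                cosv = np.clip(np.einsum("ij,ij->i", nrm, to_cam) / dist, 0, None)
                out.append(np.sum(l_vals * cosv * bin_area / dist**2))
            return np.asarray(out)

        mc = view_totals(l_mc)
        diff = view_totals(l_diff)
        mc_n = mc / mc.max()
        diff_n = diff / diff.max()
        assert np.max(np.abs(mc_n - diff_n)) < 0.10
        # both show the strong proximal/distal asymmetry
        assert mc_n.max() / mc_n.min() > 3.0
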