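"""Forward simulation of calibrated multi-view acquisitions.

The imaging chain mirrors a cooled, absolutely calibrated CCD camera:

    surface radiance -> photons through the lens aperture -> photoelectrons
    -> (shot noise, on-chip binning, read noise, 16-bit digitization)
    -> flat-field calibration back to absolute radiance units.

Rendering is triangle-driven: every visible surface triangle contributes
``L * area * cos(obliqueness) * aperture-solid-angle`` photons/s, deposited
on the detector as a small Gaussian footprint around its projected centroid.
For a transparent medium the bare source is imaged directly with
inverse-square falloff.  Flat-field calibration against a known-radiance
diffuse source inverts the whole radiometric chain per pixel (including the
cos^4 vignetting applied in rendering), so calibrated images are in absolute
units regardless of lens throughput.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import CameraPose, SurfaceMesh, surface_pixel_map
from .optics import OpticalMedium, PointSource, boundary_exitance, surface_fluence

__all__ = [
    "PLANCK_H",
    "SPEED_OF_LIGHT",
    "CcdParameters",
    "DetectorImage",
    "CalibrationMap",
    "SceneModel",
    "ViewSet",
    "photon_energy_J",
    "radiance_units",
    "vignette_map",
    "render_view",
    "render_flat_field",
    "apply_ccd_noise",
    "digitize",
    "bin_pixels",
    "flat_field_calibrate",
    "apply_calibration",
    "undo_calibration",
    "simulate_acquisition",
    "angular_capture_profile",
]

PLANCK_H = 6.62607015e-34  # J s
SPEED_OF_LIGHT = 2.99792458e8  # m/s

UNITS_ELECTRONS = "electrons"
UNITS_COUNTS = "counts"
UNITS_W = "W/cm^2/sr"
UNITS_PHOTONS = "photons/s/cm^2/sr"


def photon_energy_J(wavelength_nm: float) -> float:
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return PLANCK_H * SPEED_OF_LIGHT / (wavelength_nm * 1e-9)


@dataclass(frozen=True)
class CcdParameters:
    """Cooled scientific CCD: well capacity, noise terms and digitization.

    Defaults describe a back-illuminated 512x512 sensor with 24 um pixels:
    85% quantum efficiency at 560 nm, 350,000 e- full well, 2.6 uV/e-
    sensitivity, 5 e- RMS read noise, <0.1 e-/pixel/s dark current at the
    -50 C operating point and a 16-bit ADC.  The ADC maps the full well to
    full scale; a small bias offset keeps read noise representable.
    """

    quantum_efficiency: float = 0.85
    full_well_e: float = 350_000.0
    sensitivity_uV_per_e: float = 2.6
    read_noise_e: float = 5.0
    dark_current_e_per_s: float = 0.1
    adc_bits: int = 16
    binning: int = 1
    bias_counts: float = 100.0

    def __post_init__(self):
        if not (0.0 < self.quantum_efficiency <= 1.0):
            raise ValueError("quantum efficiency must be in (0, 1]")
        if self.binning not in (1, 2, 4, 8):
            raise ValueError("binning must be one of {1, 2, 4, 8}")

    @property
    def adc_max(self) -> int:
        return 2**self.adc_bits - 1

    @property
    def electrons_per_count(self) -> float:
        return self.full_well_e / self.adc_max


@dataclass
class DetectorImage:
    """Single-view detector frame with acquisition metadata."""

    pixels: np.ndarray
    exposure_s: float
    view_angle_deg: float = 0.0
    camera_id: int = 0
    units: str = UNITS_COUNTS

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("detector image must be 2-D")
        if self.exposure_s < 0:
            raise ValueError("exposure must be non-negative")

    def total(self) -> float:
        return float(self.pixels.sum())


@dataclass
class CalibrationMap:
    """Per-pixel gain converting bias-subtracted counts/s to W/cm^2/sr."""

    gain: np.ndarray
    reference_radiance_W: float
    dead_pixels: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=float)
        live = np.ones(self.gain.shape, dtype=bool)
        if len(self.dead_pixels):
            live[tuple(np.asarray(self.dead_pixels).T)] = False
        if np.any(self.gain[live] <= 0):
            raise ValueError("calibration gain must be strictly positive on live pixels")


@dataclass
class SceneModel:
    """Phantom surface, embedding medium and internal sources."""

    mesh: SurfaceMesh
    medium: OpticalMedium
    sources: list[PointSource]

    def __post_init__(self):
        if self.medium.turbid:
            pos = np.array([s.xyz for s in self.sources]) if self.sources else np.empty((0, 3))
            if len(pos) and not np.all(self.mesh.contains(pos)):
                raise ValueError("all sources must lie inside the mesh for a turbid medium")

    @property
    def wavelength_nm(self) -> float:
        return self.sources[0].wavelength_nm if self.sources else 560.0


@dataclass
class ViewSet:
    """Full multi-view acquisition: calibrated images + raw counts + metadata."""

    images: list[DetectorImage]          # calibrated, photons/s/cm^2/sr
    counts: list[DetectorImage]          # raw ADC counts
    poses: list[CameraPose]
    ccd: CcdParameters
    exposure_s: float
    calibrations: dict[int, CalibrationMap]
    wavelength_nm: float = 560.0
    ground_truth: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, indices) -> "ViewSet":
        idx = list(indices)
        return ViewSet(
            images=[self.images[i] for i in idx],
            counts=[self.counts[i] for i in idx],
            poses=[self.poses[i] for i in idx],
            ccd=self.ccd,
            exposure_s=self.exposure_s,
            calibrations=self.calibrations,
            wavelength_nm=self.wavelength_nm,
            ground_truth=dict(self.ground_truth),
        )


# --------------------------------------------------------------------------- #
# unit conversions
# --------------------------------------------------------------------------- #

def radiance_units(image: DetectorImage, wavelength_nm: float, to_units: str) -> DetectorImage:
    """Convert a calibrated image between W/cm^2/sr and photons/s/cm^2/sr."""
    e_ph = photon_energy_J(wavelength_nm)
    if image.units == to_units:
        return replace(image, pixels=image.pixels.copy())
    if image.units == UNITS_W and to_units == UNITS_PHOTONS:
        return replace(image, pixels=image.pixels / e_ph, units=UNITS_PHOTONS)
    if image.units == UNITS_PHOTONS and to_units == UNITS_W:
        return replace(image, pixels=image.pixels * e_ph, units=UNITS_W)
    raise ValueError(f"cannot convert units {image.units!r} -> {to_units!r}")


# --------------------------------------------------------------------------- #
# rendering
# --------------------------------------------------------------------------- #

def vignette_map(camera: CameraPose, binning: int = 1) -> np.ndarray:
    """cos^4 field-angle falloff over the (binned) pixel grid."""
    n_rows = camera.detector_pixels[0] // binning
    n_cols = camera.detector_pixels[1] // binning
    pitch = camera.pixel_pitch_mm * binning
    r = (np.arange(n_rows) - (n_rows - 1) / 2.0) * pitch
    c = (np.arange(n_cols) - (n_cols - 1) / 2.0) * pitch
    tan2 = (r[:, None] ** 2 + c[None, :] ** 2) / camera.image_distance_mm**2
    return 1.0 / (1.0 + tan2) ** 2


def _splat(image: np.ndarray, rows, cols, values, sigma_px, half: int = 7) -> None:
    """Deposit values as normalized Gaussian footprints (in place)."""
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    values = np.asarray(values, dtype=float)
    sigma = np.maximum(np.asarray(sigma_px, dtype=float), 0.6)
    n_rows, n_cols = image.shape
    r0 = np.round(rows).astype(int)
    c0 = np.round(cols).astype(int)
    off = np.arange(-half, half + 1)
    rr = r0[:, None] + off[None, :]  # (N, W)
    cc = c0[:, None] + off[None, :]
    dr = rr - rows[:, None]
    dc = cc - cols[:, None]
    s2 = 2.0 * sigma[:, None] ** 2
    wr = np.exp(-(dr**2) / s2)  # (N, W)
    wc = np.exp(-(dc**2) / s2)
    w = wr[:, :, None] * wc[:, None, :]  # (N, W, W)
    w /= w.sum(axis=(1, 2), keepdims=True)
    w *= values[:, None, None]
    rr = np.clip(rr, 0, n_rows - 1)
    cc = np.clip(cc, 0, n_cols - 1)
    flat = (rr[:, :, None] * n_cols + cc[:, None, :]).ravel()
    np.add.at(image.ravel(), flat, w.ravel())


def _bilinear_sample(image: np.ndarray, rows, cols) -> np.ndarray:
    """Bilinear interpolation with zero padding outside the frame."""
    n_rows, n_cols = image.shape
    r = np.asarray(rows, dtype=float)
    c = np.asarray(cols, dtype=float)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    fr = r - r0
    fc = c - c0
    out = np.zeros(r.shape, dtype=float)
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        ri, ci = r0 + dr, c0 + dc
        ok = (ri >= 0) & (ri < n_rows) & (ci >= 0) & (ci < n_cols)
        out[ok] += w[ok] * image[ri[ok], ci[ok]]
    return out


def render_view(
    scene: SceneModel,
    camera: CameraPose,
    exposure_s: float,
    ccd: CcdParameters | None = None,
) -> DetectorImage:
    """Noiseless expected photoelectron image at native detector resolution.

    Turbid media: diffusion fluence at each visible triangle -> boundary
    exitance -> etendue-weighted deposit.  Transparent media: direct
    line-of-sight imaging of the bare sources with inverse-square falloff.
    """
    ccd = ccd or CcdParameters()
    n_rows, n_cols = camera.detector_pixels
    image = np.zeros((n_rows, n_cols), dtype=float)
    vign = vignette_map(camera, binning=1)
    qe_t = ccd.quantum_efficiency * exposure_s

    if scene.medium.turbid:
        spm = surface_pixel_map(scene.mesh, camera, binning=1)
        if len(spm["face"]):
            cent = scene.mesh.face_centroids[spm["face"]]
            nrm = scene.mesh.face_normals[spm["face"]]
            phi = np.zeros(len(cent))
            for src in scene.sources:
                phi += surface_fluence(src, cent, nrm, scene.medium)
            radiance = boundary_exitance(phi, scene.medium)  # photons/s/mm^2/sr
            flux = radiance * spm["weight"]                  # photons/s into lens
            r_i = np.clip(np.round(spm["row"]).astype(int), 0, n_rows - 1)
            c_i = np.clip(np.round(spm["col"]).astype(int), 0, n_cols - 1)
            electrons = flux * qe_t * vign[r_i, c_i]
            # footprint size of the projected triangle, in native pixels
            size_obj = np.sqrt(scene.mesh.face_areas[spm["face"]] * spm["cos"])
            size_px = size_obj * camera.image_distance_mm / (spm["depth"] * camera.pixel_pitch_mm)
            _splat(image, spm["row"], spm["col"], electrons, 0.5 * size_px)
    else:
        cam_pos = np.asarray(camera.position)
        for src in scene.sources:
            rows, cols, depth = camera.project(src.xyz[None, :], binning=1)
            if depth[0] <= 0:
                continue
            d2 = float(np.sum((src.xyz - cam_pos) ** 2))
            flux = src.power * camera.aperture_area_mm2 / (4.0 * np.pi * d2)
            r, c = float(rows[0]), float(cols[0])
            if -0.5 < r < n_rows - 0.5 and -0.5 < c < n_cols - 0.5:
                ri = int(np.clip(round(r), 0, n_rows - 1))
                ci = int(np.clip(round(c), 0, n_cols - 1))
                electrons = flux * qe_t * vign[ri, ci]
                # small Gaussian spot (optics are not perfectly stigmatic)
                _splat(image, np.array([r]), np.array([c]), np.array([electrons]),
                       np.array([1.0]), half=5)

    return DetectorImage(image, exposure_s, camera.view_angle_deg, camera.camera_id,
                         units=UNITS_ELECTRONS)


def render_flat_field(
    camera: CameraPose,
    ccd: CcdParameters,
    reference_radiance_W: float,
    exposure_s: float,
    wavelength_nm: float = 560.0,
) -> DetectorImage:
    """Expected electrons from imaging a uniform source of known radiance.

    The flat source fills the field of view at the focus distance, so every
    pixel sees the same radiance through the fixed per-pixel etendue
    ``(pitch/v)^2 * aperture_area`` (times vignetting).
    """
    radiance_ph_mm2 = reference_radiance_W / photon_energy_J(wavelength_nm) / 100.0
    etendue = (camera.pixel_pitch_mm / camera.image_distance_mm) ** 2 * camera.aperture_area_mm2
    vign = vignette_map(camera, binning=1)
    e = radiance_ph_mm2 * etendue * ccd.quantum_efficiency * exposure_s * vign
    return DetectorImage(e, exposure_s, camera.view_angle_deg, camera.camera_id,
                         units=UNITS_ELECTRONS)


# --------------------------------------------------------------------------- #
# CCD noise chain and digitization
# --------------------------------------------------------------------------- #

def bin_pixels(arr: np.ndarray, binning: int) -> np.ndarray:
    """Sum-bin an array by an integer factor along both axes."""
    if binning == 1:
        return arr
    n_rows, n_cols = arr.shape
    if n_rows % binning or n_cols % binning:
        raise ValueError("image shape not divisible by the binning factor")
    return arr.reshape(n_rows // binning, binning, n_cols // binning, binning).sum(axis=(1, 3))


def apply_ccd_noise(image: DetectorImage, ccd: CcdParameters, seed=None) -> DetectorImage:
    """Stochastic CCD chain: shot noise, binning, read noise, digitization.

    Order follows CCD physics: Poisson shot noise on signal + dark charge,
    per-pixel full-well clipping, on-chip binning (electron sum), one read
    noise draw per binned pixel, then 16-bit digitization with a bias offset.
    """
    if image.units != UNITS_ELECTRONS:
        raise ValueError("apply_ccd_noise expects an image in expected-electron units")
    rng = np.random.default_rng(seed)
    expected = image.pixels + ccd.dark_current_e_per_s * image.exposure_s
    electrons = rng.poisson(expected).astype(float)
    electrons = np.minimum(electrons, ccd.full_well_e)
    binned = bin_pixels(electrons, ccd.binning)
    binned = binned + rng.normal(0.0, ccd.read_noise_e, size=binned.shape)
    counts = np.round(binned / ccd.electrons_per_count + ccd.bias_counts)
    counts = np.clip(counts, 0, ccd.adc_max)
    return replace(image, pixels=counts, units=UNITS_COUNTS)


def digitize(image: DetectorImage, ccd: CcdParameters) -> DetectorImage:
    """Deterministic (noiseless) binning + count conversion.

    Keeps counts as floats and skips clipping/rounding so the noiseless
    pipeline stays exactly linear; the stochastic path lives in
    :func:`apply_ccd_noise`.
    """
    if image.units != UNITS_ELECTRONS:
        raise ValueError("digitize expects an image in expected-electron units")
    binned = bin_pixels(image.pixels, ccd.binning)
    counts = binned / ccd.electrons_per_count + ccd.bias_counts
    return replace(image, pixels=counts, units=UNITS_COUNTS)


# --------------------------------------------------------------------------- #
# flat-field calibration
# --------------------------------------------------------------------------- #

def flat_field_calibrate(
    flat_images: list[DetectorImage],
    reference_radiance_W: float,
    ccd: CcdParameters,
) -> CalibrationMap:
    """Per-pixel gain from flats acquired at a known uniform radiance.

    gain = reference_radiance / mean(bias-subtracted counts per second);
    pixels with non-positive mean are flagged dead and excluded.
    """
    if not flat_images:
        raise ValueError("need at least one flat-field image")
    if reference_radiance_W <= 0:
        raise ValueError("reference radiance must be positive")
    rate = np.mean(
        [(f.pixels - ccd.bias_counts) / f.exposure_s for f in flat_images], axis=0
    )
    dead = np.argwhere(rate <= 0)
    gain = np.zeros_like(rate)
    live = rate > 0
    gain[live] = reference_radiance_W / rate[live]
    return CalibrationMap(gain=gain, reference_radiance_W=reference_radiance_W, dead_pixels=dead)


def apply_calibration(image: DetectorImage, calib: CalibrationMap, ccd: CcdParameters) -> DetectorImage:
    """Counts -> absolute radiance (W/cm^2/sr); dead pixels map to zero.

    A zero-exposure frame carries no radiance information: the calibration
    map stays valid but the calibrated image is identically zero.
    """
    if image.units != UNITS_COUNTS:
        raise ValueError("calibration expects an image in ADC counts")
    if image.exposure_s <= 0:
        warnings.warn("zero exposure: calibrated radiance undefined, returning zeros")
        return replace(image, pixels=np.zeros_like(image.pixels), units=UNITS_W)
    cal = (image.pixels - ccd.bias_counts) / image.exposure_s * calib.gain
    return replace(image, pixels=cal, units=UNITS_W)


def undo_calibration(image: DetectorImage, calib: CalibrationMap, ccd: CcdParameters) -> DetectorImage:
    """Inverse of :func:`apply_calibration` on live pixels (round-trip identity)."""
    if image.units != UNITS_W:
        raise ValueError("undo_calibration expects W/cm^2/sr")
    counts = np.zeros_like(image.pixels)
    live = calib.gain > 0
    counts[live] = image.pixels[live] / calib.gain[live] * image.exposure_s + ccd.bias_counts
    return replace(image, pixels=counts, units=UNITS_COUNTS)


# --------------------------------------------------------------------------- #
# end-to-end acquisition
# --------------------------------------------------------------------------- #

def simulate_acquisition(
    scene: SceneModel,
    poses: list[CameraPose],
    ccd: CcdParameters | None = None,
    exposure_s: float = 60.0,
    seed=None,
    noise: bool = True,
    reference_radiance_W: float = 3.0e-7,
    n_flats: int = 3,
    flat_exposure_s: float = 60.0,
) -> ViewSet:
    """Render -> CCD -> flat-field-calibrate every view of a gantry rotation.

    Calibrated images are returned in photons/s/cm^2/sr at the binned
    resolution; the exact ground truth (source positions and powers) rides
    along in ``ground_truth``.  With ``noise=False`` the chain is fully
    deterministic and exactly linear in source power.
    """
    ccd = ccd or CcdParameters()
    rng = np.random.default_rng(seed)

    # one calibration per physical camera, from simulated flats
    calibrations: dict[int, CalibrationMap] = {}
    for pose in poses:
        if pose.camera_id in calibrations:
            continue
        flats = []
        for _ in range(n_flats):
            flat_e = render_flat_field(pose, ccd, reference_radiance_W, flat_exposure_s,
                                       scene.wavelength_nm)
            if noise:
                flats.append(apply_ccd_noise(flat_e, ccd, seed=rng.integers(2**31)))
            else:
                flats.append(digitize(flat_e, ccd))
        calibrations[pose.camera_id] = flat_field_calibrate(flats, reference_radiance_W, ccd)

    images, counts = [], []
    for pose in poses:
        electrons = render_view(scene, pose, exposure_s, ccd)
        if noise:
            raw = apply_ccd_noise(electrons, ccd, seed=rng.integers(2**31))
        else:
            raw = digitize(electrons, ccd)
        cal = apply_calibration(raw, calibrations[pose.camera_id], ccd)
        cal = radiance_units(cal, scene.wavelength_nm, UNITS_PHOTONS)
        counts.append(raw)
        images.append(cal)

    gt = {
        "source_positions_mm": [list(s.position) for s in scene.sources],
        "source_powers_photons_per_s": [s.power for s in scene.sources],
        "wavelength_nm": scene.wavelength_nm,
        "medium": scene.medium.name or "custom",
        "mu_a": scene.medium.mu_a,
        "mu_s_prime": scene.medium.mu_s_prime,
        "refractive_index": scene.medium.refractive_index,
        "turbid": scene.medium.turbid,
    }
    return ViewSet(images=images, counts=counts, poses=poses, ccd=ccd,
                   exposure_s=exposure_s, calibrations=calibrations,
                   wavelength_nm=scene.wavelength_nm, ground_truth=gt)


def angular_capture_profile(views: ViewSet) -> pd.DataFrame:
    """Total captured light per view angle (sum of calibrated pixel values)."""
    if len(views) == 0:
        raise ValueError("need at least one view")
    rows = [
        {"angle_deg": img.view_angle_deg, "total_light": img.total(),
         "units": img.units}
        for img in views.images
    ]
    return pd.DataFrame(rows).sort_values("angle_deg").reset_index(drop=True)
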