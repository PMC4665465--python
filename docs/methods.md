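# Methods

`mblt` simulates and inverts multi-view bioluminescence acquisitions of
point-like light sources embedded in a homogeneous turbid cylinder. This
note records the physical model, the numerical choices behind it, and what
the in-silico experiments can and cannot demonstrate.

## Photon transport model

Light transport in the highly scattering medium is treated in the
steady-state diffusion approximation,

```
D ∇²φ(x) − μ_a φ(x) = −S(x),      D = 1 / (3 (μ_a + μ_s′)),
μ_eff = sqrt(μ_a / D) = sqrt(3 μ_a (μ_a + μ_s′)),
```

with fluence rate φ (photons/s/mm²), absorption coefficient μ_a (1/mm),
reduced scattering coefficient μ_s′ (1/mm) and diffusion coefficient D
(mm). A point source of power S photons/s in an unbounded medium produces
the Green's-function fluence `φ(r) = S exp(−μ_eff r) / (4π D r)`; this is
what `point_source_fluence` evaluates and what the reconstruction uses as
its interior-fluence kernel.

**Boundary treatment.** At the phantom wall two corrections are applied,
both derived from the partial-current (effective reflection coefficient)
framework and both validated against an independent Monte-Carlo photon
transport simulation (isotropic scattering at μ_s′, per-angle Fresnel
boundary escape, 10⁶ photons — see `tests/test_acquisition.py`):

1. *Extrapolated-boundary image correction.* The infinite-medium Green's
   function over-fills the region near the wall, where photons escape
   rather than diffuse back. The fluence reaching a surface patch is
   therefore evaluated as `K = G(r) − G(r_img)`, where the negative image
   sits mirrored across the extrapolated boundary a distance
   `z_b = 2D(1+R_eff)/(1−R_eff)` outside the local tangent plane
   (`r_img² = r² + 4 z_b (d + z_b)`, d = source depth below the plane).
   Without the image term the simulated angular capture profile deviates
   from Monte-Carlo transport by 11% of peak; with it, by 5%.
2. *Exitance.* With the extrapolated boundary condition `φ = z_b ∂φ/∂n`,
   the escaping flux is `J = D φ / z_b = φ (1−R_eff) / (2 (1+R_eff))`,
   emitted with a Lambertian angular law (radiance L = J/π). The
   Monte-Carlo oracle measures 0.9× this constant, confirming the factor.
   R_eff is computed from the angular Fresnel integrals of the diffuse
   intensity by numerical quadrature; for the n = 1.34 gel against air,
   R_eff ≈ 0.44 and z_b ≈ 1.71 mm.

A transparent medium ("air") bypasses all of this: the bare source is
imaged directly with inverse-square falloff.

**Default media.** 1% Intralipid/agarose gel at 560 nm is modelled with
μ_s′ = 1.0 /mm, μ_a = 0.002 /mm, n = 1.34 — standard values for this
widely used tissue-mimicking phantom, which scatters strongly but absorbs
very little. All media are config-exposed; a registry ships `air`,
`intralipid_1pct_560nm` and `soft_tissue_generic`.

## Camera and radiometric chain

Twenty views at 18° steps are produced by four cameras rotating through
five stops about the +z axis (modelled as camera motion about a fixed
scene; by reciprocity this equals rotating the phantom). Each camera is a
thin-lens perspective device: 25 mm focal length, f/0.95, 512×512 pixels
of 24 µm, focused on the rotation axis. The standoff (115 mm) is chosen so
the 30 mm phantom fills about two thirds of the 44 mm field of view.

Rendering is triangle-driven: each visible surface triangle contributes
`L · area · cosθ · A_aperture/d²` photons/s (radiance × étendue), times
quantum efficiency and exposure, deposited as a small Gaussian footprint
around its projected centroid. Visibility is back-face culling (exact for
the convex cylinder) with a brute-force ray-cast fallback for non-convex
meshes. A cos⁴ field-angle vignetting is applied, and removed again by
calibration.

The CCD chain follows the physical signal path: Poisson shot noise on
signal + dark charge (0.1 e−/pixel/s), full-well clipping (350,000 e−),
on-chip binning (electron sum), one 5 e− RMS read-noise draw per binned
pixel, then 16-bit digitization (full well mapped to full scale, small
bias offset). The noiseless path keeps float counts and skips clipping so
it is exactly linear — the property the quantitative tests rely on.

Flat-field calibration images a uniform source of known radiance
(3.0×10⁻⁷ W/cm²/sr) through the same chain; the per-pixel gain
`reference / mean(counts/s)` converts science frames to absolute radiance,
absorbing lens throughput, vignetting and pixel-sensitivity variations.
Calibrated frames are carried in photons/s/cm²/sr (`hc/λ` converts to
W/cm²/sr).

## Reconstruction

Three steps, run by `reconstruct`:

1. **Backprojection initialization.** Calibrated radiances are sampled at
   a few hundred side-wall patches (each averaged over the views that see
   it at cosθ > 0.25) and inverted to surface fluences. Every interior
   voxel then accumulates `fluence / K(voxel → patch)` — the detected
   intensity weighted by the attenuation-compensating inverse of the
   surface kernel — and keeps a low quantile (q = 0.05) across patches.
   For consistent single-source data this field peaks at the true source:
   the quantile acts as a consistency test ("what source power at this
   voxel is compatible with *every* patch?").
2. **Data-consistency refinement and initial fluence.** The estimate is
   refined against the measured/predicted surface-intensity ratios
   (p_t/p_o): candidate source voxels are grown greedily (new candidates
   where a unit source best absorbs the residual), powers are refit by
   non-negative least squares, and positions are polished by
   26-neighborhood single-voxel moves until the residual stops improving.
   The initial fluence is then `φ⁰_j = Σ_i S_i G(r_ij)` with the
   Green's-function self-term regularized over a voxel-volume-equivalent
   sphere (r_min = 0.62 · voxel).

   *Why not a one-shot estimate?* The surface data of two symmetric
   sources are better explained — in the single-source consistency sense —
   by one stronger source between them: the quantile field of step 1 peaks
   at the midpoint for a symmetric pair, and no volumetric Gaussian
   deconvolution of the resulting φ⁰ can re-separate what the estimate has
   already merged. Depth is equally fragile: an unregularized voxel-wise
   EM fit drifts toward surface-layer solutions, because a positive single
   layer just inside the wall can mimic the boundary signature of any
   deeper source (the classic non-uniqueness of the inverse source
   problem). The greedy consistency fit resolves both failure modes for
   the point-like sources this instrument targets, while remaining driven
   by the same p_t/p_o ratio weights.
3. **Iterative Gaussian EM deblurring.** Multiplicative Richardson–Lucy
   updates `φ^{n+1} = φ^n · [(φ⁰ / (φ^n ⊗ ϱ)) ⊗ ϱ̂]` sharpen φ⁰ into the
   final source map, with ϱ a unit-sum isotropic Gaussian (σ = 1.5 mm ≈ 3
   voxels, truncated at 3σ) and ϱ̂ its mirror. The 0/0 ratio is defined as
   0. Near the grid boundary the back-step is renormalized by the kernel
   mass remaining on the grid, which suppresses the edge amplification of
   truncated multiplicative deconvolution; in the interior the update is
   the textbook one, so total intensity is conserved for interior-
   supported data (checked to 1e−6 over 100 iterations). Iterations stop
   at 200 or when the L1 relative change drops below 1e−4; non-convergence
   flags the result rather than raising.

**Absolute scale.** The refined estimate is re-projected through the full
forward model (render → CCD → calibration, noiseless) and scaled so the
predicted total detected light matches the measurement; the final map is
expressed in photons/s at that scale. Because measurement and prediction
share one forward code path, radiometric approximations cancel — this is
what makes the air-vs-Intralipid total-power comparison meaningful.

**Peak readout.** Local maxima (26-connectivity, lexicographic tie-break
on plateaus) above a fraction of the global maximum are greedily separated
by a minimum distance; positions are refined per axis by 3-point parabolic
interpolation to sub-voxel precision (raw-voxel mode available).

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| μ_s′, μ_a, n | 1.0 /mm, 0.002 /mm, 1.34 | 1% Intralipid at 560 nm |
| voxel size | 0.5 mm | reconstruction grid resolution |
| phantom | 30 mm ⌀ × 40.5 mm | height chosen so cap planes tile voxel layers and z = 0 is a voxel center |
| views / step | 20 / 18° | full gantry rotation |
| exposure | 60 s (30 s for bright noisy runs) | per angular position |
| source power | 1.4×10¹⁰ photons/s | order of the phantom-experiment totals; 1.98×10⁸ for the cell-like weak-source preset (10⁶ cells × 198 photons/s/cell) |
| σ (deblurring) | 1.5 mm | Gaussian kernel width, ≈3 voxels |
| max_iter / tol | 200 / 1e−4 | RL stopping rule |
| n_surface_samples | 500 | wall patches used by steps 1–2; shallow sources (<4 mm deep) need ≥400 |
| backprojection quantile | 0.05 | robustness of the consistency field |
| max_sources | 6 | greedy candidate budget |

Reconstruction defaults are tuned on, and config-exposed for, the packaged
phantom experiments; the preset runs crop the volume to |z| ≤ 8 mm around
the source plane (65×65×33 voxels), and the repeated-recovery tests use
lighter settings (25 RL iterations, 400 wall samples, no absolute
rescaling) since they only assess localization.

## What the synthetic data do and do not emulate

The simulator reproduces: absolutely calibrated multi-camera geometry,
diffusion-regime surface radiance of embedded point sources with
index-mismatched boundary loss, the full CCD noise chain, flat-field
calibration, and the strong view-angle asymmetry of off-axis sources (the
simulated Intralipid profile swings ~8× over the rotation and captures up
to ~2.6× more light than the bare source at proximal views; transport
truth for these optical parameters, not a fitted number).

It does **not** emulate: heterogeneous or absorbing tissue, spectrally
resolved attenuation, luciferin kinetics beyond an optional global power
scale, animal surfaces (meshes are analytic), ambient light leaks,
cosmic-ray hits, or detector nonlinearity. Passing tests therefore
demonstrate correctness of the method under its own physical model and
robustness to its own noise chain — not performance on live-animal data,
where model mismatch (unknown optical properties, non-convex surfaces)
dominates.

The degeneracy demonstration is the designed reminder of the inherent
limitation: a deep symmetric source pair a few millimetres apart produces
surface data within <1% RMS of a single stronger on-axis source, so no
surface-based algorithm can distinguish them. This is a property of the
physics, not an implementation defect.

## Known limitations

- The source model is sparse (point-like candidates); extended diffuse
  emitters are represented by a few atoms and their recovered shape is not
  meaningful below the deblurring width.
- Absolute exitance is accurate to ~10% against transport; quantitation
  relies on the data-consistency rescaling rather than on the absolute
  constant.
- The local-plane image correction degrades for sources within ~1 mm of a
  strongly curved boundary.
- Localization tolerances are stated for sources ≥3 mm inside the wall;
  shallower sources need denser wall sampling than the defaults.
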