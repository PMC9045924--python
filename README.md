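# desmoke

Polarization-difference smoke removal for surgical images, together with the
physics tooling that motivates it: Mie scattering of smoke particles, a
polarized (Stokes-vector) Monte Carlo simulation of a smoke slab over
tissue, a forward degradation model used as a synthetic-data generator, and
a polarimetric/colorimetric evaluation suite.

The imaging model treats the smoke-degraded radiance per pixel, color
channel and polarization channel as

    I = J * exp(-u) + A * (1 - exp(-u))

where `u` is the optical thickness of the local smoke column, `A` the
ambient ("airlight") radiance of an infinitely thick smoke layer, and `J`
the smoke-free radiance. Subtracting the cross-polarized from the
co-polarized channel cancels the (depolarized) object term, giving the
transmission per color channel

    t = 1 - (Ico - Icro) / Aco

and the restored image `J = 2*(Icro - Acro)/t + 2*Acro`. The co-channel
airlight `Aco` is estimated from the image itself by haze-line Hough voting
over 64 quantized colors.

## Layout

| module                 | contents |
|------------------------|----------|
| `desmoke.mie`          | Mie series (efficiencies, anisotropy, S11/S12/S33/S34 phase tables), Gaussian polydisperse populations |
| `desmoke.montecarlo`   | meridian-plane Stokes Monte Carlo: smoke slab over a Fresnel + depolarizing-Lambertian tissue, co/cross detector grids |
| `desmoke.forward`      | synthetic scenes, optical-depth maps, the forward degradation model (ground truth generator) |
| `desmoke.pipeline`     | airlight estimation, polarization difference, per-channel transmission, reconstruction |
| `desmoke.metrics`      | degree of polarization, PSNR, SSIM, CIEDE2000, combined evaluation reports |
| `desmoke.io` / `.cli`  | PNG/TIFF I/O, provenance sidecars, the `desmoke` command |

## CLI

```sh
# synthetic ground-truth/degraded pair with JSON sidecar
desmoke synth --kind checker --dop 0.0 --smoke-level 1.5 \
    --smoke-kind multiscale-noise --seed 7 --out scene/

# smoke removal (airlights estimated unless supplied)
desmoke run --co scene/degraded_co.png --cross scene/degraded_cross.png \
    --out restored.png --save-transmission t.tiff

# quantitative evaluation, optionally with DOP of co/cross pairs
desmoke eval --ref scene/truth_co.png --test restored.png --report report.json

# single-sphere Mie properties
desmoke mie --diameter 0.2 --wavelength 0.63 --m 1.57 --density 2e-3

# polarized Monte Carlo from a TOML config
desmoke simulate-mc mc.toml --out mc_out/ --seed 1
```

`simulate-mc` expects sections `[medium]` (`diameter_um`, `wavelength_um`,
`particle_index_re`, `mu_s`, `mu_a`, `tissue_albedo`, …), `[detector]`
(`heights_cm`, `extent_cm`, `bins`) and `[run]` (`n_photons`, `seed`); see
`desmoke simulate-mc --help`.

## Refractive-index convention

The smoke-particle refractive index is quoted in the source material as
1.57+0.4277i, yet the tabulated anisotropy/scattering values are those of a
*non-absorbing* sphere with m = 1.57 in air — consistent with the table
listing a separate, small absorption coefficient (0.0100 cm⁻¹), which
would be impossible for particles absorbing with k = 0.4277. `compute_mie`
implements the full complex-index physics (validated against an
independent high-precision Bessel-function oracle); reproduction of the
tabulated values passes the real part, and that convention is used by the
acceptance layer.

## Conventions and defaults

- Images are linear radiance in [0, 1]; no gamma decoding by default
  (`--srgb-decode` opts in). 8-bit PNG, 16-bit TIFF, 32-bit float TIFF.
- Transmission is clamped to `[t_min, 1]`, `t_min = 0.05` (`--tmin`).
- Negative polarization differences are clamped to zero.
- Masked SSIM is evaluated on the bounding-box crop of the mask; PSNR and
  CIEDE2000 select masked pixels exactly.
- PSNR of identical images reports a 100 dB cap.
- Every CLI run writes a `provenance.json` beside its outputs recording the
  resolved configuration and seed.
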