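# musical-sr

Subspace super-resolution for blinking-fluorophore image stacks.

Wide-field fluorescence microscopy cannot resolve structure below the Abbe
limit λ/(2NA) ≈ 200 nm in a single image — but a *time series* of images of
blinking fluorophores carries more information: each frame is a different
random superposition of the same per-emitter PSFs, so the stack's
second-order statistics encode emitter positions at much finer scales.
This package reconstructs that structure with a MUSIC-type subspace
algorithm, without requiring sparse blinking, special fluorophores, or long
acquisitions, making it suitable for live-cell stacks as short as ~50
frames. It is aimed at microscopists and method developers who want a
tested, scriptable reference implementation with a matching synthetic-data
generator, so every stage is verifiable without experimental data.

## Algorithm

For each sliding N_w × N_w soft window (default 7 × 7, N = 49 pixels) of
the K-frame stack:

1. **Eigenimages.** The N × K window matrix G is factored by SVD,
   G = U Σ Vᵀ. Columns of U are eigenimages; singular values rank how
   prominently each pattern recurs over time.
2. **Subspace split.** Eigenimages with σᵢ ≥ σ₀ form the signal subspace
   (the range); the rest form the null subspace (noise). By default
   σ₀ = 0.02 σ₁ per window.
3. **Projection.** For each test point **r** on a subpixel grid, the unit
   steering vector **a**(**r**) — the PSF sampled over the window's pixels
   for a hypothetical emitter at **r** — is projected onto both subspaces:
   d_PR(**r**) and d_PN(**r**).
4. **Indicator.** f(**r**) = (d_PR/d_PN)^α (default α = 4). d_PN → 0
   exactly where an emitter could sit; d_PR in the numerator down-weights
   windows with no signal at **r**.
5. **Stitching.** The final map at each test point is the sum of f over all
   windows covering it.

The PSF is an Airy disk [2 J₁(v)/v]², v = 2π·NA·r/λ (or an FWHM-matched
Gaussian), parameterized by NA, emission wavelength, and pixel size.

## Worked example

Two emitters 50 nm apart — a quarter of the diffraction FWHM — blinking
independently with p_on = 0.2 over 500 frames at signal-to-background 10:

```python
import warnings
from musical_sr import (PSFModel, make_pair_scene, calibrate_brightness,
                        simulate_stack, run_musical, sample_line_profile,
                        two_peak_contrast, psf_fwhm)

psf = PSFModel("airy", numerical_aperture=1.49,
               emission_wavelength=593.0, pixel_size=65.0)
print(f"diffraction FWHM: {psf_fwhm(psf):.1f} nm")

scene = calibrate_brightness(
    make_pair_scene(50.0, psf, image_shape=(15, 15), p_on=0.2, background=10.0),
    target_sbr=10.0,
)
sim = simulate_stack(scene, n_frames=500, noise="poisson", seed=2)
m = run_musical(sim.stack, psf, n_w=7, alpha=4.0,
                sigma0_rule="rel:0.02", subpixel_factor=20)
print(f"map: {m.grid.shape[0]}x{m.grid.shape[1]} at {m.pixel_size_out:.2f} nm/cell")

row = (7 + 0.5) * 20 - 0.5                    # the emitters' row on the output grid
prof = sample_line_profile(m, (row, 92), (row, 206), 300)
contrast, resolved = two_peak_contrast(prof)
print(f"two-peak contrast: {contrast:.2f} (resolved={resolved})")
```

Output:

```
diffraction FWHM: 204.8 nm
map: 300x300 at 3.25 nm/cell
two-peak contrast: 0.38 (resolved=True)
```

The diffraction-limited PSF is 204.8 nm wide, so the mean image shows a
single blob; the reconstructed 3.25 nm-per-cell map separates the two
emitters with a clear dip between them (contrast 0.38 on the 0–1 Michelson
scale: (mean peak − dip)/(mean peak + dip)).

## Command line

```
musical simulate --output stack.tif --scene pair --separation-nm 50 \
    --frames 500 --sbr 10 --seed 1
musical run --input stack.tif --pixel-size-nm 65 --na 1.49 --wavelength-nm 593 \
    --window 7 --alpha 4 --sigma0 rel:0.02 --subpixel 20 --output map.tif
musical analyze fwhm --map map.tif --start 149.5 92 --end 149.5 206
musical psf --na 1.49 --wavelength-nm 512 --pixel-size-nm 65
```

`musical run` writes a float32 TIFF plus a JSON sidecar recording every
parameter; `musical simulate` writes the stack with ground-truth emitter
positions and the blink matrix as CSV sidecars. An optional intensity floor
(`--threshold 0.4:99.9`) suppresses diffuse background, useful for
live-cell stacks with freely diffusing label.

## Layout

- `src/musical_sr/psf.py` — Airy/Gaussian PSF models, steering vectors, FWHM
- `src/musical_sr/simulate.py` — synthetic blinking scenes and stacks
- `src/musical_sr/core.py` — eigenimages, subspace split, indicator, stitching
- `src/musical_sr/profiles.py` — line profiles, FWHM, contrast, periodicity
- `src/musical_sr/io.py`, `cli.py` — TIFF/config I/O and the `musical` CLI
- `docs/methods.md` — model assumptions, parameter rationale, limitations
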