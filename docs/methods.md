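# Methods

## Model and procedure

The reconstruction operates on a stack of K wide-field fluorescence frames
of a fixed field of view in which point emitters switch stochastically
between a bright and a dark state, with the switching of any two emitters
statistically independent. Each frame is a different random superposition
of the same spatial patterns — the PSFs of the emitters plus background —
so the second-order statistics of the stack encode the emitter geometry at
scales well below the diffraction limit.

For each N_w × N_w "soft" window of pixels (N = N_w² pixels), the window's
pixels × frames data matrix G (N × K) is factored by singular value
decomposition. The left singular vectors are the window's *eigenimages*;
a large singular value marks a statistically prominent pattern. A threshold
σ₀ splits the basis into a **signal subspace** (σᵢ ≥ σ₀, the "range") and a
**null subspace** (the rest, dominated by noise). For a test point **r** on
a subpixel grid, the PSF *steering vector* — the unit-normalized PSF sampled
at the window's pixel centers as if an emitter sat at **r** — is projected
onto both subspaces, giving d_PR(**r**) and d_PN(**r**). The per-window
indicator is

    f(r) = ( d_PR(r) / d_PN(r) )^α

which diverges where the steering vector is orthogonal to every noise
pattern (an emitter-consistent point) and is small elsewhere. Because d_PR
in the numerator automatically down-weights windows that carry no signal at
**r**, overlapping sliding windows (stride 1 pixel) are stitched by simply
summing their indicators at each test point. A `traditional_music` mode
(1/d_PN, α = 1) gives the classic pseudospectrum for comparison.

### Rank and frame count

rank(G) ≤ min(N, K). With K < N the stack cannot populate all N pixel-space
directions; the implementation completes the thin-SVD basis with an
orthonormal complement at σ = 0 (assigned to the null set), which preserves
d_PR² + d_PN² = 1 for unit steering vectors, and warns that K ≥ N is the
desirable operating regime (K ≥ 49 for the default N_w = 7).

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `na` | 1.49 | — | numerical aperture of the objective |
| `wavelength_nm` | 593 | nm | emission wavelength |
| `pixel_size_nm` | 65 | nm | sample-plane camera pixel (6.5 µm / 100×) |
| `n_w` | 7 | px | window side; chosen so one window spans ≈ 2 PSF FWHM |
| `alpha` | 4 | — | indicator exponent; larger sharpens peaks non-linearly |
| `sigma0_rule` | `rel:0.02` | — | σ₀ = 0.02 σ₁ per window; `abs:<v>` also accepted |
| `subpixel_factor` | 10 | — | test points per pixel side (output grid) |
| `min_null_fraction` | 0.1 | — | smallest informative null subspace, as a fraction of N |
| `threshold` | off (0.4, 99.9) | — | optional floor: zero values below 0.4 × the 99.9th-percentile intensity |

The PSF is the in-focus Airy intensity pattern [2 J₁(v)/v]² with
v = 2π·NA·r/λ (FWHM ≈ 0.5145 λ/NA: 176.8 nm at 512 nm emission, 204.8 nm at
593 nm), point-sampled at pixel centers; a FWHM-matched Gaussian is
available. Off-focus structure is not modelled: the intended acquisition
geometry is TIRF, whose ~110 nm evanescent excitation depth keeps emitters
near focus.

## Numerical choices

- **σ₀ rule.** The default is per-window relative (τ = 0.02 of the window's
  σ₁), adapting to local brightness; an absolute σ₀ can be supplied when a
  global choice from a singular-value plot is preferred.
- **Division floor.** d_PN is floored at 1e-12 (steering vectors are unit
  norm) so exact-null points yield large finite values.
- **Degenerate windows.** All-zero windows are skipped. Windows whose null
  subspace is *empty* under the σ₀ rule carry no localization information
  and contribute 0 (with a warning). The same applies to *near-empty* null
  subspaces (fewer than ⌈0.1·N⌉ directions, `min_null_fraction`): a steering
  vector can be near-orthogonal to only one or two noise directions on
  extended chance sets (curves in the test plane, not points), and the α-th
  power of the resulting division blows such chance alignments into spurious
  spikes that can dominate the stitched sum. Requiring a handful of null
  directions makes near-orthogonality to *all* of them occur only at
  emitter-consistent points.
- **Raw frames.** The mean image is not subtracted before the SVD (the DC
  background simply occupies one signal direction); `subtract_mean=True` is
  available.
- **Taper.** The soft-window taper defaults to uniform weights; a radial
  cosine taper is optional. Whatever the taper, the same weights multiply
  the steering vector before unit normalization so data and steering live in
  the same weighted space.
- **Grid conventions.** Pixel centers at integer coordinates; test points at
  subpixel cell centers, s × s per pixel; windows are placed only where the
  full footprint fits, so a border of (N_w−1)/2 pixels is covered only by
  interior windows and uncovered test points are 0. Output pixel size is
  pixel_size/s.
- **Tolerances.** Eigenimage orthonormality is asserted to 1e-8 Gram
  deviation; the Airy FWHM is solved by Brent bisection to ≪ 0.01 nm.

## Synthetic data

The simulator emulates the standard test scenes for fluctuation-based
super-resolution: a two-point scene at a controlled separation, rings, and
a forking filament. Blinking is i.i.d. Bernoulli(p_on) per emitter per
frame — the minimal model satisfying independent intermittency — with an
optional two-state Markov chain (k_on, k_off) for correlated dwell times.
The camera is ideal (photon counts, gain 1, no read noise by default; a
Gaussian read-noise hook exists). Shot noise is Poisson on the per-pixel
expectation. SBR is *declared* here as the peak expected pixel signal of an
isolated bright emitter divided by the mean background; published SBR
figures may use other conventions, so comparisons should check definitions.

What the simulator does **not** reproduce about real data: finite emitter
dwell-time correlations under continuous excitation (unless the Markov
option is used), photobleaching, dipole-orientation PSF asymmetry, sCMOS
pixel-dependent noise, sample drift, and out-of-focus fluorescence. Tests
passing on these synthetics therefore validate the algorithmic chain —
decomposition, projection, stitching, quantification — not robustness to
every experimental artifact.

## Verification problem sizes

The automated checks run the full pipeline on a 15 × 15-pixel field with
two emitters 40–100 nm apart, K = 500 frames, SBR 10, p_on 0.2, subpixel
factor 20, five noise realizations per condition — small enough to verify
in seconds while keeping K ≳ 10·N so the subspace split is
well-conditioned. The two-point experiment at 50 nm separation (about a
quarter of the 204.8 nm diffraction FWHM at 593 nm) resolves in ≥ 4 of 5
realizations with peak errors below 25 nm.

## Known limitations

- The per-window relative σ₀ can place the threshold inside the noise
  plateau of bright windows; the `min_null_fraction` guard removes the
  resulting pathology but discards those windows entirely rather than
  re-thresholding them.
- Side-lobe and camera-noise compensation are not implemented; at low SBR
  the map can show side-lobe structure around bright emitters.
- Single-threaded; compute scales with (number of windows) × N² × (test
  points per window).
- FWHM measurement uses raw half-max crossings with no baseline fitting;
  an optional baseline parameter exists but no Gaussian fitting.
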