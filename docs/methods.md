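# Methods

## Model

Stripe noise in scanned-probe images is non-random, scan-line aligned, and
variable in length, amplitude and density, so it is not removable by
averaging or by a fixed-band Fourier gate. The working model: a stripe
segment in the spatial domain concentrates its energy along a straight
band through the zero-frequency (DC) pixel of the 2D spectrum,
perpendicular to the stripe direction; removing the excess amplitude at
those spectral pixels removes the stripes while phase — which carries edge
positions — is never touched. All detection and restoration operates on
LogF, the natural log of the centered amplitude spectrum, because the
relevant excursions span orders of magnitude in amplitude and are
near-additive on the log scale.

Two regimes are treated separately. Near the spectrum center, intensity
varies by orders of magnitude within a few pixels, so a local-window test
would misfire; there the radial decay is modelled by an anisotropic 2D
Gaussian (in LogF) whose breadths along the image axes come from the
inertia tensor of the candidate cloud, and only pixels *above* the fitted
envelope remain suspects. Off center the spectrum is flat enough for a
local constrained-variance test: a suspected pixel is replaced by the mean
of the non-suspected pixels in its 3×3 window when it exceeds that mean by
more than one local standard deviation. Replacement can only lower values,
so the per-pixel filter Φ = exp(S′ − S) lies in (0, 1] and the restored
image can never exceed the raw measurement anywhere — the non-negative
noise assumption (stripes add height; a restored surface brighter than the
measurement would be a fabricated artifact).

The noise image is the exact complement: raw = restored + noise by
linearity of the inverse transform. The fraction of noise pixels below
−1e−6 of the dynamic range is reported as a diagnostic but not enforced;
the non-negativity of the *spatial* noise field is an empirical property
of heavily striped images, not a theorem, and mild Gibbs ripple around
removed bands is expected on weakly striped inputs.

## Parameters

All images run with one canonical parameter set; none of these need tuning
per image.

| parameter | default | role |
| --- | --- | --- |
| `h_bins` | 20 | global H histogram bins; width 0.05 on [0, 1] |
| `central_bins` | 10 | candidate-screening histogram bins |
| `pop_ratio` | 0.5 | population drop defining the threshold bin |
| `grow_ratio` | 0.85 | candidate density at which disk growth stops |
| `grow_step_frac` | 0.1 | growth increment, fraction of the inertia radius |
| `run_min_len` | 4 px | consecutive-run length confirming a stripe segment |
| `roi_frac` | 2/3 | line-span fraction of the region of interest |
| `ns` | 1 | CVAR window half-width (3×3 window) |
| `amplitude_floor_frac` | 1e−12 | relative amplitude floor before the log |
| `h_ref_scale` | 1.0 | multiplier on the computed H threshold |

`h_ref_scale < 1` recruits more candidates; it is the documented remedy
for visible residual stripes (under-denoising). The amplitude floor only
guards structural zeros against −∞; it sits far below any threshold and
cannot create candidates.

## Numerical and procedural choices

- **Spectral convention.** Unnormalized forward FFT, 1/N inverse,
  quadrants swapped so DC sits at `(rows//2, cols//2)`. Φ is a ratio, so
  any self-consistent pair would do.
- **Laplacian boundary.** Periodic wrap — the discrete spectrum is
  periodic by construction.
- **Degenerate normalization.** If a heterogeneity factor has max == min
  it is defined as 0 everywhere: a flat map contains no heterogeneous
  pixels.
- **Histogram thresholding.** Equal-width bins over [0, 1]. The "most
  spreading" run of non-empty bins wins ties by larger total population,
  then by lower value; the scan for the threshold bin starts at that run's
  most populated bin and moves toward higher values; with no qualifying
  bin the threshold is the run's upper edge (empty selection downstream).
- **Line criteria.** Confirmed stripe structure is caught two ways along
  each row and column of screened candidates: a *span* criterion (first to
  last pixel on the line covering more than `roi_frac` of the
  region-of-interest extent, gaps allowed — the signature of a band whose
  amplitude fluctuates along its length, as interference between many
  stripes produces) and a *run* criterion (≥ `run_min_len` gap-free
  pixels). Either suffices. The region of interest is the central-disk
  diameter for the central region and the larger image side off-center.
- **Inertia weights.** LogF values can be negative; weights are shifted by
  the minimum over the candidate set when negative so the tensor stays
  positive semidefinite. A zero-weight degenerate set falls back to
  uniform weights. The initial radius is floored at one pixel.
- **Gaussian fit.** Parameters (I0, c1, c2) by damped least squares with
  deterministic initialization (I0 = LogF at the centroid pixel,
  c1 = c2 = 1) and non-negativity bounds on c1, c2; breadths σx′, σy′ are
  fixed by the inertia eigensystem rotated into the image axes (only
  cos²θ/sin²θ enter, so eigenvector sign is immaterial). A fit with fewer
  than 4 pixels, a degenerate geometry, or a non-positive fitted peak is
  rejected; the pipeline then treats the whole central region as
  candidates and proceeds (a warning is emitted).
- **DC restoration gate.** The fitted peak I0 replaces the center pixel
  only when the centroid pixel is *confirmed* noisy (in C_n2), clamped to
  never exceed the measurement. Gating on the looser envelope criterion
  (f > 0) would fire on virtually every image — the DC pixel of any image
  with nonzero mean towers above a smooth envelope — and strip genuine
  scene mean from clean images. The looser gate remains available on the
  operation (`confirmed_only=False`).
- **CVAR exclusion set.** All of P_n2 and C_n2 are excluded from window
  statistics, even though only P_n3 ⊆ P_n2 is restored: suspected but
  unconfirmed pixels never contaminate the local mean. Already-tested
  ("restored") pixels do contribute — required for boundary-inward
  progress through clusters.
- **CVAR ordering.** Central pixels are tested independently against a
  frozen exclusion mask (order-free), then relabeled restored. Off-center
  clusters (8-connected, so diagonal spectral stripes stay whole) are
  processed by repeated row-major sweeps; a pixel is tested as soon as one
  usable window neighbor exists, and survivors of a progress-free sweep
  are skipped and logged. The window is clipped at image borders, not
  wrapped: it is a local smoothness estimate, and wrapping would mix
  opposite spectral corners.
- **Variance.** Population (1/N) variance, matching the 1/N_var prefactor
  of both window moments.
- **Strictness.** The replacement condition is strict (`S − ave > σ_std`),
  as is candidate selection (`H > H_ref`, `I > I_ref`).
- **Hermitian symmetry.** Φ is symmetrized by the min over each
  negated-frequency pair, taken modulo the grid (the Nyquist row/column of
  an even dimension reflects onto itself), so both output images are real
  to machine precision. Min is conservative: a pixel never keeps more
  amplitude than either half of the pair detected as clean. The mean would
  be the gentler alternative; min never under-removes relative to either
  half.
- **Identity short-circuit.** When no candidate survives, or nothing is
  replaced, the restored image is the raw array itself (bit-exact) and
  the noise image is zero — an FFT round trip would only add rounding
  noise to an identity operation.
- **Determinism.** No stage draws random numbers; identical input and
  parameters give bit-identical results.

## Synthetic benchmark

The generator emulates the two features the method depends on: a smooth
topography with granular particles, and non-negative scan-line stripe
noise. The clean scene is periodic-smoothed Gaussian relief (correlation
length 16 px, amplitude 0.3 of the particle height — chosen so neither
background nor particles dominate the spectrum) carrying 2D Gaussian
particles of fixed height and seeded 2–5 px widths. Stripes are seeded
column segments (vertical, the dominant orientation in slow-scan-vertical
AFM images; horizontal available) with flat or triangular amplitude
profiles, accumulated additively. The standard conditions are 256×256,
40 particles of height 1.0 nm, 60 stripes of amplitude 0.5–2.0 and length
20–200 px, seed 42; the scene uses the given seed and the stripe pattern
seed + 1, so surface and noise are independent draws.

What the fixture does *not* emulate: correlated stripe bunching from a
single tip-degradation event, feedback ringing adjacent to stripes,
signed artifacts (available via `signed=True` for stress tests only),
scan-line height misalignment (a flattening problem, out of scope here),
and tip-convolution blurring. Passing tests therefore demonstrate that
the spectral detection-restoration chain removes row/column-aligned
non-negative additive artifacts on realistic smooth scenes — not that any
particular real instrument's artifact budget is fully covered.

On these conditions the pipeline typically lowers RMSE against the clean
truth by 15–25 % while concentrating 30–50 % of the removed energy on the
~9 % of pixels that truly carry stripes; both numbers are recomputed, not
asserted as constants, by `scripts/acceptance.py` and the acceptance
tests.

## Limitations

- Single pass by design; re-running on the restored output is the user's
  choice, not automatic.
- The center-row/column band of the spectrum legitimately carries the
  image's own horizontal/vertical structure; very strong genuine edges
  aligned with the scan axes can contribute candidates (the paper-level
  compromise between noise removal and feature preservation applies).
- Thick off-center clusters whose interior windows contain only suspected
  pixels can remain untestable; such pixels are skipped, kept at their
  measured values, and counted in the diagnostics.
- A smooth *random* field can still yield a handful of spectral false
  positives whose replacement is clamped by the CVAR guard; deterministic
  smooth surfaces (constant, plane, dome, low-frequency cosine) pass
  through bit-exactly.
- Absolute heights: replacing the DC pixel (only when confirmed noisy)
  shifts the global mean; AFM heights are relative, but downstream
  quantitative comparisons should use the noise image to audit what was
  removed.
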