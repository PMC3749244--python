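# destripe

Removal of scan-line stripe noise from atomic force microscopy (AFM) and
scanning electron microscopy (SEM) images, by detection and restoration of
noisy pixels in the log-amplitude Fourier spectrum.

## The problem

AFM height images of biological samples — membranes, protein assemblies,
single particles — are routinely contaminated by stripe artifacts: bright
segments aligned with the scan lines, caused by lost or inadequate height
acquisition during tip–sample interaction. These stripes vary in length,
intensity and local density, cannot be averaged away, and a plain high/low-
pass Fourier gate that removes them also removes object texture. The raw
image is the only input here: no instrument metadata is needed.

## The method

Work happens on **LogF**, the natural log of the centered amplitude
spectrum `S(i,j) = ln |F(i,j)|`. A single pass:

1. **Heterogeneity.** `H(i,j) = [(L−L_min)/(L_max−L_min)] ·
   [(I−I_min)/(I_max−I_min)] ∈ [0,1]`, where `L` is the discrete Laplacian
   of LogF (center 8, eight neighbors −1) and `I` the LogF value. High `H`
   flags pixels that are bright *and* abruptly changing.
2. **Global sampling.** A 20-bin histogram of `H` yields a threshold
   `H_ref` (first bin, scanning up from the most populated bin of the
   widest non-empty run, whose population drops to ≤ ½ of that maximum);
   `I_ref = ½(max_ref + ave_ref)` over the homogeneous pixels. Candidates:
   `P_n1 = {H > H_ref and I > I_ref}`.
3. **Divide and conquer.** The intensity-weighted inertia tensor of `P_n1`
   seeds a central disk grown in steps of 1/10 of `sqrt(σ_x+σ_y)` until the
   candidate density falls to ≤ 0.85, splitting `P_n1` into the central
   region `C_0` and the off-center remainder `P_n2`. The `C_0` intensities
   are fitted (damped least squares) by an anisotropic 2D Gaussian
   `I_0 exp{−c_1(i−i_0)²/σ_x′ − c_2(j−j_0)²/σ_y′}`; only pixels rising
   above the envelope survive (`C_n1`).
4. **Screening and clustering.** A second histogram screen (10 bins) plus
   two line criteria — collected pixels spreading over > 2/3 of the region
   of interest along one row/column, or ≥ 4 strictly consecutive pixels —
   confirm the noisy sets `C_n2` (central) and `P_n3` (off-center).
5. **Constrained variance (CVAR) restoration.** Each confirmed pixel is
   compared with the mean of the *non-suspected* pixels in its 3×3 window:
   if `S − ave > sqrt(σ_var)` it is replaced by `ave`. Off-center clusters
   are eaten from the boundary inward, freshly restored values feeding the
   deeper windows. A confirmed center (zero-frequency) pixel is instead
   assigned the fitted peak `I_0`, clamped below the measurement.
6. **Filter.** `Φ(i,j) = exp(S′)/exp(S) ∈ (0,1]`, symmetrized so the
   filtered spectrum stays Hermitian. Inverse FFT of `F·Φ` and `F·(1−Φ)`
   yields the **restored** and **noise** images, which sum exactly to the
   raw image. Restoration never raises an amplitude, matching the physical
   assumption that stripe noise is non-negative height added on top of the
   true surface (the fraction of negative noise-image pixels is reported
   as a diagnostic).

## Worked example

Generate a synthetic benchmark (smooth particle scene plus 60 seeded
vertical stripe segments of amplitude 0.5–2.0 nm) and destripe it:

```
$ destripe synth --seed 42 --shape 256x256 --out-prefix fix --format text
stage=synth seed=42 shape=256x256 stripes=60 prefix=fix

$ destripe run fix.noisy.txt --out-prefix out --format text --viz
stage=read rows=256 cols=256
stage=destripe pn1=3873 c0=446 cn2=0 pn3=182 replaced=164 skipped=18 min_phi=0.0173 seconds=0.08
stage=write prefix=out format=text
```

This writes `out.restored.txt`, `out.noise.txt`, `out.phi.txt`, PNG
visualizations, and `out.diagnostics.json`:

```json
{
 "Pn1": 3873, "C0": 446, "Pn2": 3427, "Cn1": 199, "Cn2": 0, "Pn3": 182,
 "restored": 164, "replaced": 164, "skipped": 18,
 "min_phi": 0.01730075513900475,
 "conservation_residual": 1.1102230246251565e-15,
 "negative_noise_fraction": 0.5648193359375
}
```

Reading: of 65 536 spectral pixels, 3 873 were global candidates; the
confirmed noisy set (182 off-center pixels — the fluctuating horizontal
band that vertical stripes print across the spectrum's center row) had 164
pixels lowered, the deepest to 1.7 % of its measured amplitude. The
restored + noise split reproduces the raw image to 1e−15 of its range. On
this fixture the restored image's RMSE against the known clean truth drops
from 0.44 to 0.35 nm, and ~47 % of the removed energy lands on the 9 % of
pixels that truly carry stripes.

`--h-ref-scale 0.8` lowers the heterogeneity threshold to recruit more
candidates when visible stripes survive; all other parameters default to
the single canonical set used for every image.

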