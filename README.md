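# dermoct

Multiparametric OCT quantification of layered artificial-skin (AS) models:
thickness, cuticle thickness, areal surface roughness (Sa), GLCM texture
features and depth-resolved scattering coefficients, plus a synthetic
phantom generator that provides ground truth for every stage.

## Who this is for

In vitro epidermal models (air–liquid cultured keratinocytes on a transwell
membrane) are a standard substrate for photodamage, pharmacology and
cosmetics studies.  OCT images them non-destructively: an A-scan through the
model shows two bright reflector bands — the cuticle (stratum corneum) on
top and the basement membrane below — with the living keratinocyte layer in
between.  This package turns raw 3-D OCT intensity volumes into the
quantities such studies report, and ships a phantom simulator so every
estimator can be validated against known truth without lab data.

## The quantities

* **Thickness** `D(x, y) = N·Δ`, where `N` is the (sub-pixel refined) pixel
  distance between the two A-scan intensity peaks and `Δ` the axial pixel
  size in tissue (2.53 µm at n = 1.38 for the nominal geometry).
* **Surface roughness Sa** (ISO 25178-2 style): the surface profile is the
  de-meaned *thickness* field — measuring height through thickness cancels
  sample tilt — and `Sa` is the sliding-window mean of `|D − D̄|` over a
  circular region of interest.
* **Layer boundaries** by minimum-cost shortest paths (Dijkstra on the
  column-monotone 8-connected lattice) through gradient-derived weights:
  cuticle top, cuticle bottom and membrane top delimit the living-cell
  layer.
* **Texture**: intensities are quantized to G = 8 gray levels against the
  volume-global range, a gray-level co-occurrence matrix `P(i, j; d=3,
  θ=45°)` is accumulated over 20 px (z) × 100 px (x) intra-epidermal ROIs,
  and `ASM = ΣΣ P²` and `COR = ΣΣ i·j·P` are reported.
* **Scattering coefficient** (mm⁻¹, single-scattering Beer–Lambert): the
  classical depth-resolved estimator `µ[i] = I[i] / (2δ Σ_{m>i} I[m])`
  assumes complete attenuation and overestimates at depth in thin samples.
  The modified estimator fits an exponential over the cell-layer segment,
  uses it as the terminal coefficient `µ[N]`, and solves

      µ[i] = I[i] / (2δ Σ_{m=i+1}^{N} I[m]) · (1 − e^{−2δ Σ_{m=i+1}^{N} µ[m]})

  backward from `i = N−1`, which cancels the truncation bias exactly in the
  continuous limit.
* **Cohort statistics**: group mean ± SD per day, normalization to the
  same-day normal-culture (NC) mean, percent changes, Welch's one-way ANOVA
  and Welch t-tests (two-sided, α = 0.05), Pearson correlation/linear fits.

## Worked example

```python
import numpy as np
from dermoct import (PhantomSpec, generate_volume, thickness_map,
                     roughness_sa, segment_layers, volume_scattering)

spec = PhantomSpec(nx=64, ny=64, nz=256, dz=2.53, surface_depth=101.2,
                   mean_thickness=91.08, mean_cuticle=22.0,
                   roughness_amplitude=0.5, mu_s=2.16, seed=1)
vol, truth = generate_volume(spec)

tm = thickness_map(vol)
sa = roughness_sa(tm)
b = segment_layers(vol)
smap = volume_scattering(vol, b, method="modified")
print(f"thickness {tm.mean_D:.2f} um  Sa {sa.sa:.3f} um  "
      f"cuticle {b.mean_cuticle_thickness():.2f} um  "
      f"mu_s {smap.mean_mu:.3f} mm^-1")
```

prints

```
thickness 90.59 um  Sa 0.443 um  cuticle 21.88 um  mu_s 2.189 mm^-1
```

i.e. the 91.08 µm phantom thickness is recovered to a fraction of an axial
pixel, the 22 µm cuticle to ~0.1 µm, and the 2.16 mm⁻¹ scattering
coefficient to +1.4% (the discrete-sum bias of the recursion, see
`docs/methods.md`).  The measured Sa (0.443 µm) differs from the generator's
full-field 0.5 µm amplitude mainly because the circular ROI samples a finite
correlated roughness field; against the true roughness of the *same* ROI the
recovery is within a few percent (see the test suite).

The same chain runs from the shell:

```bash
dermoct phantom --out work/ --seed 1
dermoct morpho  work/phantom.tif --out work/morpho/
dermoct segment work/phantom.tif --out work/seg/
dermoct scatter work/phantom.tif --method modified --out work/scatter/
dermoct run-all --out work/cohort/ --seed 1   # synthetic 3-arm cohort + report
```

Volumes are multi-page float32 TIFFs (one page per B-scan) with a JSON
metadata sidecar; reports are CSV + JSON.

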