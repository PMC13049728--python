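# glycoforce

Quantitative analysis toolkit for single-cell biomechanics of endothelial
cells: AFM force–distance curve decomposition into an elastic (Hertz)
response and a glycocalyx polymer-brush response, force-map aggregation,
fluorescence and scratch-assay quantification, and differential-expression
set-overlap statistics.

## Who this is for

Labs measuring living cells with AFM force spectroscopy — in particular the
endothelial glycocalyx, the carbohydrate-rich brush layer whose thinning is
an early marker of vascular dysfunction in diabetes — and needing a tested,
scriptable replacement for one-off instrument-software analyses. The same
package quantifies the accompanying assays of such studies: corrected total
cell fluorescence (CTCF) of lectin staining, wound-healing gap closure, and
filtering of DEG/DEP tables against putative transcription-factor target
lists.

## The model

An approach curve records force `F` against piezo height `z` as a spherical
probe (radius `R`) approaches a cell. With contact point `z0`, deflection
`d = F/k` and separation `s = (z − z0) + d`, the force is decomposed into
two regimes sharing one origin:

* **Steric brush (non-contact, `s > 0`)** — Alexander–de Gennes entropic
  repulsion of a grafted polymer layer of length `L` and grafting density
  `N`:

  `F(h) = 50 k_B T R N^{3/2} L · exp(−2π h / L)`, valid for `0.1 < h/L < 0.8`,

  so `ln F` is affine in `h` with slope `−2π/L`.

* **Hertz contact (indentation `δ = −s > 0`)** — sphere on an elastic
  half-space with apparent Young's modulus `E` (ν = 0.5):

  `F(δ) = (4/3) · E/(1−ν²) · √R · δ^{3/2}`,

  fitted over the deep part of the indentation where the brush is fully
  squeezed (its residual constant thrust is carried as a free offset).
  Pyramidal probes use the Hertz–Sneddon law
  `F = E/(1−ν²) · (tan θ/√2) · δ²` with an indentation cap of 200 nm to
  stay clear of the substrate.

The fit yields `E` (Pa), `L` (nm), `N` (m⁻²) and `z0` per curve;
force maps aggregate these per cell, over the whole cell and its central
region. Downstream utilities implement
`CTCF = integrated density − area × background mean`, percentage gap
closure `100(A₀ − A_t)/A₀`, DEG filtering (adjusted p ≤ 0.105 and
fold change > 1.5), DEP filtering (p < 0.05, 1.2-fold), and the exact
upper-tail hypergeometric overlap test between gene sets.

## Worked example

Every input can be simulated with planted ground truth, so the full
pipeline runs without any instrument data:

```python
from glycoforce import BrushHertzModel, CurveSim, simulate_curve

curve, truth = simulate_curve(CurveSim(noise_sd_pn=3.0), seed=42)
res = BrushHertzModel(curve).fit()
print(res.summary())
```

```
Two-regime curve decomposition (Hertz + glycocalyx brush)
==========================================================
E (apparent)        1868.47 Pa  (se 178.213)
contact z0          19.3973 nm
brush plateau       52.661 pN
Hertz window        146.661-242.993 nm (55 pts, RMS 3.12975 pN)
brush detected      True
glycocalyx L        310.511 nm  (se 19.707)
grafting density N  7.12313e+13 m^-2
brush window        31.3984-246.616 nm (109 pts)
log-linear r^2      0.63615
flags               none
```

The curve was planted with E = 2000 Pa and L = 300 nm under 3 pN of force
noise: the single-curve estimates land within one standard error of both
(Ê = 1868 ± 178 Pa, L̂ = 311 ± 20 nm). `res.params`, `res.bse`,
`res.plot_decomposition()` and `res.to_row()` expose the same results
programmatically; over an ensemble of 200 such curves the median estimates
recover E within ~2% and L within ~3% (see the acceptance script below).

The same objects are reachable from the shell:

```sh
glycoforce simulate curves --seed 42 --n 1 --out demo/
glycoforce decompose demo/curve_0000.tsv
glycoforce fit-curve --model pyramid --window cap:200 mycurve.tsv
glycoforce ctcf img.tif --cells cells.tif --bg bg.tif
glycoforce overlap gene_table.csv --targets targets.txt
```

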