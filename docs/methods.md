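# Methods

## Scope and conventions

`glycoforce` analyses AFM approach curves on living cells and the companion
assays of a cell-mechanics study: force maps, fluorescence quantification,
scratch assays and differential-expression set statistics. Internally all
lengths are nm, forces pN, moduli Pa, spring constants N/m (1 N/m =
1000 pN/nm) and temperatures K; converters live at the I/O boundary.

Axis convention: piezo height `z` decreases as the tip approaches;
approach segments are stored far-to-near (strictly decreasing `z`).
Deflection `d = F/k` is positive for repulsive loading. For a contact
point `z0`, the tip–sample separation is `s = (z − z0) + d` and the
indentation is `δ = max(0, −s) = max(0, (z0 − z) − d)`: a repulsive
deflection moves the tip away from the surface, adding to the separation
and subtracting from the indentation.

## The two-regime force model

A curve on a glycocalyx-bearing cell is modelled as the sum of two
components sharing one contact point:

* **Brush (s > 0):** Alexander–de Gennes steric repulsion in its
  exponential form, `F(h) = P · exp(−2π h/L)` with prefactor
  `P = 50 k_B T R N^{3/2} L`, nominally valid for `0.1 < h/L < 0.8`.
* **Hertz (δ > 0):** `F = (4/3)·E/(1−ν²)·√R·δ^{3/2}` for the sphere;
  `F = E/(1−ν²)·(tanθ/√2)·δ²` for a four-sided pyramid (the conical
  front factor `(2/π)tanθ` is selectable, since vendor software varies).
  ν is fixed at 0.5 (incompressible cell) and overridable.

**Squeezed-brush plateau.** Naively switching the brush term off at
contact would make the total force discontinuous by `P` (a snap-in).
The package instead lets the brush force saturate at its zero-separation
value once the layer is fully compressed:
`F = brush(max(s, 0)) + hertz(max(δ, 0))`. The total force is then
continuous and monotone, and the deep regime is exactly
`P + (Hertz term)`. Correspondingly, the deep-window elastic fit inside
the decomposition frees a constant offset; the fitted offset doubles as an
independent estimate of the brush prefactor (a useful internal
diagnostic). The plain `fit_hertz` used for pyramidal modulus mapping
keeps the offset off — there is no brush term in that geometry.

## Fitting procedure

1. **Baseline.** A least-squares line over the farthest 30% of the
   approach samples is subtracted from the force channel (idempotent;
   removes drift and tilt without touching the brush regime).
2. **Contact scan.** Candidate contact points are scanned over the sample
   grid; each candidate fits a piecewise model (zero force before, power
   law after, deflection-corrected indentation) and the SSE-minimising
   `z0` is kept, with the half-width of the near-optimal region as its
   uncertainty. On brush-bearing curves this estimate is biased toward
   larger separations by less than the brush length — it only seeds the
   next stage.
3. **Deep-window Hertz fit.** Window policies: `deep:q` keeps the top
   fraction `q` (default 0.4) of the indentation range — the regime where
   the glycocalyx is assumed fully squeezed; `cap:δmax` keeps
   `0 < δ ≤ δmax` (default 200 nm, the constant-indentation policy for
   pyramidal mapping that keeps the stiff substrate out of the fit).
   Given `z0`, the model is linear in (offset, prefactor), so those are
   profiled out in closed form and the contact point is the only
   nonlinear parameter: a 256-point scan over `z0 ± 0.25·(z-range)`
   followed by bounded Brent refinement minimises the profiled SSE.
   The window point set is held fixed during each scan (so SSE values are
   comparable) and re-derived from the refined `z0`, iterating up to
   three times. This profiled search is immune to the strong
   (z0, offset, prefactor) collinearity that traps joint gradient
   descent in shallow local minima, and is exactly the brute-force grid
   search an oracle would run, up to grid resolution.
4. **Brush fit.** The fitted Hertz component is subtracted; residuals at
   positive separation are the brush candidate. Detection requires at
   least 8 points above a floor of 5× the far-baseline RMS — below that
   the curve is reported `no_brush` rather than fitted. A weighted
   log-linear regression of `ln F` on `h` (weights `F²`, the inverse
   variance of `ln F` under additive force noise) initialises `(L, N)`;
   nonlinear least squares on the exponential law refines them over all
   points in the band `0.1 ≤ h/L ≤ 0.8` (near-zero residuals are kept —
   they carry no bias and pin down the decay). The band is iterated with
   the current `L̂`, up to 10 times, converging when `L` moves < 1%;
   collapse is reported as a flagged failure.
5. **Flags.** `no_contact`, `no_brush`, `poor_hertz_fit`,
   `window_truncated`, `brush_window_collapse` form the complete flag
   vocabulary; a fittable curve never raises.

Standard errors come from the Jacobian of the equivalent nonlinear
problem at the optimum (residual-variance scaled); `L` additionally
carries the delta-method error of the exponential refinement.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| probe radius R | 1.25 | µm | spherical glass probe used for glycocalyx work |
| spring constant k | 0.02 | N/m | soft cantilever for living cells |
| temperature T | 309.35 | K | 36.2 °C measurement bath |
| force setpoint | 500 | pN | ramp truncation, not clipping |
| ν | 0.5 | — | incompressible cytoplasm |
| deep-window fraction q | 0.4 | — | "close to maximal indentation" |
| pyramid indentation cap | 200 | nm | ~10% of cell height, avoids substrate |
| pyramid half-angle θ | 20 | ° | four-sided probe face half-angle |
| brush band | 0.1–0.8 | h/L | validity of the exponential form |
| detection floor | 5 | × baseline RMS | conservative brush detection |
| map grid | 7×7 | — | 1.5 µm step, ≈ probe diameter |

"Central part of the cell" is operationalised as the erosion of the cell
mask to half its area around the mask centroid (a parameter-light proxy
for the nuclear region); the fraction is configurable. Cell summaries use
the median by default (robust to fit failures; the mean is available) and
require at least 4 valid pixels per region, else the summary is absent
with a recorded reason.

## Synthetic data: what it emulates and what it does not

The generator solves the cantilever equilibrium `k·d = F(z, d)` exactly
(bracketed root) at every piezo position, so the kinematic bookkeeping of
the stored channels is exact by construction. It emulates: the two-regime
force structure with a planted `(E, L, N, z0)`, additive i.i.d. Gaussian
force noise (thermal-noise-dominated soft-cantilever acquisition),
baseline offset/tilt, ramp truncation at the 500 pN setpoint, a default
piezo sampling step of 2 nm (a 2 µm/s ramp at ordinary sampling rates
gives finer steps than this), optional stiff-substrate upturn and a
rigid-substrate mode, elliptical cell phantoms with distinct
central/peripheral mechanics and an optional modulus-scaling
("cytochalasin") mode, disk-shaped fluorescent cells with planted
integrated totals, a rectangular wound closing at a constant rate with a
textured cell lawn, and gene/protein tables whose p-values are generated
from the same normal model as the effects (z → two-sided p →
Benjamini–Hochberg), so filters see internally consistent data.

It does **not** emulate: viscoelasticity or force-rate dependence,
adhesion on retract, bottom-effect stiffening (beyond the explicit
substrate-upturn artifact), cell topography, optical point-spread
functions, sequencing-count noise, or spatial correlation of biological
variability. Passing tests therefore demonstrate the correctness of the
estimators under the stated model, not robustness to every artifact of
real acquisitions.

## Numerical choices and degenerate inputs

* Exact hypergeometric tail probabilities by pmf summation (scipy), no
  normal approximation; the overlap universe must always be supplied
  explicitly — there is no defensible silent default.
* Fold-change thresholds apply to `|FC| = 2^{|log2FC|}` symmetrically
  (both tails of the volcano).
* Wound segmentation: windowed variance (15 px) → Otsu threshold →
  morphological open/close (5 px) → largest low-texture component. A
  frame whose "low-texture" class still carries > 30% of the textured
  class's variance has no real wound and yields an empty mask with a
  warning; the operator is invariant under intensity offsets.
* CTCF background pools all background ROIs by default (per-ROI
  averaging selectable); CTCF may legitimately be negative.
* Ties in the top-k fold-change ranking break lexicographically by gene
  id, making the ranking order-independent.
* Group comparisons are thin plumbing over scipy (Kruskal–Wallis,
  Welch t-test); identical duplicated samples give statistic 0.
* Degenerate curves: all-zero force raises a no-contact error; fewer
  than 8 window points raises a fit error; non-convergence returns a
  flagged result, never a silent number.

## Design choices where the design was open

* The separation/indentation sign convention (above) was fixed so that
  both channels derive from one coordinate; the alternatives differ by
  `2d` and are mutually inconsistent.
* The brush prefactor uses grafting density in m⁻² with the
  `50 k_B T R N^{3/2} L` form; the constant is recorded in the force law
  itself and all recovery analyses are round trips through the same form,
  so a different front constant would rescale `N` only.
* The brush separation origin is the squeezed-brush surface implied by
  the deep Hertz fit; an uncorrected piezo origin is selectable.
* Whether per-cell values pool pixels or average per-map first is an open
  question in such studies; pixel pooling is the default, both orders are
  available.

## Problem sizes

The default analyses use curves of a few hundred to ~1500 samples, 7×7
force maps (≈ 37 cell pixels), 200-curve noise ensembles, 20 map pairs
for the cytochalasin comparison, 2000-gene/200-protein tables, 500-seed
null calibrations and 1000-resample type-I checks. These sizes make the
whole acceptance run complete in about a minute on a single CPU while
keeping every Monte-Carlo tolerance comfortably resolvable.

## Known limitations

* The exponential brush form degrades below `h ≈ 0.1 L`; the package
  works within the stated band and does not implement the full AdG
  polynomial, two-layer brushes, or bimodal grafting.
* `N` is reported but weakly identified at low SNR (it enters only the
  intercept); `L` is the robust output.
* At 10 pN force noise the default brush (plateau ≈ 80 pN) is frequently
  undetectable; detection rate itself is a reported quantity, and
  non-detection is an explicit flag, not an error in `L`.
* The apparent modulus from capped pyramidal fits is an effective
  quantity; no bottom-effect correction is applied.
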