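# Methods

## The problem and the model

Binary adulteration of camellia oil (CAO) with rapeseed oil (RSO) is treated
as ideal Beer–Lambert volume mixing: the absorbance of a blend at volume
fraction f = v/100 is A(ν) = (1−f)·A_CAO(ν) + f·A_RSO(ν) at every
wavenumber ν. All four analysis stages rest on this linearity — the purity
ratio is a ratio of two affine functions of f (hence monotone), PCA of a
blend series is low-rank, LDA group means are collinear in f, and one PLSR
factor suffices for noise-free ladders. Density corrections to v/v mixing
are omitted; for edible-oil pairs they are below the noise floor of the
generator and of typical ATR measurements.

## Purity ratio

Peak height is the maximum absorbance over grid points within ±4 cm⁻¹ of the
nominal band position (no local baseline anchor). The window makes the
statistic robust to a couple of cm⁻¹ of misregistration; the absence of a
baseline anchor keeps it a pure height ratio, invariant under positive
scaling of the spectrum. The decision rule is strict: ratio > 1.000 is
"pure-CAO-consistent", exactly 1.000 flags as suspect (conservative
screening). Ratios are computed on smoothed, non-derivative spectra — band
height is meaningless after differentiation.

## Synthetic endmembers

Each oil is a sum of pseudo-Voigt bands (70 % Gaussian / 30 % Lorentzian) at
the eleven canonical triacylglycerol positions between 3006 and 722 cm⁻¹,
with fixed widths of 14–26 cm⁻¹. Three calibration rules pin the amplitudes:

1. **Ratio midpoints.** The 1096/1119 cm⁻¹ amplitudes are solved by
   fixed-point iteration so the *windowed heights* of the noise-free template
   hit a per-oil base height and ratio (CAO 1.064, RSO 0.971, PO 0.9805,
   SO 0.948, CO 0.9375, SFO 0.9135, SBO 0.9115 — the midpoints of the
   published per-oil ranges). Overlap from neighbouring bands couples the two
   heights at the few-percent level, so the iteration converges to machine
   precision in a handful of steps. The two C–O bands share one width
   (16 cm⁻¹): with unequal widths a smoothing filter would attenuate the two
   peaks unequally and systematically bias the ratio off its calibrated
   value.
2. **Crossover scale.** For the blend ratio to fall through 1.000 at volume
   fraction v*, the RSO C–O heights must exceed the CAO ones by
   k = (1−v*)(r_c−1)/(v*(1−r_r)). With v* = 0.55 this gives k ≈ 1.806, so
   the tabulated 50 % level stays just above threshold and 60 % falls just
   below — the observed decision boundary. v* is an inferred calibration
   assumption: only the 50–60 % crossover interval is observable, not the
   continuous crossing point. A consequence worth noting: under this
   calibration *both* C–O blend heights increase with adulteration (the
   1096 cm⁻¹ one faster), which is what makes the ratio decrease.
3. **Composition scaling.** Unsaturation-sensitive bands (3006, 722 cm⁻¹)
   scale with each oil's total unsaturated fatty-acid content; the
   1464/1377 cm⁻¹ CH bands scale mildly with saturated content and the
   1160 cm⁻¹ band with polyunsaturated content, from the GC-FID totals of
   the seven oils. These give each oil its own fingerprint pattern, which is
   what the 7-oil PCA separates.

### Brand variability and noise

Brand-to-brand variation has two multiplicative components, drawn once per
(oil, brand) from unit-mean log-normals:

- a **global intensity factor**, CV = `brand_amp_cv` = 0.01, emulating ATR
  contact/path-length variation. It scales the whole spectrum and leaves the
  purity ratio invariant;
- a **per-band composition jitter**, CV = `brand_comp_cv` = 0.0015,
  independent across bands, giving each brand a slightly different band
  pattern and hence a slightly different ratio (a spread of roughly ±0.005
  in the CAO ratio across brands, comfortably inside the published
  1.045–1.083 band at n = 21).

A single-level per-band multiplier cannot satisfy both roles: at CV 0.01 the
implied ratio spread (≈1.4 %) would exceed the width of the narrowest
published per-oil range (±0.7 %). Splitting the variability this way keeps
an honest per-sample intensity CV of 1 % while respecting the printed ratio
ranges.

Replicates of one brand differ only by i.i.d. Gaussian noise,
`noise_sd` = 2×10⁻⁴ AU per point. The default additive baseline is zero:
the ratio uses absolute heights with no baseline anchor, so a nonzero
default would shift every height comparison; baseline drift is exercised
explicitly (via `baseline_coeffs`) where derivative invariance is the point.
All draws are seeded deterministically from (seed, oil, brand[, replicate]),
so any generated design is bitwise reproducible.

The generator emulates band structure, composition-driven amplitude
patterns, brand variability and white noise. It does **not** emulate water
vapour/CO₂ interference, ATR penetration-depth dispersion, temperature
effects, band-position shifts between oils, or non-linear detector response.
Passing tests therefore demonstrate the correctness and internal consistency
of the chemometric pipeline under the stated spectral model — not
instrument-level performance on real oils.

## Preprocessing

Savitzky–Golay smoothing (window 11 points = 20 cm⁻¹ at the 2 cm⁻¹ grid
step, order 2) and, where used, the SG first derivative (same window,
order 3), applied in the fixed order smooth → derivative → crop so filter
edge effects never enter the modelling region. Both operators are linear
and reproduce polynomials of the fit order exactly, which preserves the
Beer–Lambert mixing structure downstream models rely on.

Which stages consume which form: the **ratio**, **LDA features** and **PCA
exploration** use smoothed non-derivative spectra (heights and peak-shaped
loadings are the objects of interest there; the wavenumber-selection
algorithm assumes loading maxima sit at band centres). **PLSR** consumes
first-derivative spectra cropped to 1800–650 cm⁻¹ — quantification is where
robustness to baseline drift matters most.

## PCA and wavenumber selection

Mean-centred SVD (no variance scaling — spectra share units), explained
variance σᵢ²/Σσⱼ², deterministic loading signs (largest-|element| positive).
Selection combines the first three components' absolute loadings weighted by
explained variance and picks local maxima greedily by magnitude with a
10 cm⁻¹ minimum separation, ties toward the higher wavenumber. On the
camellia/rapeseed admixture set this recovers the seven diagnostic bands
(1744, 1464, 1377, ~1155, 1119, 1096, ~721 cm⁻¹). The band list also ships
as the constant `SELECTED_WAVENUMBERS` so the discriminant stage can bypass
selection.

## LDA

Pooled within-class covariance Σ_g (n_g−1)S_g/(n−G), equal priors,
nearest-class-mean rule in the Mahalanobis metric; Mahalanobis distances are
rounded at the 12th decimal before the argmin so that exact ties break
toward the lexicographically first group. Canonical axes solve the
generalized eigenproblem of between-class scatter against the pooled
covariance. A ridge of 1e-8 × trace/p is added only when the condition
number exceeds 1e10. Leave-one-out refits on n−1 samples per held-out
sample; there is no randomness anywhere in the procedure. The screen's 15
replicates per group are realised as 5 camellia brands × 3 replicate
spectra, blended against one rapeseed brand.

## PLSR

Single-response NIPALS: w ∝ E'f, t = Ew, p = E't/t't, q = f't/t't, deflate
both blocks; regression vector B = W(P'W)⁻¹q. RMSEC and RMSECV are plain
root-mean-square errors with denominator n (matching the RMSECV definition;
no degrees-of-freedom correction). Slope/offset are the OLS fit of
*predicted on actual*; R² is the squared Pearson correlation — at the
near-unity fits reported here the distinction from explained variance of the
fit line is below the printed precision. Predictions are never clipped to
[0, 100]; the calibration table carries an `out_of_range` flag instead, so
cross-validation errors are not silently biased toward zero.

The calibration suite fits one model per (rapeseed brand × camellia brand)
pair — 15 models for the 3 × 5 design — on 13 points each (pure base oil
plus twelve levels, 1–50 % v/v), 4 factors by default. Levels above 50 % are
excluded from calibration because the ratio screen already flags them.

## Problem sizes and numerics

Default grid 4000→650 cm⁻¹ at 2 cm⁻¹ (1676 points; the fingerprint region
1800–650 cm⁻¹ has 576). The standard runs are 194 spectra for the
calibration design, 75 for the discriminant screen (5 groups × 15), 105 for
the blend PCA (7 groups × 15) and 147 for the 7-oil set (7 × 7 × 3); the
complete pipeline finishes in a few seconds on one core. Degenerate inputs
fail loudly rather than silently: constant y, singular pooled covariance,
empty sets, mismatched grids, windows outside the grid and non-monotonic
grids all raise with context.

## Known limitations

- The crossover position (55 % v/v) and the absolute C–O band scale are
  calibration assumptions inferred from the decision boundary, not
  measurements; only the 50–60 % bracketing is validated.
- Brand effects perturb amplitudes only; real brands also shift band centres
  slightly. A stated consequence is that classification difficulty at a
  given noise level may be optimistic relative to real oils.
- Binary blends only; ternary and higher-order adulteration is out of scope.
- The published per-oil ratio ranges for the five non-camellia, non-rapeseed
  oils constrain only each oil's calibrated midpoint here, not its simulated
  brand spread.
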