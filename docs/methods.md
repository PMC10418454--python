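# Methods

## The workflow being modelled

The package implements the standard two-band NIRS calibration study for
composite meat products: reflectance spectra are collected on two
instruments (visible/NIR at 0.35 nm pitch over 399.8–949.8 nm; NIR at
3.6 nm pitch over 942.7–1698.3 nm), the noisy edges are discarded (below
650 nm, the 942.7–960 nm inter-instrument gap, above 1650 nm), replicate
scans are averaged, and PLSR models are calibrated per trait on a random
70/27 sample split. Preprocessing and band choice are screened
exhaustively, traits that calibrate adequately advance to wavelength
selection, and reduced "multispectral" models are rebuilt on the selected
wavelengths.

Band trimming uses closed keep-intervals ([650, 950] and [960, 1650] nm),
so printed band endpoints survive trimming. Replicate averaging is a plain
arithmetic mean; because the mean is associative, averaging 3 probe
positions × 3 repeat scans hierarchically or jointly gives identical
results, and the operation accepts either layout. Spectra are modelled in
reflectance units throughout; an optional log10(1/R) absorbance transform
exists (`to_absorbance`) but is off everywhere by default, and none of the
preprocessing operators assume absorbance.

## Preprocessing operators

All operators are per-spectrum (row-wise), which makes them safe to apply
before any cross-validation split — no statistic pools across samples.

* **SNV** subtracts the row mean and divides by the row SD (n−1
  convention; any consistent convention only rescales rows uniformly). It
  exactly inverts the multiplicative-scatter model a·x + b with a > 0.
* **SNVD** follows SNV with a per-row least-squares polynomial detrend of
  degree 2 in wavelength (the Barnes-style choice; the degree is a
  parameter). The fit uses a rescaled wavelength coordinate for
  conditioning; the annihilated subspace is unchanged.
* **Der1/Der2** are Savitzky–Golay derivatives: order-2 polynomial fit in
  a 15-point moving window, derivative scaled by the physical pitch so the
  two bands' derivative magnitudes are comparable (units: intensity per
  nm^order). The half-window at each edge is dropped rather than
  extrapolated — edge values from polynomial extrapolation are fabricated
  data and the spectra are long enough that losing 7 points per side is
  immaterial. The grid must be uniform to 1% relative tolerance.

## PLSR and LOOCV

NIPALS for a single response (PLS1) with mean-centering only — no
autoscaling of X, the dominant convention for spectral data where all
columns share units. For PLS1 the NIPALS inner iteration converges in one
pass, so each component is a closed-form sequence of matrix products.
Rank exhaustion (deflated X carrying no covariance with y) raises an error
naming the component; LOOCV truncates its curve there instead.

LOOCV refits everything inside each fold, including centering. The
preprocessing operators are per-sample, so applying them once outside the
loop is mathematically identical to applying them per fold; for this
reason the LV-selection routine takes a plain matrix and no preprocessing
hook. The LV optimum is the global RMSECV minimum with a smallest-LV
tie-break; `a_max` defaults to 15 and is clamped to min(n−2, p).

The LOOCV engine advances all n folds simultaneously (fold-deleted
matrices stacked into an (n, n−1, p) tensor, each NIPALS step a batched
matmul) and produces held-out predictions at every LV count in one sweep.
A brute-force double-loop refit oracle in the test suite pins its output
to 1e-10.

## Wavelength selection

**RC selection** takes the fitted model's β curve, finds sign-aware local
extrema (peaks and valleys over the wavelength index, endpoints excluded),
ranks extrema by |β| and keeps the top k. Requesting more extrema than
exist returns all of them with a shortfall flag. Defaults follow common
practice for this workflow: 7 wavelengths for fat, 8 for protein.

**Random frog** is the canonical subset-chain scheme: from a current
subset of size q, draw a candidate size q* ~ round(N(q, (θq)²)) clipped to
[1, p]; shrink by keeping the q* variables with largest |β| in a PLS
submodel on the current subset, or grow by adding min(ω·(q*−q), p−q)
uniformly drawn outsiders before |β|-truncation back to q*; accept the
candidate if its LOOCV RMSECV is no worse, else with probability
η·(RMSECV_current/RMSECV_candidate). Importance is the fraction of
iterations each variable spent in the accepted subset. Defaults: N = 1000,
q_init = 10, θ = 0.3, ω = 3, η = 0.1. Submodel LV counts are chosen by the
submodel's own LOOCV capped at 5 — uncapped submodel tuning would make the
chain's cost explode with no benefit at these subset sizes. Degenerate
(rank-deficient) candidates are rejected and logged. Selection always runs
on calibration rows only.

Both selectors return subsets of the model grid, never interpolated
wavelengths. When an externally supplied wavelength list is used for a
rebuild, it is mapped to the nearest grid column with a tolerance of half
the local pitch.

## Evaluation

R is the Pearson correlation between reference and predicted values; RMSE
uses denominator n. RPD = SD(prediction subset, n−1)/RMSEP, with the
conventional bands (< 1.5 inadequate, 1.5–2.5 fair, 2.5–5 good, > 5
analytical-grade); the identity RPD·RMSEP = SD holds to rounding. Pearson
significance uses the t transform t = r·√((n−2)/(1−r²)) with two-sided
p-values, flagged ** (p < 0.01) and * (p < 0.05). Descriptive statistics
use the n−1 SD and CV% = 100·SD/mean. Report tables round CV to one
decimal and R/RMSE/RPD to three, matching field conventions.

A note on RPD scale: published tables in this genre sometimes mix units
between descriptive-statistics tables and model tables (e.g. trait SDs in
g/kg an order of magnitude larger than RPD·RMSEP would imply). This
package computes RPD self-consistently from its own prediction subset; no
external inconsistency is emulated.

## Pipeline decisions

* "Optimal preprocessing" per (trait, band) is the cell minimising RMSECV
  on the calibration set. Choosing by prediction-set performance would
  leak the holdout into model selection; published tables chosen that way
  may differ.
* Traits advance to wavelength selection when the optimal full-spectrum
  model's RPD is ≥ 1.5 — the standard inadequacy threshold.
* Der2 stays in the screening grid even though it rarely wins; it is part
  of the defined operator set.
* The prediction set influences nothing upstream of final metrics; a test
  corrupts prediction-set spectra and asserts every calibration-side
  choice is byte-identical.

## The synthetic data generator

The generator emulates the study conditions the analysis assumes: 97
samples, five traits with the published calibration-set moments, ranges
and correlation structure, and two-band reflectance spectra with
scatter/baseline artifacts.

**Traits.** fat, protein and ash are drawn from bounded distributions
whose *post-truncation* moments match the printed mean/SD: a
moment-matched truncated normal where feasible (protein, ash), solved
numerically from the two moment equations. For fat the printed SD
(33.2 g/kg) is about as large as the mean-to-minimum distance
(34.7 g/kg), which no truncated normal on the printed range can achieve —
the real trait is right-skewed — so fat falls back to a moment-matched
lognormal clipped to the range. Na is an affine function of ash plus
noise targeting r = 0.77 (both track the inorganic salt fraction), and
collagen is tied to protein the same way at r = 0.35; both are clipped to
their printed ranges, which attenuates the correlations only marginally.

**Spectra.** A clean spectrum is linear in concentrations,
A(λ) = Σ_k (c_k/1000)·K_k(λ), each component curve a sum of Gaussian
absorption bands: water at 771/979/1423 nm (O–H overtones and
combination), fat at 813/872/1220 nm (C–H, strong second overtone at
1220), protein at 910/1020/1190/1500 nm (N–H/C–H region). Water
concentration is the mass-balance remainder 1000 − organics − ash,
floored at 0, so it anti-correlates with the organic traits as in real
meat. Ash and Na contribute no absorption (inorganic ions are NIR-silent)
— their only route to predictability is correlation with absorbing
traits. Collagen, itself a fibrous protein, carries the protein band
pattern shifted by 5–8 nm at one quarter amplitude: identifiable in
noise-free data (a clean-mode test recovers all concentrations by least
squares to < 1e-6 relative), but nearly collinear with protein under
noise, which reproduces the weak collagen predictability such studies
report.

The observed spectrum is a·A + b + d₁u + d₂u² + ε with per-sample
multiplicative scatter a ~ N(1, 0.03), offset b ~ N(0, 0.01), linear and
quadratic drift d ~ N(0, 0.01) on a scaled wavelength coordinate, and
i.i.d. channel noise ε ~ N(0, 0.02). The two instruments draw their
corruption independently. VNIR organic amplitudes are several-fold weaker
than NIR ones (third versus second overtones), which is why the NIR band
wins the screening. The noise level was calibrated once so that
full-spectrum prediction lands in the intended regime — R_p ≈ 0.9–0.99
for fat and protein, ≈ 0.5 for collagen, ≈ 0 for ash and Na, and an RPD
gate that passes exactly {fat, protein}; exact emulation of any published
table is neither possible nor attempted.

**What passing tests do not show.** The generator's spectra are far
better-behaved than real meat spectra: Gaussian bands, strictly linear
mixing, no temperature or moisture-state band shifts, no inter-sample
path-length structure beyond the affine scatter model, no instrument
drift between sessions. Success here validates the chemometric machinery
and its leakage discipline, not field performance on real samples.

## Problem sizes and numerics

Default analyses use the 97-sample fixture (p = 857 VNIR / 195 NIR before
derivative trimming), a_max = 15, N = 1000 random-frog iterations, and
25-replicate recovery studies at n = 60, p = 100–195, SNR 10 — sizes at
which the full analysis completes in about two minutes on one CPU.
Rank-deficiency tolerances are relative (1e-12 of the initial Xᵀy scale);
RMSECV ties break to the smaller LV count; random draws all flow from
numpy Generator objects seeded explicitly, so every table and selection
is bit-reproducible per seed.

## Known limitations

* PLS1 only; multi-trait PLS2, SIMPLS and kernel variants are out of scope.
* Random frog recomputes a full LOOCV per candidate; for p in the
  thousands a cheaper acceptance surrogate would be needed.
* The RPD gate reads prediction-set RPD, mirroring the emulated study's
  own trait-retention decision; a stricter design would gate on RMSECV.
* The generator does not model Kubelka–Munk scattering physics or
  instrument line shapes; its artifacts are exactly the ones the
  preprocessing operators target.
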