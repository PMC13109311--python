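# Methods

This note records the models, numerical choices, and open design decisions
behind `leafspec`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## The synthetic leaf model

Every quantitative claim in the test suite rests on the generator in
`leafspec.synthdata`, so its assumptions matter most.

A pigment-free "base leaf" reflectance is composed of a visible plateau
(0.08), a Gaussian green-reflectance peak at 550 nm (amplitude 0.06,
σ 25 nm), and a sigmoid red edge centered at 720 nm (width 13 nm) rising to
a NIR plateau of 0.55. Pigments subtract Gaussian absorption bands
(σ 8 nm ≈ 19 nm FWHM, visibly separated at the 2.4 nm grid spacing) at the
in-vivo absorption centers: Chl a at 430 and 674 nm, Chl b at 450 and
649 nm, carotenoids at 470 nm. The red Chl a band is placed at the
reflectance-trough position (670–690 nm window) rather than the in-solvent
665 nm absorbance line, so the mean spectrum reproduces the canonical leaf
landmarks (blue trough 430–470 nm, red trough 670–690 nm, green peak
530–580 nm, red edge 690–750 nm).

- **Linear mode**: absorption depth = gain · concentration, with gains
  (0.055, 0.095, 0.16 reflectance units per mg/g for Chl a / Chl b / Car)
  sized so the deepest trough stays above zero across the default
  concentration ranges — the pigment→spectrum map is then *exactly affine*,
  which is what makes oracle tests (full-rank linear recovery, PLSR
  RP² ≥ 0.999) legitimate.
- **Nonlinear mode**: depth = d_max · (1 − e^(−k·c)), with k set so the top
  of each default range reaches 80 % of saturation and d_max matched to the
  linear depth scale there. This gives kernel/tree/neural models a genuine
  curvature to exploit over linear ones.
- **Concentration draws** are independent uniforms within field-typical
  lettuce ranges (Chl a 0.68–0.99, Chl b 0.29–0.45, Car 0.14–0.23 mg/g);
  TPC is computed, never drawn. Real pigments are correlated across samples;
  recovery tests only need known truth, so this is deliberately not modeled.
- **Noise** is additive Gaussian, default σ = 0.003 reflectance units,
  i.e. ~1 % of the mean leaf reflectance over the grid (≈0.28). At this
  level a well-specified PLSR reaches RP² ≈ 0.97 on n = 500 — a realistic
  information ceiling for a calibrated lab Vis-NIR system. (A full-scale
  1 % floor, σ = 0.01, would be 15–30 % relative noise in the visible
  bands, where leaf reflectance is only 0.03–0.08, and caps *any* estimator
  near RP² ≈ 0.7; that is not a plausible instrument.)
- **Canopy frames** place a leaf disk (radius 0.4 · min(H, W)) on a flat
  soil background (reflectance 0.18, giving > 0.3 NIR contrast at
  748.76 nm). Foreground concentrations vary radially,
  c(r) = midpoint + slope · (r/R − ½), emulating the center-to-periphery
  trends seen in real canopy maps; truth maps are returned pixel-aligned.

What passing tests therefore show: the algorithms recover what the
generator encodes. What they do not show: robustness to scatter effects,
baseline drift, specular glint, canopy geometry, water absorption, or
pigment covariance — none of which the generator emulates (leaf-optics
realism is explicitly out of scope).

## Pigment assay

The assay equations convert blank-corrected absorbances to extract
concentrations in µg/mL and then to mg per g fresh tissue via V/(1000·W).
Two readings of the published arithmetic are possible; we use the only
dimensionally consistent one: the Chl terms inside the carotenoid equation
are the *extract concentrations* (µg/mL), not the per-gram outputs, and the
trailing factor is V/(1000·W), not (V/1000)·W. Negative components (possible
with noisy absorbances) are flagged, never clipped, so downstream statistics
stay unbiased.

## Preprocessing

All three transforms are fit-free and band-count-preserving, so selection
indices stay meaningful and no calibration/prediction leakage is possible
at this stage. MA uses a centered boxcar whose window shrinks at the edges
(no invented padding); default window 5 (≈12 nm), small enough to keep the
2.4 nm-sampled troughs. SNV uses the sample (n−1) standard deviation,
fixed project-wide. D1 is a plain central difference on the wavelength grid
(one-sided at the ends; `numpy.gradient`), not Savitzky–Golay — the simplest
scheme exact for affine spectra.

## Band selection

- **CARS**: Monte-Carlo PLS on 80 % row subsets; bands ranked by
  |PLS coefficient|; the retained count follows the exponentially
  decreasing schedule r_i = a·e^(−k·i) pinned at r_1 = 1 and r_runs = 2/B;
  the adaptive reweighted sampling step draws exactly that count *without*
  replacement with probability ∝ |coefficient|, so the retained-count trace
  follows the closed form within rounding and runs are reproducible.
  Returns the iteration minimizing 5-fold CV RMSE. Defaults (50 iterations,
  ≤ 10 PLS components) follow the original CARS literature.
- **SPA**: classical successive projections; a column already in the span
  of the selection has projected norm ~0 and is never co-selected. Auto
  start scores every chain by the same PLS-CV criterion as CARS.
- **UVE**: leave-one-out PLS coefficient stability against appended
  uniform noise columns (magnitude 10⁻³·max|X|, count B, cutoff the 0.99
  quantile of the noise stabilities).
- **LARS**: entry order of the least-angle path (scikit-learn's
  `lars_path`), columns standardized internally.

Ranking ties everywhere break toward the lower band index; every selector
is a pure function of (X, y, config, seed).

Recovery is scored per pigment against that pigment's own absorption
centers (draws are independent, so other pigments' bands carry no signal
for a given target), and a center counts as recovered when a selected band
lies within one grid step (2.4 nm) of it — strict index identity on a
2.4 nm grid with 19 nm-wide, heavily collinear absorption features would
test grid phase, not selector behavior. Measured recovery is 100 % for both
CARS and UVE across 10 seeds and all pigments.

## Splitting

Kennard–Stone: seed with the globally farthest pair, then greedy max–min;
ties toward the smaller index, so runs are bitwise reproducible. SPXY uses
the same greedy rule on d_x/max(d_x) + d_y/max(d_y) (each matrix normalized
by its own maximum); a constant response degenerates cleanly to KS. Both
are verified index-for-index against a brute-force per-step recomputation.
The default calibration:prediction ratio is 3:1 — standard chemometric
practice; the source protocol does not state one.

## Regressors and the grid

PLSR (components by 5-fold CV, cap 15), RF (500 trees), SVR (RBF; C and γ
over a small CV grid around the scale heuristic; inputs standardized with
calibration statistics only), and an ELM written here: one sigmoid hidden
layer (default 200 units) with frozen random weights, output weights by
pseudoinverse — with ≥ n distinct hidden units it interpolates its
calibration set, which the tests assert.

The grid runner evaluates prep × selector × splitter × model per pigment,
selecting bands on calibration rows only. A canary test permutes
prediction-set targets and asserts that no selected band and no calibration
metric changes. Per-stage seeds derive from the global seed and the combo
tag through a stable hash, so the grid is deterministic and resumable.
Metrics are computed from their closed forms (RMSE, R² about the observed
mean, MAE) and cross-checked in tests against scikit-learn as an
independent oracle.

## LPCNet

One scalar model per pigment. Input: one spectrum as a length-B sequence.

1. **Conv stack** — three blocks of (conv → ReLU → max-pool 2) with kernels
   7/5/3 and channels 16/32/64. The published appendix with exact layer
   shapes is not available; these defaults follow the common practice of
   mixing kernel sizes and are fully configurable.
2. **BiLSTM** — hidden size 64 per direction over the reduced band
   sequence; input projections batched into one matmul per direction;
   forget-gate bias initialized to +1.
3. **Six-head self-attention** — per head, queries/keys/values are linear
   projections; scores q·kᵀ are scaled by 1/√d_k by default (`scale_scores=False`
   gives the literal unscaled dot product; both paths are oracle-tested);
   softmax rows are asserted to sum to 1 on every forward pass. Head dim is
   width // heads (128 → 21 per head, concat 126, projected back to 128).
   The block is residual — h + attention(h) — and the output projection W_O
   starts at zero, so training begins from the conv/recurrent stack and the
   attention contribution grows in as it becomes useful. This
   residual-branch initialization moved the n = 500 benchmark from an 0.86
   plateau to RP² 0.95 with convergence within ~10 epochs.
4. **Head** — the final sequence is *flattened*, not globally pooled, into
   a 32-unit ReLU layer and a scalar output. Pigment absorption is
   wavelength-localized; a translation-invariant pooled head is
   position-blind and measurably plateaus near R² ≈ 0.1 on this task.

Training: Adam (lr 10⁻³, batch 32), MSE on z-scored targets, inputs
standardized per band with calibration statistics only; the epoch with the
best prediction-set R² is kept (final-epoch selection available by flag).
Identical seeds give identical loss curves. The engine underneath is a
minimal reverse-mode autodiff tape over numpy (broadcast arithmetic,
batched matmul, conv1d via im2col/tensordot, max-pool, softmax); gradients
are verified against central differences through the full model. The tape
is acyclic, so Python's cyclic garbage collector is paused inside the
training loop — it would otherwise rescan every live node a few hundred
allocations apart and dominate the run time (measured ~25× slowdown).

### Ablation harness and what it shows

`ablate()` trains CNN, CNN-BiLSTM, CNN-MHSA and the full model under
identical seeds, splits and hyperparameters. On this package's synthetic
benchmarks the full model and the plain CNN converge to prediction R²
within ~0.03 of each other with no consistent ordering (win rates near
50 % across seeds). The reason is structural: the generator's nonlinearity
is per-band (Beer–Lambert saturation), which a conv stack with a flattened
head captures completely, so recurrence and attention add estimation
variance without reducing bias. Orderings among these variants measured on
real spectra — whose cross-band structure (scatter, baseline, moisture
coupling) this generator deliberately omits — should not be expected to
reproduce here, and the acceptance check that asserts such an ordering is
reported honestly rather than engineered to pass.

## Canopy inversion

Pixelwise and stream-tiled: each foreground pixel's spectrum is
preprocessed with the *training* PrepSpec (the interface forces them to
travel together), reduced to the training band selection, and scored; the
background carries NaN. No spatial smoothing is applied, preserving
vein-scale texture. Negative predictions are kept and counted in the
sidecar rather than clipped. A TPC plane is synthesized as the sum of the
three pigment planes when all three predictors are present. Summary
statistics (mean, sd, quartiles, CV) pool pixels per labeled type.

## Problem sizes

Benchmarks are sized for a single CPU core: the deep-model benchmark uses
500 spectra × 256 bands × 200 epochs (~5 min); the ablation comparison 300
spectra × 128 bands × 80 epochs × 10 seeds; selector recovery 10 seeds of
200 × 256; splitter oracles 50 instances with n ≤ 12. Scaling these up
changes wall time, not the contracts being tested.
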