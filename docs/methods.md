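# Methods

This note documents the models behind `nodulescope`, the defaults that
matter, and the design decisions taken where the underlying vendor
workflows leave the algorithmic details open.

## Raman forward model and pipeline

A synthetic spectrum on the fingerprint grid (default 600–1800 cm⁻¹ at
1 cm⁻¹; configurable) is

```
I(x) = slope · [ Σ_k A_k exp(−(x−c_k)²/2σ_k²) + B(x) ] + offset + ε,
ε ~ N(0, noise_sd²)
```

with the bone-like default band set 960 (PO₄ ν₁, A=500, σ=6), 1070
(carbonate), 1242 (Amide III), 1450 (CH₂) and 1660 cm⁻¹ (Amide I,
A=100, σ=16). The three middle bands are cosmetic context only; the
phosphate and Amide I bands carry the quantified truth. The default
Amide I amplitude (area ≈ 4000, mineral-to-matrix ≈ 1.9) is a plausible
level for cell-derived mineralised nodules and was fixed, together with
the default noise (2% of the phosphate amplitude), as the study
condition for all recovery experiments. `B(x)` is a degree-≤5
polynomial in the axis mapped to [−1, 1] (the well-conditioned domain),
so the degree-5 corrector is exactly well-specified against it; noise
is additive Gaussian only — intensities are in arbitrary units, so
Poisson shot noise is deliberately omitted. `slope`/`offset` emulate
multiplicative scatter distortion, which MSC inverts.

Pipeline order: smooth → baseline-correct → peak position and raw areas
→ exclusion filter (phosphate area < 500, strict inequality) → MSC over
the kept set → areas recomputed on MSC-corrected spectra for the
mineral-to-matrix ratio. Peak position is read from the un-normalised
corrected spectra (position is scale-invariant); both feature tables
are emitted rather than guessing which stage a given downstream
analysis wants.

### Baseline correction

Iterative clipped reweighting: fit a degree-5 polynomial, drop points
more than ε above the fit, refit; stop when the baseline's relative L2
change is < 1e-6 or after 100 iterations (non-convergence is logged,
the result still returned). Two numerical choices matter:

* **ε** defaults to `"auto"` = 2 × the robust (1.4826·MAD) residual
  scale. A fixed ε = 0 makes the polynomial drift onto the lower noise
  envelope (a non-constant ≈ −1.5 σ bias); the auto clip keeps it
  centred in the noise. ε remains settable as an absolute float.
* The pipeline passes the two analysis windows (930–990, 1620–1700) as
  **fit-exclusion (anchor) regions**. Without this, the wings of the
  broad Amide I band — which never rise far enough above the fit to be
  clipped — pull the polynomial upward under the band and shave a few
  percent off its area.

With both in place the corrector is exact on noiseless
polynomial(+peak) input and unbiased (≲0.3 counts) under noise.

### Peak quantification

Single Gaussian by nonlinear least squares; area is the analytic
A·σ·√(2π) (identical to numerical integration for a true Gaussian).
`fit_peak` offers an additive constant offset (default on, as a general
tool); the pipeline's `extract_features` fits the pure 3-parameter
Gaussian instead, because the anchored baseline already guarantees a
zero local offset and a free constant is nearly degenerate with the
Amide I wings in an 80 cm⁻¹ window (measured: ~7% area MAE with offset
vs ~2% without, at the default noise). Fits whose centre lands on a
window boundary are flagged and excluded from position statistics.

At the standard conditions (100 spectra, noise 2% of the phosphate
amplitude) the suite requires: position MAE < 0.1 cm⁻¹, band areas
within 3%, mineral-to-matrix within 4%.

### MSC and PLS-DA

MSC regresses each spectrum on the set mean (or an explicit reference):
y ≈ a + b·ref, corrected = (y−a)/b; exact inverse of the generator's
affine distortion. PLS-DA regresses one-hot class codes on the spectra
(PLS2/NIPALS via scikit-learn, no scaling); with components spanning
the full column rank its fitted values coincide with ordinary least
squares, which the suite checks against an independent `lstsq` oracle.
Venetian-blinds cross-validation assigns sample i to fold i mod 10 in
input order (a `--shuffle-seed` pre-permutes reproducibly; the source
ordering is otherwise preserved since no ordering is canonical).
Reporting conventions, all configurable: a sample is *classified* when
exactly one class's predicted code exceeds 0.5; sensitivity/specificity
are one-vs-rest over classified samples; classification error is
1 − (sensitivity+specificity)/2. Under label permutation this error
sits at 0.5 (chance) by construction.

## AFM forward model and analytics

Synthetic curves use the pyramidal (Bilodeau) Hertz relation
F = 0.7453·tanα · E/(1−ν²) · δ², α = 20° (a typical face half-angle
for sharp silicon probes; required, logged config), ν = 0.3, spring
constant 16 N/m, setpoint 3650 nN. Because the measured force deflects
the cantilever, the generator solves F = a(d₀ − F/k)² self-consistently
(closed form 2a·d₀²/(1+2t+√(1+4t)), t = a·d₀/k) so the forward model
and the fitter share one exact physics. Retraction mirrors the elastic
approach and appends adhesion events on the separation axis out to
4 μm: triangular (analytic energy ½·F·w) or truncated-exponential
(λ = w/4) pulls with given rupture separation, peak force and width.

Analysis choices (the vendor software leaves all of these unstated):

* **Baseline/noise**: median and 1.4826·MAD over the off-contact 30% of
  the approach; the same free-air zero is reused for the retraction,
  whose own far end contains the adhesion events.
* **Contact point**: first sustained (5-point) excursion above 5σ,
  then refined as a free fit parameter within ±50 nm.
* **Hertz fit**: the model is evaluated in piezo coordinates with the
  *predicted* force in the deflection term. Substituting the measured
  noisy force into δ attenuates E by ~8% at 1%-of-setpoint noise
  (errors-in-variables); the self-consistent form removes that bias.
  The residual includes up to 150 nm of pre-contact baseline — the flat
  stretch pins z₀, which otherwise trades against the stiffness and
  biases it upward by ~2–3%. With both, recovery over 100 noisy curves
  is unbiased (bias < 0.1%) and exact on noiseless input. The tip is
  treated as rigid by default (silicon, ~170 GPa, dwarfs the sample);
  a reduced-modulus mode using ν_tip is available and logged.
* **Adhesion**: computed on the tip-sample separation axis
  s = (z−z₀) + (F−b)/k (height-axis mode available). Events are runs
  of ≥3 consecutive points below baseline − 3σ, merged when closer
  than 100 nm (threshold chatter spans tens of nm; distinct ruptures
  are ≥0.1 μm apart). Adhesion force = deepest sub-baseline force;
  adhesion length = separation of the last event's last sub-band point
  (the *last* rupture; a deepest-event reading would be a one-line
  change); energy = trapezoidal work of the raw force over event
  regions extended to their zero crossings, in fJ (nN·μm ≡ fJ) —
  integrating `min(F−b, 0)` over the whole tail would rectify noise
  into a systematic surplus.

Aggregation follows the measurement hierarchy — curve → per-location
median → per-nodule median → pooled group distributions — excluding
flagged curves and reporting counts at every level.

## Statistics

Kruskal-Wallis (tie-corrected, χ² approximation; all-identical input is
defined as H=0, p=1) with Dunn's pooled-rank z post-hoc, Bonferroni
over all pairs by default (unadjusted values also emitted). Histograms
use half-open lower-inclusive bins with the final bin closed and
out-of-range values clamped into the end bins; default ordinal scores
are 1..k. The trend test is χ² = (N−1)r² on the score correlation
(df=1); γ = (C−D)/(C+D) over concordant/discordant pairs; standardised
residuals default to the Haberman adjusted form (the variant that
supports per-cell significance statements), raw Pearson by flag.
Calibration: at group size 50, both the omnibus and the trend test
reject 1000 null cohorts at 5% ± 1.5% (group size matters — at n=20 the
χ² approximation of H runs visibly conservative).

## Synthetic cohorts and what passing does (not) show

`CohortDesign` draws per-sample truths around the defaults: phosphate
position jitter SD 0.3 cm⁻¹, per-band amplitude CV 15%, scatter slope
CV 10% and offset SD 10, spectral noise 2% of the phosphate amplitude;
modulus CV 20% (lognormal) and force noise SD 2 nN (instrument-level;
the harsher 1%-of-setpoint level is exercised separately in the modulus
recovery study). Group effects enter as exact offsets (position shift,
Amide area scale, modulus scale). All randomness flows from one integer
seed with the sample index mixed in, so cohorts are order-independent
and bit-reproducible.

The end-to-end study (100 replicates; 40 samples/group; effects
+1 cm⁻¹, ×0.7 Amide, ×0.5 modulus; one-sided Mann-Whitney at α = 0.05
per metric) detects all three directions in ≥90% of replicates and
triggers at ~5% per metric on zero-offset cohorts. The replicated
end-to-end runs use the 2 cm⁻¹ grid (the generator grid is
configurable) to keep the study lightweight; recovery accuracy is
validated on the default 1 cm⁻¹ grid.

What the generators do **not** emulate: overlapping/asymmetric bands,
cosmic-ray spikes, Poisson shot noise, instrument drift, cantilever
dynamics or thermal calibration, substrate (bottom) effects,
viscoelasticity, or polymer-chain force signatures within adhesion
events. Passing the suite therefore demonstrates correct inversion of
the stated forward models and calibrated statistics — not parity with
any particular vendor implementation on real nodules, whose absolute
values depend on unpublished contact-point and fit-range conventions.

## Degenerate inputs and tie-breaks

All-zero spectra: zero baseline, zero corrected. Flat fit windows: a
`NoPeakError`. Non-positive Amide area: ratio undefined (NaN), flagged.
Empty post-filter sets: multivariate stage skipped with a warning,
univariate outputs intact. Curves without a detectable contact or with
a non-positive fitted modulus: flagged and excluded from summaries.
Ties in rank tests use midranks with the standard tie corrections.
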