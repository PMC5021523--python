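# Methods

## Model

The response model is divisive normalization with location-specific
suppression. Each stimulated receptive-field location *i* (three task
locations; a middle one common to both tested pairs, plus a clockwise and
a counterclockwise flanker) contributes an excitatory drive `L_ij`
(orientation-dependent, units of expected spikes per 250 ms count window)
to the numerator and a suppressive weight `α_i` (orientation-independent)
to the denominator; `σ ≥ 0` adds baseline suppression and keeps the
denominator away from zero for weak inputs. Attention to a location
multiplies that location's `L` and `α` by a single gain `β`; attending
away from the receptive field corresponds to `β = 1`. `α₁` is fixed at 1:
responses only constrain the ratios of suppressive weights to each other
and to `σ`, so one weight must pin the scale, and with `α₁` fixed,
multiplying all observed responses by *c* scales all fitted `L` by *c*
and leaves `α`, `β` unchanged (tested).

Two consequences the test suite leans on: with `β = 1` every attended
equation reduces to the attend-away equation; and with `σ = 0` a lone
attended stimulus is β-invariant (`βL/(βα) = L/α`), which is why a model
without `σ` cannot express attention effects on single stimuli.

## Task and conditions

Three iso-eccentric stimulus locations (eccentricity 3.6°, neighbouring
separation 2.3°), two orthogonal Gabor orientations, two tested location
pairs (middle+clockwise, middle+counterclockwise). The 36 fitted
conditions are 12 single-stimulus (3 locations × 2 orientations ×
{attend stimulus, attend away}) and 24 paired (2 pairs × 4 orientation
combinations × {attend A, attend B, away}). Blank presentations are
simulated for baseline estimation but never fitted. The attend-away state
is one condition by default; when a table distinguishes the two far
attention loci, their per-locus means are averaged rather than pooled.

## Synthetic populations

The generator is parameterised directly in model terms plus a planar
Gaussian receptive field. Defaults (the package's study conditions):

- Receptive-field centres scatter around the stimulus-array centroid
  (s.d. 1.8°); widths uniform 0.8–1.6° per axis with random orientation.
- Peak excitatory drive log-normal (median 12 counts/window ≈ 48 sp/s);
  `L` falls off with the location's distance from the RF centre as a
  Gaussian of scale 1.0°, with orientation tuning drawn Beta(2,2) and a
  ×exp(N(0, 0.15)) per-entry jitter.
- Suppressive weights fall off exponentially with scale 2.8° — slower
  than excitation, so suppression extends beyond the classical receptive
  field — renormalised to `α₁ = 1`, with a ×exp(N(0, 0.55)) jitter.
  The wide jitter encodes strong across-neuron heterogeneity of
  normalization strength; with weak heterogeneity the fixed-α variant
  loses almost nothing in cross-validation, contradicting the large
  spatial-tuning effect the variant comparison is meant to expose.
- `σ ~ Exponential(0.15)` (median ≈ 0.10, a small-σ regime), `β`
  log-normal with median 1.8, which puts the mean attention-modulation
  index near 0.09.
- Spike counts are Poisson per trial with mean `expected_count +
  baseline`. The additive spontaneous rate defaults to 0 (the model has
  no baseline term); population-level analyses use `baseline = 1.0`
  count/window (≈ 4 sp/s), without which the inclusion ANOVA has a
  zero-variance null, every weakly-driven location classifies as cRF,
  and sRF-cRF selectivity degenerates to ≈ 1.

What the generator does **not** emulate: trial-to-trial correlations,
overdispersion beyond Poisson, adaptation or temporal dynamics within the
window, orientation-tuned suppression, eye-position jitter, and recording
artefacts. Passing tests therefore demonstrate correctness of the
analysis machinery and the qualitative behaviour of the model family, not
robustness of the conclusions to those real-data complications.

## Neurometrics

Inclusion and classification use a one-way ANOVA (α = 0.05) of a
condition's counts against blank-presentation counts, with the extra
requirement that the stimulus mean exceed the baseline mean (neurons
suppressed below baseline by everything are excluded). A location is cRF
if either single Gabor there drives the neuron significantly above
baseline (attend away), surround if neither does while the neuron passes
global inclusion; an optional stricter surround criterion additionally
requires > 2.5 Mahalanobis s.d. from the fitted RF centre. With two
orientations tested directionally, the false-cRF rate on a true surround
location lands near the nominal 5% (calibrated in the suite). Pairs enter
population analyses when the attend-away pair response is ≥ 1
spike/window. A surround stimulus is always assigned non-preferred,
which can make the selectivity index mildly negative when noise puts the
surround mean above the cRF mean; exact ties break by (location,
orientation) order. Undefined indices (zero denominators) propagate as
missing values.

Receptive-field geometry: centre of mass of the raw 8×8 mapping grid;
bivariate Gaussian least-squares fit (log-σ / tanh-correlation
parameterisation keeps the covariance positive definite) with explained
variance ≤ 80% flagged unreliable; Mahalanobis distances use the fitted
covariance. PSTHs use 1 ms bins smoothed by a σ = 5 ms Gaussian
(area-preserving).

## Fitting and model comparison

Fits minimise SSE over the 36 condition means (not raw trials) with
Nelder-Mead in an absolute-value-transformed space, which enforces
nonnegativity while staying in the simplex family. Initialisation is
data-informed (`L` from single-stimulus attend-away means × 1.1, α = 1,
σ = 0.1, β = 1), with 10 jittered restarts by default (heavy
cross-validation loops use 1–3; restarts are optimizer numerics, not
study conditions) and a polish loop that restarts the simplex from its
own solution until the SSE improvement is below 1e-12 (≤ 3 rounds).
Convergence: relative SSE change < 1e-9 or 5×10⁴ evaluations. On
noise-free data this recovers parameters to 1% (with a 1e-3-count
absolute floor for negligible drives).

Cross-validation: per repeat, trials are randomly halved within each
condition; the model is fitted to one half's means and scored (squared
Pearson correlation) on the other half's means, both directions, averaged
over 5 repeats. Conditions with fewer than two trials are excluded with a
warning. Variants — fixed β (clamped to the population mean over included
neurons), fixed α (= 1, no spatial tuning), no σ, single shared L — are
compared by sequential F-tests on SSE (per neuron) and by paired
permutation tests on cross-validated EV across neurons; both routes are
reported because the aggregation level of the published comparison is
ambiguous. Only neurons passing inclusion are fitted: β is unidentified
on silent neurons and its fitted value can diverge.

## Population statistics

The interaction regression is OLS of attention modulation on selectivity,
suppression, and their product. An intercept is included by default (the
canonical equation has none; both modes are selectable) — it guards
against mean offsets and changes nothing when the true intercept is 0.
Configuration comparisons cross every term with the cRF-cRF / sRF-cRF
factor; `compare_slopes` reports either the joint F-test over all
configuration terms or the three-way coefficient alone. The Bayes factor
for dropping configuration uses a Zellner-Siow (JZS) g-prior marginal
likelihood (r = √2/4, 1-D quadrature in log space) by default, with a BIC
approximation as the alternative; neither claims bit-exact agreement with
any particular R implementation. Permutation tests sign-flip paired
differences with a t statistic, enumerate exhaustively when `2^n ≤
n_perm` (exact), and use the add-one-corrected estimate otherwise. No
multiple-testing correction is applied (raw p values are reported).
The attention surface over (suppression, selectivity) uses a
Gaussian-kernel local mean on a regular grid — any smooth gridded
interpolant serves here; the surface is descriptive.

Distance curves: per fitted neuron, the three locations' α values and
orientation-averaged L values are max-normalised, paired with each
location's distance from the fitted RF centre (degrees or Mahalanobis),
pooled and binned (mean ± SEM). With the generator's scales, normalised L
falls below normalised α at far distances — excitation is more spatially
concentrated than suppression.

## Image model

One model neuron per pixel. Local contrast is Gaussian-weighted RMS
contrast (σ = 2 px, mass-normalised at borders, local-mean Weber
normalisation, variance floor 1e-12). Each neuron pools the contrast
field under an excitatory Gaussian (σ = 8 px) and a suppressive Gaussian
(σ = 40 px; kernels truncated at 3σ) and responds E/(S + s) with
semisaturation s = 1e-3 (sensitivity: any s ≪ typical S only matters on
blank regions). "No surround" zeroes suppressive weights beyond the cRF
radius (16 px = 2 excitatory s.d.) without renormalising, keeping
within-cRF suppression identical. Attention is a multiplicative gain
field `1 + 6·exp(−d²/2·5²)` applied to the contrast input before both
poolings — the image analogue of β multiplying both L and α; whether the
kernel's baseline is 0 or 1 is not externally constrained, and the
multiplicative-gain reading is the one consistent with the spiking model.
Attention modulation per pixel is `(Rₐ − R)/(Rₐ + R)` with 0/0 → 0. The
bundled test scene is synthetic 1/f noise plus a few Gaussian blobs,
generated by code at run time.

## Problem sizes and determinism

The test and acceptance runs use desk-scale sizes chosen to keep the
statistics well-powered: 26–50 neurons × 40 trials/condition for recovery
and variant comparisons, 500 neurons for the population regression
(~1,600 usable Gabor pairs), 200–400 replicates for calibration rates,
128×128 images. Every random draw flows through `numpy` Generators seeded
explicitly; pipelines derive per-stage seeds from one master seed, so
identical configurations reproduce byte-identical tables.

## Known limitations

- The interaction regression is a linear probe of an index surface that
  is nonlinear in the model parameters; its coefficients depend on the
  sampled (selectivity, suppression) distribution, and small systematic
  configuration differences can surface at very large n even when one
  generative rule produced both configurations.
- Explained variance as squared correlation is offset- and
  scale-blind; a fit can score 1 while being affinely wrong (tested,
  documented).
- Trial-level (e.g. Poisson-likelihood) fitting and hierarchical sharing
  across neurons are out of scope.
- The JZS Bayes factor uses one conventional prior; conclusions reported
  here are direction-level (BF above or below 1), not calibrated
  evidence magnitudes.
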