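# attnorm

Spatially-tuned divisive normalization model of visual attention, with the
full analysis pipeline around it: synthetic spike-count generation for an
attention task, neurometric indices, constrained model fitting with
cross-validation, population-level interaction statistics, and an
image-based simulation of attention with and without a suppressive
surround.

The package is aimed at systems neuroscientists who want to test, on
fully-controlled synthetic data, how multiplicative attention gains
interact with spatially-varying excitation and divisive suppression in
extrastriate visual neurons — and at anyone who needs a seeded, tested
reference implementation of this model family.

## The model

A neuron's mean spike count to a set of Gabor stimuli is pooled excitatory
drive divided by pooled suppressive drive:

```
R = (Σ_i L_i·g_i) / (Σ_i α_i·g_i + σ),      g_i = β if location i is attended, else 1
```

- `L_ij` — excitatory drive of a stimulus of orientation *j* at
  receptive-field location *i* (expected spikes per 250 ms window),
- `α_i`  — suppressive weight of stimulated location *i*, independent of
  orientation (the *spatial tuning* of normalization); `α₁ ≡ 1` sets the
  scale,
- `σ`    — baseline (semisaturation) suppression,
- `β`    — attention gain, multiplying both the `L` and the `α` of the
  attended location; attention away means `β = 1`.

For a pair at locations 1 and 2 with attention on 1:
`R = (βL₁ + L₂)/(β + α₂ + σ)`.

Fitting minimises squared error over the task's 36 stimulus × attention
conditions with a Nelder-Mead simplex under nonnegativity; goodness of fit
is the squared Pearson correlation with held-out condition means under
two-fold cross-validation (5 random half-splits). Nested variants clamp
β (population mean), the α's (no spatial tuning), σ (none), or collapse
all `L` to one value.

From condition means the pipeline computes, per Gabor pair, the
selectivity index `(P−N)/(P+N)`, the stimulus-induced suppression index
`(P−PN)/(P+PN)`, and the attention-modulation index
`(PᵃᵗᵗN−PNᵃᵗᵗ)/(PᵃᵗᵗN+PNᵃᵗᵗ)`, then fits

```
attention = β₁·selectivity + β₂·suppression + β₃·selectivity·suppression + ε
```

whose interaction term β₃ carries the central claim: attention modulation
requires both a response difference to exploit *and* suppression to give
it leverage.

## Worked example

`examples/01_normalization_model.py` (all examples run in seconds to a
few minutes):

```
pair response, attend away:        6.000
pair response, attend strong (L=8): 6.667
pair response, attend weak   (L=4): 5.333
```

With drives of 8 and 4, unit suppressive weights and β = 2, attending the
stronger stimulus raises the pair response from 6 to 6.67 and attending
the weaker lowers it to 5.33 — attention reweights the competition that
normalization implements. `examples/04_population_interaction.py` runs
the pipeline end-to-end on 150 simulated neurons and prints the
interaction regression (β₃ ≈ +0.36, p ≈ 4e-4, suppression main effect
p ≈ 0.9, Bayes factor ≈ 58 for one rule across cRF and surround), and
`examples/05_image_attention.py` shows the image model's surround
amplifying attention modulation ~9× near the attended locus.

A thin CLI wraps the pipeline: `attnorm run-all --seed 0 --out results/`.

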