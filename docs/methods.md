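# Methods

## Generative melt-curve model

No public model exists for the shape of probe-based melt curves, so the
simulator adopts the simplest physically motivated form: probe–target
duplex dissociation is a two-state transition, giving a decreasing logistic
in temperature. A segment's raw curve is

    F(T) = b₀ + b₁·(T − T_min) + Σₖ aₖ · σ((tmₖ − T) / wₖ),   σ(u) = 1/(1+e⁻ᵘ)

with per-component melting temperature `tmₖ` (°C), width `wₖ` (°C, transition
steepness) and amplitude `aₖ` (relative fluorescence). The derivative
signature then shows one trough per component at `tmₖ` with depth
`aₖ/(4wₖ)`, matching the trough-type signatures the assay produces. The
baseline is flat by default (`b₀ = 0.2`, `b₁ = 0`).

Acquisition follows the assay's melt program: 40→87 °C with 4,076 samples
per segment, so the two concatenated segments give the 8,152 classifier
variables. The 0.1 °C/s ramp is folded into the grid; time is not modelled.

Every BS1 model includes the internal temperature marker (ThermaMark) as a
fixed rightmost component at 84.0 °C (width 0.4, amplitude 0.6). Species
components are drawn per seed from 14 slots spanning 46.5–78.5 °C
(jitter ±0.5 °C, widths 0.35–0.6 °C, amplitudes 0.6–1.2, 2–4 components per
segment); slot spacing guarantees transitions are separated by at least
twice the maximal width, and the marker stays strictly rightmost.

### Noise model

Four artefact classes, all seedable and all off in "zero-noise" mode:

| parameter | default | emulates |
|---|---|---|
| `amplitude_scale_sigma` | 0.10 (log-scale s.d.) | global peak-height/valley-depth variation from template quality |
| `degradation_factor` | ×3.5 for "processed" samples | stronger amplitude variation in degraded DNA |
| `temperature_offset_sigma` | 0.30 °C | rigid instrument temperature drift, shared by both channels of a run |
| `per_component_jitter` | 0.05 (relative s.d.) | probe-binding variability per transition |
| `additive_noise_sigma` | 0.002 (fluorescence) | instrument read noise |

Additive noise is applied **before** the global amplitude scale, i.e. it
co-scales with the signal. This models fluorescence noise as
signal-proportional and makes the QC energy *ratios* independent of a run's
degradation state, so the filtering rules behave identically for fresh and
processed samples at any seed.

### Corpus design

The default corpus mirrors the emulated study structure: 130 specimens over
28 species (counts are unequal because field sampling is opportunistic —
nine commonly traded species carry 6 specimens, the rest 4), three
replicates each (390 runs), alternating fresh/processed condition, plus 68
single-run test specimens covering all species. A packaged manifest pins
exactly 33 failed runs — 14 BS1 hybridization failures, 10 BS2 failures,
9 inconsistent replicates, at most one per specimen, concentrated on the
species whose segments amplify unreliably. Runs not named in the manifest
are pinned clean by default, so the corpus contains exactly the designed
failures; per-species hybridization-failure probabilities exist for
free-running simulation. An "inconsistent" run is simulated by shifting
every species transition by a random 2.5–4.5 °C; a failed BS1 keeps only
the marker; a failed BS2 is baseline plus noise.

Three look-alike pairs emulate sequence-identical mini-barcodes: tiger
shark/giant shovelnose ray and the two *Mobula* rays are identical in both
segments; silky/blue shark are identical in BS1 and differ in BS2 by a
0.2 °C shift of one transition (resolvable by the classifier at full grid
resolution, not by eye).

## Signature extraction

The derivative is estimated by Savitzky–Golay local-polynomial filtering
(`deriv=1`). The default window is chosen automatically to span ~0.35 °C
(31 points on the default grid) with polynomial order 2: the window is
several times narrower than any transition (minimum ~1.4 °C full width), so
troughs are essentially unattenuated, while the differentiated noise floor
(~3.5×10⁻³ in derivative units) sits two orders of magnitude below trough
depths. Order 2 was preferred over 3 because its derivative noise variance
is ~5× lower at equal window; order 3 with an 11-point window — a plausible
alternative — leaves enough differentiated noise to erode the QC margins.

Marker detection takes the rightmost local minimum with prominence ≥ 0.05
inside 84 ± 3 °C, excluding ~0.15 °C at the grid edges where the filter's
edge polynomials amplify noise. Temperature correction shifts both channels
rigidly by `84.0 − tm_detected` with linear re-interpolation; regions
shifted past the grid edge are zero-filled (zeros are neutral for both
energy-based QC and the classifier). Signatures are *not* amplitude
normalized by default — amplitude variation is a real weakness of
melt-signature classification and the pipeline preserves it; a per-segment
min–max switch exists for experimentation.

## Quality control

Rule 1, hybridization failure: after masking ±1.5 °C around the marker, a
BS1 signature fails if residual energy (sum of squares) is below
θ_h = 0.05 of the marker-band energy; a BS2 signature fails if its total
energy is below θ_h of the corpus-median BS2 energy. Because noise
co-scales with signal, both ratios are scale-invariant: the noise-floor
residual ratio is ~0.01 and genuine signatures sit above 0.5, so the
threshold is >5× from either population. A run with no detectable marker at
all is classed as a BS1 hybridization failure.

Rule 2, replicate inconsistency: within a specimen, while any pair of
surviving replicates has correlation distance (1 − Pearson r of the merged
BS1+BS2 signature) above θ_c = 0.2, the run with the largest mean distance
to its siblings is removed (ties by run id); with only two survivors no
side can be adjudicated and both are flagged; singletons are never flagged.
This iterative form replaces a plain mean-distance threshold because the
latter also condemns the *good* replicates of a specimen containing one
outlier (their mean distance is contaminated by the outlier), which would
make exact recovery of designed failures impossible. The wet-lab "re-run
and re-measure" loop has no in-silico counterpart; filtering is a single
flag-and-remove pass. A species-centroid variant of the rule is not
enabled by default.

Statuses partition the corpus (hybridization rules first, consistency
among survivors), and the report tallies removals by cause, per-condition
reliability rates and per-species amplification flags.

## Classifier

The network is written in numpy: dense layers (ReLU or tanh), softmax
output, multinomial cross-entropy, minibatch SGD (batch 32) with
backpropagation, He initialization from the config seed. Inputs are
standardized per feature with training-set statistics stored in the model.
Regularization uses proximal/decoupled updates — l1 as soft-thresholding by
`lr·l1`, l2 as weight shrinkage by `(1 − lr·l2)` clamped at zero — which is
equivalent to penalty gradients at small values and remains stable in the
penalty-dominated limit. RMSE is defined on one-hot targets versus softmax
scores (the conventional multinomial definition); accuracy and RMSE are
logged for both split sides every epoch. Argmax ties resolve to the
alphabetically first class — identical look-alike species genuinely tie at
zero noise, so the tie-break is part of the contract.

Splitting is exact-count stratified at 0.70 per species (each stratum
within one row of the global fraction; singleton strata go to the training
side with a warning). Replicates of one specimen may land on both sides,
reproducing the run-level protocol of the emulated workflow; a
group-by-specimen mode is provided as the leak-aware alternative. Note
that exact-count stratification of 357 runs yields 249/108, not the
246/111 a different splitter might produce; the exact upstream mechanism
is not documented anywhere and this package does not try to guess it.

Grid search enumerates the cartesian parameter grid (the shipped space has
432 combinations over layer sizes, activation, learning rate, l1, l2,
epochs), visits it in a seeded random order, and stops at `max_models`
(default 301) or an optional wall-clock cap. The best candidate maximizes
validation accuracy, ties broken by lower validation RMSE, then earlier
evaluation order. Models persist as self-describing JSON (config, classes,
standardization vectors, weights, metrics, history).

## Evaluation

Confusion matrices are counted in fixed panel (report) order. "Visual"
distinguishability — human judgment in the emulated workflow — is replaced
by a reproducible proxy: a species is visually indistinguishable when some
other species' noise-free mean signature is within correlation distance
δ = 0.05 in *both* segments (one clearly different segment suffices for an
inspector). Classifier distinguishability requires that no specimen of the
species is misassigned and nothing else is assigned to it; a correct
species whose winning-score margin drops below 0.1 carries a
misassignment-risk flag; species absent from the test set are reported
"unassessed", not "indistinguishable".

Panel tallies are recomputed from the packaged status-table flags. The
flags imply 26 species distinguishable by visual-or-classifier (21 of them
CITES-listed), whereas narrative summaries of such tables sometimes quote
slightly different union counts; the tallies here are always the flag
arithmetic, never a copied headline number.

## Problem sizes and numerical choices

End-to-end tests and examples run the full 390+68-run corpus at a reduced
grid of 512 points per segment (1,024 features); feature-width and
QC-count checks also exercise the full 4,076-point grid, and the
grid-search count check uses an 8-species, 48-run corpus at 128 points.
These sizes were chosen so the complete suite runs in well under a minute
while every property of interest — marker recovery to one grid step, exact
QC recovery, ≥90% validation accuracy with look-alike confusability — is
preserved at full resolution.

Degenerate inputs are handled explicitly: constant signatures have zero
derivative and no marker; correlation distance involving a constant vector
is defined as 1 (or 0 between two constants); empty corpora, duplicate run
ids, single-class training sets, mismatched grids and non-finite losses
raise immediately.

## Limitations

The logistic-mixture curve is a stand-in, not a thermodynamic model: no
nearest-neighbour Tm computation from probe/target sequences, no
amplification-efficiency or fragment-length modelling (degradation is
amplitude variance only), and no within-species sequence polymorphism.
Consequently, passing tests show that the *pipeline* recovers what the
generator encodes — they do not certify performance on real instrument
exports, where signature shape variation, baseline drift and
between-instrument differences are richer than this noise model.
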