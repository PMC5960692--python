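# Methods

This note documents the models, rules and numerical choices implemented in
`odortrace`, and what the synthetic-data tests do and do not establish.

## Data model and conventions

A recording is a `TraceSet`: units × frames × stimulus presentations, with
per-unit metadata (animal, unit id) and per-presentation metadata (odorant,
trial).  Default acquisition geometry: 5 Hz, 175 frames (35 s), stimulus
onset at frame 25, 10-s stimulus; stimulus onset defines t = 0.  All frame
windows are half-open `[start, stop)` and 0-based; "frames 10–25" therefore
denotes the 15 frames 10…24, the only reading consistent with a 15-frame
background window.  Two named analysis windows recur: the **odor response
pattern** (mean over t = 1–2 s, 5 frames) and the **post-odor response
pattern** (t = 15–16 s, i.e. 5 s after offset of a 10-s stimulus — the
latency at which trace-conditioning behaviour still shows a sensory odor
memory).

## Preprocessing

ΔF/F is computed per unit and presentation as (F_i − F_B)/F_B with F_B the
mean raw fluorescence over the background window (default frames [10, 25)).
Units with non-positive or non-finite F_B cannot be normalized and are
dropped (logged); ΔF/F is scale-free by construction.

Photobleaching is modeled as F(t) = a·e^{bt} + c and removed by least
squares (scipy `curve_fit`) on the ΔF/F trace, then subtraction and
re-zeroing of the background window.  Choices:

* **Fit window.** By default the fit excludes the stimulus epoch plus 5 s:
  a large calcium transient inside the window biases the decay rate.  A
  full-trace mode (`exclude_response=False`) implements the plain reading.
* **Response-contaminated tails.** Prolonged and off responses can outlast
  the excluded epoch, leaving no clean late segment.  Traces whose late fit
  segment is elevated above the pre-stimulus level (mean lift > 2.57 σ or
  max lift > 5.14 σ, with σ estimated from first differences of the
  pre-stimulus segment so the bleach trend itself does not inflate it) are
  refit with b pinned to the median b of the recording's clean traces and
  (a, c) solved linearly on the pre-stimulus frames.  Without this, a free
  exponential chases the response plateau and destroys the post-odor
  signal.
* **Initialization / failure.** Deterministic start values (amplitude from
  the endpoints, rate from the log-ratio of the first/last thirds, offset
  from the last value); on non-convergence a linear-trend fallback with b
  pinned to −10⁻⁴/frame is used and flagged.  b is not constrained
  negative; a positive estimate warns (focus drift) but is kept.
* **Known limitation.** Bleaching acts multiplicatively on fluorescence
  while the correction is additive, so responses remain attenuated by the
  residual bleach factor (≤ ~20% at the end of a default recording).  This
  cancels in Pearson correlations and decoding (a common per-frame scalar
  across units) and shifts category ratios only marginally.

## Response categorization

Per trace, the response threshold is 2.57 × sample SD (n−1) of the
pre-stimulus window — the one-sided normal p < 0.005 level.  Decision tree:
crossing during the stimulus → *on* if the trace falls below
`decay_fraction` (default 1/e) of the stimulus maximum at any frame within
5 s after offset, else *prolonged*; no stimulus crossing but mean ΔF/F in a
1-s window centered 5 s after offset above threshold → *off*; else *none*.

* **Crossing = 2 consecutive frames** above threshold by default.  A
  single-frame rule at a per-frame false-positive rate of 0.005 fires
  somewhere in the 50-frame stimulus window for ~20% of silent traces
  (independent of the noise level, since the threshold scales with noise),
  which would misclassify a large share of off units as on; two consecutive
  frames reduce the per-trace rate to ~10⁻³ without affecting genuine
  responses.  `min_crossing_frames=1` restores the literal rule.
* The 1/e decline is checked as "any frame below" within the 5-s window;
  an endpoint variant (`decay_rule="endpoint"`) checks only the value at
  offset + 5 s.  The off rule likewise has an `any_crossing` variant.
* Thresholds are one-sided positive; purely inhibitory responses are
  labeled none (the categorization rules are defined for positive
  deflections only).
* Trials are categorized independently, then combined per unit × odor by
  majority; ties resolve toward the weaker claim
  (none < on < off < prolonged).
* Category fractions are reported over *responding* entries per group
  (animal, odorant or compartment) with medians and quartiles across
  groups; groups without responders are excluded and logged.

## Pattern correlation

Population pattern vectors concatenate units across animals in a fixed
canonical order (animal id, then unit id) — a pseudo-population.  The
time-resolved matrix correlates single-frame patterns of two presentations
at every pair of time points; p-values use the t transform
t = r·√((n−2)/(1−r²)) with n = pooled unit count, two-sided, masked at a
per-cell α = 0.005 (no multiple-testing correction — masking is per cell by
design).  Zero-variance patterns yield undefined cells, excluded from any
averages.  Correlation traces average matrix rows over a 1-s reference
window; their variability envelope is the per-time SD over bootstrap
replicates that resample the *animals* with replacement (default 1000,
seeded).  The 5-frame odor/post-odor windows enter only the named pattern
definitions and the pairwise tables; matrix cells stay single-frame.

## Decoding

`sklearn.svm.NuSVC` with ν = 0.9, linear kernel (configurable; RBF
available), one-vs-one.  Training features are per-trial patterns averaged
over a 2-s window starting at the training time; test features are
single-frame patterns (a windowed-test mode exists).  Features are
z-scored per unit with statistics from the training fold only — without
scaling the ν-SVM's behaviour would depend on the raw ΔF/F magnitude.

* **Cross-validation** is leave-one-repetition-out: one full stimulus
  repetition held out per fold, so training folds stay class-balanced.
  ν = 0.9 requires ν·(n_i+n_j)/2 ≤ min(n_i, n_j) for every class pair;
  leaving out a single trial of one class (2 trials/class design) makes the
  problem infeasible, so leave-one-trial-out is not offered.  Resubstitution
  mode trains and tests on the same trials; on separable data the success
  at the training window is then trivially 1.  Odorants with a single trial
  can never be held out: they remain in training and are scored by
  resubstitution within their repetition block, flagged.
* **Summary**: success(train, test) is the fraction of correctly classified
  held-out trials; stim_avg(train) averages success over the 10-s stimulus
  window.
* **Chance band**: whole-trial label permutations re-run the identical
  pipeline (default 250); the band is the permutation mean and the 95th
  percentile ("upper 95% confidence bound").  Under
  leave-one-repetition-out, labels permute within each repetition block to
  preserve fold balance; under resubstitution all trial labels shuffle
  freely.  If fewer distinct arrangements exist than permutations
  requested, sampling is with replacement (logged).
* Deterministic: all randomness flows from the config seed.

## Synthetic data generator

The generator defines the study conditions: 8 animals × 25 units, four
odorants (ButL, ProL, AceA, ProA) plus the solvent mineral oil (MO), two
trials per odorant, 10-s stimuli at 5 Hz for 175 frames; response
amplitudes ~N(1.0, 0.3²) ΔF/F; Gaussian noise 0.03 ΔF/F on raw counts;
multiplicative bleaching 0.3·e^{−0.01·frame} + 0.7 (≈25% loss over the
recording, enough to make the decay rate identifiable at the default
noise); baseline 1000 counts.  Category mixtures and the two pattern knobs
below are preset per compartment archetype (`orn_like` … `kc_soma_like`);
the ORN mix uses the measured on/off/prolonged medians (25/44/27%), PN-like
presets are on-dominated (~75%), KC somata carry the largest prolonged
share.

Temporal kernels are exponential-rise (τ = 0.5 s) stimulus envelopes with
category-specific decay (on: τ = 1.5 s → below 1/e of max within 5 s of
offset; prolonged: τ = 12 s → above 1/e throughout the check window), an
off envelope rising after offset (τ = 2 s), and a delayed post-odor
component that is exactly zero until the post window opens and then follows
the prolonged tail shape.  Because every post component shares that tail
shape from t = 15 s on, late population patterns are proportional to the
post-pattern weights at *every* late time point — by design, so the
generator's odor ↔ post-odor relationship is controlled by weights, not by
envelope bookkeeping.  In the noiseless limit every kernel satisfies the
categorizer's defining inequalities for its true label (asserted in tests).

Two knobs control the population structure per odorant:

* `post_pattern_corr` (ρ): post-pattern weights are built as
  ρ·z(odor weights) + √(1−ρ²)·independent.  The construction uses the final
  odor-weight vector (including the structural zeros of off/none units) and
  calibrates its coefficient by a deterministic root solve until the
  realized weight-vector Pearson r equals ρ — otherwise the zero atoms bias
  the mixture correlation upward.  "None" units have their post weight
  forced to 0, and prolonged units get a category-consistent floor
  (0.45 × stimulus max, since a prolonged response by definition stays
  above 1/e of its max into the post window); both distortions are absorbed
  by the calibration.
* `post_trial_corr` (q): the share of the non-odor-pattern post variance
  common to both trials.  q = 1 gives reproducible post-odor patterns
  (KC-somata-like); q = 0 gives trial-unique post patterns (ORN-like),
  which is what makes post-offset decoding fall to chance for that preset
  even though ORNs have many prolonged/off responses.

Animals partition units but carry no random effect (no between-animal
variance model is assumed); animal identity matters only to the bootstrap.
Negative (inhibitory) responses can be enabled (`negative_responses`), off
by default; the categorizer labels them none.  A single master seed spawns
independent substreams for weights, categories, noise and stack rendering,
so identical seeds give bit-identical output.

Image stacks render unit traces into non-overlapping square footprints on a
bleached noisy background; footprint pixels carry the trace exactly, so box
averages invert the rendering.

**What passing tests show about real data.** The generator reproduces the
statistical structure the analyses assume (category-consistent kinetics, a
controllable odor ↔ post-odor correlation, animal grouping, bleaching,
white noise) but not: correlated/shot noise, movement artifacts, GCaMP
nonlinearity or saturation, between-animal response heterogeneity, odorant
similarity structure, or overlapping neuropil signals.  Green tests
establish the correctness and calibration of the *analysis chain*, not the
biology of any particular recording.

## Problem sizes in tests and the acceptance script

The compartment-contrast analyses run at 200 units, 5 classes, 2 trials,
250 permutations and a 1-frame test grid with a 5-frame training-time
stride; the null-calibration check uses 100 repeats of a 30-unit population
with a 99-permutation band; the acceptance script uses 100 units.  These
sizes were chosen so the full analysis (including the 2000 per-trace bleach
fits) completes in minutes while keeping Monte-Carlo error well inside the
asserted tolerances.

## Design choices that were genuinely open

* Matrix cells are single-frame patterns; only the named windows use
  5-frame averages.
* The per-cell p-value uses n = pooled unit count (the only n available to
  a per-cell Pearson test).
* Bleach fitting is per unit × trial (not per unit across trials), matching
  the per-presentation ΔF/F normalization.
* The activity filter (`filter_active_units`, default 0.75 ΔF/F) keeps a
  unit if its maximum single-frame ΔF/F in the stimulus-to-end window for
  any presentation exceeds the threshold — the most permissive reading of
  an amplitude criterion stated without a statistic; manual/visual unit
  selection is out of scope.
* Binning drops trailing partial tiles so every binned unit averages the
  same pixel count; boxes with even sizes center on the top-left pixel of
  the central 2×2.
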