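# Methods

This note documents the models implemented in `gazediag`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Gaze scoring model

Scores are computed directly on the raw 50 Hz sample grid. Each valid
sample contributes exactly 20 ms of dwell to every AOI that contains its
coordinates (boundary inclusive; AOIs may overlap, so dwell on an eye
region also counts toward the enclosing face region). No fixation-event
detection (I-VT/I-DT) or interpolation is applied: "gaze fixation time"
is interpreted as raw sample dwell. The optional `min_run` guard of the
count score (default 1) requires a minimum number of consecutive in-AOI
samples before a gaze "counts", as protection against single-sample
pass-throughs; all shipped defaults keep it at 1.

Rate windows are half-open `[0, w)` in clip time. The 1 s and 2 s
prefix windows divide by the window length, not the clip length, so all
300 rate attributes share the [0, 1] scale and are comparable across
clips of different durations.

The overall gaze-fixation percentage divides valid samples by the full
expected grid (Σ clip duration × 50), so missing rows count as
non-fixation. It is a data-quality metric: predictions for recordings
below 70% are returned but flagged unreliable, reflecting the
observation that very low fixation itself tends to co-occur with the
diagnosis and degrades score reliability.

## Candidate selection

Within each age band (younger < 10.0 y ≤ older; ages are decimals, the
split is exact) and score family, each attribute is compared between
diagnosed and typical training rows:

- rate attributes: Welch's t-test (a Mann–Whitney option exists behind
  `SelectionConfig.rate_test`); Welch is the default because it is
  deterministic, needs no distribution diagnostics, and is robust to
  unequal variances;
- count attributes: Fisher's exact test, the natural exact test for
  2 × 2 presence tables.

The candidate rule is a literal OR: `p < 0.05` **or** `|d| ≥ 0.5`
(Cohen's d with pooled SD). `|d|` rather than signed d is used at the
threshold because direction is captured separately as the orientation
sign. No multiple-testing correction is applied — the stage is meant to
be permissive, and overfitting is charged later by cross-validation.

The 20% fixation floor is computed as the pooled (diagnosed + typical)
training mean of the AOI's full-window rate score × 100. Pooled rather
than per-group means were chosen because the floor is a data-quality
guard on the AOI, not a group contrast. Per-AOI deduplication keeps the
largest |d|; exact ties prefer `rate_full > rate_1s > rate_2s > count`,
then the lexically smallest attribute id, making selection fully
deterministic. A comparison with zero pooled SD is degenerate
(`d = NaN`) and can only enter via its p-value, which is itself NaN for
constant columns — so degenerate attributes never pass.

Selection uses only the training rows handed to it; rows of held-out or
unlabeled participants never influence it. This is load-bearing for the
honesty of leave-one-out validation and is regression-tested.

## The best-fit model

Each (band, family) cell aggregates its candidates into one scalar:
rate values are oriented and divided by their training SD; count values
are aligned so 1 always means "more ASD-like"; the mean over candidates
is passed through a logistic sigmoid `σ(a·x + b)` fitted by mean binary
cross-entropy with `a ≥ 0` (the aggregate is ASD-oriented by
construction, so a negative slope could only encode noise). The
single-feature logistic objective is convex; a bounded L-BFGS-B solve
from three deterministic starts (tolerance 1e-8, ≤ 500 iterations)
suffices. A rate candidate whose training SD is zero contributes 0 and
is logged.

Bands are merged with a logistic age weight composed with an outer
sigmoid:

    s(age) = σ(A·[w(age)·s_young + (1 − w(age))·s_old] + B),
    w(age) = 1/(1 + exp(k·(age − a₀))),  A ≥ 0, k ≥ 0, a₀ ∈ [2, 25].

This form satisfies two constraints at once: scores vary smoothly along
the whole 5–17 age range (no step at the band boundary) while `k` can
grow to approximate the hard split if the data demand it. `a₀` is
initialized at 10, the band split. The 4-parameter objective is mildly
non-convex, so the fit uses three deterministic starts plus five seeded
random restarts. Cross-entropy rather than direct AUC maximization was
chosen as the "predictability" objective because it is smooth and
differentiable; an AUC-based objective would require non-smooth
optimization for, in practice, the same ranking.

Per band, the family with the higher in-band AUC becomes that band's
modality (ties go to rate, the richer family), and the two modality
scores are blended once more with the same age-weight form. The final
decision threshold is 0.5, inclusive.

An empty candidate cell aborts the fit by default (the construction is
meaningless without features). `FitConfig.allow_empty_cells=True`
instead gives that cell a constant 0.5 score; this exists for
null-calibration experiments, where no real signal is present by design
and chance candidates may not populate all four cells.

Models serialize to JSON with full provenance — candidate ids,
orientations, d and p values, training SDs, every coefficient, the
config digest and seed — and refits on identical inputs are
byte-identical. Keeping refits bit-stable required forcing contiguous
array copies before BLAS reductions: the result of a matmul or variance
otherwise depends on the memory layout of the source DataFrame.

## Evaluation

AUC is the Mann–Whitney concordance probability with ties counted ½,
computed from ranks. The ROC uses every distinct score threshold (no
binning), so small-sample operating points are exact vertices. The
Youden point maximizes sensitivity + specificity − 1 with ties broken
toward higher sensitivity; J values are rounded at 1e-9 before
comparison so float noise cannot override the tie-break. Reported
accuracy is computed at the Youden threshold.

Confidence intervals use a stratified percentile bootstrap (cases and
controls resampled separately; 2,000 replicates by default, minimum
200, seeded). Stratification guarantees both classes in every
replicate.

Leave-one-out cross-validation refits the *entire* construction —
candidate extraction, four sub-algorithms, both merges, modality
selection, final blend — without each labelled participant in turn, and
pools the out-of-sample scores into one ROC. The age-blend coefficients
are re-estimated in every fold (nothing is frozen), because any reuse of
full-sample estimates would leak the held-out row into its own score. A
fold whose removal empties a class-band cell is flagged and skipped with
a warning. Alongside the pooled ROC, each fold's 0.5-threshold vote
yields an out-of-sample confusion summary.

External validation applies a fitted model to a disjoint cohort without
any refitting; overlapping participant ids are rejected.

## The synthetic-cohort generator

The generator exists because real recordings of this kind are not
publicly shareable; every pipeline stage is exercised on simulated
cohorts whose ground truth is known.

Gaze per participant and clip is a first-order Markov chain at 50 Hz
over {each AOI of the clip, elsewhere-on-screen, off-screen}. With
probability ρ (default 0.95) the state persists, giving geometric dwell
bouts of mean 1/(1−ρ) = 20 samples ≈ 0.4 s — a realistic fixation
scale for video viewing. Emission is per *run*: each maximal
constant-state segment draws one anchor point uniformly in the state's
region and samples scatter around it with 3 px Gaussian jitter. Run-based
anchoring matters: gaze rests on a point during a fixation, and without
it every unfocused sample lands at an independent screen position, which
deposits incidental single-sample hits on every large AOI and saturates
the binary count scores. The elsewhere state emits over the whole
monitor (unfocused gaze may cross an AOI); off-screen states emit
invalid samples with blank coordinates.

Stationary weights derive from per-label attention budgets (eyes 0.24,
face 0.16, human 0.16, geometric 0.20, object 0.08, other 0.06, split
equally among same-label AOIs in a clip, plus 0.24 for elsewhere),
renormalized per clip. Per-participant weights are Dirichlet draws
around these (concentration 25), producing realistic between-participant
variability in dwell.

Group differences are planted on designated signal AOIs through two
mechanisms, both band-scopable by the participant's age:

1. a log-scale dwell shift: diagnosed participants' weights on a signal
   AOI — and on every AOI geometrically nested inside it — are
   multiplied by `exp(−δ)` (δ < 0 increases dwell, used for geometric
   regions). The default δ = 0.9 yields realized full-window-rate
   effects of |d| ≈ 0.8–1.2 at the default heterogeneity; the δ → d map
   has no closed form (renormalization, overlap, sampling noise), so it
   is measured empirically via `realized_effects`, and all recovery
   tests quote realized, not nominal, effects.
2. categorical avoidance: with probability 0.35 (diagnosed) or 0.05
   (typical) a participant never meaningfully fixates a given
   positive-δ signal AOI (weight × 0.02), drawn once per participant as
   a trait. Dwell distributions on social regions are zero-inflated in
   this way in real cohorts, and this mechanism — not the mean shift —
   is what gives the binary count scores their discriminative signal.

The default signal set places reduced-dwell effects on eye/face regions
of the social clips at all ages and on the human side of preferential
clips in the older band, plus one increased-dwell geometric region —
mirroring the clinical contrasts the stimulus battery was designed
around. All eight default signal AOIs have mean dwell above the 20%
selection floor by construction.

Per-sample invalidity (track loss / off-screen gaze) has a Beta-
distributed per-participant rate with mean 0.08 (concentration 20),
giving cohort mean fixation ≈ 91% with realistic spread — matching the
high retrieval rates typical of this instrument. Degraded participants
(default 2.5% of the diagnosed group, where low fixation is observed in
practice) use a 0.45 off-screen rate, pushing overall fixation below
the 70% reliability floor and exercising the flag path. The second
control group reuses the diagnosed/typical generators with a wider
Dirichlet (concentration 12), standing in for a clinically
heterogeneous validation sample; its default composition is 17 diagnosed
to 7 not.

Everything is driven by one `numpy` Generator seeded from
`SimConfig.seed`; simulate → score → fit → evaluate is byte-stable end
to end.

### What the generator does not emulate

Saccade kinematics, smooth pursuit, pupil size, head pose, calibration
error, stimulus-locked temporal structure within a clip (the chain is
time-homogeneous, so the 1 s/2 s prefix attributes carry no extra
planted signal), attention-grabber dynamics between clips, and
ADHD-specific gaze signatures. Passing tests therefore demonstrate that
the pipeline recovers planted dwell-level group structure and validates
honestly — not that the specific AOI geometry or the fitted coefficients
transfer to any real device's recordings.

## Problem sizes

The test suite and the acceptance script choose cohort sizes that keep
statistical claims meaningful at interactive runtimes: unit cohorts of
16 + 24, recovery checks at 100 per group, null calibration at 50 per
group over 10 seeds, the optimism-gap check and full leave-one-out at
n = 140–141 (the study-scale cohort: 39/102 plus 24 second controls in
the acceptance script), and 300–2,000 bootstrap replicates depending on
context.

## Known limitations

- AOI geometry in the packaged fixture is a plausible stand-in with the
  correct counts and semantics; real device AOIs can be substituted via
  `load_stimulus_config`.
- Raw-sample dwell (no fixation filter) is an interpretation; a device
  applying an internal fixation filter would shift rate scores slightly.
- The Fisher test is conservative at small counts, so count-family
  candidates are under-selected in small bands.
- Training AUCs on strongly-planted synthetic cohorts run higher than
  one should expect from clinical data; the leave-one-out estimate is
  the number to quote.
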