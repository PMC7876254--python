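# gazediag

AOI-based gaze feature extraction and a best-fit sigmoid-ensemble
classifier for autism spectrum disorder (ASD) screening with remote eye
tracking, for researchers building or auditing gaze-based diagnostic
instruments for 5–17-year-olds.

Children and adolescents with ASD allocate gaze atypically: less dwell on
eyes and faces in social scenes, and a relative preference for geometric
over human content in side-by-side ("preferential") displays. `gazediag`
turns 50 Hz gaze recordings over a fixed 12-clip stimulus sequence into a
single diagnostic score, and ships a seeded synthetic-cohort generator so
the entire pipeline is testable and reproducible without access to any
clinical recordings.

## The method

For each of 100 areas of interest (AOIs — circles or rectangles on a
1280 × 1024 monitor) and each participant, four attributes are computed
from raw 50 Hz samples (each valid sample = 20 ms of dwell):

- **rate scores** `r = dwell(AOI, window) / |window|` for three windows —
  the full clip and its first 1 s and 2 s — giving 300 attributes in [0, 1];
- a **count score** `c ∈ {0, 1}`: any fixed gaze on the AOI at all,
  giving 100 more.

Per age band (younger < 10 y ≤ older) and score family, an attribute is a
*candidate* if `p < 0.05` (Welch's t for rates, Fisher's exact for counts)
**or** `|d| ≥ 0.5` (Cohen's d, pooled SD); AOIs watched < 20% of the time
on average are excluded, and only the largest-|d| attribute per AOI
survives. Each of the four (band × family) cells yields a *sub-algorithm*

    score = σ(a·x + b),   x = mean over candidates of oriented,
                          SD-standardized (rate) or 0/1-aligned (count) values

with `a ≥ 0` fitted by cross-entropy. Bands are blended age-continuously,

    s(age) = σ(A·[w(age)·s_young + (1 − w(age))·s_old] + B),
    w(age) = 1 / (1 + e^{k(age − a₀)}),   k ≥ 0, a₀ ≈ 10,

the better family per band is chosen by in-band AUC, and one final blend
produces the best-fit score in (0, 1); a score ≥ 0.5 calls ASD.
Recordings with < 70% overall gaze fixation are scored but flagged
unreliable. Evaluation covers ROC/AUC (Mann–Whitney, ties ½) with
stratified-bootstrap 95% CIs, the Youden operating point, leave-one-out
cross-validation that refits the *entire* construction per fold, and
external-cohort validation without refitting.

## Worked example

```python
import gazediag as gd

stimulus = gd.default_stimulus()          # 12 clips, 100 AOIs
cfg = gd.SimConfig(n_asd=39, n_td=102, n_second_control=24, seed=1)
cohort = gd.simulate_cohort(stimulus, cfg)
matrix = gd.build_attribute_matrix(cohort.recordings, stimulus)

train = [p for p in cohort.participants if p.group != "second_control"]
model = gd.fit_best_fit(train, matrix, gd.FitConfig(seed=1, allow_empty_cells=True))
print("modality per band:", model.modality)

ids = [p.participant_id for p in train]
ages = [p.age_years for p in train]
labels = [bool(p.asd_label) for p in train]
scores = model.score_rows(matrix.values.loc[ids], ages)
report = gd.evaluate_scores(scores, labels, reps=2000, seed=1)
print(f"training AUC {report.auc:.2f} (95% CI {report.auc_ci[0]:.2f}-{report.auc_ci[1]:.2f})")
print(f"Youden point: sensitivity {report.sensitivity:.2f}, "
      f"specificity {report.specificity:.2f}, accuracy {report.accuracy:.2f}")

loo = gd.loo_cross_validate(train, matrix, gd.FitConfig(seed=1, allow_empty_cells=True))
print(f"leave-one-out AUC {loo.report.auc:.2f}")

second = [p for p in cohort.participants if p.group == "second_control"]
ext = gd.evaluate_external(model, second, matrix, reps=2000, seed=1)
print(f"second-control AUC {ext.auc:.2f} (n={ext.n_cases}+{ext.n_controls})")
```

prints

```
modality per band: {'younger': 'rate', 'older': 'rate'}
training AUC 0.99 (95% CI 0.98-1.00)
Youden point: sensitivity 0.90, specificity 1.00, accuracy 0.97
leave-one-out AUC 0.80
second-control AUC 0.76 (n=17+7)
```

The training AUC is optimistic — the candidate attributes were selected
on the same rows — which is exactly why the leave-one-out AUC (which
re-runs selection and every fit without each participant) is lower; the
gap between the two is the overfitting cost of the construction. The
second-control cohort is simulated with extra between-participant
heterogeneity, so performance there drops further. The modality choice
(which score family serves each age band) is data-driven and varies with
the seed.

The same workflow is scriptable: `gazediag simulate / score / select /
fit / predict / evaluate / loo` (see `gazediag --help`).

## Layout

- `gazediag.stimulus_model` — clips, AOIs, attribute-space enumeration
- `gazediag.gaze_io` — gaze/cohort CSV reading, writing, validation
- `gazediag.scoring` — rate/count scores, fixation %, attribute matrix
- `gazediag.attribute_selection` — effect-size candidate extraction
- `gazediag.diagnostic_model` — sub-algorithms, age blends, best-fit model
- `gazediag.evaluation` — ROC/AUC/CI, Youden, LOO, external validation
- `gazediag.synthetic_cohort` — seeded Markov-chain gaze simulator

`docs/methods.md` documents the model, the generator and every numerical
choice in detail.
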