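"""ROC/AUC evaluation, Youden operating point, LOO and external validation.

AUC is the Mann-Whitney concordance probability (ties count one half), the
ROC is built from every distinct score threshold, and 95% confidence
intervals come from a stratified percentile bootstrap.  Leave-one-out
cross-validation repeats the *entire* construction -- candidate selection
included -- without each participant in turn and pools the out-of-sample
scores, which is the honest estimate of how the construction procedure
generalizes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .diagnostic_model import BestFitModel, FitConfig, fit_best_fit, predict_rows
from .errors import FitError, ValidationError
from .gaze_io import Participant
from .scoring import AttributeMatrix

log = logging.getLogger(__name__)


def auc(scores, labels) -> float:
    """Area under the ROC curve = P(score_case > score_control) + P(tie)/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("auc: both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_points(scores, labels) -> list[tuple[float, float, float]]:
    """ROC vertices (fpr, tpr, threshold) at every distinct score cut.

    Starts at (0, 0) and ends at (1, 1); both axes are non-decreasing.
    """
    fpr, tpr, thr = _sk_roc_curve(
        np.asarray(labels).astype(int), np.asarray(scores, float), drop_intermediate=False
    )
    return [(float(f), float(t), float(h)) for f, t, h in zip(fpr, tpr, thr)]


def youden_point(roc: Sequence[tuple[float, float, float]]) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximizing J = sens + spec - 1.

    Ties are broken toward the higher sensitivity.
    """
    best = None
    for fpr, tpr, thr in roc:
        # round J so float noise cannot override the sensitivity tie-break
        key = (round(tpr - fpr, 9), tpr)
        if best is None or key > best[0]:
            best = (key, (float(thr), float(tpr), float(1.0 - fpr)))
    return best[1]


def auc_ci(
    scores,
    labels,
    reps: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Stratified percentile-bootstrap CI for the AUC.

    Resamples cases and controls separately so every replicate keeps both
    classes; requires at least 200 replicates.
    """
    if reps < 200:
        raise ValueError("auc_ci: reps must be >= 200")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    cases = scores[labels]
    controls = scores[~labels]
    if cases.size == 0 or controls.size == 0:
        raise ValidationError("auc_ci: both classes must be present")
    rng = np.random.default_rng(seed)
    boots = np.empty(reps)
    y = np.concatenate([np.ones(cases.size, bool), np.zeros(controls.size, bool)])
    for i in range(reps):
        s = np.concatenate(
            [rng.choice(cases, cases.size, replace=True),
             rng.choice(controls, controls.size, replace=True)]
        )
        boots[i] = auc(s, y)
    lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


@dataclass
class EvaluationReport:
    """ROC summary of one score set: AUC + CI, Youden point, accuracy."""

    auc: float
    auc_ci: tuple[float, float]
    youden_threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_cases: int
    n_controls: int
    roc: list[tuple[float, float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["auc_ci"] = list(self.auc_ci)
        return d


def evaluate_scores(
    scores, labels, reps: int = 2000, seed: int = 0, keep_roc: bool = True
) -> EvaluationReport:
    """Full report for a score/label set; accuracy is taken at the Youden cut."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    roc = roc_points(scores, labels)
    thr, sens, spec = youden_point(roc)
    pred = scores >= thr
    accuracy = float((pred == labels).mean())
    return EvaluationReport(
        auc=auc(scores, labels),
        auc_ci=auc_ci(scores, labels, reps=reps, seed=seed),
        youden_threshold=thr,
        sensitivity=sens,
        specificity=spec,
        accuracy=accuracy,
        n_cases=int(labels.sum()),
        n_controls=int((~labels).sum()),
        roc=roc if keep_roc else [],
    )


# ---------------------------------------------------------------------------
# leave-one-out cross-validation of the whole construction
# ---------------------------------------------------------------------------

@dataclass
class LooFold:
    participant_id: str
    score: float
    label: bool
    predicted: bool  # vote of this fold's model at the 0.5 threshold
    skipped: bool = False


@dataclass
class LooResult:
    folds: list[LooFold]
    report: EvaluationReport

    @property
    def scores(self) -> np.ndarray:
        return np.array([f.score for f in self.folds if not f.skipped])

    @property
    def labels(self) -> np.ndarray:
        return np.array([f.label for f in self.folds if not f.skipped])

    def vote_confusion(self) -> dict[str, float]:
        """Sensitivity/specificity/accuracy of the out-of-sample 0.5 votes."""
        kept = [f for f in self.folds if not f.skipped]
        y = np.array([f.label for f in kept])
        v = np.array([f.predicted for f in kept])
        return {
            "sensitivity": float(v[y].mean()) if y.any() else float("nan"),
            "specificity": float((~v[~y]).mean()) if (~y).any() else float("nan"),
            "accuracy": float((v == y).mean()),
        }


def loo_cross_validate(
    participants: Sequence[Participant],
    matrix: AttributeMatrix,
    config: FitConfig = FitConfig(),
    reps: int = 2000,
) -> LooResult:
    """Leave-one-out validation of the full construction procedure.

    For every labelled participant, the entire chain (candidate extraction,
    the four sub-algorithms, both merges, modality selection, final blend)
    is refitted on the remaining rows and the held-out participant is
    scored out-of-sample.  Folds whose removal empties a class-band cell
    are flagged and skipped.
    """
    labelled = [
        p for p in participants
        if p.asd_label is not None and p.group != "second_control"
        and p.participant_id in set(matrix.participant_ids)
    ]
    if len(labelled) < 10:
        raise ValidationError("loo_cross_validate: needs at least 10 labelled participants")
    folds: list[LooFold] = []
    for held in labelled:
        rest = [p for p in labelled if p.participant_id != held.participant_id]
        try:
            model = fit_best_fit(rest, matrix, config)
        except (FitError, ValidationError) as exc:
            log.warning("LOO fold %s skipped: %s", held.participant_id, exc)
            folds.append(
                LooFold(held.participant_id, float("nan"), bool(held.asd_label), False, True)
            )
            continue
        pred = predict_rows(model, [held], matrix)[0]
        folds.append(
            LooFold(
                participant_id=held.participant_id,
                score=pred.score,
                label=bool(held.asd_label),
                predicted=pred.asd_predicted,
            )
        )
    kept = [f for f in folds if not f.skipped]
    report = evaluate_scores(
        [f.score for f in kept], [f.label for f in kept], reps=reps, seed=config.seed
    )
    return LooResult(folds=folds, report=report)


def evaluate_external(
    model: BestFitModel,
    participants: Sequence[Participant],
    matrix: AttributeMatrix,
    reps: int = 2000,
    seed: int = 0,
) -> EvaluationReport:
    """Apply a fitted model, without refitting, to an independent cohort.

    Participants overlapping the model's training set are rejected.
    """
    overlap = {p.participant_id for p in participants} & set(model.training_ids)
    if overlap:
        raise ValidationError(f"external cohort overlaps training ids: {sorted(overlap)[:5]}")
    labelled = [p for p in participants if p.asd_label is not None]
    preds = predict_rows(model, labelled, matrix)
    return evaluate_scores(
        [p.score for p in preds],
        [bool(p.asd_label) for p in labelled],
        reps=reps,
        seed=seed,
    )


def save_report(report: EvaluationReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def plot_roc(reports: dict[str, EvaluationReport], path) -> None:
    """Optional ROC figure; requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, rep in reports.items():
        if not rep.roc:
            continue
        fpr = [p[0] for p in rep.roc]
        tpr = [p[1] for p in rep.roc]
        ax.plot(fpr, tpr, label=f"{name} (AUC={rep.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
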