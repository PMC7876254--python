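"""The best-fit diagnostic algorithm: sigmoid sub-algorithms merged over age.

Construction follows a fixed hierarchy.  Four *sub-algorithms* are fitted
-- one per (age band, score family) cell: the cell's candidate attributes
are oriented (so "more ASD-like" is always positive), rate attributes are
standardized by their training SD, count attributes are aligned 0/1, and
the per-participant mean is passed through a fitted logistic sigmoid
sigma(a*x + b) with a >= 0.  The younger and older sub-algorithms of each
family are then blended into an age-continuous *merged algorithm*

    s(age) = sigma(A * [w(age) * s_young + (1 - w(age)) * s_old] + B),
    w(age) = 1 / (1 + exp(k * (age - a0))),

with (A, B, k, a0) fitted by binary cross-entropy, k >= 0 and a0
initialized at the 10-year band split.  Per band, the better-fitting
family is chosen by in-band AUC, and the two chosen modality scores are
blended once more with the same age-weight form into the final best-fit
score.  A score of 0.5 or higher calls ASD.  Participants whose overall
gaze-fixation percentage falls below 70% are still scored but flagged as
unreliable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .attribute_selection import (
    BANDS,
    FAMILIES,
    CandidateSet,
    SelectedCandidate,
    SelectionConfig,
    band_training_split,
    select_candidates,
)
from .errors import FitError, ValidationError
from .gaze_io import GazeRecordingSet, Participant
from .scoring import AttributeMatrix, score_participant
from .stimulus_model import StimulusSet

log = logging.getLogger(__name__)

#: final decision threshold on the best-fit score
DECISION_THRESHOLD = 0.5
#: data-quality floor: predictions below this fixation % are flagged
DEFAULT_FIXATION_FLOOR_PCT = 70.0

_EPS = 1e-12


def _sigmoid(z: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass(frozen=True)
class FitConfig:
    """Every knob of the construction chain, for reproducible refits."""

    selection: SelectionConfig = SelectionConfig()
    n_restarts: int = 5
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-8
    fixation_floor_pct: float = DEFAULT_FIXATION_FLOOR_PCT
    age_center_init: float = 10.0
    #: an empty candidate cell normally aborts the fit; with this flag the
    #: cell instead contributes a constant, non-informative 0.5 score
    #: (useful for null-calibration experiments where no real signal exists)
    allow_empty_cells: bool = False

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# attribute aggregation
# ---------------------------------------------------------------------------

def aggregate_attributes(
    candidates: Sequence[SelectedCandidate],
    row: pd.Series | dict,
    sds: dict[str, float],
) -> float:
    """Oriented, normalized mean of the candidate attributes for one row.

    Rate attributes contribute orientation * value / training-SD; count
    attributes contribute the orientation-aligned 0/1 value.  A rate
    attribute whose training SD is zero contributes 0 (flagged upstream).
    Higher aggregate = more ASD-like gaze.
    """
    if not candidates:
        raise ValidationError("aggregate_attributes: empty candidate set")
    total = 0.0
    for c in candidates:
        v = float(row[c.attribute_id])
        if c.kind == "count":
            total += v if c.orientation > 0 else 1.0 - v
        else:
            sd = sds.get(c.attribute_id, 0.0)
            total += 0.0 if sd <= 0 else c.orientation * v / sd
    return total / len(candidates)


def _aggregate_many(
    candidates: Sequence[SelectedCandidate],
    values: pd.DataFrame,
    sds: dict[str, float],
) -> np.ndarray:
    """Vectorized :func:`aggregate_attributes` over the rows of *values*."""
    if not candidates:
        return np.zeros(len(values))
    cols = [c.attribute_id for c in candidates]
    # contiguous copy: the matmul result must not depend on the memory layout
    # of the source frame (keeps refits bit-identical)
    X = np.ascontiguousarray(values[cols].to_numpy(dtype=float))
    w = np.zeros(len(candidates))
    offset = 0.0
    for j, c in enumerate(candidates):
        if c.kind == "count":
            w[j] = 1.0 if c.orientation > 0 else -1.0
            offset += 0.0 if c.orientation > 0 else 1.0
        else:
            sd = sds.get(c.attribute_id, 0.0)
            w[j] = 0.0 if sd <= 0 else c.orientation / sd
    return (X @ w + offset) / len(candidates)


# ---------------------------------------------------------------------------
# sigmoid fitting
# ---------------------------------------------------------------------------

def fit_sigmoid(
    aggregates: Sequence[float],
    labels: Sequence[int],
    max_iter: int = 500,
    tol: float = 1e-8,
) -> tuple[float, float]:
    """Fit sigma(a*x + b) to binary labels by mean cross-entropy, a >= 0.

    The single-feature logistic objective is convex, so a bounded
    quasi-Newton solve from a deterministic start suffices.
    """
    x = np.asarray(aggregates, dtype=float)
    y = np.asarray(labels, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise FitError("fit_sigmoid: both classes must be present")

    def loss(theta):
        a, b = theta
        p = np.clip(_sigmoid(a * x + b), _EPS, 1.0 - _EPS)
        g = p - y
        return (
            _bce(p, y),
            np.array([np.mean(g * x), np.mean(g)]),
        )

    scale = x.std() or 1.0
    starts = [(1.0 / scale, -x.mean() / scale), (0.0, 0.0), (4.0 / scale, -4.0 * x.mean() / scale)]
    best = None
    for x0 in starts:
        res = minimize(
            loss,
            x0=np.asarray(x0),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None), (None, None)],
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(best.x[1])


@dataclass
class SubAlgorithm:
    """One (band, family) cell: candidates + normalizers + fitted sigmoid."""

    band: str
    family: str
    candidates: CandidateSet
    sds: dict[str, float]
    a: float = 0.0
    b: float = 0.0

    def aggregate(self, values: pd.DataFrame) -> np.ndarray:
        return _aggregate_many(self.candidates.candidates, values, self.sds)

    def score(self, values: pd.DataFrame) -> np.ndarray:
        """Sub-algorithm score in (0, 1) for each row of *values*."""
        return _sigmoid(self.a * self.aggregate(values) + self.b)


def fit_sub_algorithm(
    matrix: AttributeMatrix,
    participants: Sequence[Participant],
    band: str,
    family: str,
    config: FitConfig = FitConfig(),
) -> SubAlgorithm:
    """Select candidates and fit the sigmoid for one (band, family) cell."""
    cands = select_candidates(matrix, participants, band, family, config.selection)
    if len(cands) == 0:
        if not config.allow_empty_cells:
            raise FitError(f"no candidate attributes for cell band={band!r} family={family!r}")
        # constant sub-algorithm: sigma(0) = 0.5 for every participant
        return SubAlgorithm(band=band, family=family, candidates=cands, sds={})
    asd_ids, td_ids = band_training_split(matrix, participants, band)
    train_ids = asd_ids + td_ids
    sds: dict[str, float] = {}
    for c in cands.candidates:
        if c.kind != "count":
            sd = float(matrix.values.loc[train_ids, c.attribute_id].std(ddof=1))
            if sd <= 0:
                log.warning("zero training SD for %s; attribute contributes 0", c.attribute_id)
            sds[c.attribute_id] = sd
    sub = SubAlgorithm(band=band, family=family, candidates=cands, sds=sds)
    agg = sub.aggregate(matrix.values.loc[train_ids])
    y = np.array([1.0] * len(asd_ids) + [0.0] * len(td_ids))
    sub.a, sub.b = fit_sigmoid(agg, y, max_iter=config.max_iter, tol=config.tol)
    return sub


# ---------------------------------------------------------------------------
# age blending
# ---------------------------------------------------------------------------

def _age_weight(ages: np.ndarray, k: float, a0: float) -> np.ndarray:
    """Weight of the *younger* component: 1 at low ages, 0 at high ages."""
    return _sigmoid(-k * (ages - a0))


def _fit_blend(
    s_young: np.ndarray,
    s_old: np.ndarray,
    ages: np.ndarray,
    y: np.ndarray,
    config: FitConfig,
    rng: np.random.Generator,
) -> tuple[float, float, float, float]:
    """Fit (A, B, k, a0) of the outer sigmoid blend by cross-entropy.

    A >= 0 keeps the blend ASD-oriented; k >= 0 makes the younger weight
    monotonically decreasing in age; a0 starts at the 10-year band split.
    Deterministic multi-start (plus seeded random restarts) guards against
    the mild non-convexity of the joint (k, a0) surface.
    """

    def loss(theta):
        A, B, k, a0 = theta
        w = _age_weight(ages, k, a0)
        p = _sigmoid(A * (w * s_young + (1.0 - w) * s_old) + B)
        return _bce(p, y)

    a0_init = config.age_center_init
    starts = [
        np.array([4.0, -2.0, 1.0, a0_init]),
        np.array([8.0, -4.0, 4.0, a0_init]),
        np.array([2.0, -1.0, 0.25, a0_init]),
    ]
    for _ in range(config.n_restarts):
        starts.append(
            np.array(
                [
                    rng.uniform(0.5, 12.0),
                    rng.uniform(-6.0, 1.0),
                    rng.uniform(0.0, 6.0),
                    rng.uniform(7.0, 13.0),
                ]
            )
        )
    bounds = [(0.0, None), (None, None), (0.0, None), (2.0, 25.0)]
    best = None
    for x0 in starts:
        res = minimize(
            loss,
            x0=x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.max_iter, "ftol": config.tol},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("age-blend fit failed to produce a finite loss")
    A, B, k, a0 = (float(v) for v in best.x)
    return A, B, k, a0


@dataclass
class MergedAlgorithm:
    """Age-continuous blend of the younger and older sub-algorithms."""

    family: str
    young: SubAlgorithm
    old: SubAlgorithm
    A: float = 1.0
    B: float = 0.0
    k: float = 1.0
    a0: float = 10.0

    def score(self, values: pd.DataFrame, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        w = _age_weight(ages, self.k, self.a0)
        inner = w * self.young.score(values) + (1.0 - w) * self.old.score(values)
        return _sigmoid(self.A * inner + self.B)


def merge_bands(
    young: SubAlgorithm,
    old: SubAlgorithm,
    participants: Sequence[Participant],
    matrix: AttributeMatrix,
    config: FitConfig = FitConfig(),
    rng: Optional[np.random.Generator] = None,
) -> MergedAlgorithm:
    """Blend two same-family sub-algorithms into one age-continuous score."""
    if young.family != old.family:
        raise ValidationError("merge_bands: families differ")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ids, ages, y = _training_rows(matrix, participants)
    values = matrix.values.loc[ids]
    merged = MergedAlgorithm(family=young.family, young=young, old=old)
    merged.A, merged.B, merged.k, merged.a0 = _fit_blend(
        young.score(values), old.score(values), ages, y, config, rng
    )
    return merged


def _training_rows(
    matrix: AttributeMatrix, participants: Sequence[Participant]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """All labelled ASD/TD rows present in the matrix, with ages and labels."""
    ids, ages, y = [], [], []
    present = set(matrix.participant_ids)
    for p in participants:
        if p.participant_id in present and p.asd_label is not None and p.group != "second_control":
            ids.append(p.participant_id)
            ages.append(p.age_years)
            y.append(float(p.asd_label))
    return ids, np.asarray(ages), np.asarray(y)


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    # local import to avoid a cycle with evaluation
    from .evaluation import auc

    return auc(scores, labels)


def select_modality(
    rate_final: MergedAlgorithm,
    count_final: MergedAlgorithm,
    participants: Sequence[Participant],
    matrix: AttributeMatrix,
) -> dict[str, str]:
    """Per band, pick the family whose merged score has the higher in-band AUC.

    Ties go to the rate family.
    """
    ids, ages, y = _training_rows(matrix, participants)
    by_id = {p.participant_id: p for p in participants}
    values = matrix.values.loc[ids]
    s_rate = rate_final.score(values, ages)
    s_count = count_final.score(values, ages)
    choice: dict[str, str] = {}
    for band in BANDS:
        mask = np.array([by_id[i].band == band for i in ids])
        auc_rate = _auc(s_rate[mask], y[mask])
        auc_count = _auc(s_count[mask], y[mask])
        choice[band] = "count" if auc_count > auc_rate else "rate"
    return choice


# ---------------------------------------------------------------------------
# the best-fit model
# ---------------------------------------------------------------------------

@dataclass
class BestFitModel:
    """The fully fitted hierarchy: 4 sub-algorithms -> 2 merges -> 1 blend."""

    rate_final: MergedAlgorithm
    count_final: MergedAlgorithm
    modality: dict[str, str]  # band -> chosen family
    A: float
    B: float
    k: float
    a0: float
    config: FitConfig
    training_ids: list[str] = field(default_factory=list)
    threshold: float = DECISION_THRESHOLD

    def _modality_scores(
        self, values: pd.DataFrame, ages: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        by_family = {
            "rate": self.rate_final.score(values, ages),
            "count": self.count_final.score(values, ages),
        }
        return by_family[self.modality["younger"]], by_family[self.modality["older"]]

    def score_rows(self, values: pd.DataFrame, ages) -> np.ndarray:
        """Best-fit score in (0, 1) per row; continuous in age."""
        ages = np.asarray(ages, dtype=float)
        s_y, s_o = self._modality_scores(values, ages)
        w = _age_weight(ages, self.k, self.a0)
        return _sigmoid(self.A * (w * s_y + (1.0 - w) * s_o) + self.B)

    def labels(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores) >= self.threshold


def fit_best_fit(
    participants: Sequence[Participant],
    matrix: AttributeMatrix,
    config: FitConfig = FitConfig(),
) -> BestFitModel:
    """Run the full construction chain on the given training rows.

    Candidate selection uses band-specific rows only; every blend fit then
    uses all labelled rows.  Deterministic given config and data.
    """
    ids, ages, y = _training_rows(matrix, participants)
    by_id = {p.participant_id: p for p in participants}
    for band in BANDS:
        for lab in (True, False):
            n = sum(1 for i in ids if by_id[i].band == band and by_id[i].asd_label is lab)
            if n < 2:
                raise ValidationError(
                    f"band {band!r}: needs >= 2 participants with asd_label={lab}"
                )
    rng = np.random.default_rng(config.seed)
    subs = {
        (band, family): fit_sub_algorithm(matrix, participants, band, family, config)
        for family in FAMILIES
        for band in BANDS
    }
    rate_final = merge_bands(
        subs[("younger", "rate")], subs[("older", "rate")], participants, matrix, config, rng
    )
    count_final = merge_bands(
        subs[("younger", "count")], subs[("older", "count")], participants, matrix, config, rng
    )
    modality = select_modality(rate_final, count_final, participants, matrix)

    values = matrix.values.loc[ids]
    by_family = {
        "rate": rate_final.score(values, ages),
        "count": count_final.score(values, ages),
    }
    s_y = by_family[modality["younger"]]
    s_o = by_family[modality["older"]]
    A, B, k, a0 = _fit_blend(s_y, s_o, ages, y, config, rng)
    return BestFitModel(
        rate_final=rate_final,
        count_final=count_final,
        modality=modality,
        A=A, B=B, k=k, a0=a0,
        config=config,
        training_ids=list(ids),
    )


@dataclass(frozen=True)
class Prediction:
    participant_id: str
    score: float
    asd_predicted: bool
    fixation_pct: float
    low_fixation: bool  # True: below the reliability floor; score kept but flagged


def predict(
    model: BestFitModel,
    participant: Participant,
    recording: GazeRecordingSet,
    stimulus: StimulusSet,
) -> Prediction:
    """Score one new participant from raw gaze; flags low-fixation records.

    A recording whose overall fixation percentage is below the configured
    floor (default 70%) is still scored, but marked unreliable.
    """
    from .stimulus_model import enumerate_attribute_space

    row, fixation = score_participant(recording, stimulus)
    cols = [s.attribute_id for s in enumerate_attribute_space(stimulus)]
    values = pd.DataFrame([row], columns=cols, index=[participant.participant_id])
    score = float(model.score_rows(values, [participant.age_years])[0])
    return Prediction(
        participant_id=participant.participant_id,
        score=score,
        asd_predicted=score >= model.threshold,
        fixation_pct=fixation,
        low_fixation=fixation < model.config.fixation_floor_pct,
    )


# ---------------------------------------------------------------------------
# serialization: JSON with full provenance (attributes, orientations, SDs,
# all coefficients, config digest, seed) -- byte-stable for a fixed fit
# ---------------------------------------------------------------------------

def _sub_to_dict(sub: SubAlgorithm) -> dict:
    return {
        "band": sub.band,
        "family": sub.family,
        "a": sub.a,
        "b": sub.b,
        "sds": {k: sub.sds[k] for k in sorted(sub.sds)},
        "candidates": [asdict(c) for c in sub.candidates.candidates],
    }


def _sub_from_dict(d: dict) -> SubAlgorithm:
    cands = CandidateSet(
        band=d["band"],
        family=d["family"],
        candidates=[SelectedCandidate(**c) for c in d["candidates"]],
    )
    return SubAlgorithm(
        band=d["band"], family=d["family"], candidates=cands,
        sds=dict(d["sds"]), a=d["a"], b=d["b"],
    )


def _merged_to_dict(m: MergedAlgorithm) -> dict:
    return {
        "family": m.family,
        "A": m.A, "B": m.B, "k": m.k, "a0": m.a0,
        "young": _sub_to_dict(m.young),
        "old": _sub_to_dict(m.old),
    }


def _merged_from_dict(d: dict) -> MergedAlgorithm:
    return MergedAlgorithm(
        family=d["family"],
        young=_sub_from_dict(d["young"]),
        old=_sub_from_dict(d["old"]),
        A=d["A"], B=d["B"], k=d["k"], a0=d["a0"],
    )


def model_to_dict(model: BestFitModel) -> dict:
    return {
        "format": "gazediag-best-fit-model/1",
        "rate_final": _merged_to_dict(model.rate_final),
        "count_final": _merged_to_dict(model.count_final),
        "modality": dict(model.modality),
        "blend": {"A": model.A, "B": model.B, "k": model.k, "a0": model.a0},
        "threshold": model.threshold,
        "config": asdict(model.config),
        "config_digest": model.config.digest(),
        "training_ids": list(model.training_ids),
    }


def model_from_dict(d: dict) -> BestFitModel:
    cfg = d["config"]
    config = FitConfig(
        selection=SelectionConfig(**cfg["selection"]),
        **{k: v for k, v in cfg.items() if k != "selection"},
    )
    return BestFitModel(
        rate_final=_merged_from_dict(d["rate_final"]),
        count_final=_merged_from_dict(d["count_final"]),
        modality=dict(d["modality"]),
        A=d["blend"]["A"], B=d["blend"]["B"], k=d["blend"]["k"], a0=d["blend"]["a0"],
        config=config,
        training_ids=list(d["training_ids"]),
        threshold=d["threshold"],
    )


def save_model(model: BestFitModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path) -> BestFitModel:
    with open(path, "r", encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))


def predict_rows(
    model: BestFitModel,
    participants: Sequence[Participant],
    matrix: AttributeMatrix,
) -> list[Prediction]:
    """Batch scoring from a precomputed attribute matrix."""
    ids = [p.participant_id for p in participants]
    ages = [p.age_years for p in participants]
    scores = model.score_rows(matrix.values.loc[ids], ages)
    return [
        Prediction(
            participant_id=pid,
            score=float(s),
            asd_predicted=bool(s >= model.threshold),
            fixation_pct=float(matrix.fixation_pct.loc[pid]),
            low_fixation=bool(matrix.fixation_pct.loc[pid] < model.config.fixation_floor_pct),
        )
        for pid, s in zip(ids, scores)
    ]
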