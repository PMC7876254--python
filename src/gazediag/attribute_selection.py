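"""Candidate-attribute extraction by group comparison per age band.

For each age band (younger < 10 y, older >= 10 y) and score family (rate,
count), every attribute is compared between diagnosed (ASD) and typical
(TD) training participants.  An attribute becomes a *candidate* when it is
nominally significant (p < 0.05) OR carries at least a medium effect size
(|Cohen's d| >= 0.5).  Candidates from AOIs whose group-mean gaze-fixation
percentage is below 20% are dropped (guards against chance findings on
rarely-watched regions), and within each AOI only the single attribute
with the largest |d| survives -- this also collapses the three rate
windows sharing an AOI.  No multiple-testing correction is applied: the
stage is deliberately permissive, and overfitting is controlled later by
cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .gaze_io import Participant
from .scoring import AttributeMatrix
from .stimulus_model import RATE_KINDS, AttributeSpec

log = logging.getLogger(__name__)

BANDS = ("younger", "older")
FAMILIES = ("rate", "count")

#: tie-break preference among kinds when |d| is equal within one AOI
_KIND_PREFERENCE = {"rate_full": 0, "rate_1s": 1, "rate_2s": 2, "count": 3}


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds and test choices for candidate extraction."""

    p_threshold: float = 0.05
    d_threshold: float = 0.5
    fixation_floor_pct: float = 20.0
    rate_test: str = "welch"  # or "mannwhitney"


@dataclass(frozen=True)
class ComparisonResult:
    """ASD-vs-TD comparison of one attribute within one age band."""

    attribute_id: str
    aoi_id: str
    kind: str
    d: float  # Cohen's d, ASD minus TD, pooled SD; NaN when degenerate
    p: float
    mean_asd: float
    mean_td: float
    group_mean_fixation_pct: float

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.d)


@dataclass(frozen=True)
class SelectedCandidate:
    attribute_id: str
    aoi_id: str
    kind: str
    orientation: int  # +1: ASD scores higher; -1: ASD scores lower
    d: float
    p: float


@dataclass
class CandidateSet:
    """Candidates for one (age band, score family) cell."""

    band: str
    family: str
    candidates: list[SelectedCandidate] = field(default_factory=list)
    provenance: list[ComparisonResult] = field(default_factory=list)

    @property
    def attribute_ids(self) -> list[str]:
        return [c.attribute_id for c in self.candidates]

    @property
    def aoi_ids(self) -> set[str]:
        return {c.aoi_id for c in self.candidates}

    def __len__(self) -> int:
        return len(self.candidates)


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d with pooled SD: (mean(a) - mean(b)) / s_pooled.

    Returns NaN when the pooled SD is zero (degenerate comparison).
    Requires at least two observations per group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("cohens_d requires >= 2 observations per group")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def _cohens_d_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Cohen's d for matrices with rows = observations."""
    na, nb = A.shape[0], B.shape[0]
    pooled = ((na - 1) * A.var(axis=0, ddof=1) + (nb - 1) * B.var(axis=0, ddof=1)) / (
        na + nb - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (A.mean(axis=0) - B.mean(axis=0)) / np.sqrt(pooled)
    d[pooled <= 0] = np.nan
    return d


def _rate_pvalues(A: np.ndarray, B: np.ndarray, method: str) -> np.ndarray:
    if method == "welch":
        # near-constant columns (e.g. rarely-watched AOIs) trigger scipy's
        # catastrophic-cancellation warning; they come out as p = nan and
        # are handled by the selection mask downstream
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(A, B, axis=0, equal_var=False)
        return np.asarray(res.pvalue)
    if method == "mannwhitney":
        res = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided")
        return np.asarray(res.pvalue)
    raise ValueError(f"unknown rate test {method!r}")


def _fisher_pvalues(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Two-sided Fisher exact p per binary column."""
    na, nb = A.shape[0], B.shape[0]
    ka = A.sum(axis=0).astype(int)
    kb = B.sum(axis=0).astype(int)
    out = np.empty(A.shape[1])
    cache: dict[tuple[int, int], float] = {}
    for j, (x, y) in enumerate(zip(ka, kb)):
        key = (int(x), int(y))
        if key not in cache:
            table = [[x, na - x], [y, nb - y]]
            cache[key] = float(stats.fisher_exact(table, alternative="two-sided")[1])
        out[j] = cache[key]
    return out


def band_training_split(
    matrix: AttributeMatrix, participants: Sequence[Participant], band: str
) -> tuple[list[str], list[str]]:
    """(ASD ids, TD ids) of labelled training participants in *band*."""
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}")
    asd, td = [], []
    present = set(matrix.participant_ids)
    for p in participants:
        if p.participant_id not in present or p.asd_label is None or p.band != band:
            continue
        if p.group == "second_control":
            continue
        (asd if p.asd_label else td).append(p.participant_id)
    return asd, td


def group_compare(
    matrix: AttributeMatrix,
    participants: Sequence[Participant],
    attribute: AttributeSpec | str,
    band: str,
    config: SelectionConfig = SelectionConfig(),
) -> ComparisonResult:
    """Compare one attribute between ASD and TD rows of one age band.

    Rate attributes use Welch's t-test (or Mann-Whitney, per config);
    binary count attributes use Fisher's exact test.
    """
    attr_id = attribute if isinstance(attribute, str) else attribute.attribute_id
    spec = matrix.spec_by_id()[attr_id]
    asd_ids, td_ids = band_training_split(matrix, participants, band)
    if len(asd_ids) < 2 or len(td_ids) < 2:
        raise ValidationError(
            f"band {band!r}: needs >= 2 participants per group "
            f"(got {len(asd_ids)} ASD, {len(td_ids)} TD)"
        )
    a = np.ascontiguousarray(matrix.values.loc[asd_ids, attr_id].to_numpy())[:, None]
    b = np.ascontiguousarray(matrix.values.loc[td_ids, attr_id].to_numpy())[:, None]
    if spec.is_rate:
        p = _rate_pvalues(a, b, config.rate_test)[0]
    else:
        p = _fisher_pvalues(a, b)[0]
    d = _cohens_d_columns(a, b)[0]
    rate_full_col = f"{spec.aoi_id}:rate_full"
    fix = 100.0 * matrix.values.loc[asd_ids + td_ids, rate_full_col].mean()
    return ComparisonResult(
        attribute_id=attr_id,
        aoi_id=spec.aoi_id,
        kind=spec.kind,
        d=float(d),
        p=float(p),
        mean_asd=float(a.mean()),
        mean_td=float(b.mean()),
        group_mean_fixation_pct=float(fix),
    )


def select_candidates(
    matrix: AttributeMatrix,
    participants: Sequence[Participant],
    band: str,
    family: str,
    config: SelectionConfig = SelectionConfig(),
) -> CandidateSet:
    """Extract the candidate attributes of one (band, family) cell.

    Selection uses only the training rows present in *matrix* whose band
    matches; adding unrelated rows never changes the result (required for
    honest leave-one-out evaluation).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    asd_ids, td_ids = band_training_split(matrix, participants, band)
    if len(asd_ids) < 2 or len(td_ids) < 2:
        raise ValidationError(
            f"band {band!r}: needs >= 2 participants per group "
            f"(got {len(asd_ids)} ASD, {len(td_ids)} TD)"
        )
    kinds = RATE_KINDS if family == "rate" else ("count",)
    specs = [s for s in matrix.specs if s.kind in kinds]
    cols = [s.attribute_id for s in specs]
    # contiguous copies: reduction results must not depend on the memory
    # layout of the source frame (keeps leave-one-out refits bit-identical)
    A = np.ascontiguousarray(matrix.values.loc[asd_ids, cols].to_numpy())
    B = np.ascontiguousarray(matrix.values.loc[td_ids, cols].to_numpy())

    d = _cohens_d_columns(A, B)
    if family == "rate":
        p = _rate_pvalues(A, B, config.rate_test)
    else:
        p = _fisher_pvalues(A, B)

    # per-AOI group-mean fixation percentage over the pooled training rows
    aoi_ids = sorted({s.aoi_id for s in specs})
    rate_full_cols = [f"{a}:rate_full" for a in aoi_ids]
    fix_pct = 100.0 * np.ascontiguousarray(
        matrix.values.loc[asd_ids + td_ids, rate_full_cols].to_numpy()
    ).mean(axis=0)
    fix_by_aoi = dict(zip(aoi_ids, fix_pct))

    provenance = [
        ComparisonResult(
            attribute_id=s.attribute_id,
            aoi_id=s.aoi_id,
            kind=s.kind,
            d=float(d[j]),
            p=float(p[j]),
            mean_asd=float(A[:, j].mean()),
            mean_td=float(B[:, j].mean()),
            group_mean_fixation_pct=float(fix_by_aoi[s.aoi_id]),
        )
        for j, s in enumerate(specs)
    ]

    with np.errstate(invalid="ignore"):
        passes = (np.nan_to_num(p, nan=1.0) < config.p_threshold) | (
            np.abs(np.nan_to_num(d, nan=0.0)) >= config.d_threshold
        )
    passing = [r for j, r in enumerate(provenance) if passes[j]]
    # fixation-percentage exclusion
    passing = [r for r in passing if r.group_mean_fixation_pct >= config.fixation_floor_pct]

    # per-AOI deduplication: keep the largest |d|; ties prefer rate_full >
    # rate_1s > rate_2s > count, then lexical attribute id
    best: dict[str, ComparisonResult] = {}
    for r in passing:
        cur = best.get(r.aoi_id)
        if cur is None:
            best[r.aoi_id] = r
            continue
        key_new = (-abs(r.d) if np.isfinite(r.d) else 0.0, _KIND_PREFERENCE[r.kind], r.attribute_id)
        key_cur = (
            -abs(cur.d) if np.isfinite(cur.d) else 0.0,
            _KIND_PREFERENCE[cur.kind],
            cur.attribute_id,
        )
        if key_new < key_cur:
            best[r.aoi_id] = r

    candidates = [
        SelectedCandidate(
            attribute_id=r.attribute_id,
            aoi_id=r.aoi_id,
            kind=r.kind,
            orientation=1 if (not np.isfinite(r.d)) or r.d >= 0 else -1,
            d=r.d,
            p=r.p,
        )
        for r in sorted(best.values(), key=lambda r: r.attribute_id)
    ]
    if not candidates:
        log.warning("no candidate attributes for band=%s family=%s", band, family)
    return CandidateSet(band=band, family=family, candidates=candidates, provenance=provenance)
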