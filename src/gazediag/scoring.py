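"""Gaze scores: AOI rate scores, AOI count scores, fixation percentage.

Scores are computed directly on the raw 50 Hz samples: each valid sample
contributes exactly 20 ms of dwell to every AOI containing it, with no
event detection or interpolation.  Rate scores divide dwell time inside an
AOI by the analysis-window duration (full clip, first 1 s or first 2 s),
so all rate scores live on a common [0, 1] scale; the count score is a
binary "ever fixed gaze on this AOI" indicator.  The attribute matrix
stacks all 4 x n_AOI scores per participant in the canonical attribute
order, plus the overall gaze-fixation percentage (the share of the whole
stimulus period with valid on-screen gaze -- a data-quality metric).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .errors import ValidationError
from .gaze_io import GazeRecordingSet
from .stimulus_model import (
    Aoi,
    AttributeSpec,
    MovieClip,
    StimulusSet,
    enumerate_attribute_space,
)

#: dwell contributed by one 50 Hz sample, in milliseconds
SAMPLE_MS = 20.0

WINDOWS = ("full", "first_1s", "first_2s")
_KIND_TO_WINDOW = {"rate_full": "full", "rate_1s": "first_1s", "rate_2s": "first_2s"}


def aoi_mask(aoi: Aoi, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized inclusive point-in-AOI test; NaN coordinates are outside."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    with np.errstate(invalid="ignore"):
        if aoi.shape == "circle":
            inside = (x - aoi.cx) ** 2 + (y - aoi.cy) ** 2 <= aoi.r**2
        else:
            inside = (x >= aoi.x) & (x <= aoi.x + aoi.w) & (y >= aoi.y) & (y <= aoi.y + aoi.h)
    return inside & np.isfinite(x) & np.isfinite(y)


def _window_ms(clip: MovieClip, window: str) -> float:
    if window == "full":
        return clip.duration_s * 1000.0
    if window == "first_1s":
        w = 1000.0
    elif window == "first_2s":
        w = 2000.0
    else:
        raise ValueError(f"unknown window {window!r}")
    if w > clip.duration_s * 1000.0:
        raise ValidationError(
            f"window {window!r} exceeds clip {clip.clip_id!r} duration {clip.duration_s:g} s"
        )
    return w


def aoi_rate_score(rec: GazeRecordingSet, clip: MovieClip, aoi: Aoi, window: str = "full") -> float:
    """Fraction of *window* spent inside *aoi* (dwell time / window length).

    The window is half-open ``[0, w)`` in clip time; invalid samples count
    toward the denominator (time-based) but never the numerator.
    """
    df = rec.samples(clip.clip_id)
    w_ms = _window_ms(clip, window)
    t = df["t_ms"].to_numpy()
    in_window = t < w_ms
    valid = df["valid"].to_numpy() & in_window
    inside = aoi_mask(aoi, df["x_px"].to_numpy(), df["y_px"].to_numpy()) & valid
    return float(inside.sum() * SAMPLE_MS / w_ms)


def _has_run(mask: np.ndarray, min_run: int) -> bool:
    """True iff *mask* contains a run of >= min_run consecutive True values."""
    if min_run <= 1:
        return bool(mask.any())
    if mask.size < min_run:
        return False
    c = np.convolve(mask.astype(np.int32), np.ones(min_run, dtype=np.int32), mode="valid")
    return bool((c == min_run).any())


def aoi_count_score(rec: GazeRecordingSet, clip: MovieClip, aoi: Aoi, min_run: int = 1) -> int:
    """1 iff the clip contains >= *min_run* consecutive valid samples inside *aoi*."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    df = rec.samples(clip.clip_id)
    inside = aoi_mask(aoi, df["x_px"].to_numpy(), df["y_px"].to_numpy())
    inside &= df["valid"].to_numpy()
    return int(_has_run(inside, min_run))


def overall_fixation_percentage(rec: GazeRecordingSet, stimulus: StimulusSet) -> float:
    """Percent of the stimulus period with valid on-screen gaze, in [0, 100].

    The denominator is the full expected 50 Hz grid over all clips, so
    missing samples count as non-fixation.  All clips must be present.
    """
    missing = [c.clip_id for c in stimulus.clips if c.clip_id not in rec.clips]
    if missing:
        raise ValidationError(
            f"participant {rec.participant_id!r}: missing clip(s) {missing}"
        )
    valid = sum(int(rec.samples(c.clip_id)["valid"].sum()) for c in stimulus.clips)
    expected = stimulus.expected_samples()
    return 100.0 * valid / expected


@dataclass
class AttributeMatrix:
    """Participants x attributes score matrix plus per-participant fixation %.

    ``values`` is indexed by participant id with one column per attribute id
    in canonical enumeration order; ``fixation_pct`` is aligned on the same
    index.
    """

    values: pd.DataFrame
    fixation_pct: pd.Series
    specs: list[AttributeSpec] = field(default_factory=list)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.values.index)

    def spec_by_id(self) -> dict[str, AttributeSpec]:
        return {s.attribute_id: s for s in self.specs}

    def row(self, participant_id: str) -> pd.Series:
        return self.values.loc[participant_id]

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out["overall_fixation_pct"] = self.fixation_pct
        out.to_csv(path, index_label="participant_id")

    @classmethod
    def from_csv(cls, path, stimulus: StimulusSet) -> "AttributeMatrix":
        df = pd.read_csv(path, index_col="participant_id")
        df.index = df.index.astype(str)
        specs = enumerate_attribute_space(stimulus)
        expected = [s.attribute_id for s in specs]
        missing = [c for c in expected if c not in df.columns]
        if missing or "overall_fixation_pct" not in df.columns:
            raise ValidationError(f"attribute matrix: missing column(s) {missing[:3]}...")
        return cls(
            values=df[expected].astype(float),
            fixation_pct=df["overall_fixation_pct"].astype(float),
            specs=specs,
        )


def score_participant(
    rec: GazeRecordingSet, stimulus: StimulusSet, min_run: int = 1
) -> tuple[np.ndarray, float]:
    """All attribute scores of one participant, in canonical order.

    Vectorized over AOIs within each clip; equivalent to calling
    :func:`aoi_rate_score` / :func:`aoi_count_score` attribute by attribute.
    """
    out: list[float] = []
    for clip in stimulus.clips:
        df = rec.samples(clip.clip_id)
        t = df["t_ms"].to_numpy()
        x = df["x_px"].to_numpy()
        y = df["y_px"].to_numpy()
        valid = df["valid"].to_numpy().astype(bool)
        full_ms = clip.duration_s * 1000.0
        w1 = t < 1000.0
        w2 = t < 2000.0
        for aoi in sorted(clip.aois, key=lambda a: a.aoi_id):
            inside = aoi_mask(aoi, x, y) & valid
            out.append(inside.sum() * SAMPLE_MS / full_ms)
            out.append(inside[w1].sum() * SAMPLE_MS / 1000.0)
            out.append(inside[w2].sum() * SAMPLE_MS / 2000.0)
            out.append(float(_has_run(inside, min_run)))
    return np.asarray(out), overall_fixation_percentage(rec, stimulus)


def build_attribute_matrix(
    recordings: dict[str, GazeRecordingSet],
    stimulus: StimulusSet,
    min_run: int = 1,
) -> AttributeMatrix:
    """Score every participant and assemble the attribute matrix.

    Row order is sorted participant id; scoring one participant never
    depends on another, so the result is order-independent.
    """
    specs = enumerate_attribute_space(stimulus)
    cols = [s.attribute_id for s in specs]
    ids = sorted(recordings)
    rows = np.empty((len(ids), len(cols)))
    fix = np.empty(len(ids))
    for i, pid in enumerate(ids):
        rows[i], fix[i] = score_participant(recordings[pid], stimulus, min_run=min_run)
    values = pd.DataFrame(rows, index=pd.Index(ids, name="participant_id"), columns=cols)
    return AttributeMatrix(
        values=values,
        fixation_pct=pd.Series(fix, index=values.index, name="overall_fixation_pct"),
        specs=specs,
    )
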