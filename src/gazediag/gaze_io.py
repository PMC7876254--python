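"""Tabular I/O for gaze recordings and cohort tables.

Gaze CSV layout: ``participant_id,clip_id,t_ms,x_px,y_px,valid`` -- one row
per 50 Hz sample, timestamps in integer milliseconds from clip onset on a
20 ms grid.  Invalid samples (eye lost or off-screen) keep their grid slot
with blank coordinates so rate denominators stay well-defined.

Cohort CSV layout: ``participant_id,age_years,group,asd_label``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .stimulus_model import StimulusSet

GAZE_COLUMNS = ["participant_id", "clip_id", "t_ms", "x_px", "y_px", "valid"]
COHORT_COLUMNS = ["participant_id", "age_years", "group", "asd_label"]
GROUPS = frozenset({"ASD", "TD", "second_control", "unknown"})

#: inclusive age range of the studied population (years)
AGE_RANGE = (5.0, 17.0)
#: the age split between the two modelling bands (younger < 10 <= older)
AGE_BAND_SPLIT = 10.0


class GazeSample(NamedTuple):
    """One 50 Hz sample: ms from clip onset, pixel coordinates, validity."""

    t: int
    x: float
    y: float
    valid: bool


@dataclass
class GazeRecordingSet:
    """All gaze samples of one participant, keyed by clip id.

    Each clip maps to a DataFrame with columns ``t_ms`` (int), ``x_px``,
    ``y_px`` (float, NaN when invalid) and ``valid`` (bool), sorted by
    strictly increasing ``t_ms``.
    """

    participant_id: str
    clips: dict[str, pd.DataFrame] = field(default_factory=dict)

    def samples(self, clip_id: str) -> pd.DataFrame:
        return self.clips[clip_id]

    def iter_samples(self, clip_id: str):
        """Yield :class:`GazeSample` tuples for one clip."""
        for row in self.clips[clip_id].itertuples(index=False):
            yield GazeSample(int(row.t_ms), float(row.x_px), float(row.y_px), bool(row.valid))

    def has_clips(self, clip_ids) -> bool:
        return all(c in self.clips for c in clip_ids)

    def n_samples(self) -> int:
        return sum(len(df) for df in self.clips.values())


@dataclass(frozen=True)
class Participant:
    participant_id: str
    age_years: float
    group: str
    asd_label: Optional[bool] = None

    @property
    def band(self) -> str:
        """Age band: 'younger' below 10 years, 'older' at 10 and above."""
        return "younger" if self.age_years < AGE_BAND_SPLIT else "older"


def _check_columns(df: pd.DataFrame, expected: list[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing column(s) {missing}; header must be {expected}")


def _parse_valid(col: pd.Series) -> np.ndarray:
    s = col.astype(str).str.strip().str.lower()
    truthy = s.isin({"1", "true", "t", "yes"})
    falsy = s.isin({"0", "false", "f", "no"})
    bad = ~(truthy | falsy)
    if bad.any():
        raise FormatError(f"gaze table: unparseable 'valid' value {col[bad].iloc[0]!r}")
    return truthy.to_numpy()


def read_gaze_table(path, stimulus: StimulusSet) -> dict[str, GazeRecordingSet]:
    """Read a gaze CSV into per-participant recording sets.

    Rows are grouped by participant and clip and sorted by time; unknown
    clip ids and non-monotone timestamps are rejected with the offending
    location named.  Invalid samples are retained with ``valid=False``.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "clip_id": str})
    _check_columns(df, GAZE_COLUMNS, "gaze table")
    out: dict[str, GazeRecordingSet] = {}
    if df.empty:
        return out
    known = set(stimulus.clip_ids)
    bad_clips = set(df["clip_id"].unique()) - known
    if bad_clips:
        raise ValidationError(f"gaze table: unknown clip id(s) {sorted(bad_clips)}")
    df = df.copy()
    df["valid"] = _parse_valid(df["valid"])
    df["t_ms"] = df["t_ms"].astype(np.int64)
    for col in ("x_px", "y_px"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)

    for (pid, clip_id), grp in df.groupby(["participant_id", "clip_id"], sort=True):
        clip = stimulus.clip(clip_id)
        rec = grp.sort_values("t_ms")[["t_ms", "x_px", "y_px", "valid"]].reset_index(drop=True)
        t = rec["t_ms"].to_numpy()
        if (t < 0).any():
            raise ValidationError(f"participant {pid!r} clip {clip_id!r}: negative timestamp")
        if len(t) > 1 and (np.diff(t) <= 0).any():
            raise ValidationError(
                f"participant {pid!r} clip {clip_id!r}: timestamps not strictly increasing"
            )
        if t.size and t[-1] >= clip.duration_s * 1000:
            raise ValidationError(
                f"participant {pid!r} clip {clip_id!r}: timestamp {t[-1]} ms exceeds "
                f"clip duration {clip.duration_s:g} s"
            )
        v = rec["valid"].to_numpy()
        x, y = rec["x_px"].to_numpy(), rec["y_px"].to_numpy()
        on = v & np.isfinite(x) & np.isfinite(y)
        if (v & ~np.isfinite(x)).any() or (v & ~np.isfinite(y)).any():
            raise ValidationError(
                f"participant {pid!r} clip {clip_id!r}: valid sample with blank coordinates"
            )
        out_of_bounds = on & (
            (x < 0) | (x >= stimulus.monitor_width) | (y < 0) | (y >= stimulus.monitor_height)
        )
        if out_of_bounds.any():
            raise ValidationError(
                f"participant {pid!r} clip {clip_id!r}: valid sample off the monitor"
            )
        out.setdefault(pid, GazeRecordingSet(participant_id=pid)).clips[clip_id] = rec
    return out


def write_gaze_table(recordings: dict[str, GazeRecordingSet], path) -> None:
    """Write recordings back to the gaze CSV layout (round-trip safe)."""
    frames = []
    for pid in sorted(recordings):
        rec = recordings[pid]
        for clip_id in sorted(rec.clips):
            df = rec.clips[clip_id].copy()
            df.insert(0, "clip_id", clip_id)
            df.insert(0, "participant_id", pid)
            frames.append(df)
    if frames:
        all_df = pd.concat(frames, ignore_index=True)
        all_df["valid"] = all_df["valid"].astype(int)
    else:
        all_df = pd.DataFrame(columns=GAZE_COLUMNS)
    all_df.to_csv(path, index=False)


def read_cohort_table(path, permissive: bool = False) -> list[Participant]:
    """Read the cohort CSV; duplicate ids and out-of-range ages are rejected.

    ``permissive=True`` waives the [5, 17] year age-range check.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "group": str})
    _check_columns(df, COHORT_COLUMNS, "cohort table")
    if df["participant_id"].duplicated().any():
        dup = df["participant_id"][df["participant_id"].duplicated()].iloc[0]
        raise ValidationError(f"cohort table: duplicate participant id {dup!r}")
    participants: list[Participant] = []
    for row in df.itertuples(index=False):
        age = float(row.age_years)
        if not permissive and not (AGE_RANGE[0] <= age <= AGE_RANGE[1]):
            raise ValidationError(
                f"participant {row.participant_id!r}: age {age:g} outside "
                f"[{AGE_RANGE[0]:g}, {AGE_RANGE[1]:g}] (pass permissive=True to allow)"
            )
        if row.group not in GROUPS:
            raise ValidationError(
                f"participant {row.participant_id!r}: unknown group {row.group!r}"
            )
        label = row.asd_label
        if pd.isna(label) or label == "":
            asd: Optional[bool] = None
        else:
            asd = bool(int(label))
        participants.append(
            Participant(
                participant_id=str(row.participant_id),
                age_years=age, group=str(row.group), asd_label=asd,
            )
        )
    return participants


def write_cohort_table(participants: list[Participant], path) -> None:
    rows = [
        {
            "participant_id": p.participant_id,
            "age_years": p.age_years,
            "group": p.group,
            "asd_label": "" if p.asd_label is None else int(p.asd_label),
        }
        for p in participants
    ]
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def cohort_by_id(participants: list[Participant]) -> dict[str, Participant]:
    return {p.participant_id: p for p in participants}
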