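"""Seeded synthetic gaze cohorts with plantable group differences.

Real Gazefinder recordings are not publicly shareable, so every pipeline
stage is exercised on simulated cohorts.  Gaze is modelled per participant
and clip as a first-order Markov chain at 50 Hz over the states {each AOI
of the clip, elsewhere-on-screen, off-screen}: with probability *rho* (the
stickiness) the gaze stays in its current state, producing multi-sample
fixations; otherwise it redraws a state from the participant's stationary
weights.  Stationary weights are drawn per participant from a Dirichlet
around clip-level base weights (semantic-label attention budgets split
among same-label AOIs), which creates realistic between-participant
variability.  For participants carrying the diagnosis, the weights of
designated *signal AOIs* -- and of any AOI geometrically nested inside
them -- are shifted by -delta on the log scale (band-scoped by age), so
reduced dwell on social regions and increased dwell on geometric regions
emerge with a configurable effect size.  Off-screen states emit invalid
samples; a configurable fraction of diagnosed participants is simulated
with degraded tracking (bursty off-screen gaze, fixation < 70%) to
exercise the low-fixation flag.

The delta -> Cohen's d mapping has no closed form (weights renormalize and
AOIs overlap); it is calibrated empirically via :func:`realized_effects`,
and recovery tests quote realized, not nominal, effects.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .gaze_io import GazeRecordingSet, Participant, write_cohort_table, write_gaze_table
from .scoring import build_attribute_matrix
from .stimulus_model import Aoi, MovieClip, StimulusSet, region_contained

#: attention budget per semantic label, split equally among same-label AOIs
LABEL_BUDGETS = {
    "eyes": 0.24,
    "face": 0.16,
    "human": 0.16,
    "geometric": 0.20,
    "object": 0.08,
    "other": 0.06,
}
#: budget of the unfocused "elsewhere on screen" state
ELSEWHERE_BUDGET = 0.24

#: default log-scale dwell shift for planted signal AOIs
DEFAULT_DELTA = 0.9


@dataclass(frozen=True)
class SignalSpec:
    """A planted group difference on one AOI.

    ``delta`` > 0 reduces the diagnosed group's dwell weight by the factor
    exp(-delta) (social regions); ``delta`` < 0 increases it (geometric
    regions).  ``scope`` restricts the shift to one age band.
    """

    aoi_id: str
    scope: str = "both"  # "younger" | "older" | "both"
    delta: float = DEFAULT_DELTA

    def applies(self, age: float) -> bool:
        if self.scope == "both":
            return True
        band = "younger" if age < 10.0 else "older"
        return self.scope == band


def default_signal_specs(delta: float = DEFAULT_DELTA) -> tuple[SignalSpec, ...]:
    """Eight default signal AOIs mirroring the expected clinical contrasts:

    reduced dwell on eyes/faces in social scenes at all ages, and -- in the
    older band -- reduced dwell on the human side and increased dwell on
    the geometric side of preferential clips.
    """
    return (
        SignalSpec("still.eyes_band", "both", delta),
        SignalSpec("classroom.teacher_face", "both", delta),
        SignalSpec("pref_b.human_face", "both", delta),
        SignalSpec("pref_d.human_face", "both", delta),
        SignalSpec("pref_a.human_face", "older", delta),
        SignalSpec("pref_c.human_face", "older", delta),
        SignalSpec("pref_f1.human_face", "older", delta),
        SignalSpec("pref_e1.geo_side", "older", -delta),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort."""

    n_asd: int = 39
    n_td: int = 102
    n_second_control: int = 0
    second_control_asd_fraction: float = 17.0 / 24.0
    age_range: tuple[float, float] = (5.0, 17.0)
    signal_aois: tuple[SignalSpec, ...] = field(default_factory=default_signal_specs)
    stickiness: float = 0.95  # self-transition prob; ~0.4 s mean fixation at 50 Hz
    offscreen_rate: float = 0.08  # mean per-sample invalid probability
    offscreen_concentration: float = 20.0  # Beta concentration of per-person rate
    low_fixation_fraction: float = 0.025  # share of diagnosed with degraded tracking
    degraded_offscreen_rate: float = 0.45
    dirichlet_concentration: float = 25.0  # between-participant dwell heterogeneity
    second_control_concentration: float = 12.0  # wider heterogeneity in 2nd control
    #: probability that a participant categorically avoids a (positive-delta)
    #: signal AOI -- never fixates it at all; dwell distributions on social
    #: regions are zero-inflated in this way in real cohorts, and this is
    #: what gives the binary count score its discriminative signal
    asd_avoidance: float = 0.35
    td_avoidance: float = 0.05
    avoidance_factor: float = 0.02  # residual weight multiplier when avoiding
    seed: int = 0

    def validate(self, stimulus: StimulusSet) -> None:
        if not (0.0 < self.stickiness < 1.0):
            raise ConfigError("stickiness must be in (0, 1)")
        for p in (self.offscreen_rate, self.degraded_offscreen_rate, self.low_fixation_fraction):
            if not (0.0 <= p < 1.0):
                raise ConfigError("probabilities must lie in [0, 1)")
        known = {a.aoi_id for a in stimulus.iter_aois()}
        for sig in self.signal_aois:
            if sig.aoi_id not in known:
                raise ConfigError(f"signal AOI {sig.aoi_id!r} absent from stimulus")
            if sig.scope not in ("younger", "older", "both"):
                raise ConfigError(f"signal scope {sig.scope!r} invalid")


@dataclass
class GroundTruth:
    """What was planted: per-participant state and the signal list."""

    signal_aois: list[dict]
    participants: dict[str, dict]  # id -> {asd, age, degraded, group}
    propensities: dict[str, dict[str, list[float]]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "signal_aois": self.signal_aois,
                    "participants": self.participants,
                    "propensities": self.propensities,
                },
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")


@dataclass
class SimulatedCohort:
    participants: list[Participant]
    recordings: dict[str, GazeRecordingSet]
    truth: GroundTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort_table(self.participants, outdir / "cohort.csv")
        write_gaze_table(self.recordings, outdir / "gaze.csv")
        self.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# clip-level machinery
# ---------------------------------------------------------------------------

class _ClipModel:
    """Precomputed emission states and base weights for one clip."""

    def __init__(self, clip: MovieClip):
        self.clip = clip
        self.aois: list[Aoi] = sorted(clip.aois, key=lambda a: a.aoi_id)
        label_counts: dict[str, int] = {}
        for a in self.aois:
            label_counts[a.label] = label_counts.get(a.label, 0) + 1
        w = np.array(
            [LABEL_BUDGETS[a.label] / label_counts[a.label] for a in self.aois]
        )
        self.base_weights = np.append(w, ELSEWHERE_BUDGET)  # last = elsewhere
        # nested[i] = indices of AOI states contained in AOI i (incl. itself)
        self.nested: list[list[int]] = [
            [j for j, inner in enumerate(self.aois) if region_contained(inner, outer)]
            for outer in self.aois
        ]
        self.index = {a.aoi_id: i for i, a in enumerate(self.aois)}


#: SD of the per-sample fixation jitter around a run's anchor point, pixels
FIXATION_JITTER_PX = 3.0


def _emit_coordinates(
    states: np.ndarray,
    model: _ClipModel,
    stimulus: StimulusSet,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixation-like coordinates: one anchor point per Markov run.

    Each maximal constant-state run gets a single anchor drawn uniformly
    within the state's region (the whole monitor for the unfocused
    "elsewhere" state), and samples scatter around it with small Gaussian
    jitter -- gaze rests on a point during a fixation rather than jumping
    within the region at 50 Hz.
    """
    n = states.size
    # run id per sample and the state of each run
    changes = np.r_[True, states[1:] != states[:-1]]
    rid = np.cumsum(changes) - 1
    run_states = states[changes]
    n_runs = run_states.size
    ax = np.full(n_runs, np.nan)
    ay = np.full(n_runs, np.nan)
    for i, aoi in enumerate(model.aois):
        m = run_states == i
        cnt = int(m.sum())
        if not cnt:
            continue
        if aoi.shape == "circle":
            r = aoi.r * np.sqrt(rng.random(cnt))
            th = rng.uniform(0.0, 2.0 * np.pi, cnt)
            ax[m] = aoi.cx + r * np.cos(th)
            ay[m] = aoi.cy + r * np.sin(th)
        else:
            ax[m] = rng.uniform(aoi.x, aoi.x + aoi.w, cnt)
            ay[m] = rng.uniform(aoi.y, aoi.y + aoi.h, cnt)
    m = run_states == len(model.aois)  # elsewhere
    cnt = int(m.sum())
    if cnt:
        ax[m] = rng.uniform(0.0, stimulus.monitor_width, cnt)
        ay[m] = rng.uniform(0.0, stimulus.monitor_height, cnt)
    x = ax[rid] + rng.normal(0.0, FIXATION_JITTER_PX, n)
    y = ay[rid] + rng.normal(0.0, FIXATION_JITTER_PX, n)
    # guard the half-open monitor bounds after 0.1 px rounding
    np.clip(x, 0.0, stimulus.monitor_width - 0.1, out=x)
    np.clip(y, 0.0, stimulus.monitor_height - 0.1, out=y)
    return x, y


def _markov_states(
    weights: np.ndarray, rho: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sticky Markov chain: stay with prob rho, else redraw from *weights*."""
    fresh = rng.choice(weights.size, size=n, p=weights)
    stay = rng.random(n) < rho
    stay[0] = False
    idx = np.maximum.accumulate(np.where(~stay, np.arange(n), 0))
    return fresh[idx]


def _draw_avoidance(
    cfg: SimConfig, rng: np.random.Generator, asd: bool
) -> dict[str, bool]:
    """Per-participant categorical avoidance traits for positive-delta signals.

    Avoidance is drawn once per participant (a trait, not a per-clip event)
    and in a fixed order over the signal list, keeping the random stream
    stable across configurations.
    """
    rate = cfg.asd_avoidance if asd else cfg.td_avoidance
    return {
        sig.aoi_id: (sig.delta > 0 and rng.random() < rate)
        for sig in cfg.signal_aois
    }


def _participant_weights(
    model: _ClipModel,
    cfg: SimConfig,
    rng: np.random.Generator,
    asd: bool,
    age: float,
    concentration: float,
    avoidance: dict[str, bool],
) -> np.ndarray:
    """Per-participant stationary weights over this clip's on-screen states."""
    base = model.base_weights.copy()
    for sig in cfg.signal_aois:
        if sig.aoi_id not in model.index:
            continue
        factor = 1.0
        if avoidance.get(sig.aoi_id, False) and sig.applies(age):
            factor = cfg.avoidance_factor
        elif asd and sig.applies(age):
            factor = np.exp(-sig.delta)
        if factor != 1.0:
            for j in model.nested[model.index[sig.aoi_id]]:
                base[j] *= factor
    base /= base.sum()
    return rng.dirichlet(concentration * base)


def simulate_participant(
    stimulus: StimulusSet,
    cfg: SimConfig,
    rng: np.random.Generator,
    participant_id: str,
    asd: bool,
    age: float,
    degraded: bool = False,
    concentration: Optional[float] = None,
    clip_models: Optional[dict[str, _ClipModel]] = None,
) -> tuple[GazeRecordingSet, dict[str, list[float]]]:
    """Simulate one participant's full recording set.

    Returns the recordings and the realized per-clip stationary dwell
    propensities (on-screen states in AOI-id order, then elsewhere).
    """
    if clip_models is None:
        clip_models = {c.clip_id: _ClipModel(c) for c in stimulus.clips}
    conc = concentration if concentration is not None else cfg.dirichlet_concentration
    off_mean = cfg.degraded_offscreen_rate if degraded else cfg.offscreen_rate
    oc = cfg.offscreen_concentration
    p_off = float(rng.beta(off_mean * oc, (1.0 - off_mean) * oc)) if off_mean > 0 else 0.0
    avoidance = _draw_avoidance(cfg, rng, asd)
    rec = GazeRecordingSet(participant_id=participant_id)
    propensities: dict[str, list[float]] = {}
    for clip in stimulus.clips:
        model = clip_models[clip.clip_id]
        w_on = _participant_weights(model, cfg, rng, asd, age, conc, avoidance)
        weights = np.append(w_on * (1.0 - p_off), p_off)  # last = off-screen
        n = clip.n_samples(stimulus.sample_rate_hz)
        states = _markov_states(weights, cfg.stickiness, n, rng)
        x, y = _emit_coordinates(states, model, stimulus, rng)
        off = states == weights.size - 1
        x[off] = np.nan
        y[off] = np.nan
        rec.clips[clip.clip_id] = pd.DataFrame(
            {
                "t_ms": np.arange(n, dtype=np.int64) * 20,
                "x_px": np.round(x, 1),
                "y_px": np.round(y, 1),
                "valid": ~off,
            }
        )
        propensities[clip.clip_id] = [float(v) for v in np.round(weights, 6)]
    return rec, propensities


def simulate_cohort(stimulus: StimulusSet, cfg: SimConfig) -> SimulatedCohort:
    """Simulate a full cohort: ASD, TD and optional second-control groups.

    Fully deterministic given ``cfg.seed``.  Degraded (low-fixation)
    tracking is assigned to the first ``low_fixation_fraction`` share of
    diagnosed participants, mirroring the observation that low fixation
    percentages occur in the diagnosed group.
    """
    cfg.validate(stimulus)
    rng = np.random.default_rng(cfg.seed)
    participants: list[Participant] = []
    recordings: dict[str, GazeRecordingSet] = {}
    truth = GroundTruth(
        signal_aois=[asdict(s) for s in cfg.signal_aois],
        participants={},
    )
    clip_models = {c.clip_id: _ClipModel(c) for c in stimulus.clips}
    lo, hi = cfg.age_range

    n_degraded = int(round(cfg.low_fixation_fraction * cfg.n_asd))

    def add(pid: str, group: str, asd: bool, degraded: bool, conc: float) -> None:
        age = float(np.round(rng.uniform(lo, hi), 2))
        rec, prop = simulate_participant(
            stimulus, cfg, rng, pid, asd, age, degraded, conc, clip_models
        )
        participants.append(
            Participant(participant_id=pid, age_years=age, group=group, asd_label=asd)
        )
        recordings[pid] = rec
        truth.participants[pid] = {
            "asd": asd, "age": age, "degraded": degraded, "group": group,
        }
        truth.propensities[pid] = prop

    for i in range(cfg.n_asd):
        add(f"asd{i + 1:03d}", "ASD", True, i < n_degraded, cfg.dirichlet_concentration)
    for i in range(cfg.n_td):
        add(f"td{i + 1:03d}", "TD", False, False, cfg.dirichlet_concentration)
    n_sc_asd = int(round(cfg.second_control_asd_fraction * cfg.n_second_control))
    for i in range(cfg.n_second_control):
        add(
            f"sc{i + 1:03d}", "second_control", i < n_sc_asd, False,
            cfg.second_control_concentration,
        )
    return SimulatedCohort(participants=participants, recordings=recordings, truth=truth)


def simulate_degraded(
    stimulus: StimulusSet,
    cfg: SimConfig,
    participant_id: str = "degraded001",
    age: float = 8.0,
    asd: bool = True,
    seed: Optional[int] = None,
) -> GazeRecordingSet:
    """One participant with degraded tracking (overall fixation < 70%)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rec, _ = simulate_participant(
        stimulus, cfg, rng, participant_id, asd=asd, age=age, degraded=True
    )
    return rec


def realized_effects(
    recordings: dict[str, GazeRecordingSet],
    participants: Sequence[Participant],
    stimulus: StimulusSet,
) -> pd.Series:
    """Realized Cohen's d (diagnosed minus typical) of full-window rate
    scores, per AOI.  This is the empirical delta -> d calibration map."""
    from .attribute_selection import _cohens_d_columns

    matrix = build_attribute_matrix(recordings, stimulus)
    asd_ids = [p.participant_id for p in participants if p.asd_label]
    td_ids = [p.participant_id for p in participants if p.asd_label is False]
    aoi_ids = sorted(a.aoi_id for a in stimulus.iter_aois())
    cols = [f"{a}:rate_full" for a in aoi_ids]
    d = _cohens_d_columns(
        matrix.values.loc[asd_ids, cols].to_numpy(),
        matrix.values.loc[td_ids, cols].to_numpy(),
    )
    return pd.Series(d, index=aoi_ids, name="realized_d")
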