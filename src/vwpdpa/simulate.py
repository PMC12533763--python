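"""Synthetic visual-world cohorts with known divergence latencies.

Generates complete cohorts — 1000 Hz gaze streams, trial metadata and
participant metadata — that are valid inputs for the preprocessing module
and whose ground-truth divergence latencies are known by construction, so
the whole pipeline is testable without external eye-tracking data.

The generative model: on each trial a participant produces a sequence of
fixations with Gamma-distributed durations (fixation persistence gives the
autocorrelation real gaze data has; per-sample independence would make the
bin-wise t tests anticonservative).  Each fixation lands on one of the four
images, drawn from a role-probability distribution evaluated at the
fixation's onset; the distribution shifts from a uniform-ish baseline to a
target-dominant asymptote following logistic transitions at the condition's
true latencies.  Fixations are separated by short invalid gaps (saccades /
blinks) to exercise the missing-sample rules.

All distributional choices are stand-ins: the study this design mirrors
reports no distributional description of its gaze data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from .preprocess import QUADRANTS, RoiLayout, rotate_role_assignment
from .timeline import (
    DEFAULT_PREVIEW_MS,
    StimulusTimeline,
    default_timeline,
)

# ---------------------------------------------------------------------------
# Looking curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LookingCurveParams:
    """Single logistic transition of the probability of fixating a role:
    baseline before the divergence latency, asymptote after, with scale
    ``slope_ms`` (smaller = sharper)."""

    baseline_p: float
    asymptote_p: float
    latency_ms: float
    slope_ms: float

    def __post_init__(self) -> None:
        if not 0 <= self.baseline_p <= 1 or not 0 <= self.asymptote_p <= 1:
            raise ValidationError("probabilities must lie in [0, 1]")
        if not self.baseline_p < self.asymptote_p:
            raise ValidationError("baseline_p must be below asymptote_p")
        if not self.slope_ms > 0:
            raise ValidationError("slope_ms must be positive")


def looking_probability(t_ms, params: LookingCurveParams):
    """P(fixate the rising role) at time t: baseline + range · logistic."""
    t = np.asarray(t_ms, dtype=float)
    p = params.baseline_p + (params.asymptote_p - params.baseline_p) * expit(
        (t - params.latency_ms) / params.slope_ms
    )
    return p if t.ndim else float(p)


def role_distribution(
    t_ms,
    params: LookingCurveParams,
    roles: Sequence[str],
    competitor: str | None = None,
    competitor_weight: float = 1.5,
):
    """Full four-role distribution implied by one looking curve.

    The first role in ``roles`` follows the curve; the remainder is split
    among the other three, with ``competitor`` up-weighted before the
    latency (it decays to uniform as the transition completes).
    """
    t = np.atleast_1d(np.asarray(t_ms, dtype=float))
    p_a = np.atleast_1d(looking_probability(t, params))
    pre = 1.0 - expit((t - params.latency_ms) / params.slope_ms)
    others = [r for r in roles[1:]]
    w = np.ones((len(t), len(others)))
    if competitor is not None:
        j = others.index(competitor)
        w[:, j] = 1.0 + (competitor_weight - 1.0) * pre
    w /= w.sum(axis=1, keepdims=True)
    out = np.empty((len(t), len(roles)))
    out[:, 0] = p_a
    out[:, 1:] = (1.0 - p_a)[:, None] * w
    return out if np.ndim(t_ms) else out[0]


@dataclass(frozen=True)
class RoleCurve:
    """Piecewise-logistic probability curve: start at ``levels[0]`` and
    transition to each subsequent level at the matching latency."""

    levels: tuple[float, ...]
    latencies_ms: tuple[float, ...] = ()
    slope_ms: float = 5.0

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.latencies_ms) + 1:
            raise ValidationError("need one more level than latencies")
        if any(not 0 <= p <= 1 for p in self.levels):
            raise ValidationError("levels must lie in [0, 1]")
        if self.slope_ms <= 0:
            raise ValidationError("slope_ms must be positive")

    def __call__(self, t_ms):
        t = np.asarray(t_ms, dtype=float)
        p = np.full(t.shape, self.levels[0])
        for k, lat in enumerate(self.latencies_ms):
            p = p + (self.levels[k + 1] - self.levels[k]) * expit((t - lat) / self.slope_ms)
        return p


@dataclass(frozen=True)
class ConditionCurves:
    """Role→curve map for one condition; probabilities are renormalized to
    sum to exactly 1 at every time point."""

    curves: Mapping[str, RoleCurve]

    def roles(self) -> list[str]:
        return list(self.curves)

    def probabilities(self, t_ms) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        P = np.stack([c(t) for c in self.curves.values()], axis=1)
        s = P.sum(axis=1, keepdims=True)
        if np.any(s <= 0):
            raise ValidationError("role probabilities sum to zero")
        return P / s


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------

SUB1, SUB2, FILLER = "1", "2", "filler"

#: Role vocabularies per (sub_experiment, condition).
CONDITION_ROLES: dict[tuple[str, str], tuple[str, ...]] = {
    (SUB1, "CP"): ("target", "cu_target", "distractor1", "distractor2"),
    (SUB1, "CU"): ("target", "cu_target", "distractor1", "distractor2"),
    (SUB2, "CP"): ("target", "agent_competitor", "verb_distractor", "distractor1"),
    (FILLER, "neutral"): ("target", "distractor1", "distractor2", "distractor3"),
}

#: Design trial counts per condition.
DEFAULT_ITEMS: dict[tuple[str, str], int] = {
    (SUB1, "CP"): 24,
    (SUB1, "CU"): 24,
    (SUB2, "CP"): 16,
    (FILLER, "neutral"): 40,
}

BASELINE_P = 0.25
ASYMPTOTE_P = 0.85
FLOOR_P = 0.05
MID_P = 0.45  # shared target/agent-competitor level between the two sub-2 stages
#: Default logistic scale: a near-categorical preference switch, so the
#: latency parameter is identified at bin resolution (the transition
#: completes within roughly one 20 ms bin).  Larger values give graded
#: population dynamics but blur what "true latency" means for recovery
#: studies.
DEFAULT_SLOPE_MS = 5.0


@dataclass(frozen=True)
class GroupLatencies:
    """True divergence latencies (ms) for one group, one per contrast."""

    prediction: float = 800.0
    cost: float = 1800.0
    early: float = 800.0
    late: float = 1180.0
    filler: float = 1780.0


def condition_curves(
    lat: GroupLatencies, slope_ms: float = DEFAULT_SLOPE_MS
) -> dict[tuple[str, str], ConditionCurves]:
    """Default looking curves realizing the given latencies.

    Baselines are equal across roles, so each contrast's latency parameter
    is exactly the time its two roles' probabilities separate — the
    estimand the divergence point analysis targets.
    """
    b, a, f, m, s = BASELINE_P, ASYMPTOTE_P, FLOOR_P, MID_P, slope_ms
    return {
        (SUB1, "CP"): ConditionCurves(
            {
                "target": RoleCurve((b, a), (lat.prediction,), s),
                "cu_target": RoleCurve((b, f), (lat.prediction,), s),
                "distractor1": RoleCurve((b, f), (lat.prediction,), s),
                "distractor2": RoleCurve((b, f), (lat.prediction,), s),
            }
        ),
        (SUB1, "CU"): ConditionCurves(
            {
                # listener first predicts the CP target, then revises to the
                # unexpected CU target once it is heard
                "target": RoleCurve((b, a, f), (lat.prediction, lat.cost), s),
                "cu_target": RoleCurve((b, f, a), (lat.prediction, lat.cost), s),
                "distractor1": RoleCurve((b, f), (lat.prediction,), s),
                "distractor2": RoleCurve((b, f), (lat.prediction,), s),
            }
        ),
        (SUB2, "CP"): ConditionCurves(
            {
                # agent narrows to {target, agent competitor}; verb narrows
                # to the target alone
                "target": RoleCurve((b, m, a), (lat.early, lat.late), s),
                "agent_competitor": RoleCurve((b, m, f), (lat.early, lat.late), s),
                "verb_distractor": RoleCurve((b, f), (lat.early,), s),
                "distractor1": RoleCurve((b, f), (lat.early,), s),
            }
        ),
        (FILLER, "neutral"): ConditionCurves(
            {
                "target": RoleCurve((b, a), (lat.filler,), s),
                "distractor1": RoleCurve((b, f), (lat.filler,), s),
                "distractor2": RoleCurve((b, f), (lat.filler,), s),
                "distractor3": RoleCurve((b, f), (lat.filler,), s),
            }
        ),
    }


#: Which contrast's latency applies to each condition's ground truth.
CONTRAST_LATENCY_FIELDS = {
    "sub1_prediction": "prediction",
    "sub1_cost": "cost",
    "sub2_early": "early",
    "sub2_late": "late",
    "filler": "filler",
}


@dataclass(frozen=True)
class MetaDistribution:
    """Normal stand-in for one participant-metadata variable."""

    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.clip(rng.normal(self.mean, self.sd, size=n), self.lo, self.hi)


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_participants: int
    latencies: GroupLatencies = field(default_factory=GroupLatencies)
    slope_ms: float = DEFAULT_SLOPE_MS
    accuracy_p: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            (SUB1, "CP"): 0.99,
            (SUB1, "CU"): 0.92,
            (SUB2, "CP"): 0.97,
            (FILLER, "neutral"): 0.97,
        }
    )
    intelligibility: MetaDistribution = MetaDistribution(100.0, 0.0, 0.0, 100.0)
    effort: MetaDistribution = MetaDistribution(8.0, 4.0, 0.0, 100.0)
    age: MetaDistribution = MetaDistribution(69.0, 5.9, 50.0, 85.0)
    hearing_level: MetaDistribution = MetaDistribution(14.7, 6.2, -10.0, 120.0)
    #: Optional explicit looking curves per condition; overrides the default
    #: curves built from ``latencies`` (useful for degenerate test cohorts,
    #: e.g. an exact step preference).
    curves_override: Mapping[tuple[str, str], ConditionCurves] | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValidationError("each group needs at least 2 participants")
        for k, p in self.accuracy_p.items():
            if not 0 < p <= 1:
                raise ValidationError(f"accuracy_p for {k} must lie in (0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    items: Mapping[tuple[str, str], int] = field(default_factory=lambda: dict(DEFAULT_ITEMS))
    sample_rate_hz: float = 1000.0
    fixation_mean_ms: float = 250.0
    fixation_shape: float = 4.0
    saccade_gap_ms: float = 30.0
    timeline: StimulusTimeline = field(default_factory=default_timeline)
    preview_ms: float = DEFAULT_PREVIEW_MS
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("cohort needs at least one group")
        if self.fixation_mean_ms <= 0 or self.fixation_shape <= 0:
            raise ValidationError("fixation duration parameters must be positive")
        span = self.preview_ms + self.timeline.selection_cue_ms
        if span < self.fixation_mean_ms:
            raise ValidationError("trial window shorter than one average fixation")
        for key in self.items:
            if key not in CONDITION_ROLES:
                raise ValidationError(f"unknown condition {key}")


def default_cohort_spec(seed: int = 0, slope_ms: float = DEFAULT_SLOPE_MS) -> CohortSpec:
    """The full three-group study design.

    Latency structure mirrors the qualitative result pattern the design
    anticipates: equal early-contrast latencies across groups and
    late-contrast (second-stage prediction) latencies delayed by +115 and
    +190 ms in the two hearing-loss groups.  These offsets are generator
    defaults, not empirical claims.
    """
    return CohortSpec(
        groups=(
            GroupSpec("PwNH", 30, GroupLatencies(), slope_ms=slope_ms),
            GroupSpec(
                "PwHL_low_demand",
                32,
                GroupLatencies(late=1295.0),
                slope_ms=slope_ms,
                intelligibility=MetaDistribution(96.9, 5.0, 0.0, 100.0),
                effort=MetaDistribution(14.0, 7.0, 0.0, 100.0),
                age=MetaDistribution(72.3, 5.2, 50.0, 90.0),
                hearing_level=MetaDistribution(46.4, 7.8, 0.0, 120.0),
            ),
            GroupSpec(
                "PwHL_high_demand",
                31,
                GroupLatencies(late=1370.0),
                slope_ms=slope_ms,
                intelligibility=MetaDistribution(88.4, 10.0, 0.0, 100.0),
                effort=MetaDistribution(30.0, 12.0, 0.0, 100.0),
                age=MetaDistribution(72.5, 5.3, 50.0, 90.0),
                hearing_level=MetaDistribution(46.7, 10.6, 0.0, 120.0),
            ),
        ),
        seed=seed,
    )


def single_group_spec(
    label: str = "G1",
    n_participants: int = 30,
    n_items: int = 24,
    latency_ms: float = 800.0,
    seed: int = 0,
    slope_ms: float = DEFAULT_SLOPE_MS,
    **kwargs,
) -> CohortSpec:
    """One group, CP items only — the minimal cohort for recovery studies."""
    return CohortSpec(
        groups=(
            GroupSpec(
                label,
                n_participants,
                GroupLatencies(prediction=latency_ms),
                slope_ms=slope_ms,
            ),
        ),
        items={(SUB1, "CP"): n_items},
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    samples: pd.DataFrame
    trials: pd.DataFrame
    participants: pd.DataFrame
    ground_truth: dict


def _simulate_trial_arrays(
    rng: np.random.Generator,
    curves: ConditionCurves,
    layout: RoiLayout,
    role_of_quadrant: Mapping[str, str],
    t0_ms: int,
    t1_ms: int,
    fix_mean: float,
    fix_shape: float,
    gap_ms: int,
    sample_step_ms: float,
):
    """One trial's per-sample (t, x, y, valid) arrays at the sample rate."""
    span = t1_ms - t0_ms
    n_draw = max(4, int(span / (fix_mean + gap_ms) * 2) + 8)
    roles = curves.roles()
    quad_of_role = {r: q for q, r in role_of_quadrant.items()}
    boxes = layout.image_boxes()

    durs = np.maximum(
        1, np.round(rng.gamma(fix_shape, fix_mean / fix_shape, size=n_draw))
    ).astype(np.int64)
    while (durs + gap_ms).sum() < span:  # pragma: no cover - rare top-up
        durs = np.concatenate(
            [
                durs,
                np.maximum(
                    1, np.round(rng.gamma(fix_shape, fix_mean / fix_shape, size=n_draw))
                ).astype(np.int64),
            ]
        )
    seg = np.empty(2 * len(durs), dtype=np.int64)
    seg[0::2] = durs
    seg[1::2] = gap_ms
    ends = np.cumsum(seg)
    n_seg = int(np.searchsorted(ends, span) + 1)
    seg = seg[:n_seg]
    durs = durs[: (n_seg + 1) // 2]

    onsets = t0_ms + np.concatenate([[0], np.cumsum(seg)[:-1]])[0::2][: len(durs)]
    P = curves.probabilities(onsets.astype(float))
    u = rng.random(len(durs))
    ridx = (u[:, None] > np.cumsum(P, axis=1)).sum(axis=1)
    ridx = np.minimum(ridx, len(roles) - 1)

    qx0 = np.empty(len(durs))
    qy0 = np.empty(len(durs))
    for j, role in enumerate(roles):
        m = ridx == j
        if m.any():
            b = boxes[quad_of_role[role]]
            qx0[m] = b.x0 + rng.random(int(m.sum())) * (b.x1 - b.x0)
            qy0[m] = b.y0 + rng.random(int(m.sum())) * (b.y1 - b.y0)

    seg_x = np.zeros(n_seg)
    seg_y = np.zeros(n_seg)
    seg_valid = np.zeros(n_seg, dtype=bool)
    seg_x[0::2] = qx0
    seg_y[0::2] = qy0
    seg_valid[0::2] = True

    x = np.repeat(seg_x, seg)[:span]
    y = np.repeat(seg_y, seg)[:span]
    valid = np.repeat(seg_valid, seg)[:span]
    t = t0_ms + np.arange(span, dtype=np.int64)
    if sample_step_ms > 1:
        stride = int(round(sample_step_ms))
        t, x, y, valid = t[::stride], x[::stride], y[::stride], valid[::stride]
    return t, x, y, valid


def simulate_cohort(spec: CohortSpec, layout: RoiLayout | None = None) -> SimulatedCohort:
    """Generate a full cohort (samples + trial and participant metadata).

    Deterministic given ``spec.seed``: the same spec yields byte-identical
    output files.
    """
    if layout is None:
        layout = RoiLayout()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    step = 1000.0 / spec.sample_rate_hz
    if step < 1 or abs(step - round(step)) > 1e-9:
        raise ValidationError("sample_rate_hz must divide 1000 into whole milliseconds")
    t0 = -int(round(spec.preview_ms))
    t1 = int(np.ceil(spec.timeline.selection_cue_ms))
    gap = int(round(spec.saccade_gap_ms))

    part_rows = []
    trial_rows = []
    sample_chunks: dict[str, list] = {"participant_id": [], "trial_id": [], "t_ms": [], "x": [], "y": [], "valid": []}
    truth: dict[str, dict] = {}

    for gi, g in enumerate(spec.groups):
        curves_by_cond = condition_curves(g.latencies, g.slope_ms)
        if g.curves_override:
            curves_by_cond = {**curves_by_cond, **dict(g.curves_override)}
        truth[g.label] = {
            name: getattr(g.latencies, fld)
            for name, fld in CONTRAST_LATENCY_FIELDS.items()
            if _contrast_condition(name) in spec.items
        }
        intel = g.intelligibility.draw(rng, g.n_participants)
        effort = g.effort.draw(rng, g.n_participants)
        age = g.age.draw(rng, g.n_participants)
        hl = g.hearing_level.draw(rng, g.n_participants)
        for pi in range(g.n_participants):
            pid = f"{g.label}_{pi + 1:02d}"
            part_rows.append(
                {
                    "participant_id": pid,
                    "group": g.label,
                    "intelligibility_pct": round(float(intel[pi]), 2),
                    "effort_rating": round(float(effort[pi]), 2),
                    "age": round(float(age[pi]), 1),
                    "hearing_level": round(float(hl[pi]), 1),
                }
            )
            tcount = 0
            for (sub, cond), n_items in spec.items.items():
                roles = CONDITION_ROLES[(sub, cond)]
                curves = curves_by_cond[(sub, cond)]
                correct = "cu_target" if (sub, cond) == (SUB1, "CU") else "target"
                acc_p = g.accuracy_p.get((sub, cond), 0.97)
                for k in range(n_items):
                    tcount += 1
                    tid = f"t{tcount:03d}"
                    rot = (k + pi) % 4
                    roq = rotate_role_assignment(roles, rot)
                    correct_hit = rng.random() < acc_p
                    if correct_hit:
                        clicked = correct
                    else:
                        others = [r for r in roles if r != correct]
                        clicked = others[rng.integers(0, len(others))]
                    trial_rows.append(
                        {
                            "participant_id": pid,
                            "trial_id": tid,
                            "item_id": f"{sub}_{cond}_{k + 1:02d}",
                            "sub_experiment": sub,
                            "condition": cond,
                            "q1_role": roq["q1"],
                            "q2_role": roq["q2"],
                            "q3_role": roq["q3"],
                            "q4_role": roq["q4"],
                            "clicked_role": clicked,
                            "accuracy": int(clicked == correct),
                            "block": 1 + (k % 2),
                            "rotation_id": rot,
                        }
                    )
                    t, x, y, valid = _simulate_trial_arrays(
                        rng,
                        curves,
                        layout,
                        roq,
                        t0,
                        t1,
                        spec.fixation_mean_ms,
                        spec.fixation_shape,
                        gap,
                        step,
                    )
                    sample_chunks["participant_id"].append(np.full(len(t), pid, dtype=object))
                    sample_chunks["trial_id"].append(np.full(len(t), tid, dtype=object))
                    sample_chunks["t_ms"].append(t.astype(float))
                    sample_chunks["x"].append(np.round(x, 1))
                    sample_chunks["y"].append(np.round(y, 1))
                    sample_chunks["valid"].append(valid)

    samples = pd.DataFrame(
        {k: np.concatenate(v) for k, v in sample_chunks.items()}
    )
    samples["valid"] = samples["valid"].astype(bool)
    trials = pd.DataFrame(trial_rows)
    participants = pd.DataFrame(part_rows)
    ground_truth = {
        "seed": spec.seed,
        "true_latencies_ms": truth,
        "spec": {
            "groups": [
                {"label": g.label, "n_participants": g.n_participants, "slope_ms": g.slope_ms}
                for g in spec.groups
            ],
            "items": {f"{s}:{c}": n for (s, c), n in spec.items.items()},
            "sample_rate_hz": spec.sample_rate_hz,
            "fixation_mean_ms": spec.fixation_mean_ms,
            "fixation_shape": spec.fixation_shape,
            "saccade_gap_ms": spec.saccade_gap_ms,
            "preview_ms": spec.preview_ms,
        },
    }
    return SimulatedCohort(samples, trials, participants, ground_truth)


def _contrast_condition(contrast_name: str) -> tuple[str, str]:
    return {
        "sub1_prediction": (SUB1, "CP"),
        "sub1_cost": (SUB1, "CU"),
        "sub2_early": (SUB2, "CP"),
        "sub2_late": (SUB2, "CP"),
        "filler": (FILLER, "neutral"),
    }[contrast_name]


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    """Write samples.tsv, trials.csv, participants.csv and ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": outdir / "samples.tsv",
        "trials": outdir / "trials.csv",
        "participants": outdir / "participants.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    cohort.samples.to_csv(paths["samples"], sep="\t", index=False)
    cohort.trials.to_csv(paths["trials"], index=False)
    cohort.participants.to_csv(paths["participants"], index=False)
    paths["ground_truth"].write_text(json.dumps(cohort.ground_truth, indent=2, sort_keys=True))
    return paths
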