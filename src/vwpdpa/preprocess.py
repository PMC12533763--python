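"""Gaze-to-ROI mapping, fixation-proportion binning, and cohort filtering.

The pipeline here turns raw 1000 Hz gaze samples into the unit of all
downstream statistics: per participant × condition × image-role × 20 ms bin
fixation proportions.  Regions of interest are the four 300×300 px images,
each padded by 50 px on every side; a sample counts as a look to an image
when it falls inside that image's padded box.

Conventions
-----------
* A bin's proportion for a role is (valid samples in that role's ROI) /
  (valid samples in the bin).  Off-ROI looks stay in the denominator, so
  role proportions sum to at most 1.
* Invalid samples (blinks, track loss) are removed from numerator and
  denominator; a bin with no valid samples is missing, not zero.
* Participant timecourses are unweighted means over trial-level bin
  proportions; missing trial-bins are excluded from the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .timeline import BinGrid

logger = logging.getLogger("vwpdpa")

# ---------------------------------------------------------------------------
# Screen geometry and regions of interest
# ---------------------------------------------------------------------------

#: Quadrant order: top-left, top-right, bottom-left, bottom-right.
QUADRANTS = ("q1", "q2", "q3", "q4")


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle with closed edges on all sides."""

    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1


@dataclass(frozen=True)
class RoiLayout:
    """Four-image array geometry on the experiment screen.

    Images sit in the screen corners, inset by ``margin`` px.  ROIs are the
    image boxes expanded by ``pad`` px on every side and clamped to the
    screen.  The default 32 px margin keeps the clamped padded boxes
    pairwise disjoint (4 px gaps), so ROI membership is unambiguous even
    with closed edges.

    ``rotation_id`` records which counterbalanced role placement a layout
    instance was built for; the geometry itself is rotation-invariant
    (rotations permute role labels over quadrants, not boxes).
    """

    screen_w: int = 1024
    screen_h: int = 768
    image_w: int = 300
    image_h: int = 300
    pad: int = 50
    margin: int = 32
    rotation_id: int = 0

    def __post_init__(self) -> None:
        boxes = list(self.padded_boxes().values())
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                a, b = boxes[i], boxes[j]
                if a.x0 <= b.x1 and b.x0 <= a.x1 and a.y0 <= b.y1 and b.y0 <= a.y1:
                    raise ValidationError(
                        "padded ROI boxes overlap; increase screen size or "
                        "reduce margin/pad"
                    )

    def image_boxes(self) -> dict[str, Box]:
        xl, yt = float(self.margin), float(self.margin)
        xr = float(self.screen_w - self.margin - self.image_w)
        yb = float(self.screen_h - self.margin - self.image_h)
        w, h = self.image_w, self.image_h
        return {
            "q1": Box(xl, yt, xl + w, yt + h),
            "q2": Box(xr, yt, xr + w, yt + h),
            "q3": Box(xl, yb, xl + w, yb + h),
            "q4": Box(xr, yb, xr + w, yb + h),
        }

    def padded_boxes(self) -> dict[str, Box]:
        out = {}
        for q, b in self.image_boxes().items():
            out[q] = Box(
                max(0.0, b.x0 - self.pad),
                max(0.0, b.y0 - self.pad),
                min(float(self.screen_w), b.x1 + self.pad),
                min(float(self.screen_h), b.y1 + self.pad),
            )
        return out


def rotate_role_assignment(roles: Sequence[str], rotation_id: int) -> dict[str, str]:
    """Counterbalanced quadrant→role map: cyclic shift of the role list.

    With four rotations each role occurs in each quadrant once (25% of the
    time when items are balanced over rotations).
    """
    if len(roles) != 4 or len(set(roles)) != 4:
        raise ValidationError("exactly four distinct roles required")
    r = rotation_id % 4
    shifted = list(roles[r:]) + list(roles[:r])
    return dict(zip(QUADRANTS, shifted))


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GazeSample:
    participant_id: str
    trial_id: str
    t_ms: float
    x: float
    y: float
    valid: bool = True


@dataclass(frozen=True)
class TrialRecord:
    participant_id: str
    trial_id: str
    item_id: str
    sub_experiment: str  # "1", "2", or "filler"
    condition: str  # "CP", "CU", or "neutral"
    role_of_quadrant: Mapping[str, str]
    clicked_role: str
    accuracy: int | None = None
    block: int = 1

    def __post_init__(self) -> None:
        if set(self.role_of_quadrant) != set(QUADRANTS):
            raise ValidationError("role_of_quadrant must map exactly q1..q4")
        if len(set(self.role_of_quadrant.values())) != 4:
            raise ValidationError("quadrant roles must be distinct")


def correct_role(sub_experiment: str, condition: str) -> str:
    """Role of the image that correctly answers a trial.

    CP and neutral sentences end in the ``target`` image's word; CU
    sentences end in the unexpected-but-plausible ``cu_target``.
    """
    if str(sub_experiment) == "1" and condition == "CU":
        return "cu_target"
    return "target"


# ---------------------------------------------------------------------------
# ROI assignment
# ---------------------------------------------------------------------------


def assign_quadrant(x, y, layout: RoiLayout):
    """Quadrant index (0..3) of the padded box containing each point, −1 if
    none.  Boxes are disjoint, so membership is unique."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.full(x.shape, -1, dtype=np.int64)
    for i, q in enumerate(QUADRANTS):
        b = layout.padded_boxes()[q]
        hit = (x >= b.x0) & (x <= b.x1) & (y >= b.y0) & (y <= b.y1)
        out[hit] = i
    return out


def assign_roi(sample: GazeSample, layout: RoiLayout, trial: TrialRecord) -> str | None:
    """Image role whose padded ROI contains the sample, else ``None``.

    Invalid samples map to ``None`` (they are counted separately as
    missing, never as off-ROI looks).
    """
    if not sample.valid:
        return None
    q = int(assign_quadrant(np.array(sample.x), np.array(sample.y), layout))
    if q < 0:
        return None
    return trial.role_of_quadrant[QUADRANTS[q]]


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def bin_trial(
    samples: pd.DataFrame,
    layout: RoiLayout,
    trial: TrialRecord,
    grid: BinGrid,
) -> pd.DataFrame:
    """Per-bin per-role fixation proportions for one trial.

    Parameters
    ----------
    samples
        Frame with columns ``t_ms, x, y`` and optional ``valid``, sorted by
        time, covering (part of) the analysis window.

    Returns
    -------
    DataFrame indexed by ``bin_start_ms`` with one column per role plus
    ``n_valid``; bins without valid samples have NaN proportions.
    """
    t = samples["t_ms"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValidationError("samples within a trial must be strictly increasing in t_ms")
    valid = (
        samples["valid"].to_numpy(dtype=bool)
        if "valid" in samples.columns
        else np.ones(len(samples), dtype=bool)
    )
    bidx = grid.bin_index(t) if len(t) else np.array([], dtype=int)
    keep = valid & (bidx >= 0)
    if not keep.any():
        logger.warning(
            "trial %s/%s: no valid samples in analysis window",
            trial.participant_id,
            trial.trial_id,
        )
    q = assign_quadrant(samples["x"].to_numpy(float), samples["y"].to_numpy(float), layout)
    roles = [trial.role_of_quadrant[qq] for qq in QUADRANTS]
    nb = grid.n_bins
    tot = np.bincount(bidx[keep], minlength=nb).astype(float)
    out = pd.DataFrame(index=pd.Index(grid.bin_starts_ms, name="bin_start_ms"))
    for i, role in enumerate(roles):
        hits = np.bincount(bidx[keep & (q == i)], minlength=nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[role] = np.where(tot > 0, hits / np.where(tot > 0, tot, 1), np.nan)
    out["n_valid"] = tot.astype(int)
    return out


def aggregate_participant(
    trial_bins: Sequence[tuple[TrialRecord, pd.DataFrame]],
    keep_only_correct: bool = True,
) -> pd.DataFrame:
    """Unweighted mean of trial-level bin proportions for one participant.

    Trials with ``accuracy == 0`` are dropped when ``keep_only_correct``.
    Missing trial-bins are excluded bin-wise; ``n_trials`` records how many
    trials contributed to each bin.

    Raises
    ------
    ValidationError
        If no trial survives filtering (the participant must be excluded
        from the contrast; callers log this).
    """
    kept = [
        frame
        for trial, frame in trial_bins
        if not keep_only_correct or trial.accuracy == 1
    ]
    if not kept:
        raise ValidationError("no contributing trials after accuracy filtering")
    roles = [c for c in kept[0].columns if c != "n_valid"]
    stack = np.stack([f[roles].to_numpy(float) for f in kept])  # trial × bin × role
    have = ~np.isnan(stack[:, :, 0])
    n_trials = have.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    out = pd.DataFrame(mean, index=kept[0].index, columns=roles)
    out["n_trials"] = n_trials
    return out


def compute_bin_series(
    samples: pd.DataFrame,
    trials: pd.DataFrame,
    layout: RoiLayout,
    grid: BinGrid,
    keep_only_correct: bool = True,
) -> pd.DataFrame:
    """Participant-level fixation-proportion timecourses for a whole cohort.

    Vectorized equivalent of ``bin_trial`` + ``aggregate_participant`` over
    every trial in ``trials``.  Accuracy is recomputed from
    ``clicked_role`` against the condition's correct role; an input
    ``accuracy`` column, if present, is cross-checked and mismatches are
    logged (the recomputed value wins).

    Returns
    -------
    Long DataFrame with columns ``participant_id, sub_experiment,
    condition, role, bin_index, bin_start_ms, proportion, n_trials``.
    """
    trials = trials.reset_index(drop=True).copy()
    role_cols = ["q1_role", "q2_role", "q3_role", "q4_role"]
    for c in role_cols + ["participant_id", "trial_id", "sub_experiment", "condition", "clicked_role"]:
        if c not in trials.columns:
            raise ValidationError(f"trial metadata missing column {c!r}")
    trials["sub_experiment"] = trials["sub_experiment"].astype(str)

    recomputed = np.array(
        [
            int(row.clicked_role == correct_role(row.sub_experiment, row.condition))
            for row in trials.itertuples()
        ]
    )
    if "accuracy" in trials.columns and trials["accuracy"].notna().all():
        mism = int((trials["accuracy"].astype(int) != recomputed).sum())
        if mism:
            logger.warning("accuracy column disagrees with clicked_role on %d trials", mism)
    trials["accuracy"] = recomputed
    use = trials[trials["accuracy"] == 1] if keep_only_correct else trials
    use = use.copy()
    use["_trow"] = np.arange(len(use))

    df = samples.merge(
        use[["participant_id", "trial_id", "_trow"]],
        on=["participant_id", "trial_id"],
        how="inner",
    )
    trow = df["_trow"].to_numpy()
    valid = (
        df["valid"].to_numpy(bool) if "valid" in df.columns else np.ones(len(df), bool)
    )
    bidx = grid.bin_index(df["t_ms"].to_numpy(float))
    q = assign_quadrant(df["x"].to_numpy(float), df["y"].to_numpy(float), layout)

    roles_mat = use[role_cols].to_numpy(dtype=object)
    all_roles = pd.unique(roles_mat.ravel())
    all_roles = sorted(r for r in all_roles if isinstance(r, str))
    rcode_lut = {r: i for i, r in enumerate(all_roles)}
    trial_role_codes = np.vectorize(rcode_lut.__getitem__, otypes=[np.int64])(roles_mat)

    keep = valid & (bidx >= 0)
    nb, R, T = grid.n_bins, len(all_roles), len(use)
    key = trow[keep] * nb + bidx[keep]
    tot = np.bincount(key, minlength=T * nb).astype(float).reshape(T, nb)
    on_roi = keep & (q >= 0)
    rc = trial_role_codes[trow[on_roi], q[on_roi]]
    key2 = (trow[on_roi] * nb + bidx[on_roi]) * R + rc
    hits = np.bincount(key2, minlength=T * nb * R).reshape(T, nb, R).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = hits / tot[:, :, None]  # NaN where no valid samples

    # aggregate trials to participant × sub-experiment × condition
    gkeys = use[["participant_id", "sub_experiment", "condition"]].apply(tuple, axis=1)
    gcodes, guniq = pd.factorize(gkeys)
    G = len(guniq)
    S = np.zeros((G, nb, R))
    np.add.at(S, gcodes, np.nan_to_num(P))
    have = (tot > 0).astype(float)
    C = np.zeros((G, nb))
    np.add.at(C, gcodes, have)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = S / C[:, :, None]
    M[C == 0] = np.nan

    # role vocabulary per condition (union over that condition's trials)
    cond_roles: dict[tuple, set] = {}
    for g, (pid, sub, cond) in enumerate(guniq):
        cond_roles.setdefault((sub, cond), set())
    for i in range(len(use)):
        sub, cond = use["sub_experiment"].iat[i], use["condition"].iat[i]
        cond_roles[(sub, cond)].update(roles_mat[i])

    frames = []
    bin_starts = grid.bin_starts_ms
    for g, (pid, sub, cond) in enumerate(guniq):
        roles_here = sorted(cond_roles[(sub, cond)])
        codes = [rcode_lut[r] for r in roles_here]
        k = len(roles_here)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "sub_experiment": sub,
                    "condition": cond,
                    "role": np.repeat(roles_here, nb),
                    "bin_index": np.tile(np.arange(nb), k),
                    "bin_start_ms": np.tile(bin_starts, k),
                    "proportion": M[g][:, codes].T.ravel(),
                    "n_trials": np.tile(C[g].astype(int), k),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Participant filtering and regrouping
# ---------------------------------------------------------------------------

_OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}


@dataclass(frozen=True)
class FilterRule:
    """One metadata predicate, e.g. ``intelligibility_pct >= 50``."""

    field: str
    op: str
    value: object
    name: str = ""

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ConfigError(f"unknown operator {self.op!r}")

    def label(self) -> str:
        return self.name or f"{self.field} {self.op} {self.value}"

    def evaluate(self, meta: pd.DataFrame) -> np.ndarray:
        if self.field not in meta.columns:
            raise ConfigError(f"unknown metadata field {self.field!r}")
        return np.asarray(_OPS[self.op](meta[self.field].to_numpy(), self.value), bool)


def filter_participants(
    meta: pd.DataFrame,
    rules: Iterable[FilterRule],
) -> tuple[list, dict]:
    """Apply inclusion rules sequentially; return kept ids and a log of
    how many participants each criterion excluded."""
    mask = np.ones(len(meta), dtype=bool)
    log: dict[str, int] = {}
    for rule in rules:
        ok = rule.evaluate(meta)
        log[rule.label()] = int((mask & ~ok).sum())
        mask &= ok
    return list(meta.loc[mask, "participant_id"]), log


def regroup_by_metadata(
    meta: pd.DataFrame,
    grouping: Sequence[tuple[str, Sequence[FilterRule]]],
) -> tuple[dict, list]:
    """Map each participant to exactly one new group label.

    ``grouping`` is a list of (label, rules) pairs; a participant belongs
    to a group when it satisfies all of that group's rules.  Overlapping
    groups are a configuration error; participants matching no group are
    dropped (returned in the second element, and logged).
    """
    matches = np.zeros((len(meta), len(grouping)), dtype=bool)
    for j, (_, rules) in enumerate(grouping):
        m = np.ones(len(meta), dtype=bool)
        for rule in rules:
            m &= rule.evaluate(meta)
        matches[:, j] = m
    n_match = matches.sum(axis=1)
    if (n_match > 1).any():
        pid = meta["participant_id"].iloc[int(np.argmax(n_match > 1))]
        raise ConfigError(f"grouping rules overlap (participant {pid} matches >1 group)")
    mapping = {}
    dropped = []
    labels = [lab for lab, _ in grouping]
    for i, pid in enumerate(meta["participant_id"]):
        if n_match[i] == 1:
            mapping[pid] = labels[int(np.argmax(matches[i]))]
        else:
            dropped.append(pid)
    if dropped:
        logger.warning("regrouping dropped %d participants matching no rule", len(dropped))
    return mapping, dropped


def accuracy_summary(trials: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy and trial counts by group × sub-experiment × condition."""
    df = trials.merge(
        participants[["participant_id", "group"]], on="participant_id", how="left"
    )
    df["sub_experiment"] = df["sub_experiment"].astype(str)
    g = df.groupby(["group", "sub_experiment", "condition"], observed=True)["accuracy"]
    out = g.agg(mean_accuracy="mean", n_trials="count").reset_index()
    return out


# ---------------------------------------------------------------------------
# File IO (tab-delimited reports, CSV metadata)
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ["participant_id", "trial_id", "t_ms", "x", "y", "valid"]


def read_sample_report(path) -> pd.DataFrame:
    """Tab-delimited eye-tracker sample report; extra columns are ignored
    and a missing ``valid`` column defaults to all-valid."""
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str, "trial_id": str})
    required = ["participant_id", "trial_id", "t_ms", "x", "y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"sample report missing columns {missing}")
    if "valid" not in df.columns:
        df["valid"] = True
    df["valid"] = df["valid"].astype(bool)
    return df[SAMPLE_COLUMNS]


def expand_fixations(fixations: pd.DataFrame, sample_rate_hz: float = 1000.0) -> pd.DataFrame:
    """Expand fixation events (start, end, x, y) to the sample grid so both
    input flavors share one internal representation."""
    required = ["participant_id", "trial_id", "fix_start_ms", "fix_end_ms", "x", "y"]
    missing = [c for c in required if c not in fixations.columns]
    if missing:
        raise ValidationError(f"fixation report missing columns {missing}")
    step = 1000.0 / sample_rate_hz
    rows = []
    for r in fixations.itertuples():
        t = np.arange(np.ceil(r.fix_start_ms / step) * step, r.fix_end_ms, step)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": r.participant_id,
                    "trial_id": r.trial_id,
                    "t_ms": t,
                    "x": r.x,
                    "y": r.y,
                    "valid": True,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["participant_id", "trial_id", "t_ms"], kind="stable").reset_index(
        drop=True
    )


def read_fixation_report(path, sample_rate_hz: float = 1000.0) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str, "trial_id": str})
    return expand_fixations(df, sample_rate_hz=sample_rate_hz)


def read_trial_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "trial_id": str, "sub_experiment": str})
    return df


def read_participant_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in df.columns or "group" not in df.columns:
        raise ValidationError("participant metadata needs participant_id and group columns")
    return df
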