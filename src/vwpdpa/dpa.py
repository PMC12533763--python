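"""Divergence point analysis (DPA) by bootstrap over participants.

A divergence point (DP) is the onset of a sustained difference between two
image roles' fixation-proportion timecourses: the start of the first run of
``consec_bins`` (default 10) consecutive 20 ms bins in which a paired t
test on participant-level differences (role_a − role_b) is significant.
Its sampling distribution is estimated nonparametrically: participants are
resampled with replacement within group, the bin-wise tests and the
consecutive-bin scan are recomputed on each resample, and the convergent
onsets form the bootstrap distribution (mean + percentile CI).  Group
latency contrasts are differences of index-paired resamples, classified by
where the 95% CI falls relative to zero.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, ValidationError
from .timeline import BinGrid

# ---------------------------------------------------------------------------
# Contrast declarations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastSpec:
    """One timecourse comparison: which trials, which two roles, what test.

    ``tail`` is ``"greater"`` (role_a > role_b, the default — every
    standard contrast is directional) or ``"two-sided"``.

    ``window_start_ms``/``window_end_ms`` restrict the onset search to the
    span where the contrast is theoretically possible (e.g. from the verb
    onset for a verb-driven prediction contrast).  Cropping the timecourse
    to the window of interest is standard DPA practice: with fixation
    autocorrelation, a long pre-divergence baseline would otherwise
    contribute occasional chance runs of significant bins to the bootstrap
    distribution.  ``None`` means the full analysis grid.
    """

    name: str
    sub_experiment: str
    condition: str
    role_a: str
    role_b: str
    tail: str = "greater"
    alpha: float = 0.05
    consec_bins: int = 10
    window_start_ms: float | None = None
    window_end_ms: float | None = None

    def __post_init__(self) -> None:
        if self.role_a == self.role_b:
            raise ValidationError("contrast roles must differ")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.consec_bins < 1:
            raise ValidationError("consec_bins must be >= 1")
        if self.tail not in ("greater", "two-sided"):
            raise ValidationError(f"unknown tail {self.tail!r}")


def default_contrasts(timeline=None) -> tuple[ContrastSpec, ...]:
    """The design's five standard contrasts.

    Onset search windows open at the first word that could in principle
    drive each contrast, rounded to the bin grid: the verb for the
    prediction contrasts, the object word for the integration (cost) and
    filler contrasts.
    """
    from .timeline import BinGrid as _BG, default_timeline, round_to_bin

    if timeline is None:
        timeline = default_timeline()
    g = _BG()
    verb = round_to_bin(timeline.onset("verb"), g)
    obj = round_to_bin(timeline.onset("object"), g)
    return (
        ContrastSpec("sub1_prediction", "1", "CP", "target", "cu_target", window_start_ms=verb),
        ContrastSpec("sub1_cost", "1", "CU", "cu_target", "distractor1", window_start_ms=obj),
        ContrastSpec("sub2_early", "2", "CP", "target", "verb_distractor", window_start_ms=verb),
        ContrastSpec("sub2_late", "2", "CP", "target", "agent_competitor", window_start_ms=verb),
        ContrastSpec("filler", "filler", "neutral", "target", "distractor1", window_start_ms=obj),
    )


#: The study's five standard contrasts under the normalized sentence frame.
DEFAULT_CONTRASTS: tuple[ContrastSpec, ...] = default_contrasts()


def _window_slice(contrast: ContrastSpec, grid: BinGrid) -> tuple[int, int]:
    """Bin-index range [i0, i1) of the contrast's onset-search window."""
    i0, i1 = 0, grid.n_bins
    if contrast.window_start_ms is not None:
        i0 = max(
            0,
            int(np.ceil((contrast.window_start_ms - grid.window_start_ms) / grid.bin_ms - 1e-9)),
        )
    if contrast.window_end_ms is not None:
        i1 = min(
            grid.n_bins,
            int(np.floor((contrast.window_end_ms - grid.window_start_ms) / grid.bin_ms + 1e-9)),
        )
    if i1 - i0 < contrast.consec_bins:
        raise ValidationError(
            f"contrast {contrast.name!r}: search window shorter than consec_bins"
        )
    return i0, i1


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class DivergenceEstimate:
    """Bootstrap DP distribution for one group under one contrast.

    ``boot_dps_ms`` has length ``n_boot`` with NaN marking nonconvergent
    resamples (no qualifying run of significant bins); summary statistics
    are computed over the convergent resamples only.
    """

    group: str
    contrast: ContrastSpec
    observed_dp_ms: float | None
    boot_dps_ms: np.ndarray
    boot_mean_ms: float
    ci_low_ms: float
    ci_high_ms: float
    n_boot: int
    n_convergent: int
    seed: int

    @property
    def prop_nonconvergent(self) -> float:
        return 1.0 - self.n_convergent / self.n_boot

    def to_dict(self, include_distribution: bool = False) -> dict:
        d = {
            "group": self.group,
            "contrast": self.contrast.name,
            "observed_dp_ms": self.observed_dp_ms,
            "boot_mean_ms": self.boot_mean_ms,
            "ci_low_ms": self.ci_low_ms,
            "ci_high_ms": self.ci_high_ms,
            "n_boot": self.n_boot,
            "n_convergent": self.n_convergent,
            "seed": self.seed,
        }
        if include_distribution:
            d["boot_dps_ms"] = [None if np.isnan(v) else float(v) for v in self.boot_dps_ms]
        return d


@dataclass
class GroupDifference:
    """Paired-resample latency difference (comparison minus reference)."""

    group_ref: str
    group_cmp: str
    contrast: ContrastSpec
    mean_diff_ms: float
    ci_low_ms: float
    ci_high_ms: float
    classification: str
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "group_ref": self.group_ref,
            "group_cmp": self.group_cmp,
            "contrast": self.contrast.name,
            "mean_diff_ms": self.mean_diff_ms,
            "ci_low_ms": self.ci_low_ms,
            "ci_high_ms": self.ci_high_ms,
            "classification": self.classification,
            "n_pairs": self.n_pairs,
        }


# ---------------------------------------------------------------------------
# Participant difference matrix
# ---------------------------------------------------------------------------


def difference_matrix(
    bin_series: pd.DataFrame, contrast: ContrastSpec
) -> tuple[list, np.ndarray]:
    """Participant × bin matrix of role_a − role_b fixation proportions.

    Rows are participants (ids returned alongside); NaN where either
    role's proportion is missing in a bin.
    """
    sel = bin_series[
        (bin_series["sub_experiment"].astype(str) == str(contrast.sub_experiment))
        & (bin_series["condition"] == contrast.condition)
    ]
    if sel.empty:
        raise EstimationError(
            f"no data for sub-experiment {contrast.sub_experiment} "
            f"condition {contrast.condition}"
        )
    roles = set(sel["role"])
    for r in (contrast.role_a, contrast.role_b):
        if r not in roles:
            raise ValidationError(f"role {r!r} not present in bin series for {contrast.name}")
    wide_a = sel[sel["role"] == contrast.role_a].pivot(
        index="participant_id", columns="bin_index", values="proportion"
    )
    wide_b = sel[sel["role"] == contrast.role_b].pivot(
        index="participant_id", columns="bin_index", values="proportion"
    )
    wide_b = wide_b.reindex(index=wide_a.index, columns=wide_a.columns)
    D = wide_a.to_numpy(float) - wide_b.to_numpy(float)
    return list(wide_a.index), D


# ---------------------------------------------------------------------------
# Bin-wise t tests
# ---------------------------------------------------------------------------


def _t_and_p(V: np.ndarray, tail: str) -> tuple[np.ndarray, np.ndarray]:
    """t statistic and p value of a one-sample test against 0 along the
    second-to-last axis (participants), NaN-excluding.

    Degenerate bins follow the limiting behavior of the t statistic:
    fewer than two valid participants → p = 1; zero variance with a
    positive mean → p = 0 for the one-sided test (nonpositive mean →
    p = 1); for the two-sided test any constant nonzero mean → p = 0.
    """
    import warnings

    n = np.sum(~np.isnan(V), axis=-2)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(np.where(np.isnan(V), np.nan, V), axis=-2)
        s = np.nanstd(V, axis=-2, ddof=1)
    m = np.where(n == 0, np.nan, m)
    ok = n >= 2
    # constant columns accumulate ~1e-17 rounding noise in nanstd
    zero_var = ok & (s <= 1e-12)
    regular = ok & (s > 1e-12)
    t = np.full(m.shape, np.nan)
    p = np.ones(m.shape)
    n_safe = np.where(regular, n, 2)
    s_safe = np.where(regular, s, 1.0)
    t_reg = m / (s_safe / np.sqrt(n_safe))
    t = np.where(regular, t_reg, t)
    if tail == "greater":
        p_reg = stats.t.sf(t_reg, df=n_safe - 1)
        p = np.where(regular, p_reg, p)
        p = np.where(zero_var & (m > 0), 0.0, p)
    else:
        p_reg = 2.0 * stats.t.sf(np.abs(t_reg), df=n_safe - 1)
        p = np.where(regular, p_reg, p)
        p = np.where(zero_var & (m != 0), 0.0, p)
    t = np.where(zero_var & (m > 0), np.inf, t)
    t = np.where(zero_var & (m < 0), -np.inf, t)
    t = np.where(zero_var & (m == 0), 0.0, t)
    return t, p


def bin_tests(D, contrast: ContrastSpec, grid: BinGrid | None = None) -> pd.DataFrame:
    """Per-bin paired t tests on participant-level role differences.

    ``D`` is a participant × bin difference matrix (or a long bin-series
    frame, from which the matrix is built).  Returns a frame with columns
    ``bin_index, t, p, significant``; plus ``bin_start_ms`` when a grid is
    supplied.
    """
    if isinstance(D, pd.DataFrame) and "role" in D.columns:
        _, D = difference_matrix(D, contrast)
    D = np.asarray(D, dtype=float)
    if D.shape[0] == 0:
        raise EstimationError("empty group: no participants in difference matrix")
    if grid is not None:
        i0, i1 = _window_slice(contrast, grid)
    else:
        i0, i1 = 0, D.shape[1]
    D = D[:, i0:i1]
    t, p = _t_and_p(D, contrast.tail)
    sig = p < contrast.alpha
    out = pd.DataFrame(
        {"bin_index": np.arange(i0, i1), "t": t, "p": p, "significant": sig}
    )
    if grid is not None:
        out.insert(1, "bin_start_ms", grid.bin_starts_ms[i0:i1])
    return out


# ---------------------------------------------------------------------------
# Onset detection
# ---------------------------------------------------------------------------


def _onset_indices(flags: np.ndarray, consec: int) -> np.ndarray:
    """First index starting a run of >= consec consecutive True, per row;
    −1 when no such run exists.  ``flags`` is (n_rows, n_bins) bool."""
    F = np.atleast_2d(np.asarray(flags, dtype=bool))
    R, B = F.shape
    if consec > B:
        return np.full(R, -1, dtype=np.int64)
    c = np.zeros((R, B + 1), dtype=np.int64)
    np.cumsum(F, axis=1, out=c[:, 1:])
    wins = c[:, consec:] - c[:, :-consec]  # windowed sums, width consec
    full = wins == consec
    has = full.any(axis=1)
    first = np.argmax(full, axis=1)
    return np.where(has, first, -1)


def detect_onset(flags, contrast: ContrastSpec, grid: BinGrid) -> float | None:
    """Start time (ms) of the first run of ``consec_bins`` consecutive
    significant bins, or ``None`` if no qualifying run exists."""
    flags = np.asarray(flags, dtype=bool)
    if flags.ndim != 1:
        raise ValidationError("detect_onset expects a 1-D significance vector")
    idx = int(_onset_indices(flags, contrast.consec_bins)[0])
    if idx < 0:
        return None
    return float(grid.window_start_ms + idx * grid.bin_ms)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def _rng_for(seed: int, group: str, contrast: ContrastSpec) -> np.random.Generator:
    """Deterministic substream per (seed, group, contrast): adding a group
    or contrast never perturbs another's resamples."""
    key = (
        zlib.crc32(group.encode()) & 0x7FFFFFFF,
        zlib.crc32(contrast.name.encode()) & 0x7FFFFFFF,
    )
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _percentile_ci(values: np.ndarray, ci: tuple[float, float]) -> tuple[float, float]:
    # closest-observation quantiles keep CI endpoints on the bin grid
    lo, hi = np.quantile(values, [ci[0] / 100.0, ci[1] / 100.0], method="closest_observation")
    return float(lo), float(hi)


def bootstrap_dp(
    bin_series_or_D,
    contrast: ContrastSpec,
    grid: BinGrid,
    group: str = "group",
    n_boot: int = 2000,
    seed: int = 0,
    ci: tuple[float, float] = (2.5, 97.5),
    max_nonconvergent_warn: float = 0.2,
    chunk: int = 500,
) -> DivergenceEstimate:
    """Bootstrap the divergence point for one group under one contrast.

    Participants are drawn with replacement within the group (a
    participant drawn twice counts twice); the bin-wise t tests and the
    consecutive-bin scan are recomputed on every resample.  Nonconvergent
    resamples are excluded from the mean and CI and counted.

    Raises
    ------
    EstimationError
        If the group is empty, has fewer than two participants, or no
        resample converges.
    """
    if isinstance(bin_series_or_D, pd.DataFrame) and "role" in bin_series_or_D.columns:
        _, D = difference_matrix(bin_series_or_D, contrast)
    else:
        D = np.asarray(bin_series_or_D, dtype=float)
    n = D.shape[0]
    if n == 0:
        raise EstimationError(f"empty group {group!r}")
    if n < 2:
        raise EstimationError(f"group {group!r} needs >= 2 participants")
    i0, _i1 = _window_slice(contrast, grid)
    D = D[:, i0:_i1]
    t_origin = grid.window_start_ms + i0 * grid.bin_ms

    _, p_obs = _t_and_p(D, contrast.tail)
    obs_idx = int(_onset_indices(p_obs < contrast.alpha, contrast.consec_bins)[0])
    observed = None if obs_idx < 0 else float(t_origin + obs_idx * grid.bin_ms)

    rng = _rng_for(seed, group, contrast)
    dps = np.full(n_boot, np.nan)
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        idx = rng.integers(0, n, size=(stop - start, n))
        V = D[idx]  # resample × participant × bin
        _, p = _t_and_p(V, contrast.tail)
        oi = _onset_indices(p < contrast.alpha, contrast.consec_bins)
        conv = oi >= 0
        dps[start:stop][conv] = t_origin + oi[conv] * grid.bin_ms

    convergent = dps[~np.isnan(dps)]
    n_conv = convergent.size
    if n_conv == 0:
        raise EstimationError(
            f"no convergent bootstrap resamples for group {group!r}, "
            f"contrast {contrast.name!r}"
        )
    if n_conv < (1.0 - max_nonconvergent_warn) * n_boot:
        import logging

        logging.getLogger("vwpdpa").warning(
            "group %s contrast %s: %.1f%% of resamples nonconvergent",
            group,
            contrast.name,
            100.0 * (1 - n_conv / n_boot),
        )
    lo, hi = _percentile_ci(convergent, ci)
    return DivergenceEstimate(
        group=group,
        contrast=contrast,
        observed_dp_ms=observed,
        boot_dps_ms=dps,
        boot_mean_ms=float(convergent.mean()),
        ci_low_ms=lo,
        ci_high_ms=hi,
        n_boot=n_boot,
        n_convergent=n_conv,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def classify_difference(ci_low: float, ci_high: float, atol: float = 1e-9) -> str:
    """Label a difference CI the way the latency contrasts are reported:
    ``not_different`` when the CI strictly straddles 0, ``marginal`` when a
    bound sits exactly at 0, ``different`` when 0 lies outside the CI."""
    if ci_low > ci_high:
        raise ValidationError("ci_low must not exceed ci_high")
    if abs(ci_low) <= atol or abs(ci_high) <= atol:
        return "marginal"
    if ci_low < 0 < ci_high:
        return "not_different"
    return "different"


def compare_groups(
    est_ref: DivergenceEstimate,
    est_cmp: DivergenceEstimate,
    ci: tuple[float, float] = (2.5, 97.5),
) -> GroupDifference:
    """Latency difference distribution: comparison minus reference, paired
    by resample index over pairs where both groups converged."""
    if est_ref.contrast != est_cmp.contrast:
        raise ValidationError("cannot compare estimates built under different contrasts")
    if est_ref.n_boot != est_cmp.n_boot:
        raise ValidationError("cannot compare estimates with different n_boot")
    both = ~np.isnan(est_ref.boot_dps_ms) & ~np.isnan(est_cmp.boot_dps_ms)
    if not both.any():
        raise EstimationError("no resample pair with both groups convergent")
    diffs = est_cmp.boot_dps_ms[both] - est_ref.boot_dps_ms[both]
    lo, hi = _percentile_ci(diffs, ci)
    return GroupDifference(
        group_ref=est_ref.group,
        group_cmp=est_cmp.group,
        contrast=est_ref.contrast,
        mean_diff_ms=float(diffs.mean()),
        ci_low_ms=lo,
        ci_high_ms=hi,
        classification=classify_difference(lo, hi),
        n_pairs=int(both.sum()),
    )


# ---------------------------------------------------------------------------
# Whole-analysis driver
# ---------------------------------------------------------------------------


def run_dpa(
    bin_series: pd.DataFrame,
    group_of: dict,
    contrasts: Sequence[ContrastSpec],
    grid: BinGrid,
    reference_group: str,
    n_boot: int = 2000,
    seed: int = 0,
    ci: tuple[float, float] = (2.5, 97.5),
) -> tuple[list[DivergenceEstimate], list[GroupDifference]]:
    """Bootstrap every group under every contrast and contrast each
    non-reference group against the reference group."""
    groups = sorted(set(group_of.values()), key=lambda g: (g != reference_group, g))
    if reference_group not in groups:
        raise ValidationError(f"reference group {reference_group!r} has no participants")
    estimates: list[DivergenceEstimate] = []
    differences: list[GroupDifference] = []
    for contrast in contrasts:
        ids, D = difference_matrix(bin_series, contrast)
        per_group: dict[str, DivergenceEstimate] = {}
        for g in groups:
            rows = [i for i, pid in enumerate(ids) if group_of.get(pid) == g]
            if not rows:
                continue
            est = bootstrap_dp(
                D[rows], contrast, grid, group=g, n_boot=n_boot, seed=seed, ci=ci
            )
            per_group[g] = est
            estimates.append(est)
        ref = per_group.get(reference_group)
        if ref is None:
            continue
        for g, est in per_group.items():
            if g != reference_group:
                differences.append(compare_groups(ref, est, ci=ci))
    return estimates, differences
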