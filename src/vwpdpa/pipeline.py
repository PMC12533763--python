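"""Configured end-to-end runs: load → filter → bin → DPA → report.

A run is described by a YAML config (paths, timeline, bin grid, filters,
contrasts, bootstrap settings, seed) and produces CSV result tables, a JSON
filter/stage log, and one timecourse figure per contrast.  Stages fail with
a stage-named error so the CLI can report where a run broke.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from .dpa import (
    ContrastSpec,
    DivergenceEstimate,
    GroupDifference,
    default_contrasts,
    run_dpa,
)
from .errors import ConfigError, ValidationError
from .preprocess import (
    FilterRule,
    RoiLayout,
    accuracy_summary,
    compute_bin_series,
    filter_participants,
    read_fixation_report,
    read_participant_metadata,
    read_sample_report,
    read_trial_metadata,
    regroup_by_metadata,
)
from .timeline import BinGrid, build_timeline, default_timeline

logger = logging.getLogger("vwpdpa")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


def _parse_rules(raw: Sequence[dict]) -> list[FilterRule]:
    rules = []
    for r in raw:
        rules.append(
            FilterRule(
                field=r["field"], op=r["op"], value=r["value"], name=r.get("name", "")
            )
        )
    return rules


@dataclass
class RunConfig:
    """Everything needed to reproduce a run bit-for-bit given the inputs."""

    samples_path: str | None = None
    fixations_path: str | None = None
    trials_path: str = ""
    participants_path: str = ""
    output_dir: str = "results"
    timeline_durations: dict | None = None
    post_delay_ms: float = 2000.0
    bin_ms: int = 20
    window_start_ms: float = 0.0
    window_end_ms: float | None = None
    sample_rate_hz: float = 1000.0
    keep_only_correct: bool = True
    filters: list[FilterRule] = field(default_factory=list)
    regroup: list[tuple[str, list[FilterRule]]] | None = None
    reference_group: str = "PwNH"
    contrasts: list[ContrastSpec] | None = None
    n_boot: int = 2000
    alpha: float = 0.05
    tail: str = "greater"
    consec_bins: int = 10
    ci: tuple[float, float] = (2.5, 97.5)
    include_distributions: bool = False
    seed: int = 0
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, **overrides)

    @classmethod
    def from_dict(cls, raw: dict, **overrides) -> "RunConfig":
        known = {
            "paths",
            "timeline",
            "bin",
            "filters",
            "regroup",
            "reference_group",
            "contrasts",
            "dpa",
            "seed",
            "output_dir",
            "keep_only_correct",
            "sample_rate_hz",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        paths = raw.get("paths", {})
        tl = raw.get("timeline", {})
        binning = raw.get("bin", {})
        dpa = raw.get("dpa", {})
        cfg = cls(
            samples_path=paths.get("samples"),
            fixations_path=paths.get("fixations"),
            trials_path=paths.get("trials", ""),
            participants_path=paths.get("participants", ""),
            output_dir=raw.get("output_dir", "results"),
            timeline_durations=tl.get("durations"),
            post_delay_ms=tl.get("post_delay_ms", 2000.0),
            bin_ms=binning.get("bin_ms", 20),
            window_start_ms=binning.get("window_start_ms", 0.0),
            window_end_ms=binning.get("window_end_ms"),
            sample_rate_hz=raw.get("sample_rate_hz", 1000.0),
            keep_only_correct=raw.get("keep_only_correct", True),
            filters=_parse_rules(raw.get("filters", [])),
            regroup=(
                [(g["label"], _parse_rules(g["rules"])) for g in raw["regroup"]]
                if raw.get("regroup")
                else None
            ),
            reference_group=raw.get("reference_group", "PwNH"),
            n_boot=dpa.get("n_boot", 2000),
            alpha=dpa.get("alpha", 0.05),
            tail=dpa.get("tail", "greater"),
            consec_bins=dpa.get("consec_bins", 10),
            ci=tuple(dpa.get("ci", (2.5, 97.5))),
            include_distributions=dpa.get("include_distributions", False),
            seed=raw.get("seed", 0),
            raw=raw,
        )
        if raw.get("contrasts"):
            cfg.contrasts = [
                ContrastSpec(
                    name=c["name"],
                    sub_experiment=str(c["sub_experiment"]),
                    condition=c["condition"],
                    role_a=c["role_a"],
                    role_b=c["role_b"],
                    tail=c.get("tail", cfg.tail),
                    alpha=c.get("alpha", cfg.alpha),
                    consec_bins=c.get("consec_bins", cfg.consec_bins),
                    window_start_ms=c.get("window_start_ms"),
                    window_end_ms=c.get("window_end_ms"),
                )
                for c in raw["contrasts"]
            ]
        for k, v in overrides.items():
            if v is not None:
                setattr(cfg, k, v)
        return cfg


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------


def plot_timecourse(
    bin_series: pd.DataFrame,
    estimate: DivergenceEstimate | None,
    timeline,
    out_path,
    title: str = "",
):
    """Grand-average fixation-proportion curves for every role, with dashed
    word-onset lines, a DP marker and a CI whisker on the time axis.

    Also writes the plotted curves as ``<stem>_data.csv`` so figures can be
    checked numerically.  Returns (figure path, plot data frame).
    """
    if bin_series.empty:
        raise ValidationError("cannot plot an empty bin series")
    data = (
        bin_series.groupby(["role", "bin_start_ms"], observed=True)["proportion"]
        .mean()
        .reset_index()
    )
    fig, ax = plt.subplots(figsize=(7, 4))
    for role, sub in data.groupby("role"):
        ax.plot(sub["bin_start_ms"], sub["proportion"], label=role)
    for lab, onset in zip(timeline.word_labels, timeline.word_onsets_ms):
        ax.axvline(onset, linestyle="--", color="grey", linewidth=0.8)
        ax.text(onset, 1.02, lab, fontsize=7, ha="left", transform=ax.get_xaxis_transform())
    if estimate is not None and estimate.n_convergent > 0:
        ax.plot([estimate.boot_mean_ms], [0.0], marker="^", color="black", markersize=9)
        ax.hlines(0.0, estimate.ci_low_ms, estimate.ci_high_ms, color="black", linewidth=2)
    elif estimate is not None:
        ax.annotate("no convergent divergence point", xy=(0.02, 0.9), xycoords="axes fraction")
    ax.set_xlabel("time from audio onset (ms)")
    ax.set_ylabel("fixation proportion")
    ax.set_ylim(-0.05, 1.0)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    out_path = Path(out_path)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    data_path = out_path.with_name(out_path.stem + "_data.csv")
    data.to_csv(data_path, index=False)
    return out_path, data


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunResult:
    accuracy: pd.DataFrame
    bin_series: pd.DataFrame
    estimates: list[DivergenceEstimate]
    differences: list[GroupDifference]
    filter_log: dict
    paths: dict


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def _validate_contrasts(contrasts, trials: pd.DataFrame) -> None:
    role_cols = ["q1_role", "q2_role", "q3_role", "q4_role"]
    for c in contrasts:
        sel = trials[
            (trials["sub_experiment"].astype(str) == str(c.sub_experiment))
            & (trials["condition"] == c.condition)
        ]
        if sel.empty:
            raise ConfigError(
                f"contrast {c.name!r}: no trials with sub-experiment "
                f"{c.sub_experiment!r}, condition {c.condition!r}"
            )
        roles = set(sel[role_cols].to_numpy().ravel())
        for r in (c.role_a, c.role_b):
            if r not in roles:
                raise ConfigError(f"contrast {c.name!r}: unknown role {r!r}")


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis described by ``config`` and write outputs.

    Output files: ``accuracy_summary.csv``, ``filter_log.json``,
    ``dpa_results.csv``/``.json``, ``group_differences.csv``, one
    ``fig_<contrast>.png`` (+ ``_data.csv``) per contrast, and a
    ``run_log.jsonl`` of per-stage counts.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_log: list[dict] = []

    with _stage("load"):
        if config.samples_path:
            samples = read_sample_report(config.samples_path)
        elif config.fixations_path:
            samples = read_fixation_report(
                config.fixations_path, sample_rate_hz=config.sample_rate_hz
            )
        else:
            raise ConfigError("config needs paths.samples or paths.fixations")
        trials = read_trial_metadata(config.trials_path)
        participants = read_participant_metadata(config.participants_path)
        timeline = (
            build_timeline(config.timeline_durations, config.post_delay_ms)
            if config.timeline_durations
            else default_timeline()
        )
        grid = BinGrid.for_timeline(
            timeline,
            bin_ms=config.bin_ms,
            window_start_ms=config.window_start_ms,
            window_end_ms=config.window_end_ms,
        )
        contrasts = config.contrasts or list(default_contrasts(timeline))
        _validate_contrasts(contrasts, trials)
        stage_log.append(
            {
                "stage": "load",
                "n_samples": int(len(samples)),
                "n_trials": int(len(trials)),
                "n_participants": int(len(participants)),
            }
        )

    with _stage("filter_participants"):
        included, excl_log = filter_participants(participants, config.filters)
        participants = participants[participants["participant_id"].isin(included)]
        trials = trials[trials["participant_id"].isin(included)]
        samples = samples[samples["participant_id"].isin(included)]
        stage_log.append(
            {"stage": "filter_participants", "excluded": excl_log, "kept": len(included)}
        )

    with _stage("regroup"):
        if config.regroup:
            mapping, dropped = regroup_by_metadata(participants, config.regroup)
            participants = participants[
                participants["participant_id"].isin(mapping)
            ].copy()
            participants["group"] = participants["participant_id"].map(mapping)
            trials = trials[trials["participant_id"].isin(mapping)]
            samples = samples[samples["participant_id"].isin(mapping)]
            stage_log.append(
                {"stage": "regroup", "dropped": [str(d) for d in dropped]}
            )

    with _stage("accuracy"):
        acc = accuracy_summary(trials, participants)
        n_removed = int((trials["accuracy"] == 0).sum())
        stage_log.append(
            {
                "stage": "accuracy",
                "trials_incorrect": n_removed,
                "pct_incorrect": round(100.0 * n_removed / max(1, len(trials)), 2),
            }
        )

    with _stage("binning"):
        layout = RoiLayout()
        bin_series = compute_bin_series(
            samples, trials, layout, grid, keep_only_correct=config.keep_only_correct
        )
        group_of = dict(
            zip(participants["participant_id"], participants["group"])
        )
        stage_log.append({"stage": "binning", "n_series_rows": int(len(bin_series))})

    with _stage("dpa"):
        estimates, differences = run_dpa(
            bin_series,
            group_of,
            contrasts,
            grid,
            reference_group=config.reference_group,
            n_boot=config.n_boot,
            seed=config.seed,
            ci=config.ci,
        )
        stage_log.append(
            {
                "stage": "dpa",
                "nonconvergent": {
                    f"{e.group}:{e.contrast.name}": e.n_boot - e.n_convergent
                    for e in estimates
                },
            }
        )

    with _stage("report"):
        paths = _write_outputs(
            outdir,
            config,
            acc,
            excl_log,
            estimates,
            differences,
            bin_series,
            group_of,
            timeline,
            contrasts,
            stage_log,
        )

    return RunResult(acc, bin_series, estimates, differences, excl_log, paths)


def _write_outputs(
    outdir,
    config,
    acc,
    excl_log,
    estimates,
    differences,
    bin_series,
    group_of,
    timeline,
    contrasts,
    stage_log,
) -> dict:
    paths = {}
    paths["accuracy"] = outdir / "accuracy_summary.csv"
    acc.to_csv(paths["accuracy"], index=False)

    paths["filter_log"] = outdir / "filter_log.json"
    paths["filter_log"].write_text(
        json.dumps({"participants_excluded": excl_log}, indent=2, sort_keys=True)
    )

    res = pd.DataFrame([e.to_dict() for e in estimates])
    paths["dpa_results"] = outdir / "dpa_results.csv"
    res.to_csv(paths["dpa_results"], index=False)

    diff = pd.DataFrame([d.to_dict() for d in differences])
    paths["group_differences"] = outdir / "group_differences.csv"
    diff.to_csv(paths["group_differences"], index=False)

    paths["dpa_json"] = outdir / "dpa_results.json"
    paths["dpa_json"].write_text(
        json.dumps(
            {
                "config": config.raw,
                "seed": config.seed,
                "estimates": [
                    e.to_dict(include_distribution=config.include_distributions)
                    for e in estimates
                ],
                "differences": [d.to_dict() for d in differences],
            },
            indent=2,
            sort_keys=True,
        )
    )

    pid_group = pd.Series(group_of, name="group")
    for c in contrasts:
        sel = bin_series[
            (bin_series["sub_experiment"].astype(str) == str(c.sub_experiment))
            & (bin_series["condition"] == c.condition)
        ]
        est = next(
            (e for e in estimates if e.contrast.name == c.name), None
        )
        fig_path = outdir / f"fig_{c.name}.png"
        plot_timecourse(sel, est, timeline, fig_path, title=c.name)
        paths[f"fig_{c.name}"] = fig_path

    paths["run_log"] = outdir / "run_log.jsonl"
    with open(paths["run_log"], "w") as fh:
        for entry in stage_log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    return paths
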