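"""End-to-end orchestration: generate -> prep -> select -> encode -> trajectory -> stats.

A single master seed deterministically derives every stage seed, so a run is
reproducible bit-for-bit; every emitted artifact is listed in a manifest
with its content hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import prep, selection, state_space, stats
from .cohort import (
    ARM_CONTROL,
    ARM_TDM,
    EXIT_ALIVE,
    EXIT_DEAD,
    CohortConfig,
    generate_cohort,
    inject_missingness,
    write_cohort,
)
from .encoding import StateSpaceEncoder
from .selection import GAConfig, run_scenario

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Full-pipeline settings; defaults run at a desk-friendly scale."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    ga: GAConfig = field(
        default_factory=lambda: GAConfig(
            population_size=40, generations=25, repetitions=20, subset_size=8
        )
    )
    scenario: int = 2
    holdout_n: int = 10
    train_fraction: float = 0.8
    drop_missing_fraction: float = prep.DEFAULT_DROP_MISSING_FRACTION
    uniqueness_threshold: int = prep.DEFAULT_UNIQUENESS_THRESHOLD
    smoothing: float = 1.0
    reference_sofa: int = state_space.DEFAULT_REFERENCE_SOFA
    regularization: float | str = "auto"
    day_cutoff: int = stats.DEFAULT_DAY_CUTOFF
    n_permutations: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        if "ga" in d and isinstance(d["ga"], dict):
            d["ga"] = GAConfig(**d["ga"])
        return cls(**d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage in order and emit the report bundle.

    Returns a results dict with the in-memory tables; all artifacts are
    written under ``outdir`` and listed in ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}

    def _stage(name):
        logger.info("stage %s (seed %d)", name, stage_seed(config.seed, name))
        return stage_seed(config.seed, name)

    # -- generate ----------------------------------------------------------
    gen_cfg = dataclasses.replace(config.cohort, seed=_stage("generate"))
    cohort = generate_cohort(gen_cfg)
    if gen_cfg.missing_rate > 0:
        cohort = inject_missingness(
            cohort, gen_cfg.missing_rate, _stage("missingness")
        )
    results["cohort"] = cohort

    # -- prep --------------------------------------------------------------
    clean, schema, drop_log = prep.prepare_cohort(
        cohort,
        max_missing_fraction=config.drop_missing_fraction,
        uniqueness_threshold=config.uniqueness_threshold,
    )
    results["clean"], results["schema"], results["drop_log"] = clean, schema, drop_log

    # -- feature selection -------------------------------------------------
    ga_cfg = dataclasses.replace(config.ga, seed=_stage("select"))
    report = run_scenario(
        clean, config.scenario, ga_cfg, schema,
        holdout_n=config.holdout_n, train_fraction=config.train_fraction,
    )
    results["selection"] = report
    chosen = list(report.chosen)
    if not chosen:
        raise RuntimeError("selection stage produced an empty feature set")

    # -- encode (analysis set = everyone but the holdout patients) ---------
    analysis = clean[~clean["patient_id"].isin(report.holdout_ids)].reset_index(
        drop=True
    )
    discrete_like = [
        c for c in chosen if c in set(schema.discrete) | set(schema.pathogen)
    ]
    encoder = StateSpaceEncoder(
        discrete_columns=discrete_like, smoothing=config.smoothing
    ).fit(analysis[chosen], analysis["sofa_total"])
    encoded = encoder.transform(analysis[chosen])
    results["encoder"] = encoder

    # -- state-space trajectory --------------------------------------------
    reference = state_space.build_reference(
        encoded,
        analysis["sofa_total"].to_numpy(),
        reference_sofa=config.reference_sofa,
        regularization=config.regularization,
    )
    trajectory = state_space.daily_trajectory(encoded, analysis, reference)
    results["reference"], results["trajectory"] = reference, trajectory

    day1_mask = analysis["day"] == 1
    day1_table, day1_cmp = state_space.day1_similarity(
        encoded[day1_mask],
        analysis.loc[day1_mask, "arm"].to_numpy(),
        n_permutations=config.n_permutations,
        seed=_stage("day1"),
    )
    day1_table = pd.concat(
        [analysis.loc[day1_mask, ["patient_id"]].reset_index(drop=True),
         day1_table.reset_index(drop=True)],
        axis=1,
    )
    results["day1"], results["day1_comparison"] = day1_table, day1_cmp

    # -- outcome statistics -------------------------------------------------
    curves = stats.exit_curves(analysis)
    last_sofa = stats.last_sofa_by_day(analysis, day_cutoff=config.day_cutoff)
    comparisons = {}
    for status in (EXIT_ALIVE, EXIT_DEAD):
        try:
            comparisons[status] = stats.compare_exit_distributions(
                analysis, status
            )
        except ValueError as exc:
            comparisons[status] = {"status": status, "error": str(exc)}
    exits = stats.patient_exits(analysis)
    alive = exits[
        (exits["exit_status"] == EXIT_ALIVE)
        & (exits["exit_day"] < config.day_cutoff)
    ]
    try:
        anova = stats.anova_group_time(alive)
        anova_dict = {
            str(k): {kk: (None if pd.isna(vv) else float(vv)) for kk, vv in v.items()}
            for k, v in anova.to_dict(orient="index").items()
        }
    except ValueError as exc:
        anova, anova_dict = None, {"error": str(exc)}
    results.update(
        exit_curves=curves, last_sofa=last_sofa,
        exit_comparisons=comparisons, anova=anova,
    )

    emit_report(results, outdir, anova_dict=anova_dict)
    return results


def emit_report(results: dict, outdir: str | Path, anova_dict=None) -> Path:
    """Write tables, JSON summaries, plots and the hash manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config: RunConfig = results["config"]
    config.to_yaml(outdir / "config.yaml")
    write_cohort(results["cohort"], outdir / "cohort.csv", config=config.cohort)
    results["clean"].to_csv(outdir / "clean.csv", index=False)
    (outdir / "schema.json").write_text(
        json.dumps(results["schema"].to_dict(), indent=1)
    )
    (outdir / "drop_log.txt").write_text(
        "# column\treason\n"
        + "".join(f"{col}\t{reason}\n" for col, reason in results["drop_log"])
    )

    report: selection.SelectionReport = results["selection"]
    freq = report.frequencies.rename("frequency").to_frame()
    freq["chosen"] = [f in report.chosen for f in freq.index]
    freq.index.name = "feature"
    freq.reset_index().to_csv(outdir / "selection_frequencies.csv", index=False)
    (outdir / "selection.json").write_text(
        json.dumps(
            {
                "scenario": report.scenario_id,
                "chosen": list(report.chosen),
                "holdout_ids": list(report.holdout_ids),
                "fallback_used": report.fallback_used,
            },
            indent=1,
        )
    )
    results["encoder"].to_json(outdir / "encoder.json")

    results["trajectory"].to_csv(outdir / "trajectory.csv", index=False)
    results["day1"].to_csv(outdir / "day1_similarity.csv", index=False)
    (outdir / "day1_comparison.json").write_text(
        json.dumps(results["day1_comparison"], indent=1, default=_json_default)
    )
    results["exit_curves"].to_csv(outdir / "exit_curves.csv", index=False)
    results["last_sofa"].to_csv(outdir / "last_sofa.csv", index=False)
    reference = results["reference"]
    (outdir / "reference.json").write_text(
        json.dumps(
            {
                "n_members": int(reference.members_.shape[0]),
                "dim": int(reference.members_.shape[1]),
                "regularization": reference.regularization_,
                "norm_constant": reference.norm_constant_,
                "mean": reference.mean_.tolist(),
            },
            indent=1,
        )
    )
    (outdir / "stats.json").write_text(
        json.dumps(
            {
                "exit_comparisons": results["exit_comparisons"],
                "anova": anova_dict,
            },
            indent=1,
            default=_json_default,
        )
    )

    _plot_trajectory(results["trajectory"], outdir / "trajectory.png")
    _plot_frequencies(report, outdir / "frequencies.png")
    _plot_exit_curves(results["exit_curves"], outdir / "exit_curves.png")

    files = sorted(
        p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {p.name: _sha256(p) for p in files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir / "manifest.json"


_PNG_META = {"Software": "tdmstate"}


def _plot_trajectory(traj: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for arm, color in ((ARM_CONTROL, "tab:orange"), (ARM_TDM, "tab:blue")):
        sub = traj[traj["arm"] == arm]
        ax.plot(sub["day"], sub["normalized_mean"], "o-", label=arm, color=color)
    ax.set_xlabel("day")
    ax.set_ylabel("normalized mean distance to reference")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, metadata=_PNG_META)
    plt.close(fig)


def _plot_frequencies(report: selection.SelectionReport, path: Path) -> None:
    freq = report.frequencies.sort_values(ascending=False)
    colors = [
        "tab:blue" if f in report.chosen else "lightsteelblue" for f in freq.index
    ]
    fig, ax = plt.subplots(figsize=(max(6, 0.25 * len(freq)), 4))
    ax.bar(range(len(freq)), freq.to_numpy(), color=colors)
    ax.set_xticks(range(len(freq)))
    ax.set_xticklabels(freq.index, rotation=90, fontsize=6)
    ax.set_ylabel("pick frequency")
    fig.tight_layout()
    fig.savefig(path, metadata=_PNG_META)
    plt.close(fig)


def _plot_exit_curves(curves: pd.DataFrame, path: Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    for ax, what in zip(axes, ("alive", "dead")):
        for arm, color in ((ARM_CONTROL, "tab:orange"), (ARM_TDM, "tab:blue")):
            sub = curves[curves["arm"] == arm]
            ax.step(
                sub["day"], sub[f"cum_{what}"], where="post",
                label=arm, color=color,
            )
        ax.set_title(f"left the study {what}")
        ax.set_xlabel("day")
        ax.set_ylabel("cumulative patients")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, metadata=_PNG_META)
    plt.close(fig)
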