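"""End-to-end orchestration: simulate → build → sweep → associate → report.

Every run is seed-controlled and fully described by a :class:`RunConfig`
that is echoed into the output manifest, so any output is reproducible from
its manifest alone.  CSV outputs are sorted on (subnetwork, metric,
threshold, participant) for byte stability; two runs of the same config
produce identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .atlas import AtlasRegistry, SubnetworkSpec, load_atlas, load_subnetworks
from .build import (
    DEFAULT_SPARSITY_TARGETS,
    RawConnectome,
    SweepPlan,
    build_weighted,
    network_sparsity,
    plan_sweep,
    read_connectome,
)
from .metrics import MetricTable, ScreenResult, collinearity_screen, compute_metric_table
from .stats import (
    CorrelationResult,
    demographic_screen,
    node_driver_analysis,
    results_to_frame,
    run_association,
    summarize_persistence,
)
from .synthetic import (
    ConnectomeTemplate,
    EffectSpec,
    SynthConfig,
    effect_for_partial_r,
    gen_connectomes,
    gen_participants,
    gen_template,
    participants_to_frame,
    write_cohort,
)

__all__ = [
    "RunConfig",
    "AnalysisResult",
    "load_cohort_dir",
    "analyze_cohort",
    "run_pipeline",
    "simulate_command",
    "report_tables",
]


@dataclasses.dataclass
class RunConfig:
    """Everything a run needs; serialized verbatim into the output manifest."""

    out_dir: str
    seed: int = 0
    atlas: str = "toy20"
    input_dir: str | None = None  # read an existing cohort instead of simulating
    synth: SynthConfig | None = None
    subnetwork_config: str | None = None
    targets: tuple[float, ...] = DEFAULT_SPARSITY_TARGETS
    persistence_fraction: float = 0.8
    fdr_level: float = 0.05
    cooks_multiplier: float = 4.0
    screen_cutoff: float = 0.85
    driver_target: float = 0.30  # sweep point used for the node-driver analysis
    write_cohort_files: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        synth = raw.pop("synth", None)
        cfg = cls(**{**raw, "targets": tuple(raw.get("targets", DEFAULT_SPARSITY_TARGETS))})
        if synth is not None:
            effect = synth.get("effect", {})
            template = gen_template(
                atlas_name=cfg.atlas,
                n_nodes=load_atlas(cfg.atlas).n_nodes,
                density=synth.get("density", 0.5),
                seed=cfg.seed,
                count_scale=synth.get("count_scale", 40.0),
            )
            if "target_partial_r" in effect:
                subnets = load_subnetworks(load_atlas(cfg.atlas), cfg.subnetwork_config)
                spec = effect_for_partial_r(
                    template,
                    subnets[effect.get("subnetwork", "sensorimotor")].members,
                    effect["target_nodes"],
                    effect["target_partial_r"],
                    beta_weight=effect.get("beta_weight", 0.0),
                )
            else:
                spec = EffectSpec(
                    frozenset(effect.get("target_nodes", [])),
                    beta_weight=effect.get("beta_weight", 0.0),
                    beta_edge=effect.get("beta_edge", 0.0),
                )
            cfg.synth = SynthConfig(
                n_participants=synth["n_participants"],
                seed=cfg.seed,
                template=template,
                effect=spec,
            )
        return cfg


@dataclasses.dataclass
class AnalysisResult:
    plan: SweepPlan
    screen: ScreenResult
    demographics: pd.DataFrame
    results: list[CorrelationResult]
    results_frame: pd.DataFrame
    summary: pd.DataFrame
    drivers: pd.DataFrame
    tables: dict[float, MetricTable]
    mean_sparsities: dict[float, float]
    log: list[str]


def load_cohort_dir(directory: str | Path) -> tuple[pd.DataFrame, list[RawConnectome]]:
    """Read a cohort directory written by :func:`connsweep.synthetic.write_cohort`."""
    directory = Path(directory)
    cohort = pd.read_csv(directory / "cohort.csv")
    manifest_path = directory / "manifest.json"
    atlas_name = ""
    if manifest_path.exists():
        atlas_name = json.loads(manifest_path.read_text()).get("atlas_name") or ""
    raws = []
    for pid in cohort["id"].astype(str):
        raws.append(
            read_connectome(
                directory / f"{pid}_counts.tsv",
                directory / f"{pid}_rd.tsv",
                participant_id=pid,
                atlas_name=atlas_name,
            )
        )
    return cohort, raws


def _closest_target(targets: Sequence[float], wanted: float) -> float:
    return min(targets, key=lambda t: (abs(t - wanted), t))


def analyze_cohort(
    raws: Sequence[RawConnectome],
    cohort: pd.DataFrame,
    atlas: AtlasRegistry,
    subnets: Mapping[str, SubnetworkSpec],
    targets: Sequence[float] = DEFAULT_SPARSITY_TARGETS,
    persistence_fraction: float = 0.8,
    fdr_level: float = 0.05,
    cooks_multiplier: float = 4.0,
    screen_cutoff: float = 0.85,
    driver_target: float = 0.30,
) -> AnalysisResult:
    """Full in-memory analysis of one cohort.

    Calibrates the sweep, computes metric tables per sweep point, screens
    collinear metrics once over all points, runs the per-point association
    family, classifies persistence, and runs the node-driver analysis for the
    persistent pairs at the sweep point closest to ``driver_target``.
    """
    log: list[str] = []
    plan = plan_sweep(raws, targets)
    log.append(f"sweep: {len(plan.target_sparsities)} targets, "
               f"thresholds {dict(plan.calibrated_thresholds)}")
    demographics = demographic_screen(_with_id(cohort))

    tables: dict[float, MetricTable] = {}
    nets_by_target: dict[float, dict] = {}
    mean_sparsities: dict[float, float] = {}
    for target in plan.target_sparsities:
        thr = plan.calibrated_thresholds[target]
        nets = {r.participant_id: build_weighted(r, thr) for r in raws}
        mean_sparsities[target] = float(
            np.mean([network_sparsity(net) for net in nets.values()])
        )
        tables[target] = compute_metric_table(nets, subnets)
        nets_by_target[target] = nets
        log.append(
            f"target {target}: NS_thr={thr}, mean sparsity={mean_sparsities[target]:.4f}"
        )

    screen = collinearity_screen(
        MetricTable(
            means=pd.concat([t.means for t in tables.values()], ignore_index=True),
            nodes=pd.DataFrame(),
        ),
        cutoff=screen_cutoff,
    )
    log.append(f"collinearity screen: retained {screen.retained}, dropped {screen.dropped}")

    results: list[CorrelationResult] = []
    for target in plan.target_sparsities:
        point = run_association(
            tables[target],
            cohort,
            metrics=screen.retained,
            cooks_multiplier=cooks_multiplier,
            fdr_alpha=fdr_level,
            sparsity_target=target,
            nets=nets_by_target[target],
            subnets=subnets,
        )
        n_excl = {r.subnetwork + "/" + r.metric_name: len(r.excluded_ids) for r in point}
        log.append(f"target {target}: exclusions {n_excl}")
        results.extend(point)

    summary = summarize_persistence(results, persistence_fraction, fdr_level)
    flagged = summary[summary["persistence_class"] != "none"]
    dtarget = _closest_target(plan.target_sparsities, driver_target)
    driver_inputs = [
        r
        for r in results
        if r.sparsity_target == dtarget
        and not r.degenerate
        and ((flagged["metric"] == r.metric_name) & (flagged["subnetwork"] == r.subnetwork)).any()
    ]
    if driver_inputs:
        drivers = node_driver_analysis(tables[dtarget], cohort, driver_inputs, alpha=0.05)
    else:
        drivers = pd.DataFrame(
            columns=["subnetwork", "metric", "threshold", "node",
                     "r_partial", "p_value", "is_driver", "degenerate"]
        )
    log.append(f"drivers computed at sparsity target {dtarget} "
               f"for {len(driver_inputs)} persistent pairs")
    return AnalysisResult(
        plan=plan,
        screen=screen,
        demographics=demographics,
        results=results,
        results_frame=results_to_frame(results),
        summary=summary,
        drivers=drivers,
        tables=tables,
        mean_sparsities=mean_sparsities,
        log=log,
    )


def _with_id(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort if "id" in cohort.columns else cohort.reset_index(names="id")


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.synth is not None:
        from .synthetic import _config_echo

        d["synth"] = _config_echo(config.synth)
    d["targets"] = list(config.targets)
    return d


def simulate_command(config: SynthConfig, directory: str | Path) -> dict:
    """Generate a cohort and write it to ``directory``; returns the manifest."""
    participants = gen_participants(config)
    connectomes = gen_connectomes(participants, config)
    return write_cohort(participants, connectomes, directory, config)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write result files + manifest to the out dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if config.input_dir is not None:
            cohort, raws = load_cohort_dir(config.input_dir)
        elif config.synth is not None:
            stage = "simulate"
            participants = gen_participants(config.synth)
            raws = gen_connectomes(participants, config.synth)
            cohort = participants_to_frame(participants)
            if config.write_cohort_files:
                write_cohort(participants, raws, out / "cohort", config.synth)
        else:
            raise ValueError("config needs either input_dir or synth")
        stage = "atlas"
        atlas = load_atlas(config.atlas)
        subnets = load_subnetworks(atlas, config.subnetwork_config)
        stage = "analysis"
        res = analyze_cohort(
            raws,
            cohort,
            atlas,
            subnets,
            targets=config.targets,
            persistence_fraction=config.persistence_fraction,
            fdr_level=config.fdr_level,
            cooks_multiplier=config.cooks_multiplier,
            screen_cutoff=config.screen_cutoff,
            driver_target=config.driver_target,
        )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    means = pd.concat([t.means for t in res.tables.values()], ignore_index=True)
    means = means.sort_values(
        ["subnetwork", "threshold", "participant"], kind="mergesort", ignore_index=True
    )
    files = {
        "metric_means.csv": means,
        "correlations.csv": res.results_frame,
        "sweep_summary.csv": res.summary,
        "node_drivers.csv": res.drivers,
        "demographics.csv": res.demographics,
    }
    written = {}
    for name, frame in files.items():
        path = out / name
        frame.to_csv(path, index=False)
        written[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (out / "run.log").write_text("\n".join(res.log) + "\n")
    manifest = {
        "config": _config_dict(config),
        "seed": config.seed,
        "calibrated_thresholds": {str(k): v for k, v in res.plan.calibrated_thresholds.items()},
        "files": written,
        "complete": True,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def report_tables(results_dir: str | Path) -> str:
    """Human-readable run summary: significance marks per cell + driver lists.

    One row per metric x subnetwork x threshold with (r, p, q, tier) where
    tier is ``fdr`` (q < 0.05), ``nominal`` (p < 0.05) or blank, followed by
    the node-driver table of every persistent pair.  Writes ``report.txt``
    in the results directory and returns the text.
    """
    results_dir = Path(results_dir)
    manifest_path = results_dir / "manifest.json"
    if not manifest_path.exists() or not json.loads(manifest_path.read_text()).get("complete"):
        raise ValueError(f"{results_dir} does not contain a completed run")
    corr = pd.read_csv(results_dir / "correlations.csv")
    summary = pd.read_csv(results_dir / "sweep_summary.csv")
    drivers = pd.read_csv(results_dir / "node_drivers.csv")

    def tier(row) -> str:
        if pd.notna(row["q"]) and row["q"] < 0.05:
            return "fdr"
        if pd.notna(row["p"]) and row["p"] < 0.05:
            return "nominal"
        return ""

    corr = corr.assign(tier=corr.apply(tier, axis=1))
    lines = ["# Correlation results (metric x subnetwork x threshold)", ""]
    lines.append(corr.to_string(index=False))
    lines += ["", "# Persistence summary", "", summary.to_string(index=False), ""]
    flagged = summary[summary["persistence_class"] != "none"]
    if flagged.empty:
        lines += ["# Node drivers", "", "no significant pairs"]
    else:
        lines += ["# Node drivers (persistent pairs)", ""]
        if drivers.empty:
            lines.append("no driver table (no persistent pair at the driver threshold)")
        else:
            lines.append(drivers.to_string(index=False))
    text = "\n".join(lines) + "\n"
    (results_dir / "report.txt").write_text(text)
    return text
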