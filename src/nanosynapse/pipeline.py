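"""End-to-end orchestration: simulate/ingest → frame filter → denoise →
cluster → metrics → associate → summarize (→ compare).

:func:`analyze_field` is the canonical single-field analysis used by the
command-line interface, the validation suite and the reproduction script;
:func:`run_pipeline` wraps it with file output, a machine-readable run
manifest and logging.  Given the same seed and input, a run is deterministic
down to byte-identical JSON output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clustering import CLUSTER_PARAM_PRESETS, ClusterParams, ClusterSet, cluster_channel
from .cluster_metrics import DEFAULT_OPTS, MetricOptions
from .errors import NanosynapseError
from .locdata_io import (
    FRAME_WINDOW_PRESETS,
    FrameWindow,
    LocalizationTable,
    read_localizations,
    write_localizations,
)
from .synapse_association import (
    AssociationParams,
    AssociationResult,
    SynapseStats,
    classify,
    compare_conditions,
    summarize,
)
from .synthetic_data import (
    GroundTruth,
    SyntheticConfig,
    default_cko_config,
    default_control_config,
    generate_field,
)

log = logging.getLogger("nanosynapse")


@dataclass
class FieldAnalysis:
    """All per-field results of the standard analysis."""

    nanos: ClusterSet
    macros: ClusterSet
    assoc: AssociationResult
    stats: SynapseStats
    nano_rgs: np.ndarray
    macro_rgs: np.ndarray
    counts: dict  # localizations in/out at each filter stage


def _frame_window_for(channel: str, overrides: dict | None) -> FrameWindow | None:
    if overrides and channel in overrides:
        w = overrides[channel]
        return w if isinstance(w, FrameWindow) else FrameWindow(channel, *w)
    if channel in FRAME_WINDOW_PRESETS:
        return FrameWindow.preset(channel)
    return None


def analyze_field(
    table: LocalizationTable,
    nano_channel: str = "Tenm3",
    reference_channel: str = "Bassoon",
    cluster_params: dict[str, ClusterParams] | None = None,
    frame_windows: dict | None = None,
    assoc_params: AssociationParams = AssociationParams(),
    opts: MetricOptions = DEFAULT_OPTS,
) -> FieldAnalysis:
    """Standard two-channel analysis of one localization field.

    Frame filtering is applied first (upstream-most), then per-channel
    density denoising and DBSCAN, then classification of nanoclusters
    against the reference channel and per-synapse summaries.
    """
    cluster_params = cluster_params or {}
    counts = {"input": len(table)}
    for channel in (nano_channel, reference_channel):
        window = _frame_window_for(channel, frame_windows)
        if window is not None and channel in table.channels:
            from .locdata_io import filter_frames

            table = filter_frames(table, window)
    counts["after_frame_filter"] = len(table)

    def _params(channel: str, eps: float, min_pts: int) -> ClusterParams:
        if channel in cluster_params:
            return cluster_params[channel]
        if channel in CLUSTER_PARAM_PRESETS:
            return CLUSTER_PARAM_PRESETS[channel]
        return ClusterParams(channel, eps, min_pts)

    nano_set = cluster_channel(table, _params(nano_channel, 100.0, 10))
    macro_set = cluster_channel(table, _params(reference_channel, 300.0, 50))
    counts["nano_clustered"] = sum(c.n_locs for c in nano_set.clusters)
    counts["macro_clustered"] = sum(c.n_locs for c in macro_set.clusters)

    assoc = classify(nano_set, macro_set, assoc_params, opts)
    nano_rgs = np.array([c.rg for c in nano_set.clusters], dtype=float)
    macro_rgs = np.array([c.rg for c in macro_set.clusters], dtype=float)
    if len(macro_set) and len(nano_set):
        stats = summarize(
            assoc,
            macro_set,
            nano_rg_mean=float(nano_rgs.mean()),
            macro_rg_mean=float(macro_rgs.mean()),
        )
    else:
        stats = None
    return FieldAnalysis(
        nanos=nano_set,
        macros=macro_set,
        assoc=assoc,
        stats=stats,
        nano_rgs=nano_rgs,
        macro_rgs=macro_rgs,
        counts=counts,
    )


def analyze_condition(
    configs: list[SyntheticConfig],
) -> tuple[list[FieldAnalysis], list[GroundTruth]]:
    """Generate and analyze one synthetic field per config."""
    analyses, truths = [], []
    for cfg in configs:
        table, truth = generate_field(cfg)
        analyses.append(
            analyze_field(
                table,
                nano_channel=cfg.nano_channel,
                reference_channel=cfg.reference_channel,
            )
        )
        truths.append(truth)
    return analyses, truths


def condition_configs(kind: str, seeds) -> list[SyntheticConfig]:
    maker = {"control": default_control_config, "cko": default_cko_config}[kind]
    return [maker(seed=int(s)) for s in seeds]


# --------------------------------------------------------------------------
# config-file driven runs


@dataclass
class PipelineConfig:
    seed: int = 0
    input_path: str | None = None  # mutually exclusive with simulate
    simulate: str | None = None  # "control" or "cko"
    n_fields: int = 1
    nano_channel: str = "Tenm3"
    reference_channel: str = "Bassoon"
    synaptic_threshold: float = 80.0
    output_dir: str = "nanosynapse_run"
    cluster_params: dict = field(default_factory=dict)  # channel -> {eps, min_pts, ...}
    frame_windows: dict = field(default_factory=dict)  # channel -> [total, excluded]
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise NanosynapseError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**doc)

    def resolved_cluster_params(self) -> dict[str, ClusterParams]:
        out = {}
        for channel, kw in self.cluster_params.items():
            out[channel] = ClusterParams(channel=channel, **kw)
        return out


def _stats_doc(analysis: FieldAnalysis) -> dict:
    stats = analysis.stats
    doc = {
        "n_nanoclusters": len(analysis.nanos),
        "n_macroclusters": len(analysis.macros),
        "nano_rg_mean_nm": round(float(analysis.nano_rgs.mean()), 1) if len(analysis.nanos) else None,
        "macro_rg_mean_nm": round(float(analysis.macro_rgs.mean()), 1) if len(analysis.macros) else None,
        "counts": analysis.counts,
    }
    if stats is not None:
        doc.update(
            {
                "pct_synaptic_nano": stats.pct_synaptic_nano,
                "pct_nonsynaptic_nano": stats.pct_nonsynaptic_nano,
                "mean_nano_per_synapse": stats.mean_nano_per_synapse,
                "count_distribution": stats.count_distribution,
                "occupancy_fraction_pct": stats.occupancy_fraction,
                "occupancy_formula": stats.occupancy_formula,
            }
        )
    return doc


def write_cluster_tsv(cset: ClusterSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchannel\tn_locs\tcentroid_x_nm\tcentroid_y_nm\tcentroid_z_nm\trg_nm\n")
        for c in cset.clusters:
            fh.write(
                f"{c.id}\t{c.channel}\t{c.n_locs}\t{c.centroid[0]:.1f}\t{c.centroid[1]:.1f}"
                f"\t{c.centroid[2]:.1f}\t{c.rg:.1f}\n"
            )


def write_assoc_json(assoc: AssociationResult, path) -> None:
    doc = {
        "reference_channel": assoc.reference_channel,
        "threshold_nm": assoc.threshold,
        "nanoclusters": [
            {
                "nano_id": r.nano_id,
                "macro_id": r.macro_id,
                "edge_distance_nm": (round(r.edge_distance, 1) if np.isfinite(r.edge_distance) else None),
                "synaptic": r.synaptic,
            }
            for r in assoc.records
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis described by ``config``; returns the manifest.

    Outputs under ``config.output_dir``: per-field localization tables (for
    simulated input), cluster TSVs, association JSONs, a stats JSON, the run
    manifest and a log file.  A stage failure leaves completed stage outputs
    in place and is recorded in the manifest before the error propagates.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": [],
        "status": "running",
    }
    try:
        # -- input stage -----------------------------------------------------
        tables: list[LocalizationTable] = []
        if config.simulate is not None:
            seeds = [config.seed + i for i in range(config.n_fields)]
            cfgs = condition_configs(config.simulate, seeds)
            for i, cfg in enumerate(cfgs):
                table, truth = generate_field(cfg)
                write_localizations(table, out / f"field_{i:02d}.csv")
                truth.to_json(out / f"field_{i:02d}.truth.json")
                tables.append(table)
            manifest["stages"].append(
                {"stage": "simulate", "preset": config.simulate, "seeds": seeds}
            )
        elif config.input_path is not None:
            tables.append(read_localizations(config.input_path))
            manifest["stages"].append({"stage": "ingest", "path": config.input_path})
        else:
            raise NanosynapseError("config must set either input_path or simulate")

        # -- analysis stage --------------------------------------------------
        field_docs = []
        all_stats = []
        for i, table in enumerate(tables):
            log.info("field %d: %d localizations in", i, len(table))
            analysis = analyze_field(
                table,
                nano_channel=config.nano_channel,
                reference_channel=config.reference_channel,
                cluster_params=config.resolved_cluster_params(),
                frame_windows=config.frame_windows,
                assoc_params=AssociationParams(config.synaptic_threshold),
            )
            log.info(
                "field %d: %d nanoclusters, %d macroclusters", i, len(analysis.nanos), len(analysis.macros)
            )
            write_cluster_tsv(analysis.nanos, out / f"field_{i:02d}.nanoclusters.tsv")
            write_cluster_tsv(analysis.macros, out / f"field_{i:02d}.macroclusters.tsv")
            write_assoc_json(analysis.assoc, out / f"field_{i:02d}.assoc.json")
            field_docs.append(_stats_doc(analysis))
            if analysis.stats is not None:
                all_stats.append(analysis.stats)
        manifest["stages"].append({"stage": "analyze", "n_fields": len(tables)})

        stats_doc = {"fields": field_docs}
        if all_stats:
            stats_doc["aggregate"] = {
                "mean_pct_synaptic": float(np.mean([s.pct_synaptic_nano for s in all_stats])),
                "mean_nano_per_synapse": float(np.mean([s.mean_nano_per_synapse for s in all_stats])),
            }
        with open(out / "stats.json", "w") as fh:
            json.dump(stats_doc, fh, indent=1, sort_keys=True)
        manifest["status"] = "ok"
        return manifest
    except Exception as exc:  # record the failing stage, then propagate
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        log.removeHandler(handler)
        handler.close()


def compare_condition_runs(
    control: list[SynapseStats], test: list[SynapseStats], run_test: bool = True
) -> dict:
    cmp = compare_conditions(control, test, run_test=run_test)
    return dataclasses.asdict(cmp)
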