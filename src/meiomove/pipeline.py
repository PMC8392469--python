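"""End-to-end pipeline orchestration, configuration and run manifests.

A run configuration (YAML or JSON; flat keys mirroring the module
defaults) drives ingest -> normalise -> derive -> segment -> cluster ->
stats/motifs/causality. Every stage draws its randomness from a named
substream of the master seed, and a manifest written last records the
resolved configuration, consumed seeds and SHA-256 checksums of every
output file, so a completed run is reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .causality import aggregate_adjacency, causality_scan, export_graph
from .io import (NormalizationSpec, apply_normalization, derive_velocities,
                 read_tracks, write_tracks)
from .motifs import concat_series, discover_discords, discover_motifs, \
    matrix_profile, motif_location_distribution
from .segmentation import SegmentationParams, segment_dataset
from .stats import fit_composition_models, msd, velocity_u_test

__all__ = ["RunConfig", "RunManifest", "load_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (defaults per module)."""

    input_path: str = ""
    input_format: str | None = None
    column_map: dict | None = None
    output_dir: str = "meiomove_out"
    seed: int = 0
    # normalisation
    value_method: str = "none"
    time_zero_mode: str = "last_common_zero"
    rotate_axes: bool = False
    # segmentation / clustering
    covariates: list = field(default_factory=lambda: ["x"])
    k_max: int = 10
    l_min: int = 5
    threshold: float = 0.75
    cluster_min: int = 1
    cluster_max: int = 10
    # stats
    groups: list = field(default_factory=list)
    # motifs
    motif_var: str = "x"
    motif_window: int = 20
    motif_corr: float = 0.98
    n_motifs: int = 3
    mp_method: str = "mpx_exact"
    # causality
    causality_method: str = "vlte"
    causality_vars: list = field(default_factory=list)
    max_lag: int = 10
    alpha: float = 0.01
    adjust: str = "bonferroni"
    presence: float = 0.8
    bins: int = 3
    n_perm: int = 100
    # stage toggles
    run_segments: bool = True
    run_stats: bool = True
    run_motifs: bool = True
    run_causality: bool = False


@dataclass
class RunManifest:
    version: str
    timestamp: str
    config: dict
    seeds: dict
    outputs: dict           # file name -> sha256
    completed: bool
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON — valid YAML) run configuration file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


def run_pipeline(config: RunConfig, table: pd.DataFrame | None = None) -> RunManifest:
    """Execute the configured stages; the manifest is written last.

    ``table`` may be passed directly (already-loaded tracks); otherwise
    ``config.input_path`` is read. A failure in any stage is recorded in
    the manifest (partial completion, failing stage named) and re-raised.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    seeds: dict[str, int] = {}
    manifest = RunManifest(__version__, time.strftime("%Y-%m-%dT%H:%M:%S"),
                           asdict(config), seeds, outputs, completed=False)
    stage = "ingest"
    try:
        if table is None:
            table = read_tracks(config.input_path, config.input_format,
                                config.column_map)
        stage = "normalize"
        spec = NormalizationSpec(config.value_method, config.time_zero_mode,
                                 config.rotate_axes)
        table = apply_normalization(table, spec)
        stage = "derive"
        table = derive_velocities(table)
        path = out_dir / "tracks.csv"
        write_tracks(table, path)
        outputs[path.name] = _sha256(path)

        groups = config.groups or sorted(table["group_id"].unique())
        if config.run_stats and len(groups) < 2:
            raise ValueError("two-group statistics requested but fewer than two "
                             "groups configured or present")

        result = None
        if config.run_segments:
            stage = "segment"
            seeds[stage] = _stage_seed(config.seed, stage)
            params = SegmentationParams(config.k_max, config.l_min, config.threshold)
            result = segment_dataset(table, config.covariates, params,
                                     range(config.cluster_min, config.cluster_max + 1),
                                     random_state=seeds[stage])
            path = out_dir / "segments.csv"
            result.segments.to_csv(path, index=False)
            outputs[path.name] = _sha256(path)
            model = {"n_clusters": int(result.n_clusters),
                     "bic": result.clusterer.bic_table_,
                     "weights": result.clusterer.weights_.tolist(),
                     "means": result.clusterer.means_.tolist(),
                     "seed": seeds[stage]}
            path = out_dir / "cluster_model.json"
            path.write_text(json.dumps(model, indent=2))
            outputs[path.name] = _sha256(path)

        if config.run_stats:
            stage = "stats"
            report: dict = {}
            if result is not None:
                tests = fit_composition_models(result, groups[0], groups[1])
                report["composition"] = {
                    fid: {"p_value": t.p_value, "deviance": t.deviance,
                          "df": t.df_model, "separation": t.separation_flag}
                    for fid, t in tests.items()
                }
            report["velocity_u_test_p"] = velocity_u_test(table, groups[0], groups[1])
            curve = msd(table)
            path = out_dir / "msd.csv"
            curve.to_csv(path, index=False)
            outputs[path.name] = _sha256(path)
            path = out_dir / "stats.json"
            path.write_text(json.dumps(report, indent=2))
            outputs[path.name] = _sha256(path)

        if config.run_motifs:
            stage = "motifs"
            seeds[stage] = _stage_seed(config.seed, stage)
            concat = concat_series(table, config.motif_var, config.motif_window)
            mp = matrix_profile(concat, config.motif_window, config.mp_method,
                                seed=seeds[stage])
            motifs = discover_motifs(mp, config.n_motifs, config.motif_corr)
            motifs.discords = discover_discords(mp, config.n_motifs).discords
            locations, tests = motif_location_distribution(motifs, concat, groups)
            path = out_dir / "motif_locations.csv"
            locations.to_csv(path, index=False)
            outputs[path.name] = _sha256(path)
            path = out_dir / "motif_tests.csv"
            tests.to_csv(path, index=False)
            outputs[path.name] = _sha256(path)
            prof = pd.DataFrame({"position": np.arange(mp.profile.size),
                                 "profile": mp.profile, "index": mp.index})
            path = out_dir / "matrix_profile.csv"
            prof.to_csv(path, index=False)
            outputs[path.name] = _sha256(path)

        if config.run_causality:
            stage = "causality"
            seeds[stage] = _stage_seed(config.seed, stage)
            variables = config.causality_vars or ["linear_velocity", "angular_velocity"]
            stack = causality_scan(table, variables, config.causality_method,
                                   config.max_lag, config.alpha, config.adjust,
                                   config.bins, config.n_perm, seeds[stage])
            graph = aggregate_adjacency(stack, config.presence)
            paths = export_graph(graph, out_dir)
            for p in paths.values():
                outputs[Path(p).name] = _sha256(Path(p))
            long = pd.DataFrame(
                [{"particle": str(stack.particles[k]), "source": stack.variables[i],
                  "target": stack.variables[j],
                  "significant": int(stack.matrices[k, i, j])}
                 for k in range(stack.matrices.shape[0])
                 for i in range(len(stack.variables))
                 for j in range(len(stack.variables)) if i != j]
            )
            path = out_dir / "per_particle_adjacency.csv"
            long.to_csv(path, index=False)
            outputs[path.name] = _sha256(path)

        manifest.completed = True
    except Exception:
        manifest.failed_stage = stage
        manifest.write(out_dir / "manifest.json")
        raise
    manifest.write(out_dir / "manifest.json")
    return manifest
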