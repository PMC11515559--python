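"""End-to-end workflow: graph -> normalize -> RAS -> adjust -> analyze.

A :class:`RunConfig` (typically loaded from YAML) declares the inputs,
the adjustment schemes to run, the two-group comparison and/or the
unsupervised exploration, and the seeds.  :func:`run_workflow` executes
the stages in order and writes all tables plus a machine-readable
manifest (versions, seeds, config echo) to the output directory.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .differential import differential_reactions, pathway_activity
from .explore import marker_reactions, stability_iterations
from .graph import load_graph_table, parse_kgml, remove_reactions, write_graph_table
from .io import read_annotations, read_counts
from .ras import compute_ras, normalize_counts
from .transition import adjust_ras, scale_reactions

__all__ = ["RunConfig", "ConfigError", "WorkflowError", "run_workflow"]

VALID_SCHEMES = ("W", "W1", "W2", "W3")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class WorkflowError(RuntimeError):
    """A workflow stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    counts: str
    outdir: str
    graph_table: str | None = None
    kgml_files: tuple[str, ...] = ()
    annotations: str | None = None
    remove: tuple[str, ...] = ("R06010", "R06004")
    schemes: tuple[str, ...] = ("W", "W1", "W2", "W3")
    x_node: str = "C01290"
    normalize: bool = True
    # differential comparison
    group_column: str | None = None
    group_a: str | None = None
    group_b: str | None = None
    alpha: float = 0.05
    epsilon: float = 1e-9
    # unsupervised exploration
    explore: bool = False
    n_neighbors: int = 15
    min_dist: float = 0.1
    min_pts: int = 5
    n_iter: int = 0
    marker_mode: str = "vs_rest"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("kgml_files", "remove", "schemes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if not self.schemes:
            raise ConfigError("schemes must be non-empty")
        bad = set(self.schemes) - set(VALID_SCHEMES)
        if bad:
            raise ConfigError(f"unknown schemes {sorted(bad)}")
        if self.graph_table is None and not self.kgml_files:
            raise ConfigError("either graph_table or kgml_files is required")
        for p in [self.counts, self.graph_table, self.annotations,
                  *self.kgml_files]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"declared path does not exist: {p}")
        if self.group_column is not None and self.annotations is None:
            raise ConfigError("a group comparison requires annotations")


def run_workflow(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns the written artifact paths."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
                raise WorkflowError(name, exc) from exc
        return wrap

    # -- graph ---------------------------------------------------------
    if config.graph_table is not None:
        graph = stage("build-graph")(load_graph_table, config.graph_table)
    else:
        graph = stage("build-graph")(parse_kgml, config.kgml_files)
    if config.remove:
        graph = stage("build-graph")(remove_reactions, graph, set(config.remove))
    artifacts["graph"] = outdir / "graph.tsv"
    write_graph_table(graph, artifacts["graph"])

    # -- expression ----------------------------------------------------
    counts = stage("load-counts")(read_counts, config.counts)
    annotations = (read_annotations(config.annotations)
                   if config.annotations else None)
    if config.normalize:
        expr = stage("normalize")(normalize_counts, counts, annotations)
        values = expr.values
    else:
        values = counts.astype(float)

    # -- RAS + adjustments ---------------------------------------------
    ras = stage("ras")(compute_ras, graph, values)
    matrices = {}
    for scheme in config.schemes:
        if scheme == "W":
            matrices[scheme] = ras
        else:
            adj = stage(f"adjust-{scheme}")(
                adjust_ras, ras, graph, scheme, config.x_node)
            matrices[scheme] = adj.values
        path = outdir / f"ras_{scheme}.tsv"
        matrices[scheme].to_csv(path, sep="\t", index_label="reaction_id")
        artifacts[f"ras_{scheme}"] = path

    # -- differential --------------------------------------------------
    if config.group_column is not None:
        groups = annotations[config.group_column]
        for scheme, M in matrices.items():
            table = stage(f"diff-{scheme}")(
                differential_reactions, M, groups,
                config.group_a, config.group_b,
                config.alpha, config.epsilon)
            path = outdir / f"differential_{scheme}.tsv"
            table.to_csv(path, sep="\t")
            artifacts[f"differential_{scheme}"] = path
        pa = pathway_activity(matrices[config.schemes[0]], graph)
        artifacts["pathway_activity"] = outdir / "pathway_activity.tsv"
        pa.to_csv(artifacts["pathway_activity"], sep="\t")

    # -- exploration ---------------------------------------------------
    if config.explore and config.n_iter > 0:
        for scheme, M in matrices.items():
            scaled = stage(f"scale-{scheme}")(scale_reactions, M)
            res = stage(f"explore-{scheme}")(
                stability_iterations, scaled, config.n_iter,
                config.n_neighbors, config.min_dist, config.min_pts,
                config.seed)
            rec_path = outdir / f"stability_records_{scheme}.tsv"
            idx_path = outdir / f"stability_indices_{scheme}.tsv"
            res.records.to_csv(rec_path, sep="\t", index=False)
            res.indices.to_csv(idx_path, sep="\t", index=False)
            artifacts[f"stability_records_{scheme}"] = rec_path
            artifacts[f"stability_indices_{scheme}"] = idx_path
            last = res.records[res.records["iteration"] == 0]
            labels = last.set_index("sample")["label"].reindex(scaled.columns)
            if labels.gt(0).sum() and len(set(labels[labels > 0])) >= 2:
                markers = stage(f"markers-{scheme}")(
                    marker_reactions, scaled, labels.to_numpy(),
                    config.marker_mode)
                for cluster, table in markers.items():
                    mp = outdir / f"markers_{scheme}_cluster{cluster}.tsv"
                    table.to_csv(mp, sep="\t")
                    artifacts[f"markers_{scheme}_cluster{cluster}"] = mp

    # -- manifest ------------------------------------------------------
    manifest = {
        "rasnet_version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = manifest_path
    return artifacts
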