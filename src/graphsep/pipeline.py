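"""End-to-end driver: table -> preprocessing -> graph -> report -> figures.

Also supports analyzing an externally produced GraphML graph without the
preprocessing/building stages.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx

from .config import Config, validate_config
from .graph_analysis import LABEL_KEY, SeparationReport, build_report, degree_distribution
from .graph_build import build_graph, read_graphml
from .preprocessing import preprocess, read_table
from .visualization import (
    compute_layout,
    plot_communities,
    plot_degree_distribution,
    plot_graph,
    plot_heatmap,
)

__all__ = ["RunManifest", "run_pipeline", "analyze_graphml", "PipelineError"]

logger = logging.getLogger("graphsep")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    """What a run produced: resolved config, artifact paths, timing, warnings."""

    config: Config
    artifacts: dict = field(default_factory=dict)
    elapsed_seconds: float = 0.0
    warnings: list = field(default_factory=list)
    report: Optional[SeparationReport] = None

    def summary(self) -> str:
        lines = [f"elapsed: {self.elapsed_seconds:.2f} s"]
        for name, path in self.artifacts.items():
            lines.append(f"{name}: {path}")
        if self.warnings:
            lines.append(f"warnings: {len(self.warnings)}")
        return "\n".join(lines)


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _ctx()


def _analysis_outputs(
    g: nx.Graph, config: Config, manifest: RunManifest, max_splits: int = 100
) -> None:
    """Shared tail of both entry points: report plus the four figures."""
    outdir = Path(config.output_directory)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("graph analysis"):
        report = build_report(g, config, max_splits=max_splits)
        manifest.report = report
        if all(LABEL_KEY in g.nodes[v] for v in g.nodes) and config.neigh_prob_path:
            manifest.artifacts["neighbor_probabilities"] = str(
                outdir / config.neigh_prob_path
            )
        if config.network_metrics_filename:
            manifest.artifacts["network_metrics"] = str(
                outdir / config.network_metrics_filename
            )

    with _stage("visualization"):
        coords = compute_layout(g, seed=config.random_seed)
        manifest.artifacts["graph_plot"] = str(
            plot_graph(
                g,
                coords,
                outdir / config.graph_visualization_filename,
                overwrite=config.overwrite,
            )
        )
        if report.neighbor_probabilities is not None:
            manifest.artifacts["probability_heatmap"] = str(
                plot_heatmap(
                    report.neighbor_probabilities,
                    outdir / config.prob_heatmap_filename,
                    overwrite=config.overwrite,
                )
            )
        manifest.artifacts["community_histogram"] = str(
            plot_communities(
                report.partition,
                outdir / config.community_filename,
                overwrite=config.overwrite,
            )
        )
        manifest.artifacts["degree_distribution"] = str(
            plot_degree_distribution(
                degree_distribution(g),
                outdir / config.degree_distribution_filename,
                overwrite=config.overwrite,
            )
        )


def run_pipeline(config: Config, max_splits: int = 100) -> RunManifest:
    """Execute preprocess -> build graph -> analyze -> plot under one config."""
    t0 = time.perf_counter()
    config = validate_config(config)
    manifest = RunManifest(config=config)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        with _stage("read table"):
            table = read_table(config.input_dataframe)
        with _stage("preprocessing"):
            pt = preprocess(table, config)
            if config.preprocessed_filename:
                manifest.artifacts["preprocessed_table"] = str(
                    Path(config.output_directory) / config.preprocessed_filename
                )
        with _stage("graph creation"):
            g = build_graph(pt, config)
            if config.graph_filename:
                manifest.artifacts["graph_file"] = str(
                    Path(config.output_directory) / config.graph_filename
                )
        _analysis_outputs(g, config, manifest, max_splits=max_splits)

    manifest.warnings = [str(w.message) for w in caught]
    manifest.elapsed_seconds = time.perf_counter() - t0
    return manifest


def analyze_graphml(
    path,
    target_attribute: Optional[str] = None,
    config: Optional[Config] = None,
    max_splits: int = 100,
) -> RunManifest:
    """Analyze an externally produced GraphML graph (no preprocessing/build).

    ``target_attribute`` names the node attribute holding the class label;
    when absent from the nodes, the error lists the attributes that exist.
    Without a target the topology metrics are still produced and the
    separation metrics are skipped with a notice.
    """
    t0 = time.perf_counter()
    if config is None:
        config = Config(input_dataframe=str(path))
    config = validate_config(config)
    manifest = RunManifest(config=config)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        with _stage("read graphml"):
            g = read_graphml(path)
        if target_attribute is not None:
            missing = [v for v in g.nodes if target_attribute not in g.nodes[v]]
            if missing:
                available = sorted(
                    {k for _, data in g.nodes(data=True) for k in data}
                )
                raise PipelineError(
                    f"node attribute {target_attribute!r} not found; "
                    f"available attributes: {available}"
                )
            if target_attribute != LABEL_KEY:
                for v in g.nodes:
                    g.nodes[v][LABEL_KEY] = g.nodes[v][target_attribute]
        _analysis_outputs(g, config, manifest, max_splits=max_splits)

    manifest.warnings = [str(w.message) for w in caught]
    manifest.elapsed_seconds = time.perf_counter() - t0
    return manifest
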