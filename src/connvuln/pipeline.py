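"""End-to-end orchestration: config in, report bundle out.

``run_full_analysis`` takes a :class:`RunConfig` (edge-list paths or a
synthetic spec), runs ingestion, intact metrics, both attack sweeps,
the criticality criteria, pathway assembly, robustness summaries and
the statistical comparisons, and writes a bundle of CSV/JSON tables
plus a manifest with the effective config and per-file SHA-256
checksums.  Output is deterministic given fixed inputs and seed; a
stage failure aborts the run and removes any partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import edge_metric_table, node_metric_table
from .model import ConnectomeVulnerability
from .robustness import find_leaves, reachability_coding
from .synth import SynthSpec, generate_connectome

__all__ = ["RunConfig", "run_full_analysis", "validate_manifest"]

log = logging.getLogger("connvuln")


@dataclass
class RunConfig:
    """Effective configuration of one full analysis run.

    Either the three input paths (chemical, gap, metadata) or a
    synthetic spec (``synthetic=True`` plus any :class:`SynthSpec`
    field overrides in ``synth``) must be supplied.  Every analysis
    option has a default; the effective config is echoed into the
    output directory.
    """

    chemical: str | None = None
    gap: str | None = None
    metadata: str | None = None
    synthetic: bool = False
    synth: dict = field(default_factory=dict)
    clustering: str = "fagiolo"
    efficiency_direction: str = "out"
    node_multiplier: float = 3.0
    sd_ddof: int = 1
    grade_method: str = "floor"
    long_range_quantile: float = 0.90
    pathway_property: str = "B"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML (JSON is a YAML subset and also accepted)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: RunConfig):
    from . import io

    if config.synthetic:
        spec = SynthSpec(**{**config.synth, "seed": config.synth.get("seed", config.seed)})
        graph, meta, key = generate_connectome(spec)
        return graph, meta, key
    if not (config.chemical and config.gap):
        raise ValueError(
            "config must supply chemical and gap edge-list paths, or synthetic=true"
        )
    chem = io.read_edge_list(config.chemical, "chemical")
    gap = io.read_edge_list(config.gap, "gap")
    meta = io.read_metadata(config.metadata) if config.metadata else None
    roster = list(meta["name"]) if meta is not None else None
    graph = io.build_combined_graph(chem, gap, roster=roster)
    return graph, meta, {}


def run_full_analysis(config: RunConfig, outdir) -> Path:
    """Run every stage and write the report bundle to ``outdir``.

    Writes intact metric tables, node/edge vulnerability tables,
    critical sets with grades, the pathway report, robustness
    summaries, group comparisons, correlations and
    ``manifest.json``.  Returns the output directory.  On any stage
    failure the partial outputs are removed and the error re-raised
    with the failing stage named.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(outdir)
    stage = "setup"
    tmpdir = Path(tempfile.mkdtemp(prefix="connvuln-", dir=outdir.parent if outdir.parent.exists() else None))
    try:
        stage = "ingest"
        graph, meta, synth_key = _load_inputs(config)
        log.info("ingest: %d neurons, %d connections", graph.n_nodes, graph.n_edges)

        stage = "model"
        model = ConnectomeVulnerability(
            graph,
            meta,
            clustering=config.clustering,
            efficiency_direction=config.efficiency_direction,
            node_multiplier=config.node_multiplier,
            sd_ddof=config.sd_ddof,
            grade_method=config.grade_method,
            long_range_quantile=config.long_range_quantile,
        )

        stage = "intact-metrics"
        node_metrics = node_metric_table(graph, model.options)
        node_metrics.to_csv(tmpdir / "intact_node_metrics.csv")
        edge_metrics = edge_metric_table(graph, meta)
        edge_metrics.to_csv(tmpdir / "intact_edge_metrics.csv", index=False)

        stage = "attacks"
        results = model.fit(targets="both")
        log.info(
            "attacks: %d node and %d edge attacks complete",
            len(results.node_table),
            len(results.edge_table),
        )
        results.node_table.to_csv(tmpdir / "node_vulnerability.csv")
        results.edge_table.to_csv(tmpdir / "edge_vulnerability.csv")

        stage = "criticality"
        results.critical_node_frame().to_csv(tmpdir / "critical_nodes.csv", index=False)
        results.critical_edge_frame().to_csv(tmpdir / "critical_edges.csv", index=False)
        summary = {
            "intact": results.intact.as_dict(),
            "node_multiplier": config.node_multiplier,
            "node_thresholds": {
                p: {"mean": cs.mean, "sd": cs.sd, "threshold": cs.threshold,
                    "n_critical": len(cs)}
                for p, cs in results.critical_nodes.items()
            },
            "n_critical_neurons": len(results.critical_node_union),
            "change_points": results.change_points,
            "edge_multiplier": results.edge_multiplier,
            "edge_thresholds": {
                p: {"mean": cs.mean, "sd": cs.sd, "threshold": cs.threshold,
                    "n_critical": len(cs)}
                for p, cs in results.critical_edges.items()
            },
            "n_critical_synapses": len(results.critical_edge_union),
        }

        stage = "pathways"
        pathways = results.pathways(property=config.pathway_property)
        pathway_records = [r for pw in pathways for r in pw.to_records()]
        pd.DataFrame(
            pathway_records,
            columns=[
                "component", "source", "target", "source_class", "target_class",
                "reciprocal", "inhibitory", "properties", "n_supports",
            ],
        ).to_csv(tmpdir / "pathways.csv", index=False)
        with open(tmpdir / "pathways.json", "w") as fh:
            json.dump(
                [
                    {
                        "component": pw.component_id,
                        "nodes": pw.nodes,
                        "node_classes": pw.node_classes,
                        "edges": [
                            {**e, "properties": sorted(e["properties"]),
                             "supports": [list(s) for s in e["supports"]]}
                            for e in pw.edges
                        ],
                    }
                    for pw in pathways
                ],
                fh,
                indent=2,
            )
        if meta is not None and "soma_x" in meta.columns:
            try:
                lr = results.long_range()
                summary["long_range"] = {
                    k: v for k, v in lr.items() if k != "flags"
                }
            except ValueError:
                pass

        stage = "robustness"
        pd.DataFrame({"leaf": find_leaves(graph)}).to_csv(
            tmpdir / "leaves.csv", index=False
        )
        coded = reachability_coding(graph)
        pd.DataFrame(coded, index=graph.nodes, columns=graph.nodes).to_csv(
            tmpdir / "reachability_coded.csv"
        )

        stage = "statistics"
        if results.critical_node_union:
            results.group_comparison("nodes").to_csv(
                tmpdir / "group_comparison_nodes.csv"
            )
        if results.critical_edge_union:
            results.group_comparison("edges").to_csv(
                tmpdir / "group_comparison_edges.csv"
            )
        corr = results.correlations("nodes")
        corr.columns = ["_".join(c) for c in corr.columns]
        corr.to_csv(tmpdir / "correlations_nodes.csv")

        stage = "manifest"
        if synth_key:
            summary["synthetic_key"] = synth_key
        with open(tmpdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=_jsonable)
        files = sorted(p for p in tmpdir.iterdir() if p.is_file())
        manifest = {
            "package": "connvuln",
            "version": __version__,
            "config": config.as_dict(),
            "checksums": {p.name: _sha256(p) for p in files},
        }
        with open(tmpdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

        outdir.mkdir(parents=True, exist_ok=True)
        for p in tmpdir.iterdir():
            shutil.move(str(p), outdir / p.name)
        tmpdir.rmdir()
        log.info("report bundle written to %s", outdir)
        return outdir
    except Exception as exc:
        shutil.rmtree(tmpdir, ignore_errors=True)
        raise RuntimeError(f"analysis failed at stage {stage!r}: {exc}") from exc


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def validate_manifest(outdir) -> bool:
    """Re-hash every bundled file against the manifest; True when intact."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    for name, digest in manifest["checksums"].items():
        if _sha256(outdir / name) != digest:
            return False
    return True
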