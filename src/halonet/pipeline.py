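"""End-to-end pipeline: read -> filter -> merge -> network -> annotate -> report.

One validated flat configuration drives the whole run and is echoed
verbatim into the run log, so a run is reproducible from its log alone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .dereplication import (
    AnnotationConfig,
    AnnotationResult,
    annotate_node,
    load_compounds,
    load_neutral_losses,
    report,
)
from .isotopes import IsotopePattern, find_isotopologue_partners
from .networking import MolecularNetwork, NetworkParams, build_network, export_graphml, merge_precursors
from .spectra import SpectrumSet, filter_peaks, read_mgf, read_mzml

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run"]


class PipelineConfig(BaseModel):
    """Flat run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    input: str
    out_dir: str = "halonet_out"
    format: str = "mgf"  # "mgf" or "mzml"
    precursor_tol: float = Field(0.002, gt=0)
    frag_tol: float = Field(0.02, gt=0)
    min_intensity: float = Field(50.0, ge=0)
    min_matched: int = Field(4, ge=1)
    ppm: float = Field(5.0, gt=0)
    score_threshold: float = Field(0.7, gt=0, le=1)
    topk: int = Field(10, ge=1)
    max_component: int = Field(100, ge=2)
    rt_tol: float = Field(0.2, gt=0)
    reference: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _node_clusters(
    spectra: SpectrumSet, rt_tol: float
) -> tuple[dict[str, IsotopePattern], set[str]]:
    """Group isotopologue nodes and build each group's observed cluster.

    Nodes that are isotope satellites of a lower-m/z co-eluting node are
    folded into that node's cluster; only group representatives are
    annotated (the deduplication the published networks describe for
    their +1/+2 satellite nodes).
    """
    nodes = [(s.precursor_mz, s.base_peak_intensity(), s.rt) for s in spectra]
    groups = find_isotopologue_partners(nodes, rt_tol=rt_tol)
    items = list(spectra)
    clusters: dict[str, IsotopePattern] = {}
    representatives: set[str] = set()
    for group in groups:
        rep = items[group[0]]
        representatives.add(rep.id)
        if len(group) > 1:
            mz = [items[i].precursor_mz for i in group]
            inten = [max(items[i].base_peak_intensity(), 1.0) for i in group]
            clusters[rep.id] = IsotopePattern(tuple(mz), tuple(inten))
    return clusters, representatives


def run(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns paths of all written outputs.

    Deterministic given the configuration.  Outputs: the GraphML
    network, node/edge/family tables (TSV) and a YAML run log echoing
    the configuration actually used.
    """
    in_path = Path(config.input)
    if not in_path.exists():
        raise FileNotFoundError(f"input not found: {in_path}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    reader = read_mzml if config.format == "mzml" else read_mgf
    raw = reader(in_path)
    logger.info("read %d spectra from %s", len(raw), in_path)

    filtered = [filter_peaks(s, config.min_intensity) for s in raw]
    filtered = [s for s in filtered if len(s) > 0]
    merged = merge_precursors(
        SpectrumSet(filtered, raw.metadata), config.precursor_tol
    )
    logger.info("%d consensus spectra after merging", len(merged))

    params = NetworkParams(
        frag_tol=config.frag_tol,
        score_threshold=config.score_threshold,
        min_matched=config.min_matched,
        topk=config.topk,
        max_component=config.max_component,
    )
    network = build_network(merged, params)

    reference = load_compounds(config.reference)
    losses = load_neutral_losses()
    ann_config = AnnotationConfig(ppm=config.ppm, frag_tol=config.frag_tol)
    clusters, representatives = _node_clusters(merged, config.rt_tol)
    annotations: dict[str, AnnotationResult] = {}
    for s in merged:
        if s.id not in representatives:
            continue
        annotations[s.id] = annotate_node(
            s, clusters.get(s.id), reference, ann_config, losses
        )
    for node_id, ann in annotations.items():
        summary = ""
        if ann.top_formula is not None:
            summary = f"{ann.top_formula.hill()} [{ann.tier}]"
            if ann.matches:
                summary += " " + ";".join(str(r.number) for r in ann.matches)
        network.graph.nodes[node_id]["annotation"] = summary

    node_df, family_df = report(network, annotations)

    paths = {
        "graphml": out_dir / "network.graphml",
        "nodes": out_dir / "nodes.tsv",
        "families": out_dir / "families.tsv",
        "edges": out_dir / "edges.tsv",
        "log": out_dir / "run.yaml",
    }
    export_graphml(network, paths["graphml"])
    node_df.to_csv(paths["nodes"], sep="\t", index=False)
    family_df.to_csv(paths["families"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"source": u, "target": v, "score": d["score"], "matches": d["matches"]}
            for u, v, d in network.graph.edges(data=True)
        ],
        columns=["source", "target", "score", "matches"],
    ).to_csv(paths["edges"], sep="\t", index=False)
    with open(paths["log"], "w") as fh:
        yaml.safe_dump(
            {"config": config.model_dump(), "n_spectra": len(raw),
             "n_nodes": network.node_count(), "n_families": len(network.families),
             "n_individual": len(network.individual_nodes)},
            fh, sort_keys=True,
        )
    logger.info(
        "network: %d nodes, %d families, %d individual",
        network.node_count(), len(network.families), len(network.individual_nodes),
    )
    return {k: str(v) for k, v in paths.items()}
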