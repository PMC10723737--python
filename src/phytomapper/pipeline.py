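"""End-to-end orchestration: simulate/load -> balance audit -> lenses ->
Mapper graphs -> enrichment, with a machine-readable run manifest.

Outputs land in a single flat run directory with stage-prefixed file names;
every file is a standard text format (CSV/TSV/GMT/GraphML/JSON).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .balance import combo_counts, downsample_top_combos
from .enrichment import (
    GeneSet,
    binomial_enrichment,
    flat_set_enrichment,
    lens_correlation,
    read_gmt,
    select_extremes,
    write_gmt,
)
from .errors import ConfigurationError
from .lens import fit_reference_model, residual_lens, select_reference
from .mapper import MapperGraph, MapperNode, mapper_pipeline, node_composition, simplify_graph
from .simulate import SimulationConfig, simulate_expression, simulate_metadata, write_truth

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "save_graph", "load_graph"]

_LENS_KINDS = ("tissue", "stress")


@dataclasses.dataclass
class PipelineConfig:
    """Single configuration object for :func:`run_all`.

    Either ``simulate`` (keyword overrides for :class:`SimulationConfig`) or
    ``inputs`` (paths to a metadata CSV and an orthogroup x sample
    expression CSV, plus optional reference/term GMTs) must be provided.
    """

    seed: int = 0
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None
    lens: dict[str, Any] = dataclasses.field(default_factory=dict)
    mapper: dict[str, Any] = dataclasses.field(default_factory=dict)
    enrichment: dict[str, Any] = dataclasses.field(default_factory=dict)
    balance: dict[str, Any] = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def save_graph(G: MapperGraph, graphml_path: str | Path, membership_path: str | Path) -> None:
    """GraphML (node attrs: interval, size, mean_lens; edge attr: weight)
    plus a node-membership TSV (node, sample)."""
    nx.write_graphml(G.to_networkx(), graphml_path)
    rows = [
        {"node": node.id, "sample": s}
        for node in G.nodes
        for s in sorted(node.members)
    ]
    pd.DataFrame(rows, columns=["node", "sample"]).to_csv(
        membership_path, sep="\t", index=False
    )


def load_graph(graphml_path: str | Path, membership_path: str | Path) -> MapperGraph:
    nxg = nx.read_graphml(graphml_path, node_type=int)
    mem = pd.read_csv(membership_path, sep="\t", dtype={"node": int, "sample": str})
    members = {nid: frozenset(grp["sample"]) for nid, grp in mem.groupby("node")}
    nodes = [
        MapperNode(
            id=nid,
            interval=int(data.get("interval", -1)),
            members=members.get(nid, frozenset()),
            mean_lens=float(data.get("mean_lens", float("nan"))),
        )
        for nid, data in sorted(nxg.nodes(data=True))
    ]
    edges = [(min(u, v), max(u, v), int(d.get("weight", 1))) for u, v, d in nxg.edges(data=True)]
    return MapperGraph(nodes=nodes, edges=sorted(edges))


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    """Simulate or read the metadata, matrix and gene sets."""
    ref_sets: list[GeneSet] = []
    term_sets: list[GeneSet] = []
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("seed", cfg.seed)
        sim = SimulationConfig(**sim_kwargs)
        meta = simulate_metadata(sim)
        X, truth = simulate_expression(sim, meta)
        meta.to_csv(outdir / "simulate_metadata.csv", index=False)
        X.to_csv(outdir / "simulate_expression.csv")
        write_truth(truth, outdir / "simulate_truth.json")
        ref_sets = [
            GeneSet("planted_stress", truth.stress_gene_ids, "planted stress-responsive module"),
            GeneSet("planted_tissue", truth.tissue_gene_ids, "planted photosynthesis-analog module"),
        ]
        write_gmt(ref_sets, outdir / "simulate_gene_sets.gmt")
    elif cfg.inputs is not None:
        meta = pd.read_csv(cfg.inputs["metadata"], dtype=str)
        X = pd.read_csv(cfg.inputs["expression"], index_col=0)
        if "reference_gmt" in cfg.inputs:
            ref_sets = read_gmt(cfg.inputs["reference_gmt"])
        if "term_gmt" in cfg.inputs:
            term_sets = read_gmt(cfg.inputs["term_gmt"])
    else:
        raise ConfigurationError("config must provide either 'simulate' or 'inputs'")
    return meta, X, ref_sets, term_sets


def run_all(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage; returns the run directory. Any stage failure raises
    with the stage name logged."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def emit(name: str) -> Path:
        outputs.append(name)
        return outdir / name

    stage = "inputs"
    try:
        meta, X, ref_sets, term_sets = _load_inputs(cfg, outdir)
        for name in ("simulate_metadata.csv", "simulate_expression.csv",
                     "simulate_truth.json", "simulate_gene_sets.gmt"):
            if (outdir / name).exists():
                outputs.append(name)

        stage = "balance"
        audit = combo_counts(meta)
        audit.counts.to_csv(emit("balance_combo_counts.tsv"), sep="\t", index=False)
        bal = cfg.balance
        if bal.get("apply", False):
            meta = downsample_top_combos(
                meta,
                top_k=bal.get("top_k", 30),
                cap=bal.get("cap", 30),
                seed=bal.get("seed", cfg.seed),
            )
            combo_counts(meta).counts.to_csv(
                emit("balance_combo_counts_downsampled.tsv"), sep="\t", index=False
            )
            meta.to_csv(emit("balance_metadata_downsampled.csv"), index=False)
            X = X[list(meta["sample"])]

        lens_cfg = cfg.lens
        map_cfg = cfg.mapper
        enr_cfg = cfg.enrichment
        universe = list(X.index)
        for kind in _LENS_KINDS:
            stage = f"lens[{kind}]"
            ref = select_reference(
                meta,
                kind,
                healthy_label=lens_cfg.get("healthy_label", "healthy"),
                leaf_label=lens_cfg.get("leaf_label", "leaf"),
            )
            model = fit_reference_model(
                X,
                ref,
                rank_rule=lens_cfg.get("rank_rule", "ev:0.95"),
                transform=lens_cfg.get("transform", "log2"),
            )
            f = residual_lens(X, model)
            f.rename_axis("sample").to_frame().to_csv(emit(f"lens_{kind}.tsv"), sep="\t")

            stage = f"mapper[{kind}]"
            graph = mapper_pipeline(
                X,
                f,
                n_intervals=map_cfg.get("n_intervals", 8),
                overlap=map_cfg.get("overlap", 0.3),
                eps=map_cfg.get("eps", 0.2),
                min_samples=map_cfg.get("min_samples", 3),
                metric=map_cfg.get("metric", "correlation"),
                transform=lens_cfg.get("transform", "log2"),
            )
            save_graph(graph, emit(f"mapper_{kind}.graphml"), emit(f"mapper_{kind}_membership.tsv"))
            pd.DataFrame(graph.noise, columns=["interval", "sample"]).to_csv(
                emit(f"mapper_{kind}_noise.tsv"), sep="\t", index=False
            )
            simplified = simplify_graph(graph, map_cfg.get("target_nodes", 18))
            save_graph(
                simplified,
                emit(f"mapper_{kind}_simplified.graphml"),
                emit(f"mapper_{kind}_simplified_membership.tsv"),
            )
            for factor in ("tissue", "stress", "family"):
                node_composition(simplified, meta, factor).to_csv(
                    emit(f"mapper_{kind}_simplified_composition_{factor}.tsv"), sep="\t"
                )

            stage = f"enrichment[{kind}]"
            corr = lens_correlation(X, f, transform=lens_cfg.get("transform", "log2"))
            corr.rename_axis("orthogroup").to_csv(emit(f"enrich_{kind}_correlation.tsv"), sep="\t")
            pos, neg = select_extremes(corr, tail_frac=enr_cfg.get("tail_frac", 0.025))
            pd.DataFrame({"orthogroup": pos}).to_csv(
                emit(f"enrich_{kind}_tail_positive.tsv"), sep="\t", index=False
            )
            pd.DataFrame({"orthogroup": neg}).to_csv(
                emit(f"enrich_{kind}_tail_negative.tsv"), sep="\t", index=False
            )
            if ref_sets:
                rows = []
                for tail_name, tail in (("positive", pos), ("negative", neg)):
                    for rs in ref_sets:
                        res = binomial_enrichment(tail, rs, universe, direction="greater")
                        rows.append(
                            {
                                "tail": tail_name,
                                "set": res.set_name,
                                "k": res.k,
                                "n": res.n,
                                "p0": res.p0,
                                "p": res.p_value,
                            }
                        )
                pd.DataFrame(rows).to_csv(emit(f"enrich_{kind}_binomial.tsv"), sep="\t", index=False)
            if term_sets:
                for tail_name, tail in (("positive", pos), ("negative", neg)):
                    flat_set_enrichment(tail, term_sets, universe).to_csv(
                        emit(f"enrich_{kind}_terms_{tail_name}.tsv"), sep="\t", index=False
                    )
    except Exception:
        logger.exception("pipeline stage %r failed", stage)
        raise

    cfg_dict = cfg.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "versions": {
            "phytomapper": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
        "outputs": sorted(set(outputs)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir
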