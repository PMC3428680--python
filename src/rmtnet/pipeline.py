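"""End-to-end pipeline: construction phase then analysis phase.

Construction: preprocessing (relative abundance, prevalence filter,
standardization) -> similarity matrix -> RMT threshold scan -> unweighted
network.  Analysis: per-node and whole-network topology, module detection,
Zi-Pi roles, module eigengenes and meta-modules, degree-preserving
randomization, and trait association.  Every stage writes deterministic
TSV artifacts (nodes sorted by id) plus a machine-readable summary; a
failing stage raises with the stage name and leaves earlier artifacts in
place.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .eigengene import eigengene_analysis
from .modules import detect_modules, node_roles
from .nullmodels import compare_to_random
from .rmt import detect_threshold
from .similarity import correlation_matrix, similarity_from_correlation
from .tables import (
    AbundanceTable,
    TraitTable,
    prevalence_filter,
    read_tables,
    standardize_rows,
    to_relative_abundance,
)
from .topology import Network, build_network, global_topology, node_topology
from .traits import (
    GSMatrix,
    connectivity_distance_matrix,
    gs_distance_matrix,
    mantel_test,
    module_trait_correlations,
    otu_significance,
)

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline", "export_network"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; serializable to/from JSON."""

    abundance_path: str | None = None
    trait_path: str | None = None
    out_dir: str = "rmtnet_run"
    relative: bool = True  # convert counts to relative abundance first
    min_samples: int = 7  # prevalence filter
    threshold: float | None = None  # fixed cutoff; None = RMT scan
    scan_start: float = 0.3
    coarse_step: float = 0.1
    fine_step: float = 0.01
    alpha: float = 0.01
    min_matrix_size: int = 50
    unfolding: str = "cubic_spline"
    module_method: str = "fast_greedy"
    min_module_size: int = 8
    n_random: int = 100
    mantel_permutations: int = 999
    eigengene_cut_height: float = 0.3
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def export_network(net: Network, node_table: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write SIF, edge-attribute TSV and node-attribute TSV (sorted, diffable).

    The SIF format ("idA pp idB", one line per edge) and the attribute
    tables load directly into Cytoscape.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if node_table.empty:
        raise ValueError("empty node table")
    edges = net.edges()
    sif = out / "network.sif"
    sif.write_text("".join(f"{a}\tpp\t{b}\n" for a, b, _ in edges))
    edge_rows = [
        (a, b, d.get("similarity", np.nan), d.get("sign", 1)) for a, b, d in edges
    ]
    edge_df = pd.DataFrame(edge_rows, columns=["source", "target", "similarity", "sign"])
    edge_path = out / "edges.tsv"
    edge_df.to_csv(edge_path, sep="\t", index=False)
    node_path = out / "nodes.tsv"
    node_table.sort_index().to_csv(node_path, sep="\t", index_label="node")
    return {"sif": sif, "edges": edge_path, "nodes": node_path}


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(
    config: RunConfig,
    table: AbundanceTable | None = None,
    traits: TraitTable | None = None,
) -> dict:
    """Run both phases end to end and write artifacts to ``config.out_dir``.

    Inputs come either from ``config.abundance_path``/``trait_path`` or
    directly as in-memory tables.  Returns a summary dict (also written as
    ``summary.json`` and ``summary.tsv``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    summary: dict = {"rmtnet_version": __version__, "seed": config.seed}

    @_stage("preprocess")
    def preprocess():
        nonlocal table, traits
        if table is None:
            if config.abundance_path is None:
                raise ValueError("no abundance table provided")
            table, traits_read = read_tables(config.abundance_path, config.trait_path)
            if traits is None:
                traits = traits_read
        if config.min_samples > table.n_samples:
            raise ValueError(
                f"min_samples={config.min_samples} exceeds sample count {table.n_samples}"
            )
        rel = to_relative_abundance(table) if table.stage == "raw" and config.relative else table
        filt = prevalence_filter(rel, config.min_samples)
        std = standardize_rows(filt)
        summary["n_otus_input"] = table.n_otus
        summary["n_otus_filtered"] = filt.n_otus
        summary["n_samples"] = filt.n_samples
        return rel, filt, std

    rel, filt, std = preprocess()

    @_stage("similarity")
    def similarity():
        corr = correlation_matrix(std)
        sim = similarity_from_correlation(corr)
        sim.write_tsv(out / "similarity.tsv")
        return sim

    sim = similarity()

    @_stage("threshold")
    def threshold():
        if config.threshold is not None:
            summary["threshold"] = config.threshold
            summary["threshold_source"] = "fixed"
            return config.threshold
        scan = detect_threshold(
            sim,
            start=config.scan_start,
            coarse_step=config.coarse_step,
            fine_step=config.fine_step,
            alpha=config.alpha,
            min_matrix_size=config.min_matrix_size,
            unfolding=config.unfolding,
        )
        trace = pd.DataFrame(
            scan.trace_rows(),
            columns=["phase", "threshold", "p", "chi2", "dof", "accepted"],
        )
        trace.to_csv(out / "threshold_scan.tsv", sep="\t", index=False)
        summary["threshold"] = scan.final_threshold
        summary["threshold_source"] = "rmt_scan"
        return scan.final_threshold

    s_t = threshold()

    @_stage("network")
    def network():
        net = build_network(sim, s_t)
        summary["n_nodes"] = net.n
        summary["n_links"] = net.L
        return net

    net = network()

    @_stage("topology")
    def topology():
        nodes_df = node_topology(net)
        glob = global_topology(net)
        scalars = glob.scalar_indices()
        scalars["power_law_exponent"] = glob.power_law.exponent
        scalars["power_law_r2"] = glob.power_law.r2
        scalars["scaling_law_exponent"] = glob.scaling_law.exponent
        scalars["scaling_law_r2"] = glob.scaling_law.r2
        pd.Series(scalars, name="value").to_csv(
            out / "global_topology.tsv", sep="\t", header=True, index_label="index"
        )
        summary["global_topology"] = {k: float(v) for k, v in scalars.items()}
        return nodes_df

    nodes_df = topology()

    @_stage("modules")
    def modules_stage():
        part = detect_modules(net, method=config.module_method, seed=config.seed)
        roles = node_roles(net, part)
        part.to_frame().to_csv(out / "modules.tsv", sep="\t")
        roles.sort_index().to_csv(out / "roles.tsv", sep="\t", index_label="node")
        summary["modularity"] = part.modularity
        summary["n_modules"] = part.n_modules
        role_counts = roles["role"].value_counts().to_dict()
        summary["role_counts"] = {k: int(v) for k, v in role_counts.items()}
        return part, roles

    part, roles = modules_stage()

    @_stage("eigengenes")
    def eigengenes_stage():
        big = part.modules_of_size(config.min_module_size)
        members = {b: part.members(b) for b in big}
        members = {b: m for b, m in members.items() if len(m) >= 2}
        if len(members) < 1:
            summary["eigengene_modules"] = 0
            return None
        es = eigengene_analysis(std, members, cut_height=config.eigengene_cut_height)
        es.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t", index_label="module")
        mm = pd.concat(
            {b: s for b, s in es.memberships.items()}, names=["module", "node"]
        )
        mm.to_frame("MM").to_csv(out / "module_membership.tsv", sep="\t")
        if es.meta_modules is not None:
            pd.Series(es.meta_modules, name="meta_module").to_csv(
                out / "meta_modules.tsv", sep="\t", index_label="module"
            )
        summary["eigengene_modules"] = len(members)
        summary["variance_explained"] = {
            int(b): float(v) for b, v in es.variance_explained.items()
        }
        return es

    es = eigengenes_stage()

    @_stage("randomization")
    def randomization():
        if config.n_random < 1:
            return None
        stats_ = compare_to_random(
            net,
            n_random=config.n_random,
            seed=config.seed,
            module_method=config.module_method,
        )
        stats_.table.to_csv(out / "random_comparison.tsv", sep="\t")
        summary["modularity_z"] = (
            float(stats_.table.loc["M", "Z"]) if "M" in stats_.table.index else None
        )
        return stats_

    randomization()

    @_stage("traits")
    def traits_stage():
        if traits is None:
            return None
        gs = otu_significance(std, traits)
        gs.to_frame().to_csv(out / "otu_significance.tsv", sep="\t", index_label="OTU")
        network_nodes = [o for o in net.node_ids if o in gs.otu_ids]
        gs_net = gs.to_frame().loc[network_nodes]
        k = nodes_df.loc[network_nodes, "k"].to_numpy(float)
        usable = [t for t in gs_net.columns if not gs_net[t].isna().any()]
        if len(network_nodes) >= 4 and usable:
            dk = connectivity_distance_matrix(k)
            dgs = gs_distance_matrix(
                GSMatrix(network_nodes, usable, gs_net[usable].to_numpy(float))
            )
            mt = mantel_test(dk, dgs, n_perm=config.mantel_permutations, seed=config.seed)
            summary["mantel_r"] = mt.r
            summary["mantel_p"] = mt.p
        if es is not None:
            r_df, p_df = module_trait_correlations(es.eigengenes, traits)
            r_df.to_csv(out / "module_trait_r.tsv", sep="\t", index_label="module")
            p_df.to_csv(out / "module_trait_p.tsv", sep="\t", index_label="module")
        return gs

    traits_stage()

    @_stage("export")
    def export():
        node_table = nodes_df.join(roles[["module", "z", "P", "role"]])
        export_network(net, node_table, out)

    export()

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    flat = {
        k: v for k, v in summary.items() if not isinstance(v, dict)
    }
    pd.Series(flat).to_csv(out / "summary.tsv", sep="\t", header=False)
    return summary
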