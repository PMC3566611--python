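"""End-to-end orchestration: counts → bias → networks → summaries → conflict.

A run takes either a raw count table (plus sample sheet) or a precomputed
bias table, together with one or more named groups of edge-list files
(typically ``strict`` and ``permissive``).  For every group it merges the
edge files, restricts the network to genes carrying a bias value,
classifies genes under the four-fold network scheme, writes the 13-row
subnetwork summary table with power-law tail fits, writes per-subnetwork
degree distributions, and detects conflict candidates under the stringent
scheme.  Outputs are sorted and byte-deterministic for fixed inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import conflict as _conflict
from . import degree_stats, io, network as _network
from .network import ANY_CLASS, CLASS_CODES, InteractionNetwork, SubnetworkSummary
from .sexbias import (CONFLICT_SCHEME, NETWORK_SCHEME, ClassificationScheme,
                      classify_table, compute_bias_table)

__all__ = ["PipelineConfig", "run_pipeline", "write_table1_summary",
           "SUBNETWORK_CODES", "DEFAULT_FIT_CUTOFFS"]

log = logging.getLogger(__name__)

#: The 13 X–Y subnetwork codes reported, in canonical order.
SUBNETWORK_CODES = ["A-A", "U-A", "U-U", "U-F", "U-M",
                    "F-A", "F-U", "F-F", "F-M",
                    "M-A", "M-U", "M-F", "M-M"]

#: Default per-subnetwork lower degree cutoffs for the tail fit.
DEFAULT_FIT_CUTOFFS = {
    "A-A": 25, "U-A": 25, "U-U": 25, "U-F": 5, "U-M": 5,
    "F-A": 25, "F-U": 20, "F-F": 10, "F-M": 5,
    "M-A": 15, "M-U": 15, "M-F": 5, "M-M": 5,
}


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    edge_files: dict[str, list[str]]  # group name -> edge-list paths
    counts_path: str | None = None
    sample_sheet_path: str | None = None
    bias_path: str | None = None  # precomputed bias table (alternative route)
    out_dir: str = "sexnet_out"
    network_scheme: ClassificationScheme = NETWORK_SCHEME
    conflict_scheme: ClassificationScheme = CONFLICT_SCHEME
    bin_size: int = 5
    fit_cutoffs: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FIT_CUTOFFS))
    degree_mode: str = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.edge_files:
            raise ValueError("at least one edge-file group is required")
        have_counts = self.counts_path and self.sample_sheet_path
        if not have_counts and not self.bias_path:
            raise ValueError(
                "provide counts_path + sample_sheet_path or bias_path")
        if any(c < 1 for c in self.fit_cutoffs.values()):
            raise ValueError("fit cutoffs must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        schemes = {}
        for key in ("network_scheme", "conflict_scheme"):
            if key in raw:
                schemes[key] = ClassificationScheme(**raw.pop(key))
        return cls(**raw, **schemes)


def _config_digest(cfg: PipelineConfig) -> str:
    blob = json.dumps({
        "edge_files": cfg.edge_files,
        "counts_path": cfg.counts_path,
        "sample_sheet_path": cfg.sample_sheet_path,
        "bias_path": cfg.bias_path,
        "network_scheme": [cfg.network_scheme.biased_cutoff,
                           cfg.network_scheme.unbiased_cutoff],
        "conflict_scheme": [cfg.conflict_scheme.biased_cutoff,
                            cfg.conflict_scheme.unbiased_cutoff],
        "bin_size": cfg.bin_size,
        "fit_cutoffs": cfg.fit_cutoffs,
        "degree_mode": cfg.degree_mode,
        "seed": cfg.seed,
    }, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns a report bundle keyed by group."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.bias_path:
        bias = io.read_bias_table(cfg.bias_path)
        log.info("loaded %d precomputed bias values", len(bias))
    else:
        expr = io.read_expression(cfg.counts_path, cfg.sample_sheet_path)
        bias, inter = compute_bias_table(expr)
        log.info("computed bias for %d genes (of %d; global bias B=%.4f)",
                 len(bias), len(expr.gene_ids), inter.global_bias)
    io.write_bias_table(bias, out / "gene_bias.txt")

    bundle: dict = {"bias": bias, "groups": {}}
    for group, paths in cfg.edge_files.items():
        bundle["groups"][group] = _run_group(cfg, group, paths, bias, out)

    manifest = {
        "sexnet_version": __version__,
        "config_sha256": _config_digest(cfg),
        "n_bias_genes": int(len(bias)),
        "groups": {g: {"n_nodes": r["network"].n_nodes,
                       "n_edges": r["network"].n_edges}
                   for g, r in bundle["groups"].items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle


def _run_group(cfg: PipelineConfig, group: str, paths, bias: pd.Series,
               out: Path) -> dict:
    nets = [_network.read_edge_list(p) for p in paths]
    merged = _network.merge_networks(nets)
    log.info("[%s] merged %d file(s): %d nodes, %d edges",
             group, len(paths), merged.n_nodes, merged.n_edges)
    net = _network.restrict_nodes(merged, set(bias.index))
    log.info("[%s] restricted to scored genes: %d nodes, %d edges",
             group, net.n_nodes, net.n_edges)

    labels = classify_table(bias, cfg.network_scheme)
    code_of = {"male": "M", "female": "F", "unbiased": "U",
               "unclassified": "X"}
    node_labels = {g: code_of[labels[g]] for g in net.graph.nodes}

    summaries: list[SubnetworkSummary] = []
    for code in SUBNETWORK_CODES:
        x, y = code.split("-")
        summary = _network.summarize_subnetwork(
            net, node_labels, x, y, degree_mode=cfg.degree_mode)
        cutoff = cfg.fit_cutoffs.get(code, 1)
        degrees = _network.subnetwork_degrees(
            net, node_labels, x, y, degree_mode=cfg.degree_mode)
        fit = None
        if degrees:
            dist = degree_stats.bin_degrees(degrees, bin_size=cfg.bin_size)
            degree_stats.write_distribution(
                dist, out / f"degree_dist_{group}_{code}.tsv")
            try:
                fit = degree_stats.fit_power_law(dist, cutoff)
            except degree_stats.InsufficientDataError:
                log.warning("[%s] %s: too few bins for tail fit", group, code)
        if fit is not None:
            summary = SubnetworkSummary(
                **{**summary.__dict__,
                   "exponent": fit.exponent, "cutoff": fit.cutoff})
        summaries.append(summary)
    write_table1_summary(summaries, out / f"subnetwork_summary_{group}.tsv")

    report = _conflict.conflict_report(net, bias, cfg.conflict_scheme)
    _conflict.write_gene_list(report.indirect,
                              out / f"indirect_sexconflict_{group}.txt")
    _conflict.write_gene_list(report.direct_male,
                              out / f"direct_sexconflict_m_{group}.txt")
    _conflict.write_gene_list(report.direct_female,
                              out / f"direct_sexconflict_f_{group}.txt")
    _conflict.write_pair_list(report.direct_pairs,
                              out / f"direct_pairs_{group}.tsv")
    log.info("[%s] conflict: %d indirect genes, %d direct pairs",
             group, len(report.indirect), len(report.direct_pairs))
    return {"network": net, "labels": node_labels,
            "summaries": summaries, "conflict": report}


def write_table1_summary(summaries, path) -> None:
    """TSV with one row per subnetwork code and the nine statistics."""
    codes = [s.network_code for s in summaries]
    missing = [c for c in SUBNETWORK_CODES if c not in codes]
    if missing:
        raise ValueError(f"missing subnetwork codes: {missing}")
    modes = {s.degree_mode for s in summaries}
    with open(path, "w") as fh:
        fh.write(f"# degree_mode: {', '.join(sorted(modes))}\n")
        fh.write("network\tnodes\tedges\tedges_per_node\tmean_degree\t"
                 "sd_degree\tq25_degree\tq75_degree\texponent\tcutoff\n")
        for s in summaries:
            ratio = "NA" if s.n_nodes == 0 else f"{s.edges_per_node:.6g}"
            exp = "NA" if s.exponent is None else f"{s.exponent:.6g}"
            cut = "NA" if s.cutoff is None else str(s.cutoff)
            fh.write(f"{s.network_code}\t{s.n_nodes}\t{s.n_edges}\t{ratio}\t"
                     f"{s.mean_degree:.6g}\t{s.sd_degree:.6g}\t"
                     f"{s.q25_degree:.6g}\t{s.q75_degree:.6g}\t{exp}\t{cut}\n")


def read_table1_summary(path) -> pd.DataFrame:
    """Round-trip reader for the summary TSV."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
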