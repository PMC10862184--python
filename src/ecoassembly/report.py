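"""Pipeline orchestration and paper-style summary tables.

Percentages follow the printed convention: half-up rounding to 1 decimal, or
2 decimals when the value is below 1% (so 164 of 26,308 OTUs prints as 0.62
and 24,230 of 26,308 as 92.1).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._util import format_percent, logger, spawn_seed, write_tsv_with_provenance
from .community import (
    CLASSES,
    alpha_diversity,
    bray_curtis,
    classify_abundance,
    faith_pd,
    rarefy,
    relative_abundance_by_rank,
    subset_by_class,
)
from .io import (
    CommunityTable,
    align_inputs,
    read_community_table,
    read_metadata,
    read_taxonomy,
    read_tree,
)

__all__ = ["PipelineConfig", "summarize_classes", "class_percentage", "run_pipeline"]


def class_percentage(count: int, total: int, decimals: int | None = None) -> float:
    """A printed percentage: 100*count/total, half-up rounded.

    With ``decimals`` None the mixed printed convention applies (1 decimal,
    2 when below 1%); otherwise the stated number of decimals (1 or 2).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    pct = 100.0 * count / total
    if decimals is None:
        return format_percent(pct)
    if decimals not in (1, 2):
        raise ValueError("decimals must be 1 or 2")
    from ._util import round_half_up

    return round_half_up(pct, decimals)


def summarize_classes(
    table: CommunityTable | None = None,
    classification=None,
    counts: dict[str, int] | None = None,
    total: int | None = None,
    decimals: int | None = None,
) -> pd.DataFrame:
    """Per-class OTU counts, OTU percentages and summed relative abundance.

    Either pass a table + classification (full summary) or plain class counts
    with a total (percentage arithmetic only, e.g. for printed counts).
    """
    if counts is not None:
        if total is None:
            total = sum(counts.values())
        rows = {
            c: {"n_otus": n, "otu_pct": class_percentage(n, total, decimals)}
            for c, n in counts.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index")
    if table is None or classification is None:
        raise ValueError("need either counts or (table, classification)")
    total = table.n_otus
    reads_total = int(table.counts.sum())
    present = set(table.otu_ids)
    rows = {}
    for c in CLASSES:
        otus = [o for o in classification.otus_of(c) if o in present]
        n = len(otus)
        reads = int(table.data[otus].to_numpy().sum()) if otus else 0
        rows[c] = {
            "n_otus": n,
            "otu_pct": class_percentage(n, total) if n else 0.0,
            "reads_pct": format_percent(100.0 * reads / reads_total) if reads_total else 0.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class PipelineConfig:
    table: str
    metadata: str
    tree: str | None = None
    taxonomy: str | None = None
    rarefaction_depth: int = 10_000
    abundant_threshold: float = 0.001
    rare_threshold: float = 0.0001
    group_column: str = "layer"
    assembly_n_null: int = 1000
    assembly_distance_threshold: float = 1.7
    assembly_min_bin_size: int = 36
    network_r_threshold: float = 0.3
    network_p_threshold: float = 0.05
    network_n_bootstrap: int = 100
    network_prevalence: float = 1 / 3
    mantel_permutations: int = 999
    seed: int = 0
    outdir: str = "ecoassembly_out"
    stages: tuple[str, ...] = (
        "classify", "diversity", "spatial", "assembly", "network", "report"
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        cfg = cls(**payload)
        for key in ("table", "metadata", "tree", "taxonomy"):
            val = getattr(cfg, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"config {key}: no such file {val!r}")
        return cfg


@dataclass
class StudySummary:
    class_summary: pd.DataFrame | None = None
    network_summaries: dict = field(default_factory=dict)
    assembly_partitions: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> StudySummary:
    """Run align -> rarefy -> classify -> diversity -> spatial -> assembly ->
    network -> report; a failure in one optional stage is recorded and does
    not abort earlier completed outputs."""
    from . import assembly as asm
    from . import network as net
    from . import spatial as sp

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary = StudySummary()
    seed = config.seed

    def stage(name):
        def wrap(fn):
            if name not in config.stages and name not in ("align", "rarefy"):
                return None
            t0 = time.perf_counter()
            try:
                res = fn()
                logger.info("stage=%s elapsed=%.2fs seed=%d", name,
                            time.perf_counter() - t0, seed)
                return res
            except Exception as exc:
                logger.error("stage=%s failed: %s (remedy: check stage inputs)", name, exc)
                summary.failures[name] = str(exc)
                return None
        return wrap

    table = read_community_table(config.table)
    metadata = read_metadata(config.metadata)
    tree = read_tree(config.tree) if config.tree else None
    taxonomy = read_taxonomy(config.taxonomy) if config.taxonomy else None
    if tree is None:
        logger.info("run_pipeline: no tree configured; assembly and PD stages skipped")

    working = align_inputs(table, tree=tree, metadata=metadata, taxonomy=taxonomy)
    table = rarefy(working.table, config.rarefaction_depth, seed=spawn_seed(seed, 1))
    metadata = working.metadata.select_samples(table.sample_ids)
    write_tsv_with_provenance(out / "rarefied_table.tsv", table.data.T, seed=seed,
                              index_label="#OTU ID")

    classification = classify_abundance(
        table, config.abundant_threshold, config.rare_threshold
    )
    write_tsv_with_provenance(out / "classification.tsv", classification.to_frame(),
                              seed=seed, index_label="otu_id")

    def _diversity():
        alpha = alpha_diversity(table)
        if working.tree is not None:
            alpha["faith_pd"] = faith_pd(table, working.tree)
        write_tsv_with_provenance(out / "alpha_diversity.tsv", alpha, seed=seed,
                                  index_label="sample")
        bc = bray_curtis(table)
        write_tsv_with_provenance(out / "bray_curtis.tsv", bc.to_dataframe(), seed=seed,
                                  index_label="sample")
        return alpha, bc

    div = stage("diversity")(_diversity)

    def _spatial():
        bc = div[1] if div else bray_curtis(table)
        geo = sp.geographic_distance(metadata)
        rows = []
        mres = sp.mantel(bc, geo, config.mantel_permutations, seed=spawn_seed(seed, 2))
        rows.append({"pair": "bray_curtis~geographic", "r": mres.r, "p": mres.p,
                     "n_permutations": mres.n_permutations})
        env = metadata.environment()
        for col in env.columns:
            vals = env[col].to_numpy(dtype=float)
            import numpy as np
            d = np.abs(vals[:, None] - vals[None, :])
            d[np.isnan(d)] = np.nan
            env_dm = type(bc)(d, metadata.sample_ids, metric=f"euclidean_{col}")
            r = sp.mantel(bc, env_dm, config.mantel_permutations,
                          seed=spawn_seed(seed, 3, hash(col) & 0xFFFF))
            rows.append({"pair": f"bray_curtis~{col}", "r": r.r, "p": r.p,
                         "n_permutations": r.n_permutations})
        write_tsv_with_provenance(out / "mantel_results.tsv",
                                  pd.DataFrame(rows).set_index("pair"), seed=seed)
        breadth = sp.levins_breadth(table)
        write_tsv_with_provenance(out / "niche_breadth.tsv", breadth.to_frame(),
                                  seed=seed, index_label="otu_id")
        if taxonomy is not None:
            for cls in ("abundant", "rare"):
                try:
                    sub = subset_by_class(table, classification, cls)
                except ValueError:
                    continue
                phyla = relative_abundance_by_rank(sub, taxonomy, "phylum")
                diff = sp.differential_abundance(phyla, metadata.data[config.group_column])
                write_tsv_with_provenance(out / f"differential_taxa_{cls}.tsv", diff,
                                          seed=seed)
        return True

    stage("spatial")(_spatial)

    def _assembly():
        results = asm.run_assembly_analysis(
            table, working.tree, classification, metadata,
            distance_threshold=config.assembly_distance_threshold,
            min_bin_size=config.assembly_min_bin_size,
            n_null=config.assembly_n_null, seed=spawn_seed(seed, 4),
        )
        rows = {}
        for group, res in results.items():
            part = res["partition"]
            rows[group] = {**part.fractions, "n_pairs": part.n_pairs, "n_bins": part.n_bins}
            summary.assembly_partitions[group] = part
        write_tsv_with_provenance(out / "assembly_partition.tsv",
                                  pd.DataFrame.from_dict(rows, orient="index"),
                                  seed=seed, index_label="group",
                                  n_null=config.assembly_n_null,
                                  bnri_threshold=1.96, rc_threshold=0.95)
        scores = pd.concat({g: r["scores"] for g, r in results.items()}, names=["group"])
        write_tsv_with_provenance(out / "pair_scores.tsv", scores.reset_index(level=1, drop=True),
                                  seed=seed)
        return results

    stage("assembly")(_assembly)

    def _network():
        layers = metadata.data[config.group_column]
        for layer in sorted(layers.unique()):
            samples = [s for s in table.sample_ids if layers[s] == layer]
            if len(samples) < 4:
                continue
            sub = net.prevalence_filter(table.select_samples(samples),
                                        config.network_prevalence)
            est = net.sparcc_correlations(sub, seed=spawn_seed(seed, 5))
            est = net.sparcc_pvalues(sub, est, n_bootstrap=config.network_n_bootstrap,
                                     seed=spawn_seed(seed, 6))
            g = net.build_network(est, classification, taxonomy,
                                  config.network_r_threshold, config.network_p_threshold)
            ns = net.summarize_network(g)
            summary.network_summaries[layer] = ns
            edges = pd.DataFrame(
                [{"u": u, "v": v, "rho": d["correlation"], "p": d["p"], "sign": d["sign"]}
                 for u, v, d in g.edges(data=True)]
            )
            write_tsv_with_provenance(out / f"network_edges_{layer}.tsv", edges, seed=seed)
            nodes = pd.DataFrame(
                {"class": {v: g.nodes[v]["abundance_class"] for v in g.nodes},
                 "phylum": {v: g.nodes[v]["phylum"] for v in g.nodes},
                 "degree": ns.degree, "closeness": ns.closeness}
            )
            write_tsv_with_provenance(out / f"network_nodes_{layer}.tsv", nodes,
                                      seed=seed, index_label="otu_id")
            import networkx as nx
            nx.write_graphml(g, out / f"network_{layer}.graphml")
        return True

    stage("network")(_network)

    def _report():
        cs = summarize_classes(table, classification)
        summary.class_summary = cs
        write_tsv_with_provenance(out / "class_summary.tsv", cs, seed=seed,
                                  index_label="class")
        manifest = {p.name: p.stat().st_size for p in sorted(out.iterdir())}
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
        return cs

    stage("report")(_report)
    summary.outputs = {p.name: str(p) for p in sorted(out.iterdir())}
    return summary
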