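"""Descriptive community layer: rarefaction, abundant/rare classification,
taxonomic aggregation, alpha-diversity, Faith's PD and Bray-Curtis.

Classification uses MEAN relative abundance across all samples (computed
after rarefaction in the pipeline), with strict inequalities at both
thresholds: abundant > 0.1%, rare < 0.01%, boundary values are moderate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from ._util import logger
from .io import CommunityTable, DissimilarityMatrix, TaxonomyTable

__all__ = [
    "AbundanceClassification",
    "rarefy",
    "classify_abundance",
    "relative_abundance_by_rank",
    "alpha_diversity",
    "faith_pd",
    "bray_curtis",
    "subset_by_class",
]

CLASSES = ("abundant", "moderate", "rare")


@dataclass
class AbundanceClassification:
    """Per-OTU abundance class plus the thresholds that produced it."""

    classes: pd.Series  # otu_id -> {abundant, moderate, rare}
    mean_relative_abundance: pd.Series
    abundant_threshold: float = 0.001
    rare_threshold: float = 0.0001
    basis: str = "mean_relative_abundance"

    def __post_init__(self) -> None:
        if not (0.0 < self.rare_threshold < self.abundant_threshold < 1.0):
            raise ValueError("need 0 < rare_threshold < abundant_threshold < 1")
        bad = set(self.classes.unique()) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown class label(s): {bad}")

    def otus_of(self, cls: str) -> list[str]:
        if cls not in CLASSES:
            raise ValueError(f"class must be one of {CLASSES}")
        return list(self.classes.index[self.classes == cls])

    def counts(self) -> dict[str, int]:
        return {c: int((self.classes == c).sum()) for c in CLASSES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean_rel_abund": self.mean_relative_abundance, "class": self.classes}
        )


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped and logged; the draw is
    multivariate hypergeometric, deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_totals()
    keep = totals[totals >= depth].index
    kept = set(keep)
    dropped = [s for s in table.sample_ids if s not in kept]
    if not len(keep):
        raise ValueError(f"all samples have fewer than {depth} reads")
    if dropped:
        logger.info("rarefy: dropped %d sample(s) below depth %d: %s",
                    len(dropped), depth, ", ".join(dropped))
    rng = np.random.default_rng(seed)
    rows = []
    for s in keep:
        counts = table.data.loc[s].to_numpy()
        if counts.sum() == depth:
            rows.append(counts.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    out = pd.DataFrame(np.vstack(rows), index=list(keep), columns=table.otu_ids)
    return CommunityTable(out)


def classify_abundance(
    table: CommunityTable,
    abundant_threshold: float = 0.001,
    rare_threshold: float = 0.0001,
) -> AbundanceClassification:
    """Partition OTUs into abundant / moderate / rare by mean relative abundance."""
    if table.n_otus == 0 or table.n_samples == 0:
        raise ValueError("empty community table")
    mean_rel = table.relative_abundance().mean(axis=0)
    cls = pd.Series("moderate", index=mean_rel.index, dtype=object)
    cls[mean_rel > abundant_threshold] = "abundant"
    cls[mean_rel < rare_threshold] = "rare"
    return AbundanceClassification(
        classes=cls,
        mean_relative_abundance=mean_rel,
        abundant_threshold=abundant_threshold,
        rare_threshold=rare_threshold,
    )


def relative_abundance_by_rank(
    table: CommunityTable, taxonomy: TaxonomyTable, rank: str
) -> pd.DataFrame:
    """Samples x taxa fraction matrix at a taxonomic rank; missing -> Unclassified."""
    if rank not in taxonomy.data.columns:
        raise ValueError(f"rank {rank!r} not present in taxonomy")
    labels = pd.Series(
        [
            (taxonomy.data.at[o, rank] if o in taxonomy.data.index else "")
            for o in table.otu_ids
        ],
        index=table.otu_ids,
    ).replace("", "Unclassified")
    rel = table.relative_abundance()
    return rel.T.groupby(labels).sum().T


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

ACE_RARE_CUTOFF = 10


def _chao1(counts: np.ndarray) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _ace(counts: np.ndarray, cutoff: int = ACE_RARE_CUTOFF) -> float:
    present = counts[counts > 0]
    rare = present[present <= cutoff]
    abund = present[present > cutoff]
    s_rare, s_abund = len(rare), len(abund)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        # all rare taxa are singletons: coverage undefined, fall back to Chao1
        return _chao1(counts)
    fi = np.bincount(rare.astype(int), minlength=cutoff + 1)[1:]
    i = np.arange(1, cutoff + 1)
    gamma = max(
        (s_rare / c_ace) * float((i * (i - 1) * fi).sum()) / (n_rare * (n_rare - 1)) - 1.0
        if n_rare > 1
        else 0.0,
        0.0,
    )
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma


def alpha_diversity(table: CommunityTable) -> pd.DataFrame:
    """Observed, Chao1, ACE, Shannon (nats), Simpson (1 - sum p^2) per sample.

    Empty samples yield NaN for every index and are flagged in the log.
    """
    records = {}
    for s in table.sample_ids:
        counts = table.data.loc[s].to_numpy()
        total = counts.sum()
        if total == 0:
            logger.warning("alpha_diversity: sample %r is empty; indices undefined", s)
            records[s] = dict.fromkeys(
                ("observed", "chao1", "ace", "shannon", "simpson"), np.nan
            )
            continue
        p = counts[counts > 0] / total
        records[s] = {
            "observed": int((counts > 0).sum()),
            "chao1": _chao1(counts),
            "ace": _ace(counts),
            "shannon": float(-(p * np.log(p)).sum()),
            "simpson": float(1.0 - (p ** 2).sum()),
        }
    return pd.DataFrame.from_dict(records, orient="index").loc[table.sample_ids]


def faith_pd(table: CommunityTable, tree: TreeNode) -> pd.Series:
    """Faith's phylogenetic diversity per sample.

    PD is the total branch length of the minimal subtree spanning a sample's
    present tips and the root (rooted convention: the tip-to-root path of a
    single-taxon sample counts).
    """
    tips = {t.name for t in tree.tips()}
    missing = [o for o in table.otu_ids if o not in tips]
    if missing:
        raise ValueError(f"OTU(s) absent from tree: {missing[:5]}")
    # per tip: indices of ancestor edges (including the tip edge)
    node_len: list[float] = []
    node_index: dict[int, int] = {}
    for node in tree.traverse(include_self=True):
        node_index[id(node)] = len(node_len)
        node_len.append(float(node.length or 0.0))
    lengths = np.asarray(node_len)
    tip_paths = {}
    for tip in tree.tips():
        path = [node_index[id(tip)]]
        for anc in tip.ancestors():
            path.append(node_index[id(anc)])
        tip_paths[tip.name] = np.asarray(path, dtype=np.intp)

    out = {}
    n_edges = len(node_len)
    for s in table.sample_ids:
        present = table.data.columns[table.data.loc[s] > 0]
        mask = np.zeros(n_edges, dtype=bool)
        for o in present:
            mask[tip_paths[o]] = True
        out[s] = float(lengths[mask].sum())
    return pd.Series(out, name="faith_pd").loc[table.sample_ids]


def bray_curtis(table: CommunityTable) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarity; pairs with an all-zero sample are NaN."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = table.counts.astype(float)
    zero = x.sum(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = squareform(pdist(x, metric="braycurtis"))
    if zero.any():
        logger.warning("bray_curtis: %d all-zero sample(s); pairs flagged NaN", zero.sum())
        mat[zero, :] = np.nan
        mat[:, zero] = np.nan
        np.fill_diagonal(mat, 0.0)
    return DissimilarityMatrix(mat, table.sample_ids, metric="braycurtis")


def subset_by_class(
    table: CommunityTable, classification: AbundanceClassification, cls: str
) -> CommunityTable:
    """Restrict the table to OTUs of one abundance class; samples unchanged."""
    otus = classification.otus_of(cls)
    present = set(table.otu_ids)
    otus = [o for o in otus if o in present]
    if not otus:
        raise ValueError(f"no OTU classified {cls!r}")
    sub = table.select_otus(otus)
    empty = sub.sample_totals() == 0
    if empty.any():
        logger.warning("subset_by_class(%s): %d all-zero sample(s) retained",
                       cls, int(empty.sum()))
    return sub
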