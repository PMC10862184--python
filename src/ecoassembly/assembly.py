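"""Phylogenetic-bin null-model partitioning of community assembly processes.

The observed OTUs are divided into phylogenetic bins (clades whose maximum
within-clade patristic distance stays below a threshold, with small bins
merged into their phylogenetically nearest neighbour). Within each bin and
for every sample pair, two null-standardised scores are computed:

* beta-NRI: the z-score of the abundance-weighted beta mean nearest taxon
  distance (betaMNTD) against a taxa-shuffle null that permutes tip labels
  within the bin, abundances held fixed.
* modified Raup-Crick (RC, on Bray-Curtis): observed Bray-Curtis compared to
  null assemblages that preserve each sample's richness and total abundance
  in the bin, drawing species with probability proportional to occupancy
  frequency and filling individuals proportional to total relative abundance;
  RC = 2 * [P(null < obs) + 0.5 * P(null = obs)] - 1.

Each pair-bin comparison is then classified with the fixed thresholds
betaNRI < -1.96 (homogeneous selection), betaNRI > +1.96 (heterogeneous
selection), otherwise RC < -0.95 (homogenizing dispersal), RC > +0.95
(dispersal limitation), else drift; classifications are aggregated with bin
relative-abundance weights and averaged over pairs so the five fractions sum
to one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._util import logger, spawn_seed
from .io import CommunityTable

__all__ = [
    "PhyloBinSet",
    "AssemblyPartition",
    "PROCESSES",
    "phylo_bins",
    "beta_mntd",
    "beta_nri",
    "raup_crick",
    "null_model_scores",
    "partition_processes",
    "run_assembly_analysis",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "drift",
)

BNRI_THRESHOLD = 1.96
RC_THRESHOLD = 0.95

# binning defaults: deep bins (a handful of major clades on a unit-depth
# pure-birth tree) -- each pair-bin comparison then rests on enough taxa for
# the null-standardised scores to have useful power at desk-scale richness
DEFAULT_DISTANCE_THRESHOLD = 1.7
DEFAULT_MIN_BIN_SIZE = 36


@dataclass
class PhyloBinSet:
    """A partition of the working OTU set into phylogenetic bins."""

    bins: dict[int, list[str]]
    distance_threshold: float
    min_bin_size: int
    merged_bins: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        all_otus = [o for members in self.bins.values() for o in members]
        if len(all_otus) != len(set(all_otus)):
            raise ValueError("bins must partition the OTU set (overlap found)")

    @property
    def otu_to_bin(self) -> dict[str, int]:
        return {o: b for b, members in self.bins.items() for o in members}

    def sizes(self) -> dict[int, int]:
        return {b: len(m) for b, m in self.bins.items()}


def _patristic_matrix(tree: TreeNode) -> tuple[np.ndarray, list[str]]:
    dm = tree.tip_tip_distances()
    return np.asarray(dm.data, dtype=float), list(dm.ids)


def phylo_bins(
    tree: TreeNode,
    working_otus: list[str] | None = None,
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    min_bin_size: int = DEFAULT_MIN_BIN_SIZE,
) -> PhyloBinSet:
    """Partition tips into bins by a greedy root-to-tip clade traversal.

    A clade becomes a bin as soon as its maximum within-clade patristic
    distance is at or below ``distance_threshold``; bins smaller than
    ``min_bin_size`` are merged into the phylogenetically nearest bin (by mean
    patristic distance between members) and flagged.
    """
    if distance_threshold <= 0:
        raise ValueError("distance_threshold must be > 0")
    if min_bin_size < 2:
        raise ValueError("min_bin_size must be >= 2")
    tips_all = [t.name for t in tree.tips()]
    if working_otus is not None:
        wanted = set(working_otus)
        keep = [o for o in tips_all if o in wanted]
        if len(keep) < 2:
            raise ValueError("tree too small to form any bin")
        tree = tree.shear(keep)
    D, ids = _patristic_matrix(tree)
    index = {o: i for i, o in enumerate(ids)}

    bins: list[list[str]] = []

    def visit(node: TreeNode) -> None:
        tip_names = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        idx = [index[t] for t in tip_names]
        if len(idx) == 1 or D[np.ix_(idx, idx)].max() <= distance_threshold:
            bins.append(tip_names)
            return
        for child in node.children:
            visit(child)

    visit(tree)
    if not bins:
        raise ValueError("tree too small to form any bin")

    merged_flags = [False] * len(bins)
    # iteratively merge the smallest undersized bin into its nearest neighbour
    while len(bins) > 1:
        sizes = [len(b) for b in bins]
        small = min(range(len(bins)), key=lambda i: sizes[i])
        if sizes[small] >= min_bin_size:
            break
        si = [index[o] for o in bins[small]]
        best, best_d = None, np.inf
        for j, other in enumerate(bins):
            if j == small:
                continue
            d = D[np.ix_(si, [index[o] for o in other])].mean()
            if d < best_d:
                best, best_d = j, d
        bins[best] = bins[best] + bins[small]
        merged_flags[best] = True
        del bins[small]
        del merged_flags[small]

    out = {b: members for b, members in enumerate(bins)}
    merged = {b for b, members in enumerate(bins) if merged_flags[b]}
    if merged:
        logger.info("phylo_bins: %d bin(s) formed by forced merging", len(merged))
    return PhyloBinSet(out, distance_threshold, min_bin_size, merged)


# ---------------------------------------------------------------------------
# betaMNTD and nulls
# ---------------------------------------------------------------------------

def _bmntd_terms(D, supp1, supp2, f1, f2, perms=None):
    """betaMNTD for one pair, optionally for a batch of tip-label permutations.

    ``perms`` is a (B, k) array of permutations of the bin's tip indices; the
    null relabels the distance matrix jointly for both communities.
    Returns a scalar (perms None) or a length-B vector.
    """
    # a taxon present in both samples is its own nearest neighbour (distance
    # 0) under the observed and every relabelled matrix, so only the support
    # set-difference contributes
    shared = np.intersect1d(supp1, supp2, assume_unique=True)
    only1 = np.setdiff1d(supp1, shared, assume_unique=True)
    only2 = np.setdiff1d(supp2, shared, assume_unique=True)
    w1 = f1[np.searchsorted(supp1, only1)]
    w2 = f2[np.searchsorted(supp2, only2)]
    if perms is None:
        t1 = float(w1 @ D[np.ix_(only1, supp2)].min(axis=1)) if only1.size else 0.0
        t2 = float(w2 @ D[np.ix_(supp1, only2)].min(axis=0)) if only2.size else 0.0
        return 0.5 * (t1 + t2)
    B = perms.shape[0]
    t1 = np.zeros(B)
    t2 = np.zeros(B)
    if only1.size:
        subs = D[perms[:, only1][:, :, None], perms[:, supp2][:, None, :]]
        t1 = subs.min(axis=2) @ w1
    if only2.size:
        subs = D[perms[:, supp1][:, :, None], perms[:, only2][:, None, :]]
        t2 = subs.min(axis=1) @ w2
    return 0.5 * (t1 + t2)


def _pair_arrays(x: pd.Series, y: pd.Series, D: np.ndarray, ids: list[str]):
    x = x.reindex(ids).fillna(0.0).to_numpy(dtype=float)
    y = y.reindex(ids).fillna(0.0).to_numpy(dtype=float)
    supp1 = np.flatnonzero(x > 0)
    supp2 = np.flatnonzero(y > 0)
    return x, y, supp1, supp2


def beta_mntd(
    x: pd.Series, y: pd.Series, tree: TreeNode, abundance_weighted: bool = True
) -> float:
    """Abundance-weighted beta mean nearest taxon distance between two samples.

    betaMNTD = 0.5 * [sum_i f_i d(i, nearest taxon of the other community)
    + the symmetric term], with f the relative abundances within each
    community (or 1/richness when unweighted).
    """
    D, ids = _patristic_matrix(tree)
    xv, yv, s1, s2 = _pair_arrays(x, y, D, ids)
    if s1.size == 0 or s2.size == 0:
        raise ValueError("a community is empty on the tree's OTU set")
    if not abundance_weighted:
        xv = (xv > 0).astype(float)
        yv = (yv > 0).astype(float)
    f1 = xv[s1] / xv[s1].sum()
    f2 = yv[s2] / yv[s2].sum()
    return float(_bmntd_terms(D, s1, s2, f1, f2))


def _null_permutations(rng: np.random.Generator, n_null: int, k: int) -> np.ndarray:
    return rng.permuted(np.tile(np.arange(k), (n_null, 1)), axis=1)


def _beta_nri_core(D, s1, s2, f1, f2, n_null, rng) -> float:
    obs = _bmntd_terms(D, s1, s2, f1, f2)
    k = D.shape[0]
    chunk = max(1, min(n_null, 4_000_000 // max(1, s1.size * s2.size)))
    vals = np.empty(n_null)
    done = 0
    while done < n_null:
        b = min(chunk, n_null - done)
        perms = _null_permutations(rng, b, k)
        vals[done:done + b] = _bmntd_terms(D, s1, s2, f1, f2, perms)
        done += b
    sd = vals.std(ddof=0)
    if sd == 0.0:
        return np.nan
    return float((obs - vals.mean()) / sd)


def beta_nri(
    x: pd.Series,
    y: pd.Series,
    tree: TreeNode,
    n_null: int = 1000,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> float:
    """betaNRI z-score of betaMNTD against the within-bin taxa-shuffle null.

    Returns NaN (flagged) when the null is degenerate (sd = 0), e.g. for two
    communities with identical support, where relabelling tips cannot change
    the nearest-taxon distances.
    """
    D, ids = _patristic_matrix(tree)
    xv, yv, s1, s2 = _pair_arrays(x, y, D, ids)
    if s1.size == 0 or s2.size == 0:
        raise ValueError("a community is empty on the tree's OTU set")
    if not abundance_weighted:
        xv, yv = (xv > 0).astype(float), (yv > 0).astype(float)
    f1 = xv[s1] / xv[s1].sum()
    f2 = yv[s2] / yv[s2].sum()
    z = _beta_nri_core(D, s1, s2, f1, f2, n_null, np.random.default_rng(seed))
    if np.isnan(z):
        logger.warning("beta_nri: degenerate null (sd=0); score undefined")
    return z


# ---------------------------------------------------------------------------
# Raup-Crick
# ---------------------------------------------------------------------------

def _null_assemblages(
    rng: np.random.Generator,
    n_null: int,
    richness: int,
    total: int,
    occupancy_w: np.ndarray,
    abundance_p: np.ndarray,
) -> np.ndarray:
    """(n_null, k) integer null assemblages preserving richness and total reads."""
    k = occupancy_w.size
    available = int((occupancy_w > 0).sum())
    richness = min(richness, available, total)
    counts = np.zeros((n_null, k), dtype=np.int64)
    if richness == 0:
        return counts
    logw = np.full(k, -np.inf)
    pos = occupancy_w > 0
    logw[pos] = np.log(occupancy_w[pos])
    keys = logw[None, :] + rng.gumbel(size=(n_null, k))
    order = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    rows = np.repeat(np.arange(n_null), richness)
    counts[rows, order.ravel()] = 1  # each drawn species starts with one individual
    remaining = total - richness
    if remaining > 0:
        p = np.where(counts > 0, abundance_p[None, :], 0.0)
        p /= p.sum(axis=1, keepdims=True)  # chosen species carry abundance > 0
        counts += rng.multinomial(remaining, p)  # batched over null draws
    return counts


def _bray_curtis_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    num = np.abs(a - b).sum(axis=-1)
    den = (a + b).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _rc_core(xc, yc, occupancy_w, abundance_p, n_null, rng) -> float:
    obs = _bray_curtis_pairs(xc.astype(float), yc.astype(float))
    n1 = _null_assemblages(rng, n_null, int((xc > 0).sum()), int(xc.sum()),
                           occupancy_w, abundance_p)
    n2 = _null_assemblages(rng, n_null, int((yc > 0).sum()), int(yc.sum()),
                           occupancy_w, abundance_p)
    null = _bray_curtis_pairs(n1.astype(float), n2.astype(float))
    eps = 1e-9
    less = float((null < obs - eps).mean())
    ties = float((np.abs(null - obs) <= eps).mean())
    return 2.0 * (less + 0.5 * ties) - 1.0


def raup_crick(
    x: pd.Series,
    y: pd.Series,
    table: CommunityTable,
    otus: list[str] | None = None,
    n_null: int = 1000,
    seed: int = 0,
) -> float:
    """Modified Raup-Crick score on Bray-Curtis for one sample pair.

    Null assemblages preserve each sample's richness and total reads on the
    OTU set; species are drawn with probability proportional to occupancy
    frequency across ``table``'s samples and individuals are filled
    proportional to total relative abundance. RC is in [-1, 1].
    """
    otus = list(otus) if otus is not None else list(table.otu_ids)
    sub = table.select_otus(otus)
    occ = (sub.counts > 0).sum(axis=0).astype(float)
    tot = sub.counts.sum(axis=0).astype(float)
    xc = x.reindex(otus).fillna(0.0).to_numpy()
    yc = y.reindex(otus).fillna(0.0).to_numpy()
    if xc.sum() == 0 or yc.sum() == 0:
        raise ValueError("a community is empty on the OTU set")
    return _rc_core(
        xc.astype(np.int64), yc.astype(np.int64), occ, tot / max(tot.sum(), 1.0),
        n_null, np.random.default_rng(seed),
    )


# ---------------------------------------------------------------------------
# full scoring and partitioning
# ---------------------------------------------------------------------------

def null_model_scores(
    table: CommunityTable,
    tree: TreeNode,
    bins: PhyloBinSet,
    n_null: int = 1000,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """betaNRI and RC for every sample pair and bin.

    Returns a long DataFrame (sample_i, sample_j, bin, bnri, rc, weight);
    the per-pair seed is derived from ``seed`` and the pair/bin indices so
    results do not depend on execution order. Pairs where a community has no
    reads in a bin are skipped (logged); weights are the mean relative
    abundance of the bin across the pair, renormalised over scored bins.
    """
    D_full, ids = _patristic_matrix(tree)
    index = {o: i for i, o in enumerate(ids)}
    counts = table.data
    sample_totals = counts.sum(axis=1).to_numpy().astype(float)
    samples = table.sample_ids

    bin_data = {}
    table_otus = set(table.otu_ids)
    for b, members in bins.bins.items():
        members = [o for o in members if o in table_otus]
        if not members:
            continue
        idx = [index[o] for o in members]
        bin_data[b] = (members, D_full[np.ix_(idx, idx)], counts[members].to_numpy().astype(float))

    rows = []
    n_skipped = 0
    for (ia, sa), (ib, sb) in itertools.combinations(enumerate(samples), 2):
        for b, (members, D, C) in bin_data.items():
            xc, yc = C[ia], C[ib]
            tx, ty = xc.sum(), yc.sum()
            w = 0.5 * (tx / sample_totals[ia] + ty / sample_totals[ib])
            if tx == 0 or ty == 0:
                n_skipped += 1
                continue
            s1, s2 = np.flatnonzero(xc > 0), np.flatnonzero(yc > 0)
            if abundance_weighted:
                f1, f2 = xc[s1] / tx, yc[s2] / ty
            else:
                f1 = np.full(s1.size, 1.0 / s1.size)
                f2 = np.full(s2.size, 1.0 / s2.size)
            rng = np.random.default_rng(spawn_seed(seed, ia, ib, b))
            z = _beta_nri_core(D, s1, s2, f1, f2, n_null, rng)
            occ = (C > 0).sum(axis=0).astype(float)
            tot = C.sum(axis=0)
            rc = _rc_core(
                xc.astype(np.int64), yc.astype(np.int64),
                occ, tot / max(tot.sum(), 1.0), n_null, rng,
            )
            rows.append({"sample_i": sa, "sample_j": sb, "bin": b,
                         "bnri": z, "rc": rc, "weight": w})
    if n_skipped:
        logger.info("null_model_scores: skipped %d pair-bin(s) with an empty community",
                    n_skipped)
    out = pd.DataFrame(rows, columns=["sample_i", "sample_j", "bin", "bnri", "rc", "weight"])
    if len(out):  # renormalise weights over the scored bins of each pair
        out["weight"] = out.groupby(["sample_i", "sample_j"])["weight"].transform(
            lambda w: w / w.sum()
        )
    return out


@dataclass
class AssemblyPartition:
    """Fractions of the five assembly processes; they sum to one."""

    fractions: dict[str, float]
    n_pairs: int = 0
    n_bins: int = 0

    def __post_init__(self) -> None:
        missing = set(PROCESSES) - set(self.fractions)
        if missing:
            raise ValueError(f"missing process fraction(s): {missing}")
        total = sum(self.fractions[p] for p in PROCESSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")

    def to_series(self) -> pd.Series:
        return pd.Series({p: self.fractions[p] for p in PROCESSES})

    def dominant(self) -> str:
        return max(PROCESSES, key=lambda p: self.fractions[p])


def classify_pair_bin(bnri: float, rc: float) -> str | None:
    """Apply the fixed thresholds to one pair-bin score; None if undefined."""
    if np.isnan(bnri):
        return None
    if bnri < -BNRI_THRESHOLD:
        return "homogeneous_selection"
    if bnri > BNRI_THRESHOLD:
        return "heterogeneous_selection"
    if np.isnan(rc):
        return None
    if rc < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    if rc > RC_THRESHOLD:
        return "dispersal_limitation"
    return "drift"


def partition_processes(scores: pd.DataFrame) -> AssemblyPartition:
    """Aggregate pair-bin classifications into the five process fractions.

    Within each pair, bin classifications are combined with the bin
    relative-abundance weights; the per-pair fractions are then averaged over
    pairs with equal weight.
    """
    if scores.empty:
        raise ValueError("no pair-bin scores to partition")
    work = scores.copy()
    work["process"] = [classify_pair_bin(b, r) for b, r in zip(work["bnri"], work["rc"])]
    work = work[work["process"].notna()]
    if work.empty:
        raise ValueError("all pair-bin scores flagged or degenerate")
    per_pair = []
    for _, grp in work.groupby(["sample_i", "sample_j"]):
        wsum = grp["weight"].sum()
        fr = {p: float(grp.loc[grp["process"] == p, "weight"].sum() / wsum)
              for p in PROCESSES}
        per_pair.append(fr)
    agg = {p: float(np.mean([fr[p] for fr in per_pair])) for p in PROCESSES}
    total = sum(agg.values())
    agg = {p: v / total for p, v in agg.items()}
    return AssemblyPartition(agg, n_pairs=len(per_pair),
                             n_bins=int(scores["bin"].nunique()))


def run_assembly_analysis(
    table: CommunityTable,
    tree: TreeNode,
    classification,
    metadata,
    classes: tuple[str, ...] = ("abundant", "rare"),
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    min_bin_size: int = DEFAULT_MIN_BIN_SIZE,
    n_null: int = 1000,
    seed: int = 0,
) -> dict[str, dict]:
    """Per-(abundance class x soil layer) assembly partitioning.

    Pairs are formed within each group across sites; groups with fewer than 3
    samples are skipped with a log line. Returns, per group, the partition,
    the raw pair-bin scores and the bin set.
    """
    from .community import subset_by_class  # local import avoids a cycle

    layers = metadata.data["layer"]
    results: dict[str, dict] = {}
    for cls in classes:
        try:
            sub_class = subset_by_class(table, classification, cls)
        except ValueError as exc:
            logger.warning("run_assembly_analysis: %s", exc)
            continue
        for layer in sorted(layers.unique()):
            group = f"{cls}_{layer}"
            samples = [s for s in sub_class.sample_ids if layers.get(s) == layer]
            if len(samples) < 3:
                logger.warning("run_assembly_analysis: group %s has <3 samples; skipped",
                               group)
                continue
            sub = sub_class.select_samples(samples)
            present = [o for o, t in zip(sub.otu_ids, sub.counts.sum(axis=0)) if t > 0]
            if len(present) < 2:
                logger.warning("run_assembly_analysis: group %s has <2 OTUs; skipped", group)
                continue
            sub = sub.select_otus(present)
            bins = phylo_bins(tree, present, distance_threshold, min_bin_size)
            gtree = tree.shear(present)
            scores = null_model_scores(
                sub, gtree, bins, n_null=n_null, seed=spawn_seed(seed, hash(group) & 0xFFFF)
            )
            try:
                partition = partition_processes(scores)
            except ValueError as exc:
                logger.warning("run_assembly_analysis: group %s: %s; skipped", group, exc)
                continue
            results[group] = {"partition": partition, "scores": scores, "bins": bins}
    if not results:
        raise ValueError("no group could be analysed")
    return results
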