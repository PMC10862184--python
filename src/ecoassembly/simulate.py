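"""Synthetic community generator with known assembly regimes.

The generator emulates the statistical structure the analysis assumes: a
rarefied OTU table over 13 sites x 2 soil layers, a lognormal-like regional
abundance distribution (a few abundant OTUs carrying most reads, most OTUs
rare), phylogenetic trait structure for selection regimes, spatially
autocorrelated site effects for dispersal limitation, and site coordinates
spanning a ~500-km extent. The ground truth (regime, traits, optima,
coordinates, pool) is recorded alongside every dataset.

Every sample carries a baseline demographic-drift term: its sampling weights
are the pool times a per-sample lognormal perturbation exp(drift_sd * z),
z ~ N(0, 1) i.i.d. per OTU, before the multinomial read draw. Pure
resampling noise alone would make local communities far more similar than
any occupancy-preserving null assemblage; ecological drift is precisely
independent compositional divergence of local communities, and drift_sd sets
its magnitude (default 0.5, which places neutral communities inside the
central band of the Raup-Crick null distribution).

Regimes
-------
drift
    The baseline demographic noise only: each sample is a multinomial draw
    from its own lognormally perturbed copy of the regional pool.
selection
    Per-OTU traits evolve by Brownian motion on the tree, with variance
    accruing only below a root-depth cutoff (trait conservatism at the
    shallow-to-intermediate phylogenetic scale, i.e. inside the bins the
    null-model partition operates on; variance concentrated at the deepest
    splits would be factored out by within-bin randomisation). Traits are
    standardised to mean 0, sd 1; each sample has an environmental optimum,
    contrasted between soil layers and anchored at the +/-contrast normal
    quantiles of the realised trait distribution so both optima always sit
    inside the occupied trait range. Sampling weights are pool x
    Gaussian(trait - optimum) with filter width 1/strength standardised
    trait units.
dispersal_limitation
    Per-site lognormal perturbations of the pool with an exponential-decay
    spatial correlation kernel, so nearby sites share perturbations.
homogenizing_dispersal
    A single realized local assemblage is shared by all samples: a fraction
    ``strength`` of each sample's reads is the shared assemblage itself (mass
    effects overwhelming local drift), the rest is independent multinomial
    noise with the baseline drift term.
mixed
    Selection and dispersal log-factors combined at half strength each.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._util import logger, spawn_seed
from .io import (
    CommunityTable,
    SampleMetadata,
    TaxonomyTable,
    write_community_table,
    write_metadata,
    write_taxonomy,
    write_tree,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_tree",
    "star_tree",
    "simulate_pool",
    "brownian_traits",
    "simulate_metadata",
    "simulate_communities",
    "simulate_study",
]

REGIMES = ("drift", "selection", "dispersal_limitation", "homogenizing_dispersal", "mixed")

DEFAULT_STRENGTH = {
    "drift": 0.0,
    "selection": 5.0,            # Gaussian filter width = 1/strength trait units
    "dispersal_limitation": 2.0,  # sd of the correlated log site effect
    "homogenizing_dispersal": 0.9,  # shared-assemblage read fraction
    "mixed": 1.0,
}

# study-like sampling frame: 13 sites, two layers, ~500-km extent
LAT_RANGE = (37.0, 39.5)
LON_RANGE = (95.0, 100.0)
ELEV_RANGE = (2480.0, 4097.0)


@dataclass
class SimulationConfig:
    n_sites: int = 13
    n_layers: int = 2
    n_otus: int = 500
    reads_per_sample: int = 10_000
    lognormal_mean: float = 0.0
    lognormal_sd: float = 2.5
    regime: str = "drift"
    strength: float | None = None
    trait_rate: float = 1.0
    trait_depth_cutoff: float = 0.25  # BM variance accrues below this root depth
    selection_contrast: float = 1.25  # optima at the +/- contrast trait quantiles
    drift_sd: float = 0.5
    spatial_range_km: float = 25.0
    extent_km: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.n_sites < 1 or self.n_otus < 3 or self.reads_per_sample < 1:
            raise ValueError("counts must be positive")
        if self.strength is None:
            self.strength = DEFAULT_STRENGTH[self.regime]
        if self.strength < 0:
            raise ValueError("regime strength must be >= 0")


@dataclass
class SimulationTruth:
    regime: str
    strength: float
    pool: pd.Series
    traits: pd.Series | None = None
    optima: pd.Series | None = None
    coordinates: pd.DataFrame | None = None
    seed: int = 0


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def _otu_labels(n: int) -> list[str]:
    return [f"OTU_{i + 1:04d}" for i in range(n)]


def simulate_tree(n_otus: int, seed: int = 0) -> TreeNode:
    """Pure-birth (Yule) random rooted ultrametric tree scaled to unit depth."""
    if n_otus < 3:
        raise ValueError("need at least 3 OTUs")
    rng = np.random.default_rng(seed)
    root = TreeNode(length=0.0)
    active: list[tuple[TreeNode, float]] = []
    for _ in range(2):
        child = TreeNode(length=0.0)
        root.append(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n_otus:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node, birth = active.pop(i)
        node.length = t - birth
        for _ in range(2):
            child = TreeNode(length=0.0)
            node.append(child)
            active.append((child, t))
    t_end = t + rng.exponential(1.0 / len(active))
    labels = iter(_otu_labels(n_otus))
    # deterministic label order: assign in tip traversal order at the end
    for node, birth in active:
        node.length = t_end - birth
    for tip in root.tips():
        tip.name = next(labels)
    # scale to unit depth
    depth = t_end if t_end > 0 else 1.0
    for node in root.traverse(include_self=True):
        node.length = (node.length or 0.0) / depth
    return root


def star_tree(n_otus: int, seed: int = 0, length_sd: float = 0.5) -> TreeNode:
    """Star phylogeny with heterogeneous (lognormal) tip branch lengths.

    With equal branch lengths the taxa-shuffle null would be degenerate (all
    relabelings leave the distance matrix unchanged), so the calibration star
    uses varying lengths while keeping tips statistically exchangeable.
    """
    rng = np.random.default_rng(seed)
    root = TreeNode(length=0.0)
    lengths = rng.lognormal(mean=0.0, sigma=length_sd, size=n_otus)
    lengths /= lengths.mean()
    for name, ln in zip(_otu_labels(n_otus), lengths):
        root.append(TreeNode(name=name, length=float(ln)))
    return root


# ---------------------------------------------------------------------------
# pool, traits, metadata
# ---------------------------------------------------------------------------

def simulate_pool(
    n_otus: int, lognormal_mean: float = 0.0, lognormal_sd: float = 2.5, seed: int = 0
) -> pd.Series:
    """Normalised lognormal regional-pool relative abundances."""
    rng = np.random.default_rng(seed)
    if lognormal_sd == 0:
        vals = np.full(n_otus, 1.0 / n_otus)
    else:
        vals = rng.lognormal(mean=lognormal_mean, sigma=lognormal_sd, size=n_otus)
        vals /= vals.sum()
    return pd.Series(vals, index=_otu_labels(n_otus), name="pool")


def brownian_traits(
    tree: TreeNode, rate: float = 1.0, seed: int = 0, depth_cutoff: float = 0.0
) -> pd.Series:
    """Brownian-motion trait values at the tips (variance = rate x depth).

    With ``depth_cutoff`` > 0 variance accrues only on the part of each branch
    below that root depth, confining trait variation to the shallow and
    intermediate phylogenetic scales.
    """
    rng = np.random.default_rng(seed)
    values: dict[int, tuple[float, float]] = {id(tree): (0.0, 0.0)}  # (trait, depth)
    for node in tree.preorder(include_self=False):
        parent_val, parent_depth = values[id(node.parent)]
        length = node.length or 0.0
        effective = max(0.0, parent_depth + length - max(parent_depth, depth_cutoff))
        values[id(node)] = (
            parent_val + rng.normal(0.0, np.sqrt(rate * effective)),
            parent_depth + length,
        )
    return pd.Series({t.name: values[id(t)][0] for t in tree.tips()}, name="trait")


def simulate_metadata(n_sites: int = 13, n_layers: int = 2, seed: int = 0) -> SampleMetadata:
    """Site coordinates in a ~500-km extent, two soil layers per site, and a
    small synthetic soil-chemistry / climate block."""
    rng = np.random.default_rng(seed)
    lat = rng.uniform(*LAT_RANGE, size=n_sites)
    lon = rng.uniform(*LON_RANGE, size=n_sites)
    elev = rng.uniform(*ELEV_RANGE, size=n_sites)
    layers = ["surface", "subsurface"][:n_layers]
    rows = {}
    for s in range(n_sites):
        for layer in layers:
            sid = f"S{s + 1:02d}_{layer}"
            rows[sid] = {
                "site": f"S{s + 1:02d}",
                "layer": layer,
                "latitude": lat[s],
                "longitude": lon[s],
                "elevation": elev[s],
                "pH": rng.normal(7.5, 0.5),
                "TN": rng.lognormal(0.0, 0.4),
                "MC": rng.uniform(5, 40),
                "AP": rng.uniform(200, 600),
                "AMT": rng.normal(-1.0, 2.0) - 0.005 * (elev[s] - 3300.0),
            }
    return SampleMetadata(pd.DataFrame.from_dict(rows, orient="index"))


# ---------------------------------------------------------------------------
# community generation
# ---------------------------------------------------------------------------

def _site_distance_km(metadata: SampleMetadata) -> tuple[np.ndarray, list[str]]:
    from .spatial import geographic_distance

    sites = metadata.data.drop_duplicates("site")
    site_meta = SampleMetadata(sites.set_index("site", drop=False).rename_axis(None))
    dm = geographic_distance(site_meta)
    return dm.values, list(sites["site"])


def simulate_communities(
    pool: pd.Series,
    tree: TreeNode,
    metadata: SampleMetadata,
    regime: str = "drift",
    strength: float | None = None,
    reads: int = 10_000,
    seed: int = 0,
    trait_rate: float = 1.0,
    trait_depth_cutoff: float = 0.25,
    selection_contrast: float = 1.25,
    drift_sd: float = 0.5,
    spatial_range_km: float = 25.0,
) -> tuple[CommunityTable, SimulationTruth]:
    """Draw one community table under a named assembly regime (see module
    docstring); ``selection`` at strength 0 is byte-identical to ``drift``."""
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}")
    if strength is None:
        strength = DEFAULT_STRENGTH[regime]
    otus = list(pool.index)
    samples = metadata.sample_ids
    p = pool.to_numpy()
    rng = np.random.default_rng(spawn_seed(seed, 1))

    traits = optima = None
    log_sel = np.zeros((len(samples), len(otus)))
    log_disp = np.zeros_like(log_sel)

    want_selection = regime in ("selection", "mixed")
    want_dispersal = regime in ("dispersal_limitation", "mixed")
    sel_strength = strength if regime == "selection" else (strength / 2 if regime == "mixed" else 0.0)
    disp_strength = strength if regime == "dispersal_limitation" else (strength / 2 if regime == "mixed" else 0.0)

    if want_selection and sel_strength > 0:
        from scipy.stats import norm

        traits = brownian_traits(tree, rate=trait_rate, seed=spawn_seed(seed, 2),
                                 depth_cutoff=trait_depth_cutoff)
        traits = traits.reindex(otus)
        tau = traits.to_numpy()
        tau = (tau - tau.mean()) / tau.std()
        traits = pd.Series(tau, index=otus, name="trait")
        # optima at the +/-contrast normal quantiles of the realised traits:
        # both bands are occupied whatever shape the Brownian draw took
        hi = float(np.quantile(tau, norm.cdf(selection_contrast)))
        lo = float(np.quantile(tau, norm.cdf(-selection_contrast)))
        layer = metadata.data["layer"]
        optima = pd.Series(
            [hi if layer[s] == "surface" else lo for s in samples], index=samples
        )
        width = 1.0 / sel_strength
        for i, s in enumerate(samples):
            log_sel[i] = -((tau - optima[s]) ** 2) / (2.0 * width ** 2)

    if want_dispersal and disp_strength > 0:
        dist_km, site_ids = _site_distance_km(metadata)
        corr = np.exp(-dist_km / spatial_range_km)
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(site_ids)))
        z = chol @ rng.standard_normal((len(site_ids), len(otus)))
        site_effect = {sid: disp_strength * z[i] for i, sid in enumerate(site_ids)}
        for i, s in enumerate(samples):
            log_disp[i] = site_effect[metadata.data.at[s, "site"]]

    counts = np.zeros((len(samples), len(otus)), dtype=np.int64)
    if regime == "homogenizing_dispersal":
        m = strength
        if not (0.0 <= m < 1.0):
            raise ValueError("homogenizing_dispersal strength is a fraction in [0, 1)")
        shared = rng.multinomial(reads, p)
        shared_p = shared / reads
        det = np.floor(m * shared).astype(np.int64)
        rest = reads - int(det.sum())
        for i in range(len(samples)):
            w = shared_p * np.exp(drift_sd * rng.standard_normal(len(otus)))
            counts[i] = det + rng.multinomial(rest, w / w.sum())
    else:
        for i in range(len(samples)):
            w = p * np.exp(
                log_sel[i] + log_disp[i] + drift_sd * rng.standard_normal(len(otus))
            )
            total = w.sum()
            if total <= 0:
                raise ValueError("degenerate sampling weights (selection too strong)")
            counts[i] = rng.multinomial(reads, w / total)

    table = CommunityTable(pd.DataFrame(counts, index=samples, columns=otus))
    coords = metadata.data[["site", "latitude", "longitude"]].copy()
    truth = SimulationTruth(
        regime=regime, strength=float(strength), pool=pool,
        traits=traits, optima=optima, coordinates=coords, seed=seed,
    )
    return table, truth


def _clade_taxonomy(tree: TreeNode, cut_depth: float = 0.25) -> TaxonomyTable:
    """Pseudo-phyla: each clade crossing ``cut_depth`` from the root becomes one."""
    labels: dict[str, str] = {}
    counter = [0]

    def assign(node: TreeNode, depth: float) -> None:
        d = depth + (node.length or 0.0)
        if d >= cut_depth or node.is_tip():
            counter[0] += 1
            name = f"Phylum_{counter[0]:02d}"
            tips = [node.name] if node.is_tip() else [t.name for t in node.tips()]
            for t in tips:
                labels[t] = name
            return
        for child in node.children:
            assign(child, d)

    for child in tree.children:
        assign(child, 0.0)
    frame = pd.DataFrame(
        {
            "kingdom": "Bacteria",
            "phylum": pd.Series(labels),
            "class": "", "order": "", "family": "", "genus": "",
        }
    )
    return TaxonomyTable(frame)


def simulate_study(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """One-call fixture generation: table, tree, taxonomy, metadata and truth
    written to ``outdir`` in the io-module dialects, deterministic under the
    master seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(config.n_otus, seed=spawn_seed(config.seed, 10))
    pool = simulate_pool(config.n_otus, config.lognormal_mean, config.lognormal_sd,
                         seed=spawn_seed(config.seed, 11))
    metadata = simulate_metadata(config.n_sites, config.n_layers,
                                 seed=spawn_seed(config.seed, 12))
    table, truth = simulate_communities(
        pool, tree, metadata, regime=config.regime, strength=config.strength,
        reads=config.reads_per_sample, seed=spawn_seed(config.seed, 13),
        trait_rate=config.trait_rate, trait_depth_cutoff=config.trait_depth_cutoff,
        selection_contrast=config.selection_contrast,
        drift_sd=config.drift_sd, spatial_range_km=config.spatial_range_km,
    )
    taxonomy = _clade_taxonomy(tree)

    paths = {
        "table": outdir / "table.tsv",
        "tree": outdir / "tree.nwk",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.json",
    }
    write_community_table(table, paths["table"], seed=config.seed, regime=config.regime)
    write_tree(tree, paths["tree"])
    write_taxonomy(taxonomy, paths["taxonomy"], seed=config.seed)
    write_metadata(metadata, paths["metadata"], seed=config.seed)
    truth_payload = {
        "regime": truth.regime,
        "strength": truth.strength,
        "seed": config.seed,
        "config": asdict(config),
        "pool": {k: float(v) for k, v in truth.pool.items()},
        "traits": {k: float(v) for k, v in truth.traits.items()} if truth.traits is not None else None,
        "optima": {k: float(v) for k, v in truth.optima.items()} if truth.optima is not None else None,
    }
    paths["truth"].write_text(json.dumps(truth_payload, indent=1, sort_keys=True))
    logger.info("simulate_study: wrote %d files to %s", len(paths), outdir)
    return paths
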