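"""Reference experiments on synthetic communities under the documented study
conditions: null-model calibration, assembly-regime recovery, SparCC recovery
and false-positive control, and the distance-decay contrast.

These functions are what the acceptance machinery runs; they generate their
inputs with the :mod:`ecoassembly.simulate` defaults, execute the relevant
pipeline stage, and return plain metric dictionaries.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from ._util import spawn_seed
from .assembly import _rc_core, null_model_scores, partition_processes, phylo_bins
from .community import bray_curtis
from .io import CommunityTable
from .network import sparcc_correlations, sparcc_pvalues
from .simulate import (
    simulate_communities,
    simulate_metadata,
    simulate_pool,
    simulate_tree,
    star_tree,
)
from .spatial import geographic_distance, mantel

__all__ = [
    "null_model_calibration",
    "regime_recovery",
    "sparcc_validation",
    "distance_decay_contrast",
]


def null_model_calibration(
    seed: int,
    n_pairs: int = 550,
    n_otus_star: int = 100,
    reads_star: int = 1000,
    n_otus: int = 500,
    n_sites: int = 13,
    reads: int = 10_000,
    n_null: int = 1000,
) -> dict[str, float]:
    """Neutral calibration of both null models.

    betaNRI: ``n_pairs`` independent drift sample pairs, each drawn on its own
    star phylogeny with heterogeneous branch lengths (tips exchangeable);
    the z-scores should be standard-normal-like. Independent replicate pairs
    are essential: pairs sharing one realised pool and tree have strongly
    correlated scores, so a pair-averaged mean over a single dataset wanders
    by several tenths no matter how many pairs it holds.

    RC and the betaNRI central band: scored bin-level on a standard drift
    dataset with the default deep bins (the form the process partition
    consumes); most |RC| should stay inside 0.95 and most |betaNRI| inside
    1.96.
    """
    zs = []
    for r in range(n_pairs):
        tree = star_tree(n_otus_star, seed=spawn_seed(seed, 1, r))
        pool = simulate_pool(n_otus_star, seed=spawn_seed(seed, 2, r))
        md = simulate_metadata(n_sites=1, seed=spawn_seed(seed, 3, r))
        table, _ = simulate_communities(pool, tree, md, regime="drift",
                                        reads=reads_star, seed=spawn_seed(seed, 4, r))
        bins = phylo_bins(tree, None, distance_threshold=np.inf, min_bin_size=2)
        scores = null_model_scores(table, tree, bins, n_null=n_null,
                                   seed=spawn_seed(seed, 5, r))
        zs.extend(scores["bnri"].dropna().tolist())
    z = np.asarray(zs)

    pool_rc = simulate_pool(n_otus, seed=spawn_seed(seed, 6))
    md_rc = simulate_metadata(n_sites=n_sites, seed=spawn_seed(seed, 7))
    tree_rc = simulate_tree(n_otus, seed=spawn_seed(seed, 8))
    table_rc, _ = simulate_communities(pool_rc, tree_rc, md_rc, regime="drift",
                                       reads=reads, seed=spawn_seed(seed, 9))
    bins_rc = phylo_bins(tree_rc, None)
    scores_rc = null_model_scores(table_rc, tree_rc, bins_rc, n_null=n_null,
                                  seed=spawn_seed(seed, 10))
    rcs = scores_rc["rc"].dropna().to_numpy()
    z_bins = scores_rc["bnri"].dropna().to_numpy()
    return {
        "n_pairs_bnri": int(z.size),
        "bnri_mean": float(z.mean()),
        "bnri_sd": float(z.std(ddof=1)),
        "bnri_within_band_pct": float(100.0 * (np.abs(z_bins) <= 1.96).mean()),
        "n_pair_bins_rc": int(rcs.size),
        "rc_within_band_pct": float(100.0 * (np.abs(rcs) <= 0.95).mean()),
    }


def regime_recovery(
    seed: int,
    n_otus: int = 500,
    n_sites: int = 13,
    reads: int = 10_000,
    n_null: int = 1000,
    regimes: tuple[str, ...] = (
        "drift", "selection", "dispersal_limitation", "homogenizing_dispersal"
    ),
    distance_threshold: float | None = None,
    min_bin_size: int | None = None,
    **sim_kwargs,
) -> dict[str, dict[str, float]]:
    """Assembly-process partition for each pure regime at default strengths.

    All 26 samples (13 sites x 2 layers) form one pair set; for the selection
    regime the layers carry the contrasted environmental optima.
    """
    tree = simulate_tree(n_otus, seed=spawn_seed(seed, 11))
    pool = simulate_pool(n_otus, seed=spawn_seed(seed, 12))
    md = simulate_metadata(n_sites=n_sites, seed=spawn_seed(seed, 13))
    from .assembly import DEFAULT_DISTANCE_THRESHOLD, DEFAULT_MIN_BIN_SIZE

    bins = phylo_bins(
        tree, None,
        distance_threshold or DEFAULT_DISTANCE_THRESHOLD,
        min_bin_size or DEFAULT_MIN_BIN_SIZE,
    )
    out: dict[str, dict[str, float]] = {}
    for k, regime in enumerate(regimes):
        table, _ = simulate_communities(pool, tree, md, regime=regime,
                                        reads=reads, seed=spawn_seed(seed, 14, k),
                                        **sim_kwargs)
        scores = null_model_scores(table, tree, bins, n_null=n_null,
                                   seed=spawn_seed(seed, 15, k))
        part = partition_processes(scores)
        out[regime] = {**part.fractions, "dominant": part.dominant()}
    return out


def sparcc_validation(
    seed: int, n_samples: int = 200, n_otus: int = 50, reads: int = 5000,
    n_bootstrap: int = 100,
) -> dict[str, float]:
    """SparCC null false-positive control and planted-pair recovery.

    Null data: independent lognormal basis abundances, compositionally closed
    and multinomially sampled. Planted data: the same with OTUs 0 and 1 given
    perfectly correlated basis abundances.
    """
    rng = np.random.default_rng(spawn_seed(seed, 21))

    def closed_counts(basis):
        frac = basis / basis.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(reads, f) for f in frac])
        return CommunityTable(pd.DataFrame(
            counts, index=[f"S{i}" for i in range(n_samples)],
            columns=[f"OTU_{j:03d}" for j in range(n_otus)]))

    null_tab = closed_counts(rng.lognormal(0.0, 1.0, size=(n_samples, n_otus)))
    est_null = sparcc_correlations(null_tab, seed=spawn_seed(seed, 22))
    rho = est_null.correlations.to_numpy()
    iu = np.triu_indices(n_otus, 1)
    mean_abs = float(np.abs(rho[iu]).mean())
    est_null = sparcc_pvalues(null_tab, est_null, n_bootstrap=n_bootstrap,
                              seed=spawn_seed(seed, 23))
    pv = est_null.pvalues.to_numpy()[iu]
    ks = stats.kstest(pv, "uniform")

    basis = rng.lognormal(0.0, 1.0, size=(n_samples, n_otus))
    basis[:, 1] = 2.0 * basis[:, 0]
    planted_tab = closed_counts(basis)
    est_p = sparcc_correlations(planted_tab, seed=spawn_seed(seed, 24))
    est_p = sparcc_pvalues(planted_tab, est_p, n_bootstrap=n_bootstrap,
                           seed=spawn_seed(seed, 25))
    return {
        "null_mean_abs_rho": mean_abs,
        "null_p_ks_pvalue": float(ks.pvalue),
        "planted_rho": float(est_p.correlations.iloc[0, 1]),
        "planted_p": float(est_p.pvalues.iloc[0, 1]),
        "p_floor": 1.0 / (n_bootstrap + 1),
    }


def distance_decay_contrast(
    seed: int, n_otus: int = 500, reads: int = 10_000,
    n_permutations: int = 999, n_drift_seeds: int = 20,
) -> dict[str, float]:
    """Mantel distance-decay under dispersal limitation vs drift.

    The dispersal-limitation generator must show a significant positive
    community-dissimilarity / geographic-distance correlation; independent
    drift draws must not, in most replicates.
    """
    tree = simulate_tree(n_otus, seed=spawn_seed(seed, 31))
    pool = simulate_pool(n_otus, seed=spawn_seed(seed, 32))
    md = simulate_metadata(seed=spawn_seed(seed, 33))
    geo = geographic_distance(md)
    table, _ = simulate_communities(pool, tree, md, regime="dispersal_limitation",
                                    reads=reads, seed=spawn_seed(seed, 34))
    res = mantel(bray_curtis(table), geo, n_permutations, seed=spawn_seed(seed, 35))

    nonsig = 0
    for s in range(n_drift_seeds):
        pool_s = simulate_pool(n_otus, seed=spawn_seed(seed, 36, s))
        md_s = simulate_metadata(seed=spawn_seed(seed, 37, s))
        table_s, _ = simulate_communities(pool_s, tree, md_s, regime="drift",
                                          reads=reads, seed=spawn_seed(seed, 38, s))
        r = mantel(bray_curtis(table_s), geographic_distance(md_s),
                   n_permutations, seed=spawn_seed(seed, 39, s))
        nonsig += int(r.p > 0.05)
    return {
        "dl_mantel_r": float(res.r),
        "dl_mantel_p": float(res.p),
        "drift_nonsignificant_pct": float(100.0 * nonsig / n_drift_seeds),
    }
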