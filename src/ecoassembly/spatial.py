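"""Spatial and environmental statistics: great-circle distances, Mantel
tests, distance-decay regression, Levins niche breadth, and Kruskal-Wallis +
Benjamini-Hochberg differential abundance between groups."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import logger
from .io import CommunityTable, DissimilarityMatrix, SampleMetadata

__all__ = [
    "MantelResult",
    "geographic_distance",
    "mantel",
    "distance_decay",
    "levins_breadth",
    "compare_breadth",
    "differential_abundance",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    statistic_type: str = "pearson"
    exhaustive: bool = False


def geographic_distance(metadata: SampleMetadata) -> DissimilarityMatrix:
    """Pairwise haversine great-circle distance in km (Earth radius 6371.0 km)."""
    lat = metadata.data["latitude"].astype(float)
    lon = metadata.data["longitude"].astype(float)
    missing = lat.index[lat.isna() | lon.isna()]
    if len(missing):
        raise ValueError(f"missing coordinates for sample(s): {list(missing)}")
    phi = np.radians(lat.to_numpy())
    lam = np.radians(lon.to_numpy())
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    return DissimilarityMatrix(d, metadata.sample_ids, metric="haversine_km")


def _pearson_upper(x: np.ndarray, y: np.ndarray) -> float:
    xm, ym = x - x.mean(), y - y.mean()
    denom = math.sqrt(float((xm ** 2).sum()) * float((ym ** 2).sum()))
    if denom == 0.0:
        return np.nan
    return float((xm * ym).sum() / denom)


def mantel(
    dx: DissimilarityMatrix,
    dy: DissimilarityMatrix,
    n_permutations: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel test: Pearson correlation of upper triangles, permutation p-value.

    The permutation jointly reorders rows and columns of ``dy``. When the
    number of distinct permutations n! is no larger than ``n_permutations + 1``
    the test enumerates all of them exhaustively and the p-value is exact;
    otherwise ``n_permutations`` random permutations are drawn and
    p = (1 + #{|r*| >= |r|}) / (1 + n_permutations). Pairs with a NaN distance
    in either matrix are excluded from the correlation (pairwise deletion).
    """
    if dx.ids != dy.ids:
        if set(dx.ids) != set(dy.ids):
            raise ValueError("matrices must share sample labels")
        dy = dy.filter(dx.ids)
    n = len(dx.ids)
    if n < 3:
        raise ValueError("Mantel test needs at least 3 samples")
    iu = np.triu_indices(n, k=1)
    x = dx.values[iu]
    valid_mask_x = ~np.isnan(x)

    def corr_for(perm: np.ndarray) -> float:
        yv = dy.values[np.ix_(perm, perm)][iu]
        ok = valid_mask_x & ~np.isnan(yv)
        if ok.sum() < 3:
            return np.nan
        return _pearson_upper(x[ok], yv[ok])

    r_obs = corr_for(np.arange(n))
    if np.isnan(r_obs):
        logger.warning("mantel: zero-variance or all-NaN matrix; r undefined")
        return MantelResult(np.nan, np.nan, n_permutations)

    n_total = math.factorial(n)
    if n_total <= n_permutations + 1:
        count = 0
        for perm in itertools.permutations(range(n)):
            r_star = corr_for(np.asarray(perm))
            if not np.isnan(r_star) and abs(r_star) >= abs(r_obs) - 1e-12:
                count += 1
        return MantelResult(r_obs, count / n_total, n_total - 1, exhaustive=True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        r_star = corr_for(rng.permutation(n))
        if not np.isnan(r_star) and abs(r_star) >= abs(r_obs) - 1e-12:
            count += 1
    return MantelResult(r_obs, (1 + count) / (1 + n_permutations), n_permutations)


@dataclass
class DistanceDecayResult:
    mantel: MantelResult
    slope: float  # OLS slope of (1 - Bray-Curtis) against km
    intercept: float


def distance_decay(
    community: DissimilarityMatrix,
    geo: DissimilarityMatrix,
    n_permutations: int = 999,
    seed: int = 0,
) -> DistanceDecayResult:
    """Distance-decay: Mantel between dissimilarities plus the OLS slope of
    community similarity (1 - Bray-Curtis) against geographic distance (km)."""
    res = mantel(community, geo, n_permutations=n_permutations, seed=seed)
    if geo.ids != community.ids:
        geo = geo.filter(community.ids)
    iu = np.triu_indices(len(community.ids), k=1)
    sim = 1.0 - community.values[iu]
    km = geo.values[iu]
    ok = ~np.isnan(sim) & ~np.isnan(km)
    sim, km = sim[ok], km[ok]
    if km.size < 2 or np.ptp(km) == 0:
        logger.warning("distance_decay: degenerate geographic distances; slope undefined")
        return DistanceDecayResult(res, np.nan, np.nan)
    slope, intercept = np.polyfit(km, sim, 1)
    return DistanceDecayResult(res, float(slope), float(intercept))


def levins_breadth(table: CommunityTable) -> pd.Series:
    """Levins niche breadth B_j = 1 / sum_i p_ij^2 with p_ij the share of OTU
    j's reads found in sample i. B is the effective number of samples an OTU
    occupies evenly: 1 <= B <= n_samples. Zero-total OTUs are excluded."""
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.info("levins_breadth: excluded %d zero-total OTU(s)", int(zero.sum()))
    p = counts[:, ~zero] / totals[~zero]
    b = 1.0 / (p ** 2).sum(axis=0)
    ids = [o for o, z in zip(table.otu_ids, zero) if not z]
    return pd.Series(b, index=ids, name="levins_b")


@dataclass
class BreadthComparison:
    class_means: dict
    u_statistic: float
    p_value: float
    skipped: bool = False


def compare_breadth(breadth: pd.Series, classification) -> BreadthComparison:
    """Mean niche breadth per abundance class and a two-sided Mann-Whitney test
    between the abundant and rare classes."""
    cls = classification.classes.reindex(breadth.index)
    means = {c: float(breadth[cls == c].mean()) for c in ("abundant", "moderate", "rare")}
    a = breadth[cls == "abundant"].to_numpy()
    r = breadth[cls == "rare"].to_numpy()
    if len(a) < 2 or len(r) < 2:
        logger.warning("compare_breadth: a class has <2 OTUs; test skipped")
        return BreadthComparison(means, np.nan, np.nan, skipped=True)
    u, p = stats.mannwhitneyu(a, r, alternative="two-sided")
    return BreadthComparison(means, float(u), float(p))


def differential_abundance(
    taxa_matrix: pd.DataFrame,
    group_labels: pd.Series,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-taxon Kruskal-Wallis between groups with BH-FDR across taxa.

    ``taxa_matrix`` is samples x taxa (relative abundances); significant means
    q < alpha. Taxa constant across all samples get p = 1 by convention.
    """
    labels = group_labels.reindex(taxa_matrix.index)
    groups = labels.dropna().unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    rows = []
    for taxon in taxa_matrix.columns:
        vals = [taxa_matrix.loc[labels == g, taxon].to_numpy() for g in groups]
        flat = np.concatenate(vals)
        if np.allclose(flat, flat[0]):
            h, p = 0.0, 1.0
            logger.info("differential_abundance: %r constant; p=1 by convention", taxon)
        else:
            h, p = stats.kruskal(*vals)
        rows.append(
            {
                "taxon": taxon,
                **{f"mean_{g}": float(np.mean(v)) for g, v in zip(groups, vals)},
                "H": float(h),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows).set_index("taxon")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    return out
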