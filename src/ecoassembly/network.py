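"""SparCC compositional correlation inference and co-occurrence networks.

SparCC estimates basis (absolute-abundance) correlations from compositional
counts: per-pair log-ratio variances t_ij = var(log(x_i / x_j)) are linked to
basis variances w_i^2 by t_ij = w_i^2 + w_j^2 - 2 rho_ij w_i w_j; under the
sparsity assumption (sum of correlations small) the basis variances solve a
linear system, and strongly correlated pairs are iteratively excluded and the
system re-solved. Fractions are drawn from a Dirichlet posterior (pseudo-count
1) and the correlation estimate is averaged over resamples. Significance uses
a permutation bootstrap that shuffles each OTU's counts across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._util import format_percent, logger
from .io import CommunityTable

__all__ = [
    "CorrelationEstimate",
    "NetworkSummary",
    "sparcc_correlations",
    "sparcc_pvalues",
    "build_network",
    "summarize_network",
    "find_hubs",
]


@dataclass
class CorrelationEstimate:
    correlations: pd.DataFrame  # OTU x OTU, symmetric, unit diagonal
    pvalues: pd.DataFrame | None = None
    n_bootstrap: int = 0

    def __post_init__(self) -> None:
        c = self.correlations.to_numpy()
        if not np.allclose(c, c.T, atol=1e-9):
            raise ValueError("correlation matrix must be symmetric")


def _logratio_variances(fractions: np.ndarray) -> np.ndarray:
    """t_ij = var(log(x_i/x_j)) over samples, from the covariance of logs."""
    L = np.log(fractions)
    V = np.cov(L, rowvar=False)
    d = np.diag(V)
    return d[:, None] + d[None, :] - 2.0 * V


def _basis_correlations(
    t: np.ndarray, exclusion_threshold: float, exclusion_rounds: int
) -> np.ndarray:
    """Solve basis variances under sparsity, iteratively excluding strong pairs."""
    d = t.shape[0]
    M = np.ones((d, d)) + np.diag(np.full(d, d - 2.0))
    t_work = t.copy()
    excluded = np.zeros((d, d), dtype=bool)

    def solve() -> np.ndarray:
        tsum = np.where(excluded, 0.0, t_work).sum(axis=1)
        w2 = np.linalg.solve(M, tsum)
        w2 = np.maximum(w2, 1e-12)
        w = np.sqrt(w2)
        rho = (w2[:, None] + w2[None, :] - t) / (2.0 * np.outer(w, w))
        np.fill_diagonal(rho, 1.0)
        return np.clip(rho, -1.0, 1.0)

    rho = solve()
    for _ in range(exclusion_rounds):
        masked = np.abs(np.where(excluded, 0.0, rho))
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        # refuse to disconnect a component from the system entirely
        if M[i, i] <= 3 or M[j, j] <= 3:
            break
        excluded[i, j] = excluded[j, i] = True
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        M[i, j] = M[j, i] = 0.0
        rho = solve()
    return rho


def _sparcc_point(
    counts: np.ndarray,
    rng: np.random.Generator,
    n_iterations: int,
    exclusion_threshold: float,
    exclusion_rounds: int,
) -> np.ndarray:
    acc = np.zeros((counts.shape[1], counts.shape[1]))
    for _ in range(n_iterations):
        gam = rng.gamma(counts + 1.0)  # Dirichlet(counts + pseudo-count 1)
        fractions = gam / gam.sum(axis=1, keepdims=True)
        t = _logratio_variances(fractions)
        acc += _basis_correlations(t, exclusion_threshold, exclusion_rounds)
    rho = acc / n_iterations
    rho = 0.5 * (rho + rho.T)
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def sparcc_correlations(
    table: CommunityTable,
    n_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    exclusion_rounds: int = 10,
    seed: int = 0,
) -> CorrelationEstimate:
    """SparCC basis-correlation point estimate for every OTU pair."""
    if table.n_otus < 4:
        raise ValueError("SparCC needs at least 4 OTUs for the basis system")
    if table.n_otus < 20:
        logger.warning("sparcc_correlations: %d OTUs is below the ~20 the sparsity "
                       "approximation assumes", table.n_otus)
    rho = _sparcc_point(
        table.counts.astype(float), np.random.default_rng(seed),
        n_iterations, exclusion_threshold, exclusion_rounds,
    )
    frame = pd.DataFrame(rho, index=table.otu_ids, columns=table.otu_ids)
    return CorrelationEstimate(frame)


def sparcc_pvalues(
    table: CommunityTable,
    estimate: CorrelationEstimate,
    n_bootstrap: int = 100,
    seed: int = 0,
    n_iterations: int = 5,
    exclusion_threshold: float = 0.1,
    exclusion_rounds: int = 10,
) -> CorrelationEstimate:
    """Two-sided permutation-bootstrap p-values for a SparCC estimate.

    Each bootstrap shuffles every OTU's counts across samples independently
    (destroying all true correlation) and recomputes the SparCC estimate;
    p = (1 + #{|rho*| >= |rho_hat|}) / (1 + n_bootstrap), floored at
    1/(n_bootstrap + 1).
    """
    if n_bootstrap < 99:
        logger.warning("sparcc_pvalues: n_bootstrap=%d below the recommended 99",
                       n_bootstrap)
    rng = np.random.default_rng(seed)
    counts = table.counts.astype(float)
    obs = np.abs(estimate.correlations.to_numpy())
    exceed = np.zeros_like(obs)
    for _ in range(n_bootstrap):
        perm = np.empty_like(counts)
        for j in range(counts.shape[1]):
            perm[:, j] = counts[rng.permutation(counts.shape[0]), j]
        rho_star = _sparcc_point(perm, rng, n_iterations,
                                 exclusion_threshold, exclusion_rounds)
        exceed += np.abs(rho_star) >= obs - 1e-12
    p = (1.0 + exceed) / (1.0 + n_bootstrap)
    np.fill_diagonal(p, 1.0)
    pframe = pd.DataFrame(p, index=estimate.correlations.index,
                          columns=estimate.correlations.columns)
    return CorrelationEstimate(estimate.correlations, pframe, n_bootstrap)


# ---------------------------------------------------------------------------
# graph construction and topology
# ---------------------------------------------------------------------------

def prevalence_filter(table: CommunityTable, min_fraction: float = 1 / 3) -> CommunityTable:
    """Keep OTUs present in at least ``min_fraction`` of samples (an explicit,
    configurable pre-filter; the study reports none)."""
    frac = (table.counts > 0).mean(axis=0)
    keep = [o for o, f in zip(table.otu_ids, frac) if f >= min_fraction]
    if not keep:
        raise ValueError("prevalence filter removed every OTU")
    return table.select_otus(keep)


def build_network(
    estimate: CorrelationEstimate,
    classification,
    taxonomy=None,
    r_threshold: float = 0.3,
    p_threshold: float = 0.05,
) -> nx.Graph:
    """Undirected co-occurrence graph: edge iff |rho| > r_threshold and
    p < p_threshold; isolated nodes are dropped; edge sign = sign(rho)."""
    if estimate.pvalues is None:
        raise ValueError("estimate has no p-values; run sparcc_pvalues first")
    rho = estimate.correlations
    pv = estimate.pvalues
    g = nx.Graph()
    ids = list(rho.index)
    cls = classification.classes
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            u, v = ids[a_i], ids[b_i]
            r = float(rho.iat[a_i, b_i])
            p = float(pv.iat[a_i, b_i])
            if abs(r) > r_threshold and p < p_threshold:
                g.add_edge(u, v, correlation=r, p=p,
                           sign="positive" if r > 0 else "negative")
    if g.number_of_edges() == 0:
        logger.warning("build_network: no edge passed |rho|>%.2f, p<%.2f",
                       r_threshold, p_threshold)
    for node in g.nodes:
        g.nodes[node]["abundance_class"] = str(cls.get(node, "moderate"))
        if taxonomy is not None and node in taxonomy.data.index:
            g.nodes[node]["phylum"] = taxonomy.data.at[node, "phylum"] or "Unclassified"
        else:
            g.nodes[node]["phylum"] = "Unclassified"
    return g


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    node_counts: dict[str, int]
    node_percentages: dict[str, float]
    edge_counts: dict[tuple[str, str], dict[str, int]]  # class pair -> sign -> count
    degree: pd.Series
    closeness: pd.Series


def _harmonic_closeness(g: nx.Graph) -> pd.Series:
    """Harmonic closeness normalised by (n - 1); disconnected pairs add 0."""
    n = g.number_of_nodes()
    raw = nx.harmonic_centrality(g)
    denom = max(n - 1, 1)
    return pd.Series({v: raw[v] / denom for v in g.nodes}, dtype=float)


def summarize_network(g: nx.Graph) -> NetworkSummary:
    """Node/edge counts by abundance class and sign, degree and harmonic
    closeness per node. Node percentages follow the printed convention
    (1 decimal, 2 when below 1%)."""
    n = g.number_of_nodes()
    classes = nx.get_node_attributes(g, "abundance_class")
    node_counts: dict[str, int] = {}
    for c in classes.values():
        node_counts[c] = node_counts.get(c, 0) + 1
    node_pct = {c: format_percent(100.0 * k / n) if n else 0.0
                for c, k in node_counts.items()}
    edge_counts: dict[tuple[str, str], dict[str, int]] = {}
    for u, v, data in g.edges(data=True):
        pair = tuple(sorted((classes.get(u, "moderate"), classes.get(v, "moderate"))))
        bucket = edge_counts.setdefault(pair, {"positive": 0, "negative": 0})
        bucket[data["sign"]] += 1
    degree = pd.Series(dict(g.degree()), dtype=float)
    closeness = _harmonic_closeness(g)
    return NetworkSummary(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        node_counts=node_counts,
        node_percentages=node_pct,
        edge_counts=edge_counts,
        degree=degree,
        closeness=closeness,
    )


def find_hubs(g: nx.Graph, k: int = 10) -> pd.DataFrame:
    """Top-k hub nodes ranked by degree, ties broken by harmonic closeness,
    then lexicographic id."""
    if g.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    closeness = _harmonic_closeness(g)
    rows = [
        {
            "otu_id": v,
            "degree": int(g.degree(v)),
            "closeness": float(closeness[v]),
            "abundance_class": g.nodes[v].get("abundance_class", "moderate"),
            "phylum": g.nodes[v].get("phylum", "Unclassified"),
        }
        for v in g.nodes
    ]
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        by=["degree", "closeness", "otu_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return frame.head(min(k, len(frame)))
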