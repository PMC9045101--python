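"""Co-occurrence networks and their topology.

Primary path: pairwise Spearman correlations on relative abundances,
Benjamini-Hochberg FDR across all tested pairs, and an edge whenever
|rho| exceeds a threshold AND the corrected q-value is significant. A
SparCC-style compositional estimator is available as an alternative
correlation backend. Topology metrics follow the standard definitions
(average degree 2E/N, connectance 2E/(N(N-1)), mean local clustering,
shortest-path metrics on the largest connected component) and can be
compared against an Erdos-Renyi ensemble with matched node and edge counts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.stats

from mica.io_formats import OTUTable, relative_abundance

logger = logging.getLogger(__name__)

__all__ = [
    "TopologyMetrics",
    "spearman_network",
    "sparcc_correlations",
    "topology_metrics",
    "random_graph_baseline",
]


@dataclass
class TopologyMetrics:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    connectance: float
    avg_degree: float
    avg_path_length: float
    clustering_coefficient: float
    diameter: float
    degree_centralization: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _spearman_pvalues(ranked: np.ndarray, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Correlation and two-sided p-value matrices for ranked data."""
    rho = np.corrcoef(ranked, rowvar=False)
    n_otus = rho.shape[0]
    if n_samples <= 9:
        # exact permutation null: enumerate all n! orderings once and use the
        # resulting rho distribution for every pair
        pvals = np.ones_like(rho)
        for i in range(n_otus):
            for j in range(i + 1, n_otus):
                x, y = ranked[:, i], ranked[:, j]
                obs = rho[i, j]
                count = 0
                total = 0
                for perm in itertools.permutations(range(n_samples)):
                    r = np.corrcoef(x, y[list(perm)])[0, 1]
                    count += abs(r) >= abs(obs) - 1e-12
                    total += 1
                pvals[i, j] = pvals[j, i] = count / total
        return rho, pvals
    # t-approximation with midrank ties
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n_samples - 2) / np.clip(1 - rho**2, 1e-300, None))
    pvals = 2 * scipy.stats.t.sf(np.abs(t), df=n_samples - 2)
    return rho, pvals


def spearman_network(
    table: OTUTable,
    rho_threshold: float = 0.6,
    q_threshold: float = 0.05,
    prevalence_filter: float = 0.0,
    corr: np.ndarray | None = None,
) -> nx.Graph:
    """Thresholded correlation network over OTUs.

    Edges connect OTU pairs with |Spearman rho| > ``rho_threshold`` and
    BH-corrected q < ``q_threshold`` (both conditions jointly).
    ``prevalence_filter`` drops OTUs present in fewer than that fraction of
    samples before testing. Passing a precomputed correlation matrix via
    ``corr`` (e.g. from :func:`sparcc_correlations`) swaps the correlation
    backend while keeping the same thresholding; p-values are then computed
    from the same t-approximation on the supplied coefficients.

    Nodes carry a ``relative_abundance`` attribute (mean across samples);
    edges carry ``weight`` (the correlation) and ``sign``.
    """
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples")
    rel = relative_abundance(table)
    prevalence = (table.counts > 0).mean(axis=0)
    keep = np.flatnonzero(prevalence >= prevalence_filter)
    if keep.size < 2:
        raise ValueError("fewer than 2 OTUs pass the prevalence filter")
    otu_ids = [table.otu_ids[i] for i in keep]
    sub = rel[:, keep]

    constant = sub.std(axis=0) == 0
    if constant.any():
        logger.info(
            "skipping %d constant OTU vectors: %s",
            constant.sum(),
            [otu_ids[i] for i in np.flatnonzero(constant)[:5]],
        )
    if corr is None:
        ranked = scipy.stats.rankdata(sub, axis=0)
        rho, pvals = _spearman_pvalues(ranked, table.n_samples)
    else:
        rho = np.asarray(corr, dtype=float)
        if rho.shape != (keep.size, keep.size):
            raise ValueError("corr matrix shape does not match filtered OTUs")
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((table.n_samples - 2) / np.clip(1 - rho**2, 1e-300, None))
        pvals = 2 * scipy.stats.t.sf(np.abs(t), df=table.n_samples - 2)

    g = nx.Graph()
    mean_rel = sub.mean(axis=0)
    for k, otu in enumerate(otu_ids):
        g.add_node(otu, relative_abundance=float(mean_rel[k]))

    iu = np.triu_indices(len(otu_ids), k=1)
    valid = ~(constant[iu[0]] | constant[iu[1]])
    flat_p = pvals[iu]
    flat_rho = rho[iu]
    qvals = np.full_like(flat_p, np.nan)
    qvals[valid] = scipy.stats.false_discovery_control(flat_p[valid], method="bh")
    for idx in np.flatnonzero(valid):
        i, j = iu[0][idx], iu[1][idx]
        r, q = flat_rho[idx], qvals[idx]
        if np.abs(r) > rho_threshold and q < q_threshold:
            g.add_edge(
                otu_ids[i],
                otu_ids[j],
                weight=float(r),
                q_value=float(q),
                sign="positive" if r > 0 else "negative",
            )
    return g


def sparcc_correlations(
    table: OTUTable,
    n_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """SparCC-style basis correlations for compositional data.

    Works on log-ratio variances: for components i, j with latent basis
    variances w_i, w_j and correlation r_ij,

        Var[log(x_i / x_j)] = w_i + w_j - 2 r_ij sqrt(w_i w_j),

    a linear system solvable for the w under the sparsity assumption that
    most pairs are uncorrelated. Strongly correlated pairs (|r| above
    ``exclusion_threshold`` quantile behavior: the single most correlated
    pair each round) are iteratively excluded from the variance equations
    and the basis is re-estimated. Zeros are handled by a pseudocount on
    counts before closure. Output is clipped to [-1, 1].
    """
    if table.n_otus < 4:
        raise ValueError("SparCC needs at least 4 OTUs")
    counts = table.counts + pseudocount
    frac = counts / counts.sum(axis=1, keepdims=True)
    logf = np.log(frac)
    D = table.n_otus
    # variation matrix: T_ij = Var[log(x_i/x_j)]
    T = np.var(logf[:, :, None] - logf[:, None, :], axis=0, ddof=1)

    excluded = np.zeros((D, D), dtype=bool)
    r = np.zeros((D, D))
    for _ in range(max(1, n_iterations)):
        # solve for basis variances: for each i,
        # sum_{j != i, not excluded} (w_i + w_j - T_ij) = 2 sum r_ij sqrt(w_i w_j) ~ 0
        mask = ~excluded
        np.fill_diagonal(mask, False)
        M_eff = np.where(mask, 1.0, 0.0)
        np.fill_diagonal(M_eff, mask.sum(axis=1))
        t_i = (T * mask).sum(axis=1)
        try:
            w = np.linalg.solve(M_eff, t_i)
        except np.linalg.LinAlgError:  # pragma: no cover - near-complete exclusion
            break
        w = np.clip(w, 1e-12, None)
        sw = np.sqrt(np.outer(w, w))
        r_new = (np.add.outer(w, w) - T) / (2.0 * sw)
        np.fill_diagonal(r_new, 1.0)
        r = np.clip(r_new, -1.0, 1.0)
        # exclude the most correlated not-yet-excluded pair if above threshold
        cand = np.abs(r).copy()
        cand[excluded] = 0.0
        np.fill_diagonal(cand, 0.0)
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        if excluded.sum() // 2 >= D * (D - 1) // 4:  # keep the system solvable
            break
        excluded[i, j] = excluded[j, i] = True
    return r


def topology_metrics(net: nx.Graph) -> TopologyMetrics:
    """Standard co-occurrence network topology summary.

    Path length and diameter are computed on the largest connected component
    (flagged by the docstring convention, since thresholded microbial
    networks are usually disconnected); clustering is the mean local
    clustering coefficient over nodes with degree >= 2.
    """
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n == 0:
        import warnings

        warnings.warn("empty graph; all metrics zero", stacklevel=2)
        return TopologyMetrics(0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    signs = [d.get("sign", "positive") for _, _, d in net.edges(data=True)]
    n_pos = sum(s == "positive" for s in signs)
    n_neg = e - n_pos
    avg_degree = 2.0 * e / n
    connectance = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    deg2 = [v for v in net.nodes if net.degree(v) >= 2]
    clustering = (
        float(np.mean(list(nx.clustering(net, deg2).values()))) if deg2 else 0.0
    )
    if e > 0:
        giant = net.subgraph(max(nx.connected_components(net), key=len))
        apl = nx.average_shortest_path_length(giant) if giant.number_of_nodes() > 1 else 0.0
        diam = float(nx.diameter(giant)) if giant.number_of_nodes() > 1 else 0.0
    else:
        apl = diam = 0.0
    # Freeman degree centralization
    if n > 2:
        degrees = np.array([d for _, d in net.degree()])
        centralization = float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))
    else:
        centralization = 0.0
    return TopologyMetrics(
        n_nodes=n,
        n_edges=e,
        n_positive=n_pos,
        n_negative=n_neg,
        connectance=connectance,
        avg_degree=avg_degree,
        avg_path_length=float(apl),
        clustering_coefficient=clustering,
        diameter=diam,
        degree_centralization=centralization,
    )


def random_graph_baseline(net: nx.Graph, n_random: int = 100, seed: int = 0):
    """Erdos-Renyi ensemble with the observed node and edge counts.

    Returns ``(summary, z_scores)``: per-metric means and standard
    deviations over the ensemble, and the observed metrics' z-scores
    against it (NaN where the ensemble shows no variation).
    """
    if n_random < 10:
        raise ValueError("n_random must be >= 10")
    n, e = net.number_of_nodes(), net.number_of_edges()
    obs = topology_metrics(net).as_dict()
    rng = np.random.default_rng(seed)
    draws = []
    for k in range(n_random):
        g = nx.gnm_random_graph(n, e, seed=int(rng.integers(2**31 - 1)))
        draws.append(topology_metrics(g).as_dict())
    numeric = [
        "connectance",
        "avg_degree",
        "avg_path_length",
        "clustering_coefficient",
        "diameter",
        "degree_centralization",
    ]
    summary = {
        k: {
            "mean": float(np.mean([d[k] for d in draws])),
            "sd": float(np.std([d[k] for d in draws])),
        }
        for k in numeric
    }
    z = {}
    for k in numeric:
        sd = summary[k]["sd"]
        z[k] = float((obs[k] - summary[k]["mean"]) / sd) if sd > 0 else float("nan")
    return summary, z
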