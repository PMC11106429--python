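"""Spearman-thresholded co-occurrence networks, topology metrics, and node roles.

The computational core of the pipeline.  OTU pairs whose abundance profiles
are strongly (|rho| > 0.7) and significantly (P < 0.01) rank-correlated
across samples become edges of a simple undirected graph; the graph is then
summarized by the standard topological parameters (average degree, edge
density, average path length, clustering, linkage density a.k.a.
complexity, modularity), partitioned into modules by seeded Louvain
modularity maximization, and each node is placed on the Guimera-Amaral
(Zi, Pi) plane:

    Zi = (k_is - mean_s) / sd_s        within-module degree z-score
    Pi = 1 - sum_s (k_is / k_i)^2      participation coefficient

with roles cut at Zi = 2.5 and Pi = 0.62 (peripheral / connector /
module hub / network hub).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .io import OtuTable

__all__ = [
    "CorrelationResult",
    "CooccurrenceNetwork",
    "NetworkTopology",
    "spearman_matrix",
    "spearman_exact_pvalue",
    "build_network",
    "topology",
    "detect_modules",
    "zi_pi",
    "classify_role",
    "ROLE_ZI_THRESHOLD",
    "ROLE_PI_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Guimera-Amaral role thresholds; boundary values fall in the lower category.
ROLE_ZI_THRESHOLD = 2.5
ROLE_PI_THRESHOLD = 0.62


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    """All-pairs Spearman coefficients and two-sided p-values for one table."""

    rho: np.ndarray
    p: np.ndarray
    otu_ids: tuple[str, ...]
    n_samples: int
    method: str = "spearman"


def spearman_matrix(table: OtuTable, min_prevalence: float = 0.0) -> CorrelationResult:
    """All-pairs Spearman correlation of OTU abundance profiles.

    OTUs present (nonzero) in fewer than ``min_prevalence`` of samples are
    dropped before correlation; constant OTUs (zero rank variance, rho
    undefined) are dropped with a logged warning.  Coefficients come from
    Pearson correlation of average-ranked data (ties averaged); two-sided
    p-values use the t-approximation ``t = rho sqrt((n-2)/(1-rho^2))`` on
    n - 2 degrees of freedom, with p = 0 at |rho| = 1.
    """
    if table.n_samples < 4:
        raise ValueError("Spearman thresholding needs at least 4 samples")
    if table.n_samples < 10:
        logger.warning(
            "only %d samples: P < 0.01 requires |rho| near 1 at this n",
            table.n_samples,
        )
    counts = table.counts
    keep = np.ones(table.n_otus, dtype=bool)
    if min_prevalence > 0:
        prevalence = (counts > 0).mean(axis=1)
        keep &= prevalence >= min_prevalence
    constant = np.ptp(counts, axis=1) == 0
    if np.any(constant & keep):
        dropped = [table.otu_ids[i] for i in np.flatnonzero(constant & keep)]
        logger.warning("dropping %d constant OTU(s): %s", len(dropped),
                       ", ".join(dropped[:10]))
        keep &= ~constant
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        raise ValueError("fewer than 2 OTUs remain after filtering")

    n = table.n_samples
    ranks = np.apply_along_axis(rankdata, 1, counts[idx].astype(float))
    rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    np.fill_diagonal(p, 0.0)
    p = (p + p.T) / 2  # enforce exact symmetry

    return CorrelationResult(rho=rho, p=p,
                             otu_ids=tuple(table.otu_ids[i] for i in idx),
                             n_samples=n)


def spearman_exact_pvalue(x, y) -> float:
    """Exact two-sided permutation p-value for Spearman's rho (n <= 8).

    Enumerates all n! rank permutations; intended for the very small sample
    sizes where the t-approximation is unreliable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 8:
        raise ValueError("exact enumeration supported only for n <= 8")
    rx, ry = rankdata(x), rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CooccurrenceNetwork:
    """Simple undirected OTU graph; every edge satisfies the stored thresholds."""

    graph: nx.Graph = field(repr=False)
    rho_min: float
    p_max: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}


def build_network(corr: CorrelationResult, rho_min: float = 0.7,
                  p_max: float = 0.01,
                  positive_only: bool = False) -> CooccurrenceNetwork:
    """Threshold a correlation matrix into a co-occurrence network.

    An edge (i, j) is retained iff |rho_ij| > rho_min (strict) and
    p_ij < p_max (strict); with ``positive_only`` the criterion is
    rho_ij > rho_min, discarding strong negative correlations.  Nodes are
    the OTUs incident to at least one retained edge — isolated OTUs are
    excluded, so node counts reflect the drawn network.  An empty network
    is a valid result.
    """
    strength = corr.rho if positive_only else np.abs(corr.rho)
    mask = (strength > rho_min) & (corr.p < p_max)
    np.fill_diagonal(mask, False)
    g = nx.Graph()
    ii, jj = np.nonzero(np.triu(mask, k=1))
    for i, j in zip(ii, jj):
        r = float(corr.rho[i, j])
        g.add_edge(corr.otu_ids[i], corr.otu_ids[j],
                   rho=r, sign="+" if r >= 0 else "-", weight=abs(r))
    return CooccurrenceNetwork(graph=g, rho_min=rho_min, p_max=p_max)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkTopology:
    """The standard topological parameter vector of one network.

    ``complexity`` is linkage density E/N; identities
    average_degree = 2E/N and edge_density = 2E/(N(N-1)) hold exactly.
    Metrics of an empty network are NaN, not zero.
    """

    nodes: int
    edges: int
    edge_density: float
    average_degree: float
    average_path_length: float
    average_clustering_coefficient: float
    complexity: float
    modularity: float
    n_modules: int


def _average_path_length(g: nx.Graph, mode: str = "pairs") -> float:
    """Mean shortest-path length, unweighted.

    ``mode="pairs"``: mean over all connected pairs (multi-component graphs
    average within components).  ``mode="lcc"``: restrict to the largest
    connected component.
    """
    if g.number_of_nodes() < 2:
        return math.nan
    if mode == "lcc":
        comp = max(nx.connected_components(g), key=len)
        sub = g.subgraph(comp)
        return nx.average_shortest_path_length(sub) if len(comp) > 1 else math.nan
    if mode != "pairs":
        raise ValueError(f"unknown path-length mode {mode!r}")
    total = 0.0
    n_pairs = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        n_pairs += len(comp) * (len(comp) - 1)
    return total / n_pairs if n_pairs else math.nan


def topology(network: CooccurrenceNetwork | nx.Graph,
             modules: dict[str, int] | None = None,
             path_length_mode: str = "pairs") -> NetworkTopology:
    """Compute the topological parameter vector of a network.

    Average path length is the mean over connected node pairs (per-component
    averaging; switch with `path_length_mode`); clustering is the mean local
    clustering coefficient with degree-<2 nodes contributing 0; modularity is
    Newman's Q of the supplied partition (detected with a default seed when
    `modules` is omitted and the network has edges).
    """
    g = network.graph if isinstance(network, CooccurrenceNetwork) else network
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return NetworkTopology(0, 0, math.nan, math.nan, math.nan, math.nan,
                               math.nan, math.nan, 0)
    if modules is None and e > 0:
        modules = detect_modules(network if isinstance(network, CooccurrenceNetwork)
                                 else CooccurrenceNetwork(g, math.nan, math.nan))
    avg_degree = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1)) if n > 1 else math.nan
    complexity = e / n
    apl = _average_path_length(g, mode=path_length_mode)
    clustering = nx.average_clustering(g) if n else math.nan
    if modules:
        parts: dict[int, set] = {}
        for node, m in modules.items():
            parts.setdefault(m, set()).add(node)
        q = nx.algorithms.community.modularity(g, parts.values()) if e else math.nan
        n_modules = len(parts)
    else:
        q, n_modules = math.nan, 0
    return NetworkTopology(nodes=n, edges=e, edge_density=density,
                           average_degree=avg_degree, average_path_length=apl,
                           average_clustering_coefficient=clustering,
                           complexity=complexity, modularity=q,
                           n_modules=n_modules)


# ---------------------------------------------------------------------------
# Modules and node roles
# ---------------------------------------------------------------------------

def detect_modules(network: CooccurrenceNetwork | nx.Graph,
                   seed: int = 0) -> dict[str, int]:
    """Seeded Louvain modularity maximization (resolution 1.0).

    Module ids are canonicalized by decreasing module size (ties broken by
    smallest member) so identical inputs and seeds give identical labels.
    """
    g = network.graph if isinstance(network, CooccurrenceNetwork) else network
    if g.number_of_edges() == 0:
        raise ValueError("module detection needs at least one edge")
    comms = nx.algorithms.community.louvain_communities(g, seed=seed, weight=None)
    ordered = sorted(comms, key=lambda c: (-len(c), min(str(v) for v in c)))
    return {node: m for m, comm in enumerate(ordered) for node in comm}


def zi_pi(network: CooccurrenceNetwork | nx.Graph,
          modules: dict[str, int]) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardizes a node's within-module degree against the mean and SD of
    within-module degrees over its own module (Zi = 0 when the module's SD is
    zero: identical nodes are not hubs).  Pi = 1 - sum_s (k_is/k_i)^2 over
    all modules the node touches.  Returns a per-node table with module id,
    degree, zi, pi, and the role from :func:`classify_role`.
    """
    g = network.graph if isinstance(network, CooccurrenceNetwork) else network
    missing = [v for v in g.nodes if v not in modules]
    if missing:
        raise ValueError(f"node {missing[0]!r} missing from module map")

    # within-module degree of every node
    k_within = {v: 0 for v in g.nodes}
    k_by_module: dict[str, dict[int, int]] = {v: {} for v in g.nodes}
    for u, v in g.edges:
        mu, mv = modules[u], modules[v]
        k_by_module[u][mv] = k_by_module[u].get(mv, 0) + 1
        k_by_module[v][mu] = k_by_module[v].get(mu, 0) + 1
        if mu == mv:
            k_within[u] += 1
            k_within[v] += 1

    module_stats: dict[int, tuple[float, float]] = {}
    for m in set(modules[v] for v in g.nodes):
        ks = np.array([k_within[v] for v in g.nodes if modules[v] == m], dtype=float)
        module_stats[m] = (float(ks.mean()), float(ks.std()))  # population SD

    records = []
    for v in g.nodes:
        k = g.degree(v)
        if k == 0:
            continue  # cannot occur for thresholded networks; guard for raw graphs
        mean, sd = module_stats[modules[v]]
        zi = (k_within[v] - mean) / sd if sd > 0 else 0.0
        pi = 1.0 - sum((ks / k) ** 2 for ks in k_by_module[v].values())
        records.append({"otu": v, "module": modules[v], "degree": k,
                        "zi": zi, "pi": pi, "role": classify_role(zi, pi)})
    df = pd.DataFrame.from_records(records).set_index("otu")
    return df


def classify_role(zi: float, pi: float) -> str:
    """Place a node in the (Zi, Pi) role grid with thresholds 2.5 and 0.62.

    Boundary values (exactly 2.5 or 0.62) go to the lower category — the
    hub/connector conditions are strict 'greater than'.
    """
    if not 0.0 <= pi <= 1.0 + 1e-12:
        raise ValueError(f"participation coefficient {pi} outside [0, 1]")
    hub = zi > ROLE_ZI_THRESHOLD
    connector = pi > ROLE_PI_THRESHOLD
    if hub and connector:
        return "network_hub"
    if hub:
        return "module_hub"
    if connector:
        return "connector"
    return "peripheral"
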