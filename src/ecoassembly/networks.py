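"""Compositionality-aware co-occurrence networks.

Counts from amplicon or metagenomic profiling are compositional: only
relative information survives sequencing, so ordinary correlations between
relative abundances are spurious.  SparCC infers the correlations of the
unobserved *basis* abundances from log-ratio variances
``t_ij = var(log(x_i / x_j))`` under a sparsity assumption, iteratively
excluding strongly correlated pairs from the basis-variance system.

The module builds networks from those correlations: bootstrap p-values,
Benjamini-Hochberg correction, kingdom-aware |r| thresholds (within-kingdom
edges need stronger correlation than cross-kingdom ones), topology summary
statistics, hub detection, and a Kolmogorov-Smirnov comparison of degree
distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable
from .diversity import PermutationTestResult


# ---------------------------------------------------------------------------
# prevalence filter
# ---------------------------------------------------------------------------

def prevalence_filter(
    table: FeatureTable,
    min_samples: int = 3,
    min_count: int = 20,
    mode: str = "per_sample",
) -> FeatureTable:
    """Drop rare taxa before correlation inference.

    ``mode='per_sample'`` (default) keeps a taxon when its count exceeds
    ``min_count`` in at least ``min_samples`` samples.  The alternative
    reading, ``mode='presence_total'``, keeps taxa present (count > 0) in at
    least ``min_samples`` samples whose total count exceeds ``min_count``.
    """
    if mode == "per_sample":
        keep = (table.counts > min_count).sum(axis=0) >= min_samples
    elif mode == "presence_total":
        keep = ((table.counts > 0).sum(axis=0) >= min_samples) & (
            table.counts.sum(axis=0) > min_count
        )
    else:
        raise ValueError(f"unknown prevalence mode {mode!r}")
    kept = [t for t, k in zip(table.taxon_ids, keep) if k]
    if not kept:
        warnings.warn("prevalence filter removed every taxon", stacklevel=2)
        return table.select_taxa([])
    return table.select_taxa(kept)


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------

def _log_fractions(counts: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
    """Log component fractions; Dirichlet posterior mean (counts + 1) by
    default, or a random Dirichlet draw when a generator is supplied."""
    pseudo = counts + 1.0
    if rng is None:
        fracs = pseudo / pseudo.sum(axis=1, keepdims=True)
    else:
        fracs = np.vstack([rng.dirichlet(row) for row in pseudo])
    return np.log(fracs)


def _basis_correlations(
    logf: np.ndarray, exclusion_threshold: float, max_exclusions: int
) -> np.ndarray:
    """Solve the SparCC basis-variance system with iterative pair exclusion."""
    d = logf.shape[1]
    cov = np.cov(logf, rowvar=False)
    var = np.diag(cov)
    # variation matrix: t_ij = var(log xi) + var(log xj) - 2 cov
    t = var[:, None] + var[None, :] - 2.0 * cov
    included = ~np.eye(d, dtype=bool)
    excluded_pairs = 0
    while True:
        deg = included.sum(axis=1)
        a = included.astype(float)
        np.fill_diagonal(a, deg)
        b = (t * included).sum(axis=1)
        omega2 = np.linalg.solve(a, b)
        omega2 = np.clip(omega2, 1e-12, None)
        omega = np.sqrt(omega2)
        r = (omega2[:, None] + omega2[None, :] - t) / (2.0 * np.outer(omega, omega))
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        if excluded_pairs >= max_exclusions:
            break
        masked = np.where(included, np.abs(r), 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        if deg[i] <= 2 or deg[j] <= 2:  # excluding would degenerate the system
            break
        included[i, j] = included[j, i] = False
        excluded_pairs += 1
    return r


def sparcc(
    table: FeatureTable,
    n_outer: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusions: int | None = None,
    seed: int = 0,
    sampled_fractions: bool = False,
) -> np.ndarray:
    """SparCC basis correlations for all taxon pairs.

    Fractions are estimated by the Dirichlet posterior mean (counts + 1),
    which is deterministic, so a single pass suffices; with
    ``sampled_fractions=True`` each of ``n_outer`` passes draws fractions
    from the Dirichlet posterior and the element-wise median is returned.
    Pairs whose |r| exceeds ``exclusion_threshold`` are iteratively removed
    from the basis-variance system (strongly correlated pairs violate the
    sparsity assumption), up to ``max_exclusions`` (default: n_taxa).
    """
    if table.n_taxa < 4:
        raise ValueError("SparCC needs at least 4 taxa (basis system underdetermined)")
    if (table.sample_totals() == 0).any():
        raise ValueError("samples with zero total cannot be normalised")
    if max_exclusions is None:
        max_exclusions = table.n_taxa
    counts = table.counts.astype(float)
    if not sampled_fractions:
        logf = _log_fractions(counts, None)
        return _basis_correlations(logf, exclusion_threshold, max_exclusions)
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n_outer):
        logf = _log_fractions(counts, rng)
        runs.append(_basis_correlations(logf, exclusion_threshold, max_exclusions))
    return np.median(np.stack(runs), axis=0)


def sparcc_pvalues(
    table: FeatureTable,
    observed_r: np.ndarray,
    n_bootstrap: int = 1000,
    seed: int = 0,
    **sparcc_kwargs,
) -> np.ndarray:
    """Two-sided resampling p-values for SparCC correlations.

    Each of ``n_bootstrap`` iterations shuffles every taxon's counts
    independently across samples — destroying all between-taxon association
    while preserving each taxon's marginal count distribution — and
    recomputes SparCC on the shuffled table.
    ``p_ij = (1 + #{|r_null| >= |r_obs|}) / (1 + n_bootstrap)``, so p can
    never be exactly zero.  The diagonal is NaN (self-correlations are not
    tested).
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    rng = np.random.default_rng(seed)
    n = table.n_samples
    abs_obs = np.abs(observed_r)
    exceed = np.zeros_like(abs_obs)
    for _ in range(n_bootstrap):
        shuffled = np.empty_like(table.counts)
        for j in range(table.n_taxa):
            shuffled[:, j] = table.counts[rng.permutation(n), j]
        # independent shuffles can empty a sparse sample; such rows carry no
        # information and are dropped from the null replicate
        keep = shuffled.sum(axis=1) > 0
        boot = FeatureTable(
            counts=shuffled[keep],
            sample_ids=[s for s, k in zip(table.sample_ids, keep) if k],
            taxon_ids=list(table.taxon_ids),
            taxonomy=list(table.taxonomy),
            kingdom=list(table.kingdom),
        )
        r_null = sparcc(boot, seed=int(rng.integers(2**31 - 1)), **sparcc_kwargs)
        exceed += np.abs(r_null) >= abs_obs
    p = (1.0 + exceed) / (1.0 + n_bootstrap)
    np.fill_diagonal(p, np.nan)
    return p


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order- and shape-preserving.

    NaN entries are passed through untouched.
    """
    p = np.asarray(p_values, dtype=float)
    flat = p.ravel()
    finite = ~np.isnan(flat)
    if ((flat[finite] < 0) | (flat[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = flat.copy()
    if finite.any():
        out[finite] = multipletests(flat[finite], method="fdr_bh")[1]
    return out.reshape(p.shape)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@dataclass
class NetworkEdge:
    taxon_a: str
    taxon_b: str
    correlation: float
    p_value: float
    p_adjusted: float

    @property
    def sign(self) -> str:
        return "positive" if self.correlation > 0 else "negative"


@dataclass
class NetworkNode:
    taxon: str
    kingdom: str
    mean_relative_abundance: float


@dataclass
class CorrelationNetwork:
    """Taxa nodes plus signed, significance-filtered correlation edges."""

    nodes: list[NetworkNode]
    edges: list[NetworkEdge]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if e.taxon_a == e.taxon_b:
                raise ValueError(f"self-edge on {e.taxon_a!r}")
            key = frozenset((e.taxon_a, e.taxon_b))
            if key in seen:
                raise ValueError(f"duplicate edge {e.taxon_a!r} - {e.taxon_b!r}")
            seen.add(key)

    def degree(self) -> dict:
        deg = {n.taxon: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.taxon_a] += 1
            deg[e.taxon_b] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(
                n.taxon,
                kingdom=n.kingdom,
                mean_relative_abundance=n.mean_relative_abundance,
            )
        for e in self.edges:
            g.add_edge(
                e.taxon_a,
                e.taxon_b,
                correlation=e.correlation,
                p_adjusted=e.p_adjusted,
                sign=e.sign,
            )
        return g


def build_network(
    r: np.ndarray,
    p_adj: np.ndarray,
    table: FeatureTable,
    threshold_within: float = 0.9,
    threshold_cross: float = 0.8,
    alpha: float = 0.01,
    keep_isolated: bool = False,
) -> CorrelationNetwork:
    """Retain edges passing the kingdom-aware |r| threshold and adjusted-p
    cutoff.

    Within-kingdom pairs (bacteria-bacteria, fungi-fungi) require
    ``|r| > threshold_within``; cross-kingdom pairs ``|r| > threshold_cross``;
    every edge additionally needs ``p_adj < alpha``.  Nodes without edges are
    dropped unless ``keep_isolated``.
    """
    t = table.n_taxa
    if r.shape != (t, t) or p_adj.shape != (t, t):
        raise ValueError("correlation / p-value matrices do not match the table")
    mean_rel = table.relative_abundance().mean(axis=0)
    edges = []
    for i, j in combinations(range(t), 2):
        threshold = (
            threshold_within
            if table.kingdom[i] == table.kingdom[j]
            else threshold_cross
        )
        if np.isnan(p_adj[i, j]):
            continue
        if abs(r[i, j]) > threshold and p_adj[i, j] < alpha:
            edges.append(
                NetworkEdge(
                    taxon_a=table.taxon_ids[i],
                    taxon_b=table.taxon_ids[j],
                    correlation=float(r[i, j]),
                    p_value=float("nan"),
                    p_adjusted=float(p_adj[i, j]),
                )
            )
    connected = {e.taxon_a for e in edges} | {e.taxon_b for e in edges}
    nodes = [
        NetworkNode(
            taxon=taxon,
            kingdom=table.kingdom[k],
            mean_relative_abundance=float(mean_rel[k]),
        )
        for k, taxon in enumerate(table.taxon_ids)
        if keep_isolated or taxon in connected
    ]
    return CorrelationNetwork(
        nodes=nodes,
        edges=edges,
        provenance={
            "threshold_within": threshold_within,
            "threshold_cross": threshold_cross,
            "alpha": alpha,
        },
    )


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    diameter: int
    radius: int
    mean_degree: float
    heterogeneity: float
    centralization: float
    degree_per_node: dict


def network_stats(network: CorrelationNetwork) -> NetworkTopology:
    """Summary topology; diameter and radius are computed on the largest
    connected component (unweighted, undirected).

    ``heterogeneity = sd(degree) / mean(degree)`` and
    ``centralization = sum(k_max - k_i) / ((n - 1)(n - 2))``.
    """
    g = network.to_networkx()
    deg = dict(g.degree())
    n = g.number_of_nodes()
    if n == 0:
        return NetworkTopology(0, 0, 0, 0, 0, 0, 0.0, 0.0, 0.0, {})
    n_pos = sum(1 for e in network.edges if e.sign == "positive")
    n_neg = len(network.edges) - n_pos
    degrees = np.array(list(deg.values()), dtype=float)
    mean_deg = degrees.mean()
    heterogeneity = float(degrees.std() / mean_deg) if mean_deg > 0 else 0.0
    if n > 2:
        centralization = float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))
    else:
        centralization = 0.0
    if g.number_of_edges() > 0:
        largest = g.subgraph(max(nx.connected_components(g), key=len))
        diameter = int(nx.diameter(largest))
        radius = int(nx.radius(largest))
    else:
        diameter = radius = 0
    return NetworkTopology(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        n_positive=n_pos,
        n_negative=n_neg,
        diameter=diameter,
        radius=radius,
        mean_degree=float(mean_deg),
        heterogeneity=heterogeneity,
        centralization=centralization,
        degree_per_node=deg,
    )


def find_hubs(network: CorrelationNetwork, min_degree_exclusive: int = 4) -> list[str]:
    """Taxa with degree strictly greater than ``min_degree_exclusive``,
    sorted by degree descending, then identifier."""
    deg = network.degree()
    hubs = [t for t, d in deg.items() if d > min_degree_exclusive]
    return sorted(hubs, key=lambda t: (-deg[t], t))


def ks_compare(values_a: Sequence[float], values_b: Sequence[float]) -> PermutationTestResult:
    """Two-sample Kolmogorov-Smirnov test with the asymptotic p-value."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot compare an empty sequence")
    res = sps.ks_2samp(a, b, method="asymp")
    return PermutationTestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_permutations=0,
        extra={"method": "ks_2samp asymptotic"},
    )


def compare_degree_distributions(
    net_a: CorrelationNetwork, net_b: CorrelationNetwork
) -> PermutationTestResult:
    """KS comparison of the two networks' node-degree sequences.

    Degree sequences are integer-valued, so ties make the asymptotic KS
    p-value conservative; the test never over-rejects.
    """
    deg_a = list(net_a.degree().values())
    deg_b = list(net_b.degree().values())
    if not deg_a or not deg_b:
        raise ValueError("both networks must have at least one node")
    return ks_compare(deg_a, deg_b)
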