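"""Synthetic communities with known ground truth.

Every downstream stage of the pipeline is validated against data generated
here: metacommunities assembled under a known ecological regime (so the
assembly null models can be asked to recover it), compositional counts with
a known log-scale basis correlation (so SparCC recovery can be scored), and
count tables with planted gradient-responsive taxa (so the trajectory stage
has labelled positives).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import skbio

from .containers import FeatureTable, SampleMetadata

REGIMES = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "neutral",
)

DEFAULT_GROUPS = ("low", "medium", "high")


# ---------------------------------------------------------------------------
# phylogeny + traits
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int) -> skbio.TreeNode:
    """Simulate a Yule (pure-birth) tree with ``n_taxa`` tips.

    Lineages split at rate 1 per lineage; the tree is ultrametric and is
    rescaled so the root-to-tip height is exactly 1.  Tips are labelled
    ``t1 ... tn`` in tree traversal order.
    """
    if n_taxa < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    root = skbio.TreeNode()
    active: list[skbio.TreeNode] = []
    birth = {}
    t = 0.0
    for _ in range(2):  # root splits immediately; height measured from root
        child = skbio.TreeNode()
        root.append(child)
        active.append(child)
        birth[id(child)] = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(rng.integers(k))
        node.length = t - birth[id(node)]
        for _ in range(2):
            child = skbio.TreeNode()
            node.append(child)
            active.append(child)
            birth[id(child)] = t
    t_end = t + rng.exponential(1.0 / n_taxa)
    for node in active:
        node.length = t_end - birth[id(node)]
    root.length = None
    for node in root.traverse(include_self=False):
        node.length = node.length / t_end
    for i, tip in enumerate(root.tips()):
        tip.name = f"t{i + 1}"
    return root


def evolve_trait(tree: skbio.TreeNode, rate: float, seed: int) -> pd.Series:
    """Evolve a continuous trait along the tree by Brownian motion.

    The root trait is 0 and each branch adds an independent Gaussian step
    with variance ``rate * branch_length``, so a tip's trait variance equals
    ``rate`` times its root-to-tip distance.  Returns a Series indexed by
    tip name.
    """
    if rate <= 0:
        raise ValueError("Brownian rate must be positive")
    rng = np.random.default_rng(seed)
    value = {id(tree): 0.0}
    traits = {}
    for node in tree.preorder(include_self=False):
        length = node.length if node.length is not None else 0.0
        step = rng.normal(0.0, np.sqrt(rate * length)) if length > 0 else 0.0
        value[id(node)] = value[id(node.parent)] + step
        if node.is_tip():
            traits[node.name] = value[id(node)]
    return pd.Series(traits, dtype=float)


# ---------------------------------------------------------------------------
# metacommunity regimes
# ---------------------------------------------------------------------------

@dataclass
class RegimeSpec:
    """Parameters of a synthetic metacommunity assembled under one regime.

    ``selection_strength`` is the niche breadth sigma_w of the Gaussian
    environmental filter (trait units); ``trait_signal`` is the Brownian
    rate on the unit-height tree, so tip traits have standard deviation
    ~sqrt(trait_signal).  Environments are placed at quantiles of the
    realized tip-trait distribution (0.9 for the single shared environment
    of homogeneous selection; spread over 0.1-0.9 across groups for
    heterogeneous selection), which keeps the filter over a populated part
    of trait space on every simulated tree.  ``pool_jitter`` is the
    standard deviation of per-sample log-normal noise on pool abundances in
    the selection regimes (local environmental variation, so replicate
    samples share a clade neighbourhood without sharing identical taxon
    sets).  ``immigration`` is the Hubbell immigration probability m of the
    neutral regime.
    """

    regime: str
    n_samples_per_group: int = 5
    n_taxa: int = 800
    depth: int = 1000
    selection_strength: float = 0.15
    trait_signal: float = 1.0
    pool_jitter: float = 1.0
    n_regions: int = 3
    immigration: float = 0.1
    groups: Sequence[str] = DEFAULT_GROUPS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        for name in ("n_samples_per_group", "n_taxa", "depth", "n_regions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.immigration <= 1.0:
            raise ValueError("immigration must lie in [0, 1]")
        if self.pool_jitter < 0:
            raise ValueError("pool_jitter must be non-negative")
        if self.regime.endswith("selection") and self.selection_strength <= 0:
            raise ValueError("selection_strength must be positive for selection regimes")


#: trait quantile of the single shared environment (homogeneous selection)
HOMOGENEOUS_ENV_QUANTILE = 0.9
#: trait quantile range spanned by group environments (heterogeneous selection)
HETEROGENEOUS_ENV_QUANTILES = (0.1, 0.9)


def simulate_metacommunity(
    spec: RegimeSpec,
) -> tuple[FeatureTable, skbio.TreeNode, SampleMetadata, pd.DataFrame]:
    """Assemble a metacommunity under the regime named in ``spec``.

    Returns the count table, the phylogeny used, per-sample metadata
    (``group`` column), and a truth frame with the per-sample environment
    or region and the regime name.
    """
    rng = np.random.default_rng(spec.seed)
    tree = simulate_tree(spec.n_taxa, seed=int(rng.integers(2**31 - 1)))
    traits = evolve_trait(tree, spec.trait_signal, seed=int(rng.integers(2**31 - 1)))
    taxa = list(traits.index)
    trait_vals = traits.to_numpy()
    # regional pool: log-normal abundances, so richness/evenness resemble
    # amplicon tables
    pool = rng.lognormal(0.0, 1.0, size=spec.n_taxa)
    pool /= pool.sum()

    groups = list(spec.groups)
    n = spec.n_samples_per_group * len(groups)
    sample_ids = [f"s{i + 1}" for i in range(n)]
    group_of = np.repeat(groups, spec.n_samples_per_group)
    counts = np.zeros((n, spec.n_taxa), dtype=np.int64)
    truth_extra = np.empty(n, dtype=object)

    if spec.regime in ("homogeneous_selection", "heterogeneous_selection"):
        if spec.regime == "homogeneous_selection":
            envs = {g: float(np.quantile(trait_vals, HOMOGENEOUS_ENV_QUANTILE)) for g in groups}
        else:
            lo, hi = HETEROGENEOUS_ENV_QUANTILES
            qs = np.linspace(lo, hi, len(groups))
            envs = {g: float(np.quantile(trait_vals, q)) for g, q in zip(groups, qs)}
        for i in range(n):
            e = envs[group_of[i]]
            filt = np.exp(-((trait_vals - e) ** 2) / (2.0 * spec.selection_strength**2))
            w = pool * np.exp(rng.normal(0.0, spec.pool_jitter, spec.n_taxa)) * filt
            if w.sum() <= 0:
                raise RuntimeError("environmental filter left no viable taxa")
            counts[i] = rng.multinomial(spec.depth, w / w.sum())
            truth_extra[i] = f"env={e:.3g}"
    elif spec.regime == "dispersal_limitation":
        region = rng.permutation(np.arange(spec.n_taxa) % spec.n_regions)
        for i in range(n):
            r = i % spec.n_regions
            w = np.where(region == r, pool, 0.0)
            first = rng.multinomial(spec.depth, w / w.sum())
            counts[i] = rng.multinomial(spec.depth, first / first.sum())  # drift step
            truth_extra[i] = f"region={r}"
    elif spec.regime == "homogenizing_dispersal":
        for i in range(n):
            counts[i] = rng.multinomial(spec.depth, pool)
            truth_extra[i] = "pool"
    else:  # neutral: one-step immigration-drift from the shared pool
        for i in range(n):
            local = rng.multinomial(spec.depth, pool).astype(float)
            mix = (1.0 - spec.immigration) * local / spec.depth + spec.immigration * pool
            counts[i] = rng.multinomial(spec.depth, mix / mix.sum())
            truth_extra[i] = "neutral"

    table = FeatureTable(counts=counts, sample_ids=sample_ids, taxon_ids=taxa)
    metadata = SampleMetadata(pd.DataFrame({"group": group_of}, index=sample_ids))
    truth = pd.DataFrame(
        {"regime": spec.regime, "group": group_of, "condition": truth_extra},
        index=sample_ids,
    )
    return table, tree, metadata, truth


# ---------------------------------------------------------------------------
# compositional counts with known basis correlation
# ---------------------------------------------------------------------------

@dataclass
class BasisCorrelationSpec:
    """Log-normal basis abundances with a known log-scale correlation."""

    n_taxa: int
    n_samples: int
    depth: int
    correlation: np.ndarray | None = None  # identity when omitted
    log_mean: np.ndarray | float = 0.0
    log_sd: np.ndarray | float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be positive")
        if self.n_samples < 1 or self.n_taxa < 1:
            raise ValueError("n_samples and n_taxa must be positive")
        if self.correlation is None:
            self.correlation = np.eye(self.n_taxa)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.correlation.shape != (self.n_taxa, self.n_taxa):
            raise ValueError("correlation matrix shape does not match n_taxa")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(self.correlation).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")


def correlation_with_pairs(n_taxa: int, pairs: Sequence[tuple[int, int, float]]) -> np.ndarray:
    """Identity correlation with planted entries ``(i, j, r)`` — a
    convenience for building :class:`BasisCorrelationSpec` inputs."""
    corr = np.eye(n_taxa)
    for i, j, r in pairs:
        corr[i, j] = corr[j, i] = r
    return corr


def simulate_compositional_counts(spec: BasisCorrelationSpec) -> FeatureTable:
    """Draw multinomial counts whose basis is multivariate log-normal.

    Per sample the unobserved basis abundances are
    ``exp(log_mean + log_sd * z)`` with ``z`` multivariate normal under the
    spec's correlation; observed counts are a multinomial draw of ``depth``
    reads from the closed (sum-to-one) fractions — the data-generating model
    SparCC assumes.
    """
    rng = np.random.default_rng(spec.seed)
    # eigendecomposition square root: tolerant of semi-definite inputs
    evals, evecs = np.linalg.eigh(spec.correlation)
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    z = rng.standard_normal((spec.n_samples, spec.n_taxa)) @ root.T
    log_abund = np.asarray(spec.log_mean) + np.asarray(spec.log_sd) * z
    basis = np.exp(log_abund)
    fractions = basis / basis.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(spec.depth, f) for f in fractions])
    return FeatureTable(
        counts=counts,
        sample_ids=[f"s{i + 1}" for i in range(spec.n_samples)],
        taxon_ids=[f"t{j + 1}" for j in range(spec.n_taxa)],
    )


# ---------------------------------------------------------------------------
# gradient-responsive taxa
# ---------------------------------------------------------------------------

PATTERNS = ("group1_low_only", "group2_medium_high", "group3_high_only")

_PATTERN_ZONES = {
    "group1_low_only": ("low",),
    "group2_medium_high": ("medium", "high"),
    "group3_high_only": ("high",),
}


def simulate_gradient_taxa(
    n_samples_per_group: int,
    n_taxa: int,
    n_responsive: int,
    effect: float,
    noise_sd: float,
    seed: int,
    groups: Sequence[str] = DEFAULT_GROUPS,
) -> tuple[FeatureTable, SampleMetadata, pd.Series]:
    """Plant taxa whose abundance peaks in designated zones of a gradient.

    Baseline per-taxon abundances are log-normal; each responsive taxon is
    multiplied by ``effect`` in the zones of its pattern (low-only,
    medium+high, or high-only, cycling over the planted taxa).  Counts are
    the rounded abundances.  Returns the table, metadata, and per-taxon
    truth labels (``none`` for non-responsive taxa).
    """
    if n_responsive > n_taxa:
        raise ValueError("n_responsive cannot exceed n_taxa")
    if effect <= 1:
        raise ValueError("effect must be a fold-change > 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if list(groups) != list(DEFAULT_GROUPS):
        raise ValueError("the gradient generator uses the ordered zones low/medium/high")
    rng = np.random.default_rng(seed)
    n = n_samples_per_group * len(groups)
    group_of = np.repeat(list(groups), n_samples_per_group)
    taxon_ids = [f"t{j + 1}" for j in range(n_taxa)]
    truth = pd.Series("none", index=taxon_ids, dtype=object)

    # responsive taxa get a common baseline that clears the downstream >1 %
    # relative-abundance filter only in their peak zones; the background
    # carries most of the community mass so that boosting taxa in one zone
    # barely perturbs the relative abundance of the others (compositional
    # coupling would otherwise distort the planted patterns)
    log_base = rng.normal(np.log(20.0), 1.0, size=n_taxa)
    log_base[:n_responsive] = np.log(30.0)
    patterns = [PATTERNS[j % 3] for j in range(n_responsive)]
    truth.iloc[:n_responsive] = patterns

    log_effect = np.zeros((n, n_taxa))
    for j, pat in enumerate(patterns):
        in_zone = np.isin(group_of, _PATTERN_ZONES[pat])
        log_effect[in_zone, j] = np.log(effect)
    abundance = np.exp(log_base[None, :] + log_effect + rng.normal(0.0, noise_sd, (n, n_taxa)))
    counts = np.rint(abundance).astype(np.int64)
    sample_ids = [f"s{i + 1}" for i in range(n)]
    table = FeatureTable(counts=counts, sample_ids=sample_ids, taxon_ids=taxon_ids)
    metadata = SampleMetadata(pd.DataFrame({"group": group_of}, index=sample_ids))
    return table, metadata, truth
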