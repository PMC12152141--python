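"""Phylogenetic and taxonomic null models of community assembly.

Quantifies, for every pair of communities, how far observed phylogenetic
turnover (beta mean nearest taxon distance, betaMNTD) and taxonomic turnover
(Bray-Curtis) deviate from null expectations, and translates the two
standardized deviations — betaNTI and RC_bray — into a five-way
classification of the dominant ecological assembly process:

* betaNTI < -2            -> homogeneous selection
* betaNTI > +2            -> heterogeneous (variable) selection
* |betaNTI| < 2, RC > +0.95 -> dispersal limitation
* |betaNTI| < 2, RC < -0.95 -> homogenizing dispersal
* otherwise               -> undominated (no single dominant process)

Thresholds use strict inequalities; boundary values fall to the stochastic /
undominated side.  The betaNTI null shuffles taxon labels across the tips of
the phylogeny; the RC_bray null reassembles each community probabilistically
while preserving its observed richness and total abundance, with presence
probability proportional to occupancy and abundance filling proportional to
mean relative abundance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import skbio

from .containers import DistanceMatrix, FeatureTable, SampleMetadata

logger = logging.getLogger(__name__)

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


@dataclass
class NullModelConfig:
    """Configuration shared by the betaNTI and RC_bray null models.

    ``n_null`` is the number of null randomizations (999 by convention);
    ``shuffle_all_tips`` controls whether the betaNTI tip shuffle spans all
    tips of the supplied tree (default) or only the taxa observed in the
    table — the two choices define nulls of different breadth.
    """

    n_null: int = 999
    abundance_weighted: bool = True
    seed: int = 0
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    shuffle_all_tips: bool = True

    def __post_init__(self) -> None:
        if self.n_null < 2:
            raise ValueError("n_null must be >= 2")
        if self.n_null < 100:
            warnings.warn(
                f"n_null={self.n_null} is below 100; standardized deviations "
                "will be noisy — use >= 999 for inference",
                stacklevel=2,
            )
        if self.bnti_threshold <= 0 or self.rc_threshold <= 0:
            raise ValueError("classification thresholds must be positive")


@dataclass
class AssemblyProfile:
    """Per-group fractions of sample pairs assigned to each process."""

    group: str
    fractions: dict
    n_pairs: int
    n_undefined: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.n_pairs > 0 and abs(total - 1.0) > 1e-12:
            raise ValueError(f"process fractions sum to {total}, not 1")


# ---------------------------------------------------------------------------
# tree/table alignment
# ---------------------------------------------------------------------------

def _align_to_tree(table: FeatureTable, tree: skbio.TreeNode):
    """Restrict the table to taxa present as tree tips; report drops.

    Returns (counts over shared taxa, shared taxon ids, full tip-distance
    matrix, tip index of each shared taxon).  Raises if a sample retains no
    taxa.
    """
    tip_dm = tree.tip_tip_distances()
    tip_ids = list(tip_dm.ids)
    tip_index = {t: i for i, t in enumerate(tip_ids)}
    shared = [t for t in table.taxon_ids if t in tip_index]
    missing = [t for t in table.taxon_ids if t not in tip_index]
    if missing:
        logger.warning(
            "%d taxa absent from the tree were dropped (e.g. %s)",
            len(missing),
            missing[:5],
        )
    if not shared:
        raise ValueError("no taxa shared between the table and the tree")
    sub = table.select_taxa(shared)
    empty = [s for s, t in zip(sub.sample_ids, sub.sample_totals()) if t == 0]
    if empty:
        raise ValueError(f"samples with no taxa on the tree: {empty}")
    idx = np.array([tip_index[t] for t in shared])
    return sub, np.asarray(tip_dm.data, dtype=float), idx


def _sample_weights(counts: np.ndarray, abundance_weighted: bool) -> list[np.ndarray]:
    """Per-sample weights over the taxa present in that sample."""
    weights = []
    for row in counts:
        present = np.flatnonzero(row > 0)
        if abundance_weighted:
            w = row[present] / row[present].sum()
        else:
            w = np.full(len(present), 1.0 / len(present))
        weights.append(w)
    return weights


def _bmntd_matrix(
    d_tips: np.ndarray,
    taxon_tip_idx: np.ndarray,
    present: list[np.ndarray],
    weights: list[np.ndarray],
) -> np.ndarray:
    """betaMNTD for all sample pairs given a taxon -> tip-index mapping.

    ``present[i]`` holds column indices (into the shared-taxon list) of the
    taxa in sample i; ``weights[i]`` the matching relative weights.
    """
    n = len(present)
    # min distance from every shared taxon to its nearest taxon in sample j
    tip_rows = taxon_tip_idx  # shared-taxon order -> tip index
    mind = np.empty((len(tip_rows), n))
    for j in range(n):
        cols = tip_rows[present[j]]
        mind[:, j] = d_tips[np.ix_(tip_rows, cols)].min(axis=1)
    out = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        v = 0.5 * (
            weights[i] @ mind[present[i], j] + weights[j] @ mind[present[j], i]
        )
        out[i, j] = out[j, i] = v
    return out


def bmntd(
    table: FeatureTable,
    tree: skbio.TreeNode,
    abundance_weighted: bool = True,
) -> DistanceMatrix:
    """Beta mean nearest taxon distance between every pair of samples.

    For each taxon in one sample, the patristic distance to its nearest
    taxon in the other sample is found; these minima are averaged with the
    taxon's relative abundance as weight (or uniformly when
    ``abundance_weighted=False``) and the two directions are averaged.
    """
    sub, d_tips, idx = _align_to_tree(table, tree)
    present = [np.flatnonzero(row > 0) for row in sub.counts]
    weights = _sample_weights(sub.counts, abundance_weighted)
    mat = _bmntd_matrix(d_tips, idx, present, weights)
    return DistanceMatrix(list(sub.sample_ids), mat)


def bnti(
    table: FeatureTable,
    tree: skbio.TreeNode,
    config: NullModelConfig | None = None,
) -> DistanceMatrix:
    """Beta nearest taxon index: standardized deviation of betaMNTD from a
    tip-shuffling null.

    Null replicates permute the taxon -> tip assignment (across all tips of
    the tree by default), keeping both tree shape and count table fixed;
    ``betaNTI = (obs - mean_null) / sd_null`` per pair.  Pairs whose null
    distribution has zero spread are undefined and returned as NaN (the
    diagonal is NaN by construction).
    """
    config = config or NullModelConfig()
    sub, d_tips, idx = _align_to_tree(table, tree)
    present = [np.flatnonzero(row > 0) for row in sub.counts]
    weights = _sample_weights(sub.counts, config.abundance_weighted)
    obs = _bmntd_matrix(d_tips, idx, present, weights)
    rng = np.random.default_rng(config.seed)
    n = sub.n_samples
    null_sum = np.zeros((n, n))
    null_sq = np.zeros((n, n))
    n_tips = d_tips.shape[0]
    for _ in range(config.n_null):
        if config.shuffle_all_tips:
            perm = rng.permutation(n_tips)
            shuffled_idx = perm[idx]
        else:
            shuffled_idx = rng.permutation(idx)
        null = _bmntd_matrix(d_tips, shuffled_idx, present, weights)
        null_sum += null
        null_sq += null**2
    mean = null_sum / config.n_null
    var = null_sq / config.n_null - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    # sd indistinguishable from zero at float precision (relative to the
    # betaMNTD scale) marks a degenerate null
    z[sd <= 1e-8 * (np.abs(mean) + 1.0)] = np.nan
    np.fill_diagonal(z, np.nan)
    n_undef = int(np.isnan(z[np.triu_indices(n, k=1)]).sum())
    if n_undef:
        logger.warning("betaNTI undefined (sd_null = 0) for %d pair(s)", n_undef)
    return DistanceMatrix(list(sub.sample_ids), z)


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis) null model
# ---------------------------------------------------------------------------

def rc_score(n_less: int, n_equal: int, n_null: int) -> float:
    """Rank position of an observed dissimilarity within its null
    distribution, rescaled to [-1, 1] (ties counted half)."""
    return 2.0 * ((n_less + 0.5 * n_equal) / n_null) - 1.0


def _null_community(
    rng: np.random.Generator,
    occupancy: np.ndarray,
    mean_rel: np.ndarray,
    s_obs: int,
    n_obs: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One probabilistic community: ``s_obs`` taxa, ``n_obs`` individuals.

    Presence drawn without replacement with probability proportional to
    occupancy (Gumbel top-k); each present taxon gets one individual and the
    remaining ``n_obs - s_obs`` are allocated multinomially with probability
    proportional to mean relative abundance.  Returns (taxon indices,
    counts).
    """
    keys = np.log(occupancy) + rng.gumbel(size=occupancy.size)
    chosen = np.argpartition(keys, -s_obs)[-s_obs:]
    counts = np.ones(s_obs, dtype=np.int64)
    remaining = n_obs - s_obs
    if remaining > 0:
        p = mean_rel[chosen]
        counts += rng.multinomial(remaining, p / p.sum())
    return chosen, counts


def _bray_curtis_sparse(
    idx_a: np.ndarray, cnt_a: np.ndarray, idx_b: np.ndarray, cnt_b: np.ndarray, n_taxa: int
) -> float:
    a = np.zeros(n_taxa)
    b = np.zeros(n_taxa)
    a[idx_a] = cnt_a
    b[idx_b] = cnt_b
    return 1.0 - 2.0 * np.minimum(a, b).sum() / (a.sum() + b.sum())


def raup_crick_bray(
    table: FeatureTable,
    config: NullModelConfig | None = None,
    presence_only: bool = False,
    reference: FeatureTable | None = None,
) -> DistanceMatrix:
    """Raup-Crick deviation of Bray-Curtis turnover from a null model.

    For each sample pair, ``n_null`` pairs of null communities are
    assembled, each preserving the observed richness and total abundance of
    its sample; ``RC = 2 * rank(obs within nulls) - 1`` lies in [-1, 1].
    RC near +1: communities more dissimilar than expected by chance; near
    -1: more similar.  ``presence_only=True`` computes the dissimilarities
    on presence/absence (Sorensen) instead of abundances.

    By default taxon occupancies and mean relative abundances that drive the
    null are estimated from ``table`` itself; pass ``reference`` (a table
    over a superset of the taxa, e.g. the regional pool) to estimate them
    externally.
    """
    config = config or NullModelConfig()
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"samples with zero total: {bad}")
    counts = table.counts
    if presence_only:
        counts = (counts > 0).astype(np.int64)
    if reference is not None:
        missing = [t for t in table.taxon_ids if t not in set(reference.taxon_ids)]
        if missing:
            raise ValueError(f"reference table lacks taxa: {missing[:5]}")
        # embed observed counts into the reference taxon universe
        col = {t: k for k, t in enumerate(reference.taxon_ids)}
        expanded = np.zeros((counts.shape[0], reference.n_taxa), dtype=np.int64)
        for k, t in enumerate(table.taxon_ids):
            expanded[:, col[t]] = counts[:, k]
        counts = expanded
        stats_counts = reference.counts
        if presence_only:
            stats_counts = (stats_counts > 0).astype(np.int64)
    else:
        stats_counts = counts
    n, t = counts.shape
    occupancy = (stats_counts > 0).mean(axis=0)
    rel = stats_counts / stats_counts.sum(axis=1, keepdims=True)
    mean_rel = rel.mean(axis=0)
    keep = (occupancy > 0) | (counts > 0).any(axis=0)
    occupancy = np.clip(occupancy, 1e-12, None)
    mean_rel = np.clip(mean_rel, 1e-12, None)
    occupancy = occupancy[keep]
    mean_rel = mean_rel[keep]
    counts = counts[:, keep]
    t_kept = int(keep.sum())
    richness_obs = (counts > 0).sum(axis=1)
    totals_obs = counts.sum(axis=1)
    rng = np.random.default_rng(config.seed)
    out = np.full((n, n), np.nan)
    for i, j in combinations(range(n), 2):
        obs = _bray_curtis_sparse(
            np.arange(t_kept), counts[i], np.arange(t_kept), counts[j], t_kept
        )
        less = equal = 0
        for _ in range(config.n_null):
            ia, ca = _null_community(rng, occupancy, mean_rel, richness_obs[i], totals_obs[i])
            ib, cb = _null_community(rng, occupancy, mean_rel, richness_obs[j], totals_obs[j])
            bc = _bray_curtis_sparse(ia, ca, ib, cb, t_kept)
            if bc < obs - 1e-12:
                less += 1
            elif abs(bc - obs) <= 1e-12:
                equal += 1
        out[i, j] = out[j, i] = rc_score(less, equal, config.n_null)
    return DistanceMatrix(list(table.sample_ids), out)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_pair(
    bnti_value: float,
    rc_value: float,
    config: NullModelConfig | None = None,
) -> str:
    """Assign one sample pair to its dominant assembly process.

    Uses the strict inequalities quoted in the module docstring; NaN in
    either input yields ``"undefined"``.
    """
    config = config or NullModelConfig()
    if np.isnan(bnti_value) or np.isnan(rc_value):
        return "undefined"
    bt, rt = config.bnti_threshold, config.rc_threshold
    if bnti_value < -bt:
        return "homogeneous_selection"
    if bnti_value > bt:
        return "heterogeneous_selection"
    if rc_value > rt:
        return "dispersal_limitation"
    if rc_value < -rt:
        return "homogenizing_dispersal"
    return "undominated"


def assembly_profile(
    bnti_dm: DistanceMatrix,
    rc_dm: DistanceMatrix,
    metadata: SampleMetadata,
    grouping: str = "within",
    config: NullModelConfig | None = None,
) -> list[AssemblyProfile]:
    """Per-group fractions of sample pairs assigned to each process.

    ``grouping='within'`` (default) classifies within-group pairs only;
    ``'involving'`` counts, for each group, every pair with at least one
    member in the group; ``'all'`` produces a single profile over all
    pairs.  Undefined pairs (NaN betaNTI) are excluded from the fractions
    and reported via ``n_undefined``.
    """
    config = config or NullModelConfig()
    if bnti_dm.sample_ids != rc_dm.sample_ids:
        raise ValueError("betaNTI and RC matrices cover different samples")
    ids = bnti_dm.sample_ids
    labels = metadata.groups_for(ids)
    pair_sets: dict[str, list[tuple[int, int]]] = {}
    all_pairs = list(combinations(range(len(ids)), 2))
    if grouping == "within":
        for g in np.unique(labels):
            idx = np.flatnonzero(labels == g)
            if len(idx) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
            pair_sets[str(g)] = list(combinations(idx.tolist(), 2))
    elif grouping == "involving":
        for g in np.unique(labels):
            pair_sets[str(g)] = [
                (i, j) for i, j in all_pairs if labels[i] == g or labels[j] == g
            ]
    elif grouping == "all":
        pair_sets["all"] = all_pairs
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    profiles = []
    for g, pairs in pair_sets.items():
        tally = {p: 0 for p in PROCESSES}
        undef = 0
        for i, j in pairs:
            label = classify_pair(bnti_dm.values[i, j], rc_dm.values[i, j], config)
            if label == "undefined":
                undef += 1
            else:
                tally[label] += 1
        classified = sum(tally.values())
        fractions = {
            p: (tally[p] / classified if classified else 0.0) for p in PROCESSES
        }
        profiles.append(
            AssemblyProfile(
                group=g, fractions=fractions, n_pairs=classified, n_undefined=undef
            )
        )
    return profiles


def modal_process(profile: AssemblyProfile) -> str:
    """The process with the largest fraction (ties broken by PROCESSES order)."""
    return max(PROCESSES, key=lambda p: profile.fractions[p])
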