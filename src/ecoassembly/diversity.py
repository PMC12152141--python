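"""Alpha/beta diversity, ordination, and permutational statistics.

Implements the descriptive layer of a gradient microbiome study: rarefaction,
richness and Shannon diversity, Bray-Curtis dissimilarity, principal
coordinates analysis, PERMANOVA (with pairwise post hoc tests), within-group
turnover comparison, and the symmetric Procrustes permutation test (protest)
used to compare two ordinations of the same samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .containers import DistanceMatrix, FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    """Sample coordinates from a metric ordination.

    Axes are ordered by non-increasing eigenvalue; only positive-eigenvalue
    axes carry coordinates, but the full eigenvalue spectrum (including any
    negative values) is reported.
    """

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.proportion_explained = np.asarray(self.proportion_explained, dtype=float)


@dataclass
class PermutationTestResult:
    """Outcome of a permutation test (PERMANOVA, protest, KS comparison)."""

    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    effect_size: float = float("nan")  # R-squared where defined
    label: str = ""
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rarefaction and alpha diversity
# ---------------------------------------------------------------------------

def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped and reported via a
    warning (matching common practice: undersequenced samples are excluded
    rather than an error raised).
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep_mask = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep_mask) if not k]
    if dropped:
        warnings.warn(
            f"rarefy: dropped {len(dropped)} sample(s) below depth {depth}: {dropped}",
            stacklevel=2,
        )
    kept = [s for s, k in zip(table.sample_ids, keep_mask) if k]
    sub = table.select_samples(kept)
    new_counts = np.empty_like(sub.counts)
    for i in range(sub.n_samples):
        if sub.counts[i].sum() == depth:
            new_counts[i] = sub.counts[i]
        else:
            new_counts[i] = rng.multivariate_hypergeometric(sub.counts[i], depth)
    return FeatureTable(
        counts=new_counts,
        sample_ids=sub.sample_ids,
        taxon_ids=sub.taxon_ids,
        taxonomy=sub.taxonomy,
        kingdom=sub.kingdom,
    )


def richness(table: FeatureTable) -> pd.Series:
    """Observed richness: number of taxa with a positive count per sample."""
    return pd.Series((table.counts > 0).sum(axis=1), index=table.sample_ids, name="richness")


def shannon(table: FeatureTable, base: float = np.e) -> pd.Series:
    """Shannon diversity H = -sum p_i log p_i (natural log by default)."""
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"cannot compute Shannon diversity for all-zero samples: {bad}")
    p = table.relative_abundance()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1) / np.log(base)
    return pd.Series(h, index=table.sample_ids, name="shannon")


# ---------------------------------------------------------------------------
# beta diversity and ordination
# ---------------------------------------------------------------------------

def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity: 1 - 2 sum(min) / (sum_i + sum_j)."""
    if table.n_samples < 2:
        raise ValueError("Bray-Curtis needs at least 2 samples")
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"samples with zero total have undefined Bray-Curtis: {bad}")
    condensed = pdist(table.counts.astype(float), metric="braycurtis")
    return DistanceMatrix(list(table.sample_ids), squareform(condensed))


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-9) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a dissimilarity matrix.

    Double-centers ``-d^2/2`` and eigendecomposes.  Axes with eigenvalues
    below ``eig_tol * max(eigenvalue)`` carry no coordinates; negative
    eigenvalues (possible because Bray-Curtis is a semimetric) are retained
    in the eigenvalue report but no correction is applied.
    ``proportion_explained`` is computed over positive eigenvalues only.
    """
    d = dm.values
    if np.isnan(d).any():
        raise ValueError("ordination input contains undefined (NaN) distances")
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    evals, evecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > eig_tol * max(evals.max(), 1.0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    pos_sum = evals[pos].sum()
    proportion = np.where(evals > 0, evals / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    return OrdinationResult(
        sample_ids=list(dm.sample_ids),
        coordinates=coords,
        eigenvalues=evals,
        proportion_explained=proportion,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_ss(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray):
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    dm: DistanceMatrix,
    groups: Sequence[str],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> PermutationTestResult:
    """One-way PERMANOVA (Anderson's pseudo-F) with label permutation.

    ``F = (SS_among / (a-1)) / (SS_within / (n-a))`` from sums of squared
    dissimilarities; ``R^2 = SS_among / SS_total``; the p-value uses the
    ``(1 + exceedances) / (1 + n_permutations)`` estimator, so it can never
    be exactly zero.
    """
    labels = np.asarray(list(groups), dtype=object)
    if len(labels) != dm.n_samples:
        raise ValueError("group labels do not match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValueError(f"every group needs >= 2 samples; too small: {small}")
    n, a = len(labels), len(uniq)
    d2 = dm.values**2
    ss_total, ss_within = _permanova_ss(d2, labels, uniq)
    ss_among = ss_total - ss_within

    def f_stat(ss_w):
        # ss_w = 0 (all within-group distances zero) legitimately gives +inf
        with np.errstate(divide="ignore"):
            return ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))

    f_obs = f_stat(ss_within)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        _, ss_w = _permanova_ss(d2, perm, uniq)
        if f_stat(ss_w) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    r2 = ss_among / ss_total if ss_total > 0 else float("nan")
    return PermutationTestResult(
        statistic=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        effect_size=float(r2),
    )


def pairwise_permanova(
    dm: DistanceMatrix,
    groups: Sequence[str],
    n_permutations: int = 10_000,
    seed: int = 0,
    adjust: str = "BH",
) -> list[PermutationTestResult]:
    """PERMANOVA on every group pair, BH-adjusted across pairs.

    Adjusted p-values are stored in ``extra['p_adjusted']``.
    """
    labels = np.asarray(list(groups), dtype=object)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    results = []
    rng = np.random.default_rng(seed)
    for g1, g2 in combinations(uniq, 2):
        mask = np.isin(labels, [g1, g2])
        ids = [s for s, m in zip(dm.sample_ids, mask) if m]
        res = permanova(
            dm.submatrix(ids),
            labels[mask],
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        res.label = f"{g1} vs {g2}"
        results.append(res)
    raw = [r.p_value for r in results]
    if adjust == "BH":
        adjusted = multipletests(raw, method="fdr_bh")[1]
    elif adjust in (None, "none"):
        adjusted = raw
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    for r, p_adj in zip(results, adjusted):
        r.extra["p_adjusted"] = float(p_adj)
    return results


# ---------------------------------------------------------------------------
# within-group turnover
# ---------------------------------------------------------------------------

@dataclass
class TurnoverResult:
    """Within-group community turnover and its omnibus comparison.

    ``per_group`` maps each group to its turnover values (within-group
    pairwise dissimilarities, or distances to the group centroid in PCoA
    space under ``method='centroid'``); groups are compared by one-way
    ANOVA with a Tukey HSD post hoc.
    """

    per_group: dict
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame
    method: str
    note: str = ""


def within_group_turnover(
    dm: DistanceMatrix,
    groups: Sequence[str],
    method: str = "pairwise",
) -> TurnoverResult:
    """Compare community turnover between groups.

    ``method='pairwise'`` (default) takes each group's multiset of
    within-group pairwise dissimilarities; ``method='centroid'`` uses
    distances to the group centroid in the positive-axis PCoA space
    (betadisper-style).
    """
    labels = np.asarray(list(groups), dtype=object)
    if len(labels) != dm.n_samples:
        raise ValueError("group labels do not match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 samples for turnover")
    per_group: dict[str, np.ndarray] = {}
    if method == "pairwise":
        for g in uniq:
            idx = np.flatnonzero(labels == g)
            sub = dm.values[np.ix_(idx, idx)]
            per_group[g] = sub[np.triu_indices(len(idx), k=1)]
    elif method == "centroid":
        coords = pcoa(dm).coordinates
        for g in uniq:
            idx = np.flatnonzero(labels == g)
            centroid = coords[idx].mean(axis=0)
            per_group[g] = np.linalg.norm(coords[idx] - centroid, axis=1)
    else:
        raise ValueError(f"unknown turnover method {method!r}")
    values = [per_group[g] for g in uniq]
    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0:
        return TurnoverResult(
            per_group=per_group,
            anova_f=float("nan"),
            anova_p=1.0,
            tukey=pd.DataFrame(columns=["group_a", "group_b", "difference", "p_value"]),
            method=method,
            note="no variation among turnover values; omnibus test undefined",
        )
    f, p = sps.f_oneway(*values)
    hsd = sps.tukey_hsd(*values)
    rows = []
    for i, j in combinations(range(len(uniq)), 2):
        rows.append(
            {
                "group_a": uniq[i],
                "group_b": uniq[j],
                "difference": float(np.mean(values[i]) - np.mean(values[j])),
                "p_value": float(hsd.pvalue[i, j]),
            }
        )
    return TurnoverResult(
        per_group=per_group,
        anova_f=float(f),
        anova_p=float(p),
        tukey=pd.DataFrame(rows),
        method=method,
    )


def parametric_ok(values_by_group: Sequence[np.ndarray], alpha: float = 0.05) -> bool:
    """Shapiro-Wilk normality per group plus Bartlett homogeneity of
    variance; True when no test rejects at ``alpha`` (the documented switch
    between ANOVA/Tukey and Kruskal-Wallis/Wilcoxon pipelines)."""
    for v in values_by_group:
        if len(v) >= 3 and np.ptp(v) > 0 and sps.shapiro(v).pvalue < alpha:
            return False
    cleaned = [v for v in values_by_group if len(v) >= 2]
    if len(cleaned) >= 2 and any(np.ptp(v) > 0 for v in cleaned):
        if sps.bartlett(*cleaned).pvalue < alpha:
            return False
    return True


# ---------------------------------------------------------------------------
# Procrustes / protest
# ---------------------------------------------------------------------------

def _procrustes_prepare(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0, keepdims=True)
    norm = np.sqrt((x**2).sum())
    if norm == 0:
        raise ValueError("degenerate configuration: all points identical")
    return x / norm


def procrustes_m2(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Procrustes residual m^2 between two configurations.

    Both configurations are centered and scaled to unit sum of squares; the
    optimal rotation (and symmetric scaling) gives
    ``m^2 = 1 - (sum of singular values of X'Y)^2``.
    """
    if x.shape[1] < y.shape[1]:
        x = np.hstack([x, np.zeros((x.shape[0], y.shape[1] - x.shape[1]))])
    elif y.shape[1] < x.shape[1]:
        y = np.hstack([y, np.zeros((y.shape[0], x.shape[1] - y.shape[1]))])
    xs = _procrustes_prepare(x)
    ys = _procrustes_prepare(y)
    trace = np.linalg.svd(xs.T @ ys, compute_uv=False).sum()
    return float(max(0.0, 1.0 - trace**2))


def procrustes_test(
    coords_a: OrdinationResult,
    coords_b: OrdinationResult,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Protest: permutation test of concordance between two ordinations.

    The statistic is the Procrustes correlation ``t = sqrt(1 - m^2)``;
    significance comes from permuting the row order of the second
    configuration.  ``effect_size`` reports ``t^2`` (the R-squared commonly
    quoted for protest).
    """
    if set(coords_a.sample_ids) != set(coords_b.sample_ids):
        raise ValueError("ordinations cover different sample sets")
    order = [coords_b.sample_ids.index(s) for s in coords_a.sample_ids]
    x = coords_a.coordinates
    y = coords_b.coordinates[order]
    t_obs = np.sqrt(1.0 - procrustes_m2(x, y))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(order))
        if np.sqrt(1.0 - procrustes_m2(x, y[perm])) >= t_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermutationTestResult(
        statistic=float(t_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        effect_size=float(t_obs**2),
        extra={"m2": float(1.0 - t_obs**2)},
    )
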