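"""Gradient-responsive taxa: selection, validation, and peak grouping.

A taxon "responds" to the gradient when it is abundant (>1 % relative
abundance somewhere), prevalent (present in more than a minimum number of
samples), and its relative abundance differs between gradient zones by
one-way ANOVA.  The selected subset is validated against the full community
with a symmetric Procrustes permutation test on Bray-Curtis ordinations,
then each selected taxon is assigned to the zone pattern where it peaks
(low-only, medium+high, or high-only) by a Tukey HSD decision table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable, SampleMetadata
from .diversity import PermutationTestResult, bray_curtis, pcoa, procrustes_test

PATTERN_LABELS = (
    "group1_low_only",
    "group2_medium_high",
    "group3_high_only",
    "other",
)


@dataclass
class ResponsiveTaxaResult:
    """Taxa passing the abundance, prevalence, and ANOVA filters."""

    selected_taxa: list[str]
    p_values: pd.Series  # per tested taxon, ANOVA p across groups
    group_means: pd.DataFrame  # taxon x group mean relative abundance
    thresholds: dict = field(default_factory=dict)


def _anova_pvalue(values_by_group: list[np.ndarray]) -> float:
    pooled = np.concatenate(values_by_group)
    if np.ptp(pooled) == 0:  # constant taxon: no between-group variation
        return 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = sps.f_oneway(*values_by_group).pvalue
    return float(p) if np.isfinite(p) else 1.0


def select_responsive_taxa(
    table: FeatureTable,
    metadata: SampleMetadata,
    min_rel_abundance: float = 0.01,
    min_prevalence: int = 10,
    alpha: float = 0.01,
    abundance_mode: str = "max",
    adjust: str | None = None,
) -> ResponsiveTaxaResult:
    """Select taxa that respond to the gradient.

    A taxon is selected iff (a) its relative abundance exceeds
    ``min_rel_abundance`` in at least one sample (``abundance_mode='max'``,
    default) or on average (``'mean'``); (b) it has a positive count in
    strictly more than ``min_prevalence`` samples; and (c) one-way ANOVA of
    its relative abundance across groups gives p < ``alpha`` (unadjusted by
    default; ``adjust='BH'`` applies Benjamini-Hochberg across the taxa
    passing the first two filters).
    """
    if table.n_taxa == 0 or table.n_samples == 0:
        raise ValueError("empty feature table")
    labels = metadata.groups_for(table.sample_ids)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups for the ANOVA filter")
    rel = table.relative_abundance()
    if abundance_mode == "max":
        abundant = rel.max(axis=0) > min_rel_abundance
    elif abundance_mode == "mean":
        abundant = rel.mean(axis=0) > min_rel_abundance
    else:
        raise ValueError(f"unknown abundance_mode {abundance_mode!r}")
    prevalent = (table.counts > 0).sum(axis=0) > min_prevalence
    candidates = np.flatnonzero(abundant & prevalent)
    p_values = {}
    for j in candidates:
        groups = [rel[labels == g, j] for g in uniq]
        p_values[table.taxon_ids[j]] = _anova_pvalue(groups)
    p_series = pd.Series(p_values, dtype=float)
    effective = p_series
    if adjust == "BH" and len(p_series):
        effective = pd.Series(
            multipletests(p_series.to_numpy(), method="fdr_bh")[1], index=p_series.index
        )
    selected = [t for t in p_series.index if effective[t] < alpha]
    means = pd.DataFrame(
        {g: rel[labels == g].mean(axis=0) for g in uniq}, index=table.taxon_ids
    )
    return ResponsiveTaxaResult(
        selected_taxa=selected,
        p_values=p_series,
        group_means=means.loc[list(p_series.index)] if len(p_series) else means.iloc[:0],
        thresholds={
            "min_rel_abundance": min_rel_abundance,
            "min_prevalence": min_prevalence,
            "alpha": alpha,
            "abundance_mode": abundance_mode,
            "adjust": adjust,
        },
    )


def validate_subset(
    table_full: FeatureTable,
    selected: ResponsiveTaxaResult | Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Protest concordance between the full community and the selected
    subset.

    Bray-Curtis + PCoA ordinations are computed for the full table and the
    selected-taxa sub-table, and compared by the symmetric Procrustes
    permutation test.  A high correlation means the subset carries the
    community-structure signal of the whole dataset.
    """
    taxa = selected.selected_taxa if isinstance(selected, ResponsiveTaxaResult) else list(selected)
    if not taxa:
        raise ValueError("empty taxon selection")
    sub = table_full.select_taxa(taxa)
    if (sub.sample_totals() == 0).any():
        empty = [s for s, t in zip(sub.sample_ids, sub.sample_totals()) if t == 0]
        warnings.warn(
            f"dropping {len(empty)} sample(s) with no counts in the selected "
            f"taxa from the Procrustes comparison: {empty}",
            stacklevel=2,
        )
        kept = [s for s in sub.sample_ids if s not in set(empty)]
        if len(kept) < 3:
            raise ValueError("fewer than 3 samples carry the selected taxa")
        sub = sub.select_samples(kept)
        table_full = table_full.select_samples(kept)
    ord_full = pcoa(bray_curtis(table_full))
    ord_sub = pcoa(bray_curtis(sub))
    return procrustes_test(ord_full, ord_sub, n_permutations=n_permutations, seed=seed)


@dataclass
class TrajectoryGroups:
    """Per-taxon peak-abundance pattern along the low/medium/high gradient."""

    patterns: pd.Series  # taxon -> one of PATTERN_LABELS
    alpha: float


def group_by_peak(
    table: FeatureTable,
    metadata: SampleMetadata,
    selected: ResponsiveTaxaResult | Sequence[str],
    alpha: float = 0.05,
    group_order: Sequence[str] = ("low", "medium", "high"),
) -> TrajectoryGroups:
    """Assign each selected taxon to the zone pattern where it peaks.

    Tukey HSD on per-group relative abundances drives a decision table:
    ``group1_low_only`` when low significantly exceeds both other zones;
    ``group2_medium_high`` when medium and high each significantly exceed
    low and do not differ from one another; ``group3_high_only`` when high
    exceeds both others; anything else is ``other`` (never forced into a
    pattern).
    """
    taxa = selected.selected_taxa if isinstance(selected, ResponsiveTaxaResult) else list(selected)
    labels = metadata.groups_for(table.sample_ids)
    missing = [g for g in group_order if g not in set(labels)]
    if missing:
        raise ValueError(f"metadata lacks required group levels: {missing}")
    rel = table.relative_abundance()
    lookup = {t: k for k, t in enumerate(table.taxon_ids)}
    low, med, high = group_order
    patterns = {}
    for t in taxa:
        j = lookup[t]
        by_group = {g: rel[labels == g, j] for g in group_order}
        if np.ptp(np.concatenate(list(by_group.values()))) == 0:
            patterns[t] = "other"
            continue
        hsd = sps.tukey_hsd(by_group[low], by_group[med], by_group[high])
        mean = {g: by_group[g].mean() for g in group_order}
        idx = {low: 0, med: 1, high: 2}

        def sig_greater(a, b):
            return mean[a] > mean[b] and hsd.pvalue[idx[a], idx[b]] < alpha

        def similar(a, b):
            return hsd.pvalue[idx[a], idx[b]] >= alpha

        if sig_greater(low, med) and sig_greater(low, high):
            patterns[t] = "group1_low_only"
        elif sig_greater(high, low) and sig_greater(high, med):
            patterns[t] = "group3_high_only"
        elif sig_greater(med, low) and sig_greater(high, low) and similar(med, high):
            patterns[t] = "group2_medium_high"
        else:
            patterns[t] = "other"
    return TrajectoryGroups(
        patterns=pd.Series(patterns, dtype=object), alpha=alpha
    )
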