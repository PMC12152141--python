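"""Self-validation studies: null calibrations, regime recovery, parameter
recovery, and statistical power, all measured on synthetic data with known
ground truth.

Each function runs the relevant pipeline stages from scratch at desk-scale
problem sizes and returns the measured quantity; the test suite asserts on
these numbers and the acceptance script reports them.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np

from . import diversity as div
from .assembly import (
    NullModelConfig,
    assembly_profile,
    bnti,
    modal_process,
    raup_crick_bray,
    _null_community,
)
from .containers import FeatureTable, SampleMetadata
from .networks import sparcc
from .synthetic import (
    BasisCorrelationSpec,
    RegimeSpec,
    correlation_with_pairs,
    simulate_compositional_counts,
    simulate_gradient_taxa,
    simulate_metacommunity,
    simulate_tree,
)
from .trajectory import group_by_peak, select_responsive_taxa


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31 - 1)) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# null self-calibration
# ---------------------------------------------------------------------------

def bnti_null_tail(seed: int, n_instances: int = 6, n_samples: int = 20,
                   n_taxa: int = 80, depth: int = 400, n_null: int = 299) -> float:
    """Fraction of |betaNTI| > 2 when counts are random w.r.t. the tree.

    Communities are multinomial draws from a log-normal pool with no
    trait-environment structure, so the tip-shuffling null is true and the
    two-sided 2-sigma tail should hold ~5 % of pairs (pooled over
    instances; pairs within an instance are correlated).
    """
    seeds = _child_seeds(seed, n_instances)
    rng = np.random.default_rng(seed)
    tails = []
    for s in seeds:
        tree = simulate_tree(n_taxa, seed=s)
        taxa = [t.name for t in tree.tips()]
        pool = rng.lognormal(0, 1, n_taxa)
        pool /= pool.sum()
        counts = np.vstack([rng.multinomial(depth, pool) for _ in range(n_samples)])
        table = FeatureTable(counts=counts,
                             sample_ids=[f"s{i}" for i in range(n_samples)],
                             taxon_ids=taxa)
        z = bnti(table, tree, NullModelConfig(n_null=n_null, seed=s + 1)).values
        v = z[np.triu_indices(n_samples, k=1)]
        tails.append(np.nanmean(np.abs(v) > 2))
    return float(np.mean(tails))


def rc_null_tail(seed: int, n_samples: int = 20, n_taxa: int = 80,
                 depth: int = 500, n_null: int = 299) -> float:
    """Fraction of |RC_bray| > 0.95 when the observed pair is itself drawn
    from the Raup-Crick null.

    A reference table fixes occupancy and mean relative abundance; observed
    communities are generated by the very procedure the null uses, so RC
    should be ~uniform and the 0.95 tails should hold ~5 % of pairs.
    """
    rng = np.random.default_rng(seed)
    pool = rng.lognormal(0, 1, n_taxa)
    pool /= pool.sum()
    base = np.vstack([rng.multinomial(depth, pool) for _ in range(30)])
    reference = FeatureTable(counts=base, sample_ids=[f"r{i}" for i in range(30)],
                             taxon_ids=[f"t{j}" for j in range(n_taxa)])
    occupancy = np.clip((base > 0).mean(axis=0), 1e-12, None)
    mean_rel = np.clip((base / base.sum(axis=1, keepdims=True)).mean(axis=0), 1e-12, None)
    richness = (base > 0).sum(axis=1)
    totals = base.sum(axis=1)
    obs = np.zeros((n_samples, n_taxa), dtype=np.int64)
    for i in range(n_samples):
        idx, cnt = _null_community(rng, occupancy, mean_rel,
                                   int(richness[i % 30]), int(totals[i % 30]))
        obs[i, idx] = cnt
    table = FeatureTable(counts=obs, sample_ids=[f"s{i}" for i in range(n_samples)],
                         taxon_ids=[f"t{j}" for j in range(n_taxa)])
    rc = raup_crick_bray(table, NullModelConfig(n_null=n_null, seed=seed + 1),
                         reference=reference).values
    v = rc[np.triu_indices(n_samples, k=1)]
    return float(np.nanmean(np.abs(v) > 0.95))


def permanova_type1(seed: int, n_sims: int = 500, n_samples: int = 12,
                    n_taxa: int = 25, n_permutations: int = 99,
                    alpha: float = 0.05) -> float:
    """Rejection rate of PERMANOVA on exchangeable (label-free) data."""
    rng = np.random.default_rng(seed)
    labels = ["a"] * (n_samples // 2) + ["b"] * (n_samples - n_samples // 2)
    rejections = 0
    for _ in range(n_sims):
        counts = rng.integers(1, 50, size=(n_samples, n_taxa))
        table = FeatureTable(counts=counts,
                             sample_ids=[f"s{i}" for i in range(n_samples)],
                             taxon_ids=[f"t{j}" for j in range(n_taxa)])
        res = div.permanova(div.bray_curtis(table), labels,
                            n_permutations=n_permutations,
                            seed=int(rng.integers(2**31 - 1)))
        rejections += res.p_value <= alpha
    return rejections / n_sims


def protest_type1(seed: int, n_sims: int = 500, n_samples: int = 15,
                  n_axes: int = 3, n_permutations: int = 99,
                  alpha: float = 0.05) -> float:
    """Rejection rate of the Procrustes permutation test on independent
    Gaussian configurations."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        ids = [f"s{i}" for i in range(n_samples)]
        a = div.OrdinationResult(ids, rng.standard_normal((n_samples, n_axes)),
                                 np.ones(n_axes), np.ones(n_axes) / n_axes)
        b = div.OrdinationResult(ids, rng.standard_normal((n_samples, n_axes)),
                                 np.ones(n_axes), np.ones(n_axes) / n_axes)
        res = div.procrustes_test(a, b, n_permutations=n_permutations,
                                  seed=int(rng.integers(2**31 - 1)))
        rejections += res.p_value <= alpha
    return rejections / n_sims


# ---------------------------------------------------------------------------
# regime recovery
# ---------------------------------------------------------------------------

def regime_recovery(regime: str, seed: int, n_instances: int = 2,
                    n_null: int = 199) -> dict:
    """Simulate a metacommunity regime at the frozen generator defaults and
    measure what the assembly stage infers.

    Returns the modal process over all pooled sample pairs plus the
    regime-specific signature rates: fraction of between-environment pairs
    with betaNTI > 2, fraction with |betaNTI| < 2, and fraction with
    RC < -0.95.
    """
    seeds = _child_seeds(seed, n_instances)
    labels_all = []
    z_pairs: list[float] = []
    rc_pairs: list[float] = []
    between_z: list[float] = []
    for s in seeds:
        spec = RegimeSpec(regime=regime, seed=s)
        table, tree, metadata, _ = simulate_metacommunity(spec)
        config = NullModelConfig(n_null=n_null, seed=s + 1)
        z = bnti(table, tree, config)
        rc = raup_crick_bray(table, config)
        groups = metadata.groups_for(table.sample_ids)
        n = table.n_samples
        for i, j in combinations(range(n), 2):
            z_pairs.append(z.values[i, j])
            rc_pairs.append(rc.values[i, j])
            if groups[i] != groups[j]:
                between_z.append(z.values[i, j])
    z_arr = np.asarray(z_pairs)
    rc_arr = np.asarray(rc_pairs)
    # pooled profile over all pairs of all instances
    from .assembly import classify_pair

    tally: dict[str, int] = {}
    for zv, rv in zip(z_arr, rc_arr):
        lab = classify_pair(zv, rv)
        if lab != "undefined":
            tally[lab] = tally.get(lab, 0) + 1
    total = sum(tally.values())
    fractions = {k: v / total for k, v in tally.items()}
    modal = max(fractions, key=fractions.get)
    return {
        "regime": regime,
        "modal_process": modal,
        "modal_fraction": fractions[modal],
        "namesake_fraction": fractions.get(regime, 0.0),
        "fractions": fractions,
        "frac_between_bnti_gt2": (
            float(np.nanmean(np.asarray(between_z) > 2)) if between_z else float("nan")
        ),
        "frac_abs_bnti_lt2": float(np.nanmean(np.abs(z_arr) < 2)),
        "frac_rc_lt_m095": float(np.nanmean(rc_arr < -0.95)),
        "n_pairs": int(total),
    }


# ---------------------------------------------------------------------------
# SparCC recovery
# ---------------------------------------------------------------------------

def sparcc_recovery(seed: int, n_taxa: int = 50, n_samples: int = 500,
                    depth: int = 2000, planted_r: float = 0.8) -> dict:
    """Plant basis-correlation pairs at ``planted_r`` and measure recovery
    error plus the background correlation level on independent data."""
    pairs = [(0, 1, planted_r), (2, 3, planted_r), (4, 5, planted_r)]
    corr = correlation_with_pairs(n_taxa, pairs)
    spec = BasisCorrelationSpec(n_taxa=n_taxa, n_samples=n_samples, depth=depth,
                                correlation=corr, seed=seed)
    r = sparcc(simulate_compositional_counts(spec))
    planted_errors = [abs(r[i, j] - planted_r) for i, j, _ in pairs]
    mask = ~np.eye(n_taxa, dtype=bool)
    rmse = float(np.sqrt(((r - corr)[mask] ** 2).mean()))

    null_spec = BasisCorrelationSpec(n_taxa=30, n_samples=n_samples, depth=depth,
                                     seed=seed + 1)
    r0 = sparcc(simulate_compositional_counts(null_spec))
    null_median = float(np.median(np.abs(r0[~np.eye(30, dtype=bool)])))
    return {
        "planted_r": planted_r,
        "recovered_r": [float(r[i, j]) for i, j, _ in pairs],
        "max_planted_error": float(max(planted_errors)),
        "rmse": rmse,
        "null_median_abs_r": null_median,
    }


# ---------------------------------------------------------------------------
# trajectory power and size
# ---------------------------------------------------------------------------

def trajectory_power(seed: int, n_instances: int = 3, n_samples_per_group: int = 10,
                     n_taxa: int = 150, n_responsive: int = 12,
                     effect: float = 8.0, noise_sd: float = 0.3) -> dict:
    """Fraction of planted gradient-responsive taxa that are selected and
    assigned their true peak pattern."""
    seeds = _child_seeds(seed, n_instances)
    n_planted = selected = correct = 0
    for s in seeds:
        table, metadata, truth = simulate_gradient_taxa(
            n_samples_per_group, n_taxa, n_responsive, effect, noise_sd, seed=s)
        result = select_responsive_taxa(table, metadata)
        patterns = group_by_peak(table, metadata, result)
        responsive = truth[truth != "none"]
        n_planted += len(responsive)
        chosen = set(result.selected_taxa)
        for t in responsive.index:
            if t in chosen:
                selected += 1
                if patterns.patterns.get(t) == responsive[t]:
                    correct += 1
    return {
        "n_planted": n_planted,
        "frac_selected": selected / n_planted,
        "frac_correct_pattern": correct / n_planted,
    }


def trajectory_null_rate(seed: int, n_tables: int = 40, n_samples_per_group: int = 5,
                         n_taxa: int = 50, alpha: float = 0.01) -> float:
    """Fraction of taxa passing the ANOVA filter on effect-free tables.

    Abundance/prevalence filters are disabled so the measured rate isolates
    the ANOVA criterion; it should sit near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    n = 3 * n_samples_per_group
    ids = [f"s{i}" for i in range(n)]
    metadata = SampleMetadata.from_mapping(
        {s: ("low", "medium", "high")[i // n_samples_per_group]
         for i, s in enumerate(ids)}
    )
    passed = total = 0
    for _ in range(n_tables):
        counts = np.rint(rng.lognormal(np.log(30), 0.5, size=(n, n_taxa))).astype(int)
        table = FeatureTable(counts=counts, sample_ids=ids,
                             taxon_ids=[f"t{j}" for j in range(n_taxa)])
        res = select_responsive_taxa(table, metadata, min_rel_abundance=0.0,
                                     min_prevalence=0, alpha=alpha)
        passed += len(res.selected_taxa)
        total += len(res.p_values)
    return passed / total
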