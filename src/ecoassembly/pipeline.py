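"""End-to-end orchestration of the synthetic-study pipeline.

``run_pipeline`` validates every stage's parameter block up front, then runs
simulate -> diversity -> assembly -> network -> trajectory in dependency
order, writing TSV artifacts plus a machine-readable manifest.  A single
global seed is expanded into per-stage child seeds through
``numpy.random.SeedSequence(entropy=seed, spawn_key=(stage_index,))`` so any
stage can be re-run in isolation and reproduce its outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly as asm
from . import diversity as div
from . import io as eio
from . import networks as net
from . import trajectory as traj
from .containers import FeatureTable, SampleMetadata
from .synthetic import RegimeSpec, simulate_metacommunity

logger = logging.getLogger(__name__)

#: fixed stage order; index doubles as the seed spawn key
STAGES = ("simulate", "diversity", "assembly", "network", "trajectory")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Validated parameters for every stage.

    Either ``simulate`` holds a :class:`RegimeSpec` or the three input paths
    (``feature_table``, ``tree``, ``metadata``) point at existing files.
    """

    outdir: Path
    seed: int = 0
    simulate: RegimeSpec | None = None
    feature_table: Path | None = None
    tree: Path | None = None
    metadata: Path | None = None
    rarefy_depth: int | None = None
    n_permutations: int = 999
    n_null: int = 199
    abundance_weighted: bool = True
    pairing: str = "within"
    net_min_samples: int = 3
    net_min_count: int = 20
    r_within: float = 0.9
    r_cross: float = 0.8
    net_alpha: float = 0.01
    n_bootstrap: int = 200
    traj_min_rel_abundance: float = 0.01
    traj_min_prevalence: int = 10
    traj_alpha: float = 0.01

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.simulate is None and self.feature_table is None:
            raise ValueError("config needs either a simulation spec or input paths")
        if self.rarefy_depth is not None and self.rarefy_depth < 1:
            raise ValueError("rarefy_depth must be positive")
        for name in ("n_permutations", "n_null", "n_bootstrap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.pairing not in ("within", "involving", "all"):
            raise ValueError(f"unknown pairing {self.pairing!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = RegimeSpec(**sim)
        return cls(simulate=sim, **raw)

    def digest(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    artifacts: list = field(default_factory=list)
    timings: dict = field(default_factory=dict)
    status: str = "RUNNING"

    def add(self, path: Path) -> None:
        self.artifacts.append(str(path))

    def write(self, outdir: Path) -> None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _load_inputs(config: PipelineConfig, seed: int):
    if config.simulate is not None:
        spec = RegimeSpec(**{**asdict_spec(config.simulate), "seed": config.simulate.seed or seed})
        table, tree, metadata, truth = simulate_metacommunity(spec)
        return table, tree, metadata, truth
    table = eio.read_feature_table(config.feature_table)
    tree = eio.read_tree(config.tree) if config.tree else None
    metadata = eio.read_metadata(config.metadata)
    return table, tree, metadata, None


def asdict_spec(spec: RegimeSpec) -> dict:
    d = asdict(spec)
    d["groups"] = tuple(d["groups"])
    return d


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage; artifacts land under ``config.outdir``.

    Any stage failure aborts the run with the failing stage named; a FAILED
    marker and partial manifest are retained on disk.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.digest(), seed=config.seed)
    stage = "setup"
    try:
        t0 = time.perf_counter()
        stage = "simulate"
        table, tree, metadata, truth = _load_inputs(config, stage_seed(config.seed, "simulate"))
        if config.simulate is not None:
            eio.write_feature_table(table, out / "feature_table.tsv")
            eio.write_tree(tree, out / "tree.nwk")
            eio.write_metadata(metadata, out / "metadata.csv")
            truth.to_csv(out / "truth.tsv", sep="\t")
            for f in ("feature_table.tsv", "tree.nwk", "metadata.csv", "truth.tsv"):
                manifest.add(out / f)
        manifest.timings["simulate"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "diversity"
        seed = stage_seed(config.seed, "diversity")
        if config.rarefy_depth is not None:
            table = div.rarefy(table, config.rarefy_depth, seed=seed).drop_empty_taxa()
        alpha = pd.DataFrame({"richness": div.richness(table), "shannon": div.shannon(table)})
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
        manifest.add(out / "alpha_diversity.tsv")
        bc = div.bray_curtis(table)
        eio.write_distance_matrix(bc, out / "bray_curtis.tsv")
        manifest.add(out / "bray_curtis.tsv")
        ordination = div.pcoa(bc)
        coords = pd.DataFrame(
            ordination.coordinates,
            index=ordination.sample_ids,
            columns=[f"PC{i + 1}" for i in range(ordination.coordinates.shape[1])],
        )
        coords.to_csv(out / "pcoa.tsv", sep="\t", index_label="sample_id")
        manifest.add(out / "pcoa.tsv")
        labels = metadata.groups_for(table.sample_ids)
        perma = div.permanova(bc, labels, n_permutations=config.n_permutations, seed=seed)
        pairwise = div.pairwise_permanova(
            bc, labels, n_permutations=config.n_permutations, seed=seed
        )
        turnover = div.within_group_turnover(bc, labels)
        tests = [
            {
                "test": "PERMANOVA",
                "label": "all groups",
                "statistic": perma.statistic,
                "R2": perma.effect_size,
                "p_value": perma.p_value,
            }
        ]
        for r in pairwise:
            tests.append(
                {
                    "test": "pairwise PERMANOVA",
                    "label": r.label,
                    "statistic": r.statistic,
                    "R2": r.effect_size,
                    "p_value": r.extra["p_adjusted"],
                }
            )
        tests.append(
            {
                "test": "turnover ANOVA",
                "label": "within-group Bray-Curtis",
                "statistic": turnover.anova_f,
                "R2": float("nan"),
                "p_value": turnover.anova_p,
            }
        )
        pd.DataFrame(tests).to_csv(out / "diversity_tests.tsv", sep="\t", index=False)
        manifest.add(out / "diversity_tests.tsv")
        manifest.timings["diversity"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "assembly"
        if tree is not None:
            nm = asm.NullModelConfig(
                n_null=config.n_null,
                abundance_weighted=config.abundance_weighted,
                seed=stage_seed(config.seed, "assembly"),
            )
            bnti_dm = asm.bnti(table, tree, nm)
            rc_dm = asm.raup_crick_bray(table, nm)
            eio.write_distance_matrix(bnti_dm, out / "bnti.tsv")
            eio.write_distance_matrix(rc_dm, out / "rc_bray.tsv")
            profiles = asm.assembly_profile(bnti_dm, rc_dm, metadata, grouping=config.pairing)
            eio.write_assembly_profiles(profiles, out / "assembly_profiles.tsv")
            for f in ("bnti.tsv", "rc_bray.tsv", "assembly_profiles.tsv"):
                manifest.add(out / f)
        manifest.timings["assembly"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "network"
        seed = stage_seed(config.seed, "network")
        filtered = net.prevalence_filter(
            table, min_samples=config.net_min_samples, min_count=config.net_min_count
        )
        empty = [s for s, t in zip(filtered.sample_ids, filtered.sample_totals()) if t == 0]
        if empty:
            logger.warning(
                "network stage: dropping %d sample(s) with no retained taxa: %s",
                len(empty), empty[:5],
            )
            filtered = filtered.select_samples(
                [s for s in filtered.sample_ids if s not in set(empty)]
            )
        if filtered.n_taxa >= 4:
            r = net.sparcc(filtered, seed=seed)
            p = net.sparcc_pvalues(filtered, r, n_bootstrap=config.n_bootstrap, seed=seed)
            p_adj = net.bh_adjust(p)
            network = net.build_network(
                r,
                p_adj,
                filtered,
                threshold_within=config.r_within,
                threshold_cross=config.r_cross,
                alpha=config.net_alpha,
            )
            eio.write_network(network, out / "network_edges.tsv", dialect="edgelist")
            topo = net.network_stats(network)
            topo_row = {k: v for k, v in asdict(topo).items() if k != "degree_per_node"}
            pd.DataFrame([topo_row]).to_csv(out / "network_topology.tsv", sep="\t", index=False)
            hubs = net.find_hubs(network)
            pd.DataFrame(
                {"taxon": hubs, "degree": [network.degree()[h] for h in hubs]}
            ).to_csv(out / "network_hubs.tsv", sep="\t", index=False)
            for f in ("network_edges.tsv", "network_topology.tsv", "network_hubs.tsv"):
                manifest.add(out / f)
        else:
            logger.warning("network stage skipped: fewer than 4 taxa after filtering")
        manifest.timings["network"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "trajectory"
        seed = stage_seed(config.seed, "trajectory")
        selected = traj.select_responsive_taxa(
            table,
            metadata,
            min_rel_abundance=config.traj_min_rel_abundance,
            min_prevalence=config.traj_min_prevalence,
            alpha=config.traj_alpha,
        )
        sel_df = pd.DataFrame(
            {
                "p_value": selected.p_values,
                "selected": [t in set(selected.selected_taxa) for t in selected.p_values.index],
            }
        ).join(selected.group_means)
        sel_df.to_csv(out / "responsive_taxa.tsv", sep="\t", index_label="taxon")
        manifest.add(out / "responsive_taxa.tsv")
        if selected.selected_taxa:
            protest = traj.validate_subset(
                table, selected, n_permutations=config.n_permutations, seed=seed
            )
            pd.DataFrame(
                [
                    {
                        "correlation": protest.statistic,
                        "R2": protest.effect_size,
                        "p_value": protest.p_value,
                        "n_permutations": protest.n_permutations,
                    }
                ]
            ).to_csv(out / "protest.tsv", sep="\t", index=False)
            manifest.add(out / "protest.tsv")
            patterns = traj.group_by_peak(table, metadata, selected)
            patterns.patterns.to_frame("pattern").to_csv(
                out / "trajectory_groups.tsv", sep="\t", index_label="taxon"
            )
            manifest.add(out / "trajectory_groups.tsv")
        manifest.timings["trajectory"] = time.perf_counter() - t0

        manifest.status = "OK"
    except Exception:
        manifest.status = f"FAILED at stage {stage}"
        manifest.write(out)
        (out / "FAILED").write_text(f"stage: {stage}\n")
        raise
    manifest.write(out)
    manifest.add(out / "manifest.json")
    return manifest
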