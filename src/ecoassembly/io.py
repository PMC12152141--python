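"""Readers and writers for the plain-text formats the pipeline touches.

Feature tables are tab-separated with taxa as rows by default (the common
amplicon-export orientation); the orientation is always explicit, never
guessed silently.  Trees are newick (parsed with scikit-bio), metadata is
CSV/TSV, distance matrices and assembly profiles are TSV, and networks can
be written as edge-list TSV, GraphML, or SIF.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import skbio

from .containers import DistanceMatrix, FeatureTable, SampleMetadata

_RANK_PREFIX = re.compile(r"\b[a-zA-Z]__")

#: column names recognised as per-taxon annotations rather than samples
ANNOTATION_COLUMNS = ("taxonomy", "kingdom")


def strip_rank_prefixes(lineage: str) -> str:
    """Remove ``k__`` / ``p__``-style rank prefixes from a lineage string."""
    return _RANK_PREFIX.sub("", lineage)


def read_feature_table(
    path: str | Path,
    kingdom_map: Mapping[str, str] | None = None,
    orientation: str = "taxa_rows",
    strip_prefixes: bool = False,
) -> FeatureTable:
    """Read a tab-separated count table into a :class:`FeatureTable`.

    Parameters
    ----------
    path
        TSV file; the first column holds identifiers.  Columns named
        ``taxonomy`` or ``kingdom`` (taxa-as-rows orientation only) are
        treated as per-taxon annotations, not samples.
    kingdom_map
        Optional per-taxon kingdom labels; overrides any ``kingdom`` column.
    orientation
        ``"taxa_rows"`` (default) or ``"samples_rows"``.
    strip_prefixes
        Strip ``k__``-style rank prefixes from taxonomy strings.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate row identifier {dup!r} in {path}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValueError(f"duplicate column identifier {dup!r} in {path}")

    taxonomy: list[str] | None = None
    kingdom: list[str] | None = None
    if orientation == "taxa_rows":
        if "taxonomy" in raw.columns:
            taxonomy = raw["taxonomy"].tolist()
        if "kingdom" in raw.columns:
            kingdom = raw["kingdom"].tolist()
        counts_df = raw.drop(columns=[c for c in ANNOTATION_COLUMNS if c in raw.columns])
        taxon_ids = list(counts_df.index)
        sample_ids = list(counts_df.columns)
        counts = _parse_counts(counts_df, row_kind="taxon", col_kind="sample", path=path).T
    else:
        counts_df = raw
        sample_ids = list(counts_df.index)
        taxon_ids = list(counts_df.columns)
        counts = _parse_counts(counts_df, row_kind="sample", col_kind="taxon", path=path)

    if kingdom_map is not None:
        missing = [t for t in taxon_ids if t not in kingdom_map]
        if missing:
            raise ValueError(f"kingdom_map missing labels for taxa: {missing[:5]}")
        kingdom = [kingdom_map[t] for t in taxon_ids]
    if taxonomy is not None and strip_prefixes:
        taxonomy = [strip_rank_prefixes(t) for t in taxonomy]
    return FeatureTable(
        counts=counts,
        sample_ids=sample_ids,
        taxon_ids=taxon_ids,
        taxonomy=taxonomy,
        kingdom=kingdom,
    )


def _parse_counts(df: pd.DataFrame, row_kind: str, col_kind: str, path) -> np.ndarray:
    values = np.empty(df.shape, dtype=np.int64)
    arr = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = arr[i, j].strip()
            try:
                x = float(cell)
                if not float(x).is_integer():
                    raise ValueError
                values[i, j] = int(x)
            except (ValueError, OverflowError):
                raise ValueError(
                    f"non-numeric count {cell!r} at {row_kind} {df.index[i]!r}, "
                    f"{col_kind} {df.columns[j]!r} in {path}"
                ) from None
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at {row_kind} {df.index[i]!r}, {col_kind} {df.columns[j]!r}"
        )
    return values


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write taxa-as-rows TSV with taxonomy and kingdom annotation columns."""
    df = pd.DataFrame(table.counts.T, index=table.taxon_ids, columns=table.sample_ids)
    df.insert(len(df.columns), "taxonomy", table.taxonomy)
    df.insert(len(df.columns), "kingdom", table.kingdom)
    df.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read per-sample metadata (CSV by default, TSV for .tsv/.txt)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    return SampleMetadata(frame)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    metadata.frame.to_csv(path, sep=sep, index_label="sample_id")


def read_tree(path: str | Path) -> skbio.TreeNode:
    """Read a rooted newick tree; all tips must carry unique labels."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    names = []
    for tip in tree.tips():
        if tip.name is None or str(tip.name).strip() == "":
            raise ValueError(f"unlabeled tip in {path}")
        names.append(tip.name)
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate tip labels in {path}: {dupes[:5]}")
    return tree


def write_tree(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError(f"row and column identifiers differ in {path}")
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

NETWORK_DIALECTS = ("edgelist", "graphml", "sif")


def write_network(network, path: str | Path, dialect: str = "edgelist") -> None:
    """Serialize a :class:`~ecoassembly.networks.CorrelationNetwork`.

    ``edgelist`` writes a TSV with source, target, correlation, raw and
    adjusted p, and sign; ``graphml`` additionally carries node kingdom and
    mean relative-abundance attributes; ``sif`` is the minimal
    source/interaction/target triple format.
    """
    if dialect not in NETWORK_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {NETWORK_DIALECTS}")
    if dialect == "edgelist":
        rows = [
            {
                "source": e.taxon_a,
                "target": e.taxon_b,
                "correlation": e.correlation,
                "p_value": e.p_value,
                "p_adjusted": e.p_adjusted,
                "sign": e.sign,
            }
            for e in network.edges
        ]
        cols = ["source", "target", "correlation", "p_value", "p_adjusted", "sign"]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    elif dialect == "graphml":
        import networkx as nx

        nx.write_graphml(network.to_networkx(), str(path))
    else:  # sif
        with open(path, "w") as fh:
            for e in network.edges:
                fh.write(f"{e.taxon_a}\t{e.sign}\t{e.taxon_b}\n")


def write_assembly_profiles(profiles: Sequence, path: str | Path) -> None:
    """Write per-group assembly-process fractions as a tidy TSV."""
    rows = []
    for prof in profiles:
        row = {"group": prof.group, "n_pairs": prof.n_pairs, "n_undefined": prof.n_undefined}
        row.update(prof.fractions)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
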