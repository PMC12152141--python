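"""Core in-memory containers shared by every stage of the pipeline.

The pipeline moves three kinds of objects between stages: a sample-by-taxon
count table with per-taxon annotations (:class:`FeatureTable`), per-sample
study design information (:class:`SampleMetadata`), and symmetric pairwise
sample statistics (:class:`DistanceMatrix`).  Phylogenies are represented by
:class:`skbio.TreeNode` throughout and are not wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

KINGDOMS = ("bacteria", "fungi")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class FeatureTable:
    """Sample x taxon count matrix with taxonomy and kingdom annotations.

    Parameters
    ----------
    counts
        Non-negative integer matrix, rows are samples, columns are taxa.
    sample_ids, taxon_ids
        Unique, order-preserving identifiers for rows and columns.
    taxonomy
        Per-taxon semicolon-delimited lineage string; may be empty strings.
    kingdom
        Per-taxon label from ``{"bacteria", "fungi"}``.  Defaults to
        ``"bacteria"`` for single-kingdom workflows; cross-kingdom network
        construction requires explicit labels.
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    taxonomy: list[str] = field(default=None)  # type: ignore[assignment]
    kingdom: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (samples x taxa)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded, atol=1e-9):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        n_s, n_t = self.counts.shape
        if len(self.sample_ids) != n_s:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n_s} rows")
        if len(self.taxon_ids) != n_t:
            raise ValueError(f"{len(self.taxon_ids)} taxon ids for {n_t} columns")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        if self.taxonomy is None:
            self.taxonomy = [""] * n_t
        self.taxonomy = [str(t) for t in self.taxonomy]
        if len(self.taxonomy) != n_t:
            raise ValueError("taxonomy length does not match the number of taxa")
        if self.kingdom is None:
            self.kingdom = ["bacteria"] * n_t
        self.kingdom = [str(k) for k in self.kingdom]
        if len(self.kingdom) != n_t:
            raise ValueError("kingdom length does not match the number of taxa")
        bad = sorted({k for k in self.kingdom if k not in KINGDOMS})
        if bad:
            raise ValueError(f"unknown kingdom labels {bad}; expected one of {KINGDOMS}")

    # -- basic views -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalised counts; rows with zero total stay all-zero."""
        totals = self.sample_totals().astype(float)
        safe = np.where(totals > 0, totals, 1.0)
        return self.counts / safe[:, None]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    # -- subsetting ------------------------------------------------------
    def _taxon_indices(self, taxa: Iterable[str]) -> list[int]:
        lookup = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxa if t not in lookup]
        if missing:
            raise KeyError(f"taxa not in table: {missing[:5]}")
        return [lookup[t] for t in taxa]

    def select_taxa(self, taxa: Sequence[str]) -> "FeatureTable":
        idx = self._taxon_indices(taxa)
        return FeatureTable(
            counts=self.counts[:, idx],
            sample_ids=list(self.sample_ids),
            taxon_ids=[self.taxon_ids[i] for i in idx],
            taxonomy=[self.taxonomy[i] for i in idx],
            kingdom=[self.kingdom[i] for i in idx],
        )

    def select_samples(self, samples: Sequence[str]) -> "FeatureTable":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"samples not in table: {missing[:5]}")
        idx = [lookup[s] for s in samples]
        return FeatureTable(
            counts=self.counts[idx, :],
            sample_ids=[self.sample_ids[i] for i in idx],
            taxon_ids=list(self.taxon_ids),
            taxonomy=list(self.taxonomy),
            kingdom=list(self.kingdom),
        )

    def drop_empty_taxa(self) -> "FeatureTable":
        keep = self.counts.sum(axis=0) > 0
        taxa = [t for t, k in zip(self.taxon_ids, keep) if k]
        return self.select_taxa(taxa)

    def copy(self) -> "FeatureTable":
        return replace(
            self,
            counts=self.counts.copy(),
            sample_ids=list(self.sample_ids),
            taxon_ids=list(self.taxon_ids),
            taxonomy=list(self.taxonomy),
            kingdom=list(self.kingdom),
        )


@dataclass
class SampleMetadata:
    """Per-sample design information: group, optional host, open extras."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.frame.columns:
            raise ValueError("metadata must have a 'group' column")
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise ValueError(f"duplicate sample identifier in metadata: {dup!r}")
        self.frame = self.frame.copy()
        self.frame.index = self.frame.index.astype(str)

    @classmethod
    def from_mapping(
        cls,
        groups: Mapping[str, str],
        host: Mapping[str, str] | None = None,
    ) -> "SampleMetadata":
        frame = pd.DataFrame({"group": pd.Series(dict(groups), dtype=object)})
        if host is not None:
            frame["host"] = pd.Series(dict(host), dtype=object)
        return cls(frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def groups_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise KeyError(f"samples without metadata: {missing[:5]}")
        return self.frame.loc[list(sample_ids), "group"].to_numpy(dtype=object)

    def hosts_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        if "host" not in self.frame.columns:
            raise KeyError("metadata has no 'host' column")
        return self.frame.loc[list(sample_ids), "host"].to_numpy(dtype=object)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample statistic.

    Holds plain dissimilarities (zero diagonal, values >= 0) as well as
    signed null-model deviations (beta-NTI, Raup-Crick), whose diagonal is
    undefined and stored as NaN; off-diagonal NaN marks pairs flagged as
    undefined by a null model.
    """

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-8, equal_nan=True):
            raise ValueError("distance matrix is not symmetric (tolerance 1e-8)")
        # exact symmetrisation so downstream consumers can rely on it
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return float(self.values[i, j])

    def submatrix(self, samples: Sequence[str]) -> "DistanceMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [lookup[s] for s in samples]
        return DistanceMatrix(list(samples), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major (scipy condensed) order."""
        iu = np.triu_indices(self.n_samples, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_skbio(self):
        import skbio

        vals = self.values.copy()
        np.fill_diagonal(vals, 0.0)
        return skbio.DistanceMatrix(vals, ids=self.sample_ids)
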