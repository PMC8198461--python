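"""Core in-memory containers for the pipeline.

The universal currency is a log2-scale gene-by-sample expression matrix;
everything downstream (differential expression, GSEA ranking, signature
scoring, cross-dataset integration) consumes and produces these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

Direction = Literal["up", "down", "undirected"]

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "GeneSignature",
    "ProbeTable",
    "MergedDataset",
]


class ExpressionMatrix:
    """A validated log2-scale genes x samples expression matrix.

    Thin wrapper around a :class:`pandas.DataFrame` (index = gene ids,
    columns = sample ids) that enforces the invariants every downstream
    step relies on: unique gene and sample ids, all-finite numeric values,
    at least one gene and two samples.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] < 1 or data.shape[1] < 2:
            raise ValueError(
                f"expression matrix needs >=1 gene and >=2 samples, got shape {data.shape}"
            )
        dup_genes = data.index[data.index.duplicated()].unique().tolist()
        if dup_genes:
            raise ValueError(f"duplicate gene ids: {dup_genes[:10]}")
        dup_samples = data.columns[data.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise ValueError(f"duplicate sample ids: {dup_samples[:10]}")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite value at gene "
                f"{data.index[bad[0]]!r}, sample {data.columns[bad[1]]!r}"
            )
        self._data = data.astype(float)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def gene_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to the given genes (in the given order); missing ids error."""
        gene_ids = list(gene_ids)
        missing = [g for g in gene_ids if g not in self._data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        return ExpressionMatrix(self._data.loc[gene_ids])

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self._data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        return ExpressionMatrix(self._data[sample_ids])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"


@dataclass
class SampleAnnotation:
    """Per-sample metadata: group (condition or subtype) and dataset (batch).

    ``table`` has columns ``sample_id``, ``group``, ``dataset`` with one row
    per sample.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "group", "dataset")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        dup = self.table["sample_id"][self.table["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample ids in annotation: {dup.tolist()[:10]}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def groups(self) -> pd.Series:
        return pd.Series(
            self.table["group"].to_numpy(), index=self.table["sample_id"], name="group"
        )

    def datasets(self) -> pd.Series:
        return pd.Series(
            self.table["dataset"].to_numpy(), index=self.table["sample_id"], name="dataset"
        )

    def samples_in_group(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "sample_id"].tolist()

    def validate_against(self, expr: ExpressionMatrix) -> None:
        """Every sample of ``expr`` must be annotated exactly once."""
        ann = set(self.sample_ids)
        missing = [s for s in expr.sample_ids if s not in ann]
        if missing:
            raise ValueError(f"samples missing from annotation: {missing[:10]}")


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set, optionally with a per-gene direction.

    ``members`` maps gene id -> direction in {"up", "down", "undirected"}.
    The BRAF-RAS score requires both up (RAS-ward) and down (BRAF-ward)
    members; purely undirected sets serve GSEA and mean scoring.
    """

    name: str
    members: tuple[tuple[str, Direction], ...]
    source: str = ""

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.members]
        if len(genes) != len(set(genes)):
            seen: set[str] = set()
            dup = [g for g in genes if g in seen or seen.add(g)]  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate genes in signature {self.name!r}: {dup[:10]}")
        for g, d in self.members:
            if d not in ("up", "down", "undirected"):
                raise ValueError(f"bad direction {d!r} for gene {g!r}")

    @classmethod
    def from_genes(
        cls,
        name: str,
        genes: Iterable[str],
        direction: Direction = "undirected",
        source: str = "",
    ) -> "GeneSignature":
        return cls(name, tuple((g, direction) for g in genes), source)

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.members]

    @property
    def up_genes(self) -> list[str]:
        return [g for g, d in self.members if d == "up"]

    @property
    def down_genes(self) -> list[str]:
        return [g for g, d in self.members if d == "down"]

    @property
    def undirected_genes(self) -> list[str]:
        return [g for g, d in self.members if d == "undirected"]

    @property
    def is_directional(self) -> bool:
        return any(d != "undirected" for _, d in self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class ProbeTable:
    """Probe-level values with a many-probes-to-one-gene mapping.

    ``values``: probes x samples DataFrame (index = probe ids);
    ``probe_to_gene``: maps each probe id to a gene symbol, or to ``""`` /
    missing for unmapped probes (dropped at collapse time).
    """

    values: pd.DataFrame
    probe_to_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dup[:10]}")

    def mapped_probes(self) -> list[str]:
        return [p for p in self.values.index if self.probe_to_gene.get(p, "")]


@dataclass
class MergedDataset:
    """Two expression datasets joined on common genes with batch labels.

    ``values``: genes x samples DataFrame over the common genes (after
    per-dataset z-scoring when produced by :func:`merge_and_standardize`);
    ``batch``: per-sample dataset label; ``group``: per-sample class label.
    """

    values: pd.DataFrame
    batch: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        for s in (self.batch, self.group):
            if list(s.index) != list(self.values.columns):
                raise ValueError("batch/group labels must be indexed by the sample ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)
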