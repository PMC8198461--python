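"""Readers and writers for expression matrices, annotations and gene sets.

Formats are deliberately plain: tab-separated expression tables (gene ids in
the first column, sample ids in the header), CSV annotation tables
(``sample_id,group,dataset``), and GMT gene-set files. A small directional
extension of GMT encodes a per-gene direction as ``GENE|up`` / ``GENE|down``;
plain tokens stay undirected, so standard GMT files remain readable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSignature, ProbeTable, SampleAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotations",
    "write_annotations",
    "read_gene_sets",
    "write_gene_sets",
    "collapse_probes_maxmean",
]


def read_expression_matrix(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Load a genes x samples matrix from delimited text.

    The first column holds gene ids, the header row sample ids. Duplicate
    gene rows are an error — probe collapsing must be done explicitly via
    :func:`collapse_probes_maxmean`. Non-numeric cells are reported with
    their coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if len(bad):
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate gene rows {dup[:10]}; collapse probes explicitly")
    return ExpressionMatrix(numeric)


def write_expression_matrix(
    expr: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    df = expr.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep=delimiter)


def read_annotations(path: str | Path) -> SampleAnnotation:
    """Read a ``sample_id,group,dataset`` CSV annotation table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    return SampleAnnotation(pd.read_csv(path, dtype=str))


def write_annotations(ann: SampleAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, index=False)


def _parse_member(token: str) -> tuple[str, str]:
    if "|" in token:
        gene, _, direction = token.rpartition("|")
        if direction not in ("up", "down"):
            raise ValueError(f"bad direction suffix in token {token!r}")
        if not gene:
            raise ValueError(f"empty gene id in token {token!r}")
        return gene, direction
    return token, "undirected"


def read_gene_sets(path: str | Path) -> list[GeneSignature]:
    """Parse a GMT file (directional dialect allowed) into signatures.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``; a gene
    token may carry a ``|up`` / ``|down`` suffix. Line order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    signatures: list[GeneSignature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            tokens = line.split("\t")
            if len(tokens) < 3:
                raise ValueError(
                    f"{path}:{lineno}: gene-set line needs name, description and >=1 gene"
                )
            name, description = tokens[0], tokens[1]
            members = tuple(_parse_member(t) for t in tokens[2:] if t)
            try:
                sig = GeneSignature(name, members, source=description)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            signatures.append(sig)
    return signatures


def write_gene_sets(signatures: Sequence[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            tokens = [
                g if d == "undirected" else f"{g}|{d}" for g, d in sig.members
            ]
            fh.write("\t".join([sig.name, sig.source or "na", *tokens]) + "\n")


def collapse_probes_maxmean(probes: ProbeTable) -> ExpressionMatrix:
    """Collapse many-probes-per-gene rows by the MaxMean rule.

    For each gene, keep the single probe whose mean across samples is
    largest; that probe's row becomes the gene's row. Ties are broken by
    lexicographically smallest probe id so the result is deterministic.
    Unmapped probes (no gene symbol) are dropped with a logged count.
    """
    mapped = probes.mapped_probes()
    n_dropped = probes.values.shape[0] - len(mapped)
    if n_dropped:
        logger.info("collapse_probes_maxmean: dropped %d unmapped probes", n_dropped)
    if not mapped:
        raise ValueError("no probes map to a gene symbol")
    values = probes.values.loc[mapped]
    means = values.mean(axis=1)
    best: dict[str, str] = {}
    for probe in mapped:
        gene = probes.probe_to_gene[probe]
        cur = best.get(gene)
        if (
            cur is None
            or means[probe] > means[cur]
            or (means[probe] == means[cur] and probe < cur)
        ):
            best[gene] = probe
    genes = sorted(best)
    out = values.loc[[best[g] for g in genes]]
    out.index = pd.Index(genes, name="gene_id")
    return ExpressionMatrix(out)
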