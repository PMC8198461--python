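"""Thyroid-cancer signature scores and BRAF-like/RAS-like classification.

Three score families, all computed on log2-scale expression:

* mean-of-centered scores (MAPK output, thyroid differentiation): each gene
  row is median-centered across the samples of the analyzed matrix and the
  score is the per-sample mean over the signature genes;
* the BRAF-RAS score (BRS): on the same centered matrix, the mean over the
  RAS-ward (up) genes minus the mean over the BRAF-ward (down) genes —
  positive values point RAS-ward, negative BRAF-ward, matching the TCGA
  convention (negative = BRAF-like);
* a rank-based single-sample score: within each sample alone, genes are
  ranked ascending (average ranks on ties) and the signature's mean rank is
  min-max normalized; the centered score lies in [-0.5, 0.5] for an
  undirected/up set and in [-1, 1] for a directional set (the down
  component uses reversed ranks). Being rank-based, it is invariant to any
  strictly monotone transform of a sample's expression values.

The subtype call is the sign of the BRS: negative -> BRAF-like, positive ->
RAS-like (exact zero -> RAS-like, a frozen tie rule flagged in the output).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, GeneSignature

__all__ = [
    "median_center_log2",
    "signature_mean_score",
    "brs_score",
    "singscore",
    "classify_subtype",
    "compute_signature_scores",
]

MIN_COVERAGE = 0.5


def median_center_log2(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's across-sample median (midpoint rule for even n).

    Input is assumed to be on the log2 scale already; needs >= 2 samples.
    """
    if expr.shape[1] < 2:
        raise ValueError("median centering needs >= 2 samples")
    centered = expr.data.sub(expr.data.median(axis=1), axis=0)
    return ExpressionMatrix(centered)


def _present_genes(expr: ExpressionMatrix, genes: list[str], sig_name: str) -> list[str]:
    present = [g for g in genes if g in expr.data.index]
    if not present:
        raise ValueError(f"no gene of signature {sig_name!r} is present in the matrix")
    coverage = len(present) / len(genes)
    if coverage < MIN_COVERAGE:
        raise ValueError(
            f"signature {sig_name!r}: only {len(present)}/{len(genes)} genes present "
            f"({coverage:.0%} < {MIN_COVERAGE:.0%})"
        )
    if coverage < 1.0:
        warnings.warn(
            f"signature {sig_name!r}: {len(present)}/{len(genes)} genes present "
            f"({coverage:.0%} coverage)",
            stacklevel=3,
        )
    return present


def signature_mean_score(centered: ExpressionMatrix, sig: GeneSignature) -> pd.Series:
    """Per-sample mean of centered expression over the signature genes.

    Used for the MAPK output and thyroid differentiation scores. Proceeds
    (with a warning) when at least half the signature is present.
    """
    present = _present_genes(centered, sig.genes, sig.name)
    scores = centered.data.loc[present].mean(axis=0)
    scores.name = sig.name
    return scores


def brs_score(centered: ExpressionMatrix, brs_sig: GeneSignature) -> pd.Series:
    """BRAF-RAS score: mean over RAS-ward genes minus mean over BRAF-ward.

    Requires a directional signature with both classes represented in the
    matrix. Positive = RAS-ward, negative = BRAF-ward.
    """
    if not brs_sig.up_genes or not brs_sig.down_genes:
        raise ValueError(
            f"signature {brs_sig.name!r} needs both up (RAS) and down (BRAF) members"
        )
    up = [g for g in brs_sig.up_genes if g in centered.data.index]
    down = [g for g in brs_sig.down_genes if g in centered.data.index]
    if not up or not down:
        raise ValueError(
            f"signature {brs_sig.name!r}: a direction class is entirely absent from the matrix"
        )
    _present_genes(centered, brs_sig.genes, brs_sig.name)
    scores = centered.data.loc[up].mean(axis=0) - centered.data.loc[down].mean(axis=0)
    scores.name = "BRS"
    return scores


def _rank_component(ranks: np.ndarray, idx: np.ndarray, n: int) -> float:
    """Centered min-max normalized mean rank of one direction class."""
    n_s = idx.size
    raw = float(ranks[idx].mean())
    lo = (n_s + 1) / 2.0
    hi = (2 * n - n_s + 1) / 2.0
    return (raw - lo) / (hi - lo) - 0.5


def singscore(expr: ExpressionMatrix, sig: GeneSignature) -> pd.Series:
    """Rank-based single-sample signature score.

    Each sample is scored independently from its own gene ranking, so no
    cross-sample centering is involved. Undirected and up members form the
    up component (ascending ranks); down members are scored on reversed
    ranks. Scores lie in [-0.5, 0.5] per component, [-1, 1] in total for a
    directional set.
    """
    up_genes = [g for g in sig.genes if g not in set(sig.down_genes)]
    up_present = [g for g in up_genes if g in expr.data.index]
    down_present = [g for g in sig.down_genes if g in expr.data.index]
    if not up_present and not down_present:
        raise ValueError(f"no gene of signature {sig.name!r} is present in the matrix")
    _present_genes(expr, sig.genes, sig.name)
    gene_pos = {g: i for i, g in enumerate(expr.data.index)}
    up_idx = np.asarray([gene_pos[g] for g in up_present], dtype=int)
    down_idx = np.asarray([gene_pos[g] for g in down_present], dtype=int)
    n = expr.shape[0]
    values = expr.values
    out = {}
    for j, sample in enumerate(expr.sample_ids):
        ranks = rankdata(values[:, j], method="average")
        score = 0.0
        if up_idx.size:
            score += _rank_component(ranks, up_idx, n)
        if down_idx.size:
            score += _rank_component(n + 1 - ranks, down_idx, n)
        out[sample] = score
    return pd.Series(out, name=f"singscore:{sig.name}")


def classify_subtype(brs: pd.Series) -> pd.DataFrame:
    """Call each sample BRAF-like (BRS < 0) or RAS-like (BRS >= 0).

    The zero tie goes to RAS-like purely for determinism and is flagged in
    the ``tie`` column. Missing scores are an error.
    """
    if brs.isna().any():
        missing = brs.index[brs.isna()].tolist()
        raise ValueError(f"missing BRS for samples: {missing[:10]}")
    return pd.DataFrame(
        {
            "sample_id": brs.index,
            "call": np.where(brs.to_numpy() < 0, "BRAF-like", "RAS-like"),
            "brs": brs.to_numpy(),
            "tie": brs.to_numpy() == 0,
        }
    ).set_index("sample_id")


def compute_signature_scores(
    expr: ExpressionMatrix,
    mapk: GeneSignature,
    td: GeneSignature,
    brs_sig: GeneSignature,
) -> pd.DataFrame:
    """All three signature scores plus the rank-based BRS, long format.

    Median-centers the matrix once (across all analyzed samples — the
    scores are comparative by construction) and returns a tidy table with
    columns ``sample_id``, ``score_name``, ``value``.
    """
    centered = median_center_log2(expr)
    pieces = {
        "MAPK_output": signature_mean_score(centered, mapk),
        "TDS": signature_mean_score(centered, td),
        "BRS": brs_score(centered, brs_sig),
        f"singscore:{brs_sig.name}": singscore(expr, brs_sig),
    }
    long = pd.concat(
        [
            pd.DataFrame({"sample_id": s.index, "score_name": name, "value": s.to_numpy()})
            for name, s in pieces.items()
        ],
        ignore_index=True,
    )
    return long
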