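"""Preranked gene-set enrichment analysis.

Genes are ranked by a statistic (here the moderated t from the differential
expression module) and each gene set is scored with the weighted
Kolmogorov-Smirnov-like running sum: walking down the ranking, hitting a
set member adds ``|stat|^w / sum_set |stat|^w`` and missing one subtracts
``1 / (N - n_s)``; the enrichment score (ES) is the extremal deviation of
the running sum from zero, signed. The null distribution comes from random
same-size gene subsets of the ranked universe (gene-label permutation — the
only null available for preranked input). The permutation p-value and the
normalized enrichment score (NES) are computed within the same-sign
permutation population, the classic convention:

    p = (1 + #{perm same sign, |ES_perm| >= |ES|}) / (1 + #{perm same sign})
    NES = ES / mean(|ES_perm| over same-sign perms)

FDR across sets is Benjamini-Hochberg on the permutation p-values.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GeneSignature
from .diffexpr import bh_fdr

__all__ = ["rank_genes", "enrichment_score", "gsea_preranked"]


def rank_genes(de: pd.DataFrame, stat_col: str = "t_mod") -> pd.Series:
    """Order genes by descending statistic into a ranked list.

    Ties are broken by ascending gene id so the ranking is deterministic
    and invariant to input order. Returns the statistic indexed by gene id,
    best-ranked first.
    """
    if de.index.duplicated().any():
        dup = de.index[de.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate genes in ranking input: {dup[:10]}")
    stat = de[stat_col]
    if not np.all(np.isfinite(stat.to_numpy())):
        raise ValueError("ranking statistic must be finite for every gene")
    frame = pd.DataFrame(
        {"stat": stat.to_numpy(), "gene": de.index.astype(str)}
    ).sort_values(["stat", "gene"], ascending=[False, True], kind="mergesort")
    return pd.Series(
        frame["stat"].to_numpy(), index=pd.Index(frame["gene"], name="gene_id"), name="stat"
    )


def _running_sum(
    stats: np.ndarray, hit_mask: np.ndarray, weight: float
) -> np.ndarray:
    n = stats.size
    n_hit = int(hit_mask.sum())
    w = np.abs(stats) ** weight
    hit_total = w[hit_mask].sum()
    steps = np.where(
        hit_mask,
        (w / hit_total) if hit_total > 0 else (1.0 / n_hit),
        -1.0 / (n - n_hit),
    )
    return np.cumsum(steps)


def enrichment_score(
    ranked: pd.Series, sig: GeneSignature, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted running-sum enrichment score of one set against a ranking.

    Returns the signed ES (extremal deviation from zero; at an exact tie in
    magnitude the positive extreme wins) and the full running-sum profile.
    The set must intersect the ranked universe without covering it.
    """
    members = set(sig.genes)
    hit_mask = np.asarray([g in members for g in ranked.index])
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise ValueError(f"signature {sig.name!r} has no genes in the ranked universe")
    if n_hit == ranked.size:
        raise ValueError(f"signature {sig.name!r} covers the whole ranked universe")
    profile = _running_sum(ranked.to_numpy(), hit_mask, weight)
    hi = float(profile.max())
    lo = float(profile.min())
    es = hi if hi >= -lo else lo
    return es, profile


def _es_only(stats: np.ndarray, abs_w: np.ndarray, hit_idx: np.ndarray) -> float:
    """ES from sorted hit positions without materializing the full profile.

    The running sum attains its extrema immediately after a hit (maxima
    candidates) or immediately before one (minima candidates).
    """
    n = stats.size
    k = hit_idx.size
    miss = 1.0 / (n - k)
    w = abs_w[hit_idx]
    total = w.sum()
    if total > 0:
        w = w / total
    else:
        w = np.full(k, 1.0 / k)
    cum_hits = np.cumsum(w)
    i = np.arange(k)
    after = cum_hits - (hit_idx - i) * miss
    before = after - w
    hi = float(after.max())
    lo = min(float(before.min()), 0.0)
    return hi if hi >= -lo else lo


def gsea_preranked(
    ranked: pd.Series,
    sets: Sequence[GeneSignature],
    n_perm: int = 10_000,
    min_size: int = 15,
    max_size: int = 500,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA over a collection of gene sets.

    Sets are first intersected with the ranked universe and filtered to
    ``[min_size, max_size]``; each surviving set gets an ES, a gene-
    permutation p-value and NES (same-sign convention), and a BH FDR over
    all tested sets. Deterministic under ``seed``.
    """
    if n_perm < 100:
        raise ValueError("need >= 100 permutations")
    universe = list(ranked.index)
    stats = ranked.to_numpy()
    abs_w = np.abs(stats) ** weight
    index_of = {g: i for i, g in enumerate(universe)}
    surviving: list[tuple[GeneSignature, np.ndarray]] = []
    for sig in sets:
        idx = np.asarray(sorted(index_of[g] for g in sig.genes if g in index_of), dtype=int)
        if min_size <= idx.size <= max_size and idx.size < len(universe):
            surviving.append((sig, idx))
    if not surviving:
        raise ValueError(
            f"no gene set survives the [{min_size}, {max_size}] size filter"
        )
    rng = np.random.default_rng(seed)
    records = []
    n = len(universe)
    for sig, idx in surviving:
        es = _es_only(stats, abs_w, idx)
        perm_es = np.empty(n_perm)
        for j in range(n_perm):
            perm_idx = np.sort(rng.choice(n, size=idx.size, replace=False))
            perm_es[j] = _es_only(stats, abs_w, perm_idx)
        same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
        n_same = int(same_sign.sum())
        extreme = int((np.abs(perm_es[same_sign]) >= abs(es)).sum())
        p_perm = (1 + extreme) / (1 + n_same)
        mean_abs = float(np.abs(perm_es[same_sign]).mean()) if n_same else np.nan
        nes = es / mean_abs if mean_abs and mean_abs > 0 else np.nan
        records.append(
            {
                "set_name": sig.name,
                "size": idx.size,
                "es": es,
                "nes": nes,
                "p_perm": p_perm,
            }
        )
    out = pd.DataFrame(records).set_index("set_name")
    out["fdr"] = bh_fdr(out["p_perm"])
    return out
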