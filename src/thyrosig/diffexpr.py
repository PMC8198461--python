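"""Two-group differential expression with an empirical-Bayes moderated t.

The model is the two-group special case of the standard linear-modeling
approach for microarray data: per gene, an equal-variance two-sample
contrast whose variance estimate is shrunk toward a pooled prior. Writing
``s2_g`` for the pooled residual variance on ``d = n_a + n_b - 2`` degrees
of freedom, the prior ``(d0, s0^2)`` is estimated by moment matching on
``log s2_g`` under the scaled-F model ``s2_g ~ s0^2 * F(d, d0)``, and the
posterior variance is

    s~2_g = (d0 * s0^2 + d * s2_g) / (d0 + d)

The moderated t is ``log2fc / (s~_g * sqrt(1/n_a + 1/n_b))`` with two-sided
p-values from a t-distribution on ``d0 + d`` degrees of freedom (standard
normal when ``d0`` is infinite). ``d0 = 0`` disables moderation and
reproduces the classical pooled t exactly.

Benjamini-Hochberg adjustment and the fold-change/FDR gene selection rule
(|FC| >= 2, i.e. |log2FC| >= 1, and FDR < 0.05 by default) complete the
module; the moderated t is also the ranking statistic consumed by the GSEA
module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix, SampleAnnotation

__all__ = [
    "EBayesParams",
    "fit_group_stats",
    "estimate_ebayes",
    "moderated_t",
    "bh_fdr",
    "select_degs",
    "differential_expression",
]


@dataclass(frozen=True)
class EBayesParams:
    """Empirical-Bayes variance prior: ``d0`` prior df (``inf`` allowed as a
    sentinel for no-dispersion shrinkage to a common value), ``s0_sq`` prior
    variance, ``d`` residual df per gene."""

    d0: float
    s0_sq: float
    d: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior df d0 must be >= 0")
        if self.s0_sq <= 0 and not math.isclose(self.d0, 0.0):
            raise ValueError("prior variance s0_sq must be positive")
        if self.d <= 0:
            raise ValueError("residual df d must be positive")


def fit_group_stats(
    expr: ExpressionMatrix,
    ann: SampleAnnotation,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-gene group means, pooled variance and log2 fold change (a - b).

    Both groups need at least two samples; the pooled variance carries
    ``d = n_a + n_b - 2`` degrees of freedom.
    """
    ann.validate_against(expr)
    samples_a = [s for s in ann.samples_in_group(group_a) if s in expr.data.columns]
    samples_b = [s for s in ann.samples_in_group(group_b) if s in expr.data.columns]
    for label, samples in ((group_a, samples_a), (group_b, samples_b)):
        if len(samples) < 2:
            raise ValueError(
                f"group {label!r} has {len(samples)} sample(s) in the matrix; need >= 2"
            )
    a = expr.data[samples_a].to_numpy()
    b = expr.data[samples_b].to_numpy()
    n_a, n_b = a.shape[1], b.shape[1]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    d = n_a + n_b - 2
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": mean_a - mean_b,
            "avg_expr": np.concatenate([a, b], axis=1).mean(axis=1),
            "s2": ss / d,
            "n_a": n_a,
            "n_b": n_b,
            "d": float(d),
        },
        index=expr.data.index.rename("gene_id"),
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_ebayes(s2: np.ndarray | pd.Series, d: float) -> EBayesParams:
    """Estimate the variance prior (d0, s0^2) from per-gene pooled variances.

    Moment matching on ``e_g = log s2_g`` under ``s2_g ~ s0^2 F(d, d0)``:
    the excess of ``var(e)`` over ``trigamma(d/2)`` determines ``d0`` through
    the trigamma function; if the observed dispersion does not exceed what
    ``d`` alone implies, ``d0`` is infinite and all genes share ``s0^2``.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2:
        raise ValueError("need >= 2 genes to estimate the variance prior")
    if np.all(s2 <= 0):
        raise ValueError("all pooled variances are zero")
    positive = s2[s2 > 0]
    if np.ptp(positive) == 0.0:
        # exactly constant variances: no dispersion to fit, the common value
        # is the prior and the shrinkage target
        return EBayesParams(d0=math.inf, s0_sq=float(positive[0]), d=float(d))
    e = np.log(positive) - (special.digamma(d / 2.0) - math.log(d / 2.0))
    e_mean = e.mean()
    e_var = e.var(ddof=1) - float(special.polygamma(1, d / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return EBayesParams(d0=d0, s0_sq=s0_sq, d=float(d))


def moderated_t(group_stats: pd.DataFrame, eb: EBayesParams) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values for fitted group stats.

    Posterior variances shrink each gene's ``s2`` toward ``s0_sq`` with
    weight ``d0``; total df is ``d0 + d`` (normal reference when infinite).
    """
    s2 = group_stats["s2"].to_numpy()
    n_a = group_stats["n_a"].to_numpy()
    n_b = group_stats["n_b"].to_numpy()
    if math.isinf(eb.d0):
        s2_post = np.full_like(s2, eb.s0_sq)
    else:
        s2_post = (eb.d0 * eb.s0_sq + eb.d * s2) / (eb.d0 + eb.d)
    if np.any(s2_post <= 0):
        raise ValueError(
            "zero posterior variance: zero-variance genes cannot be tested with d0 = 0"
        )
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    t = group_stats["log2fc"].to_numpy() / se
    if math.isinf(eb.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=eb.d0 + eb.d)
    out = group_stats.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t
    out["p"] = p
    return out


def bh_fdr(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the sorted vector, capped at
    one; ties share the same adjusted value and the result is invariant to
    input order.
    """
    p_arr = np.asarray(p, dtype=float)
    if p_arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p_arr.size == 0:
        return p_arr.copy()
    if np.any((p_arr < 0) | (p_arr > 1)) or np.any(np.isnan(p_arr)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p_arr.size
    order = np.argsort(p_arr, kind="mergesort")
    scaled = p_arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_degs(
    results: pd.DataFrame, fc_min: float = 2.0, fdr_max: float = 0.05
) -> pd.DataFrame:
    """Apply the fold-change/FDR selection rule and assign directions.

    A gene is differentially expressed iff ``|log2fc| >= log2(fc_min)``
    (inclusive) and ``fdr < fdr_max`` (strict). Adds ``is_deg`` and
    ``direction`` columns.
    """
    if fc_min <= 0 or fdr_max <= 0:
        raise ValueError("thresholds must be positive")
    out = results.copy()
    lfc_min = math.log2(fc_min)
    out["is_deg"] = (out["log2fc"].abs() >= lfc_min) & (out["fdr"] < fdr_max)
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    return out


def differential_expression(
    expr: ExpressionMatrix,
    ann: SampleAnnotation,
    group_a: str,
    group_b: str,
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
    d0: float | None = None,
) -> pd.DataFrame:
    """Full two-group pipeline: fit, shrink, test, adjust, select.

    ``group_a`` is the treated condition and ``group_b`` the control, so
    positive ``log2fc`` means higher expression under treatment. Passing
    ``d0`` overrides the estimated prior df (0 = classical pooled t,
    ``inf`` = fully shared variance).
    """
    fitted = fit_group_stats(expr, ann, group_a, group_b)
    eb = estimate_ebayes(fitted["s2"], fitted["d"].iloc[0])
    if d0 is not None:
        s0 = eb.s0_sq if d0 > 0 else float(fitted["s2"].mean())
        eb = EBayesParams(d0=d0, s0_sq=s0, d=eb.d)
    tested = moderated_t(fitted, eb)
    tested["fdr"] = bh_fdr(tested["p"])
    return select_degs(tested, fc_min=fc_min, fdr_max=fdr_max)
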