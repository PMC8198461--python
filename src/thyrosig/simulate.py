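"""Seeded synthetic expression data emulating the study design.

Two datasets are generated on a shared gene universe:

* a cell-line experiment — three conditions (vehicle control plus two BRAF
  inhibitors) with a fixed number of technical replicates each, where
  treated samples carry signature-concordant mean shifts on the log2 scale
  (MAPK output genes down, thyroid differentiation genes up, BRAF-RAS
  signature genes shifted toward the RAS-like pole);
* a tissue cohort split into BRAF-like and RAS-like groups, shifted in
  opposite directions along the BRAF-RAS signature only.

The noise model is i.i.d. Gaussian on the log2 scale with per-gene baselines
drawn once from a declared normal distribution; technical replicates are
simulated (and analyzed downstream) as independent samples. Signature
membership uses a seed substream separate from the noise stream, so changing
the noise level never changes which genes are planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSignature, SampleAnnotation

__all__ = ["SyntheticConfig", "make_synthetic_signatures", "simulate_experiment", "simulate_cohort"]

# seed-substream tags: membership must not move when noise parameters change
_MEMBERSHIP_STREAM = 101
_EXPERIMENT_STREAM = 202
_COHORT_STREAM = 303


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 3 conditions x 3 replicates of
    cell-line profiles, a 29-tissue cohort (15 BRAF-like / 14 RAS-like),
    planted signatures of sizes 52/16/71, log2 mean shifts delta = 2 and
    Gaussian noise sigma = 0.25 around N(8, 2^2) baselines.
    """

    n_genes: int = 5000
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("DMSO", "Vemurafenib", "Dabrafenib")
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.25
    effects: dict[str, float] = field(
        default_factory=lambda: {"MAPK": 2.0, "TD": 2.0, "BRS": 2.0}
    )
    signature_sizes: tuple[int, int, int] = (52, 16, 71)
    cohort_sizes: tuple[int, int] = (15, 14)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_replicates < 2:
            raise ValueError("need >=2 replicates per condition")
        if len(self.conditions) < 2:
            raise ValueError("need a control and >=1 treated condition")
        if min(self.cohort_sizes) < 1:
            raise ValueError("cohort group sizes must be positive")
        if self.n_genes < sum(self.signature_sizes):
            raise ValueError(
                f"gene universe ({self.n_genes}) too small for disjoint signatures "
                f"(need >= {sum(self.signature_sizes)})"
            )

    @property
    def gene_universe(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def control(self) -> str:
        return self.conditions[0]


def make_synthetic_signatures(config: SyntheticConfig) -> list[GeneSignature]:
    """Draw three disjoint planted signatures from the gene universe.

    Returns MAPK-like (undirected; shifted down in treated samples), TD-like
    (undirected; shifted up) and BRS-like (mixed: roughly half up/RAS-ward,
    half down/BRAF-ward) signatures. Membership is a deterministic function
    of the seed alone.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _MEMBERSHIP_STREAM]))
    universe = np.asarray(config.gene_universe)
    n_mapk, n_td, n_brs = config.signature_sizes
    chosen = rng.choice(len(universe), size=n_mapk + n_td + n_brs, replace=False)
    mapk = universe[chosen[:n_mapk]]
    td = universe[chosen[n_mapk : n_mapk + n_td]]
    brs = universe[chosen[n_mapk + n_td :]]
    n_up = (n_brs + 1) // 2
    brs_members = tuple(
        (g, "up" if i < n_up else "down") for i, g in enumerate(brs)
    )
    return [
        GeneSignature.from_genes("MAPK_like", mapk, "undirected", source="synthetic"),
        GeneSignature.from_genes("TD_like", td, "undirected", source="synthetic"),
        GeneSignature("BRS_like", brs_members, source="synthetic"),
    ]


def _effect_vector(
    config: SyntheticConfig, signatures: list[GeneSignature]
) -> pd.Series:
    """Per-gene log2 shift applied to treated (non-control) samples."""
    by_name = {s.name: s for s in signatures}
    universe = set(config.gene_universe)
    for sig in signatures:
        unknown = [g for g in sig.genes if g not in universe]
        if unknown:
            raise ValueError(f"signature {sig.name!r} has genes outside the universe: {unknown[:5]}")
    effect = pd.Series(0.0, index=config.gene_universe)
    d_mapk = config.effects.get("MAPK", 0.0)
    d_td = config.effects.get("TD", 0.0)
    d_brs = config.effects.get("BRS", 0.0)
    if "MAPK_like" in by_name:
        effect[by_name["MAPK_like"].genes] = -d_mapk
    if "TD_like" in by_name:
        effect[by_name["TD_like"].genes] = d_td
    if "BRS_like" in by_name:
        effect[by_name["BRS_like"].up_genes] = d_brs
        effect[by_name["BRS_like"].down_genes] = -d_brs
    return effect


def _baselines(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)


def simulate_experiment(
    config: SyntheticConfig, signatures: list[GeneSignature]
) -> tuple[ExpressionMatrix, SampleAnnotation]:
    """Simulate the treated-vs-control cell-line experiment.

    Expression is ``baseline_g + effect_gs + eps``, with eps ~ N(0, sigma^2)
    and the planted effect applied only in non-control conditions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _EXPERIMENT_STREAM]))
    baselines = _baselines(config, rng)
    effect = _effect_vector(config, signatures).to_numpy()
    columns: dict[str, np.ndarray] = {}
    rows = []
    for cond in config.conditions:
        shift = 0.0 if cond == config.control else effect
        for rep in range(1, config.n_replicates + 1):
            sample = f"{cond}_{rep}"
            noise = rng.normal(0.0, config.noise_sd, size=config.n_genes)
            columns[sample] = baselines + shift + noise
            rows.append({"sample_id": sample, "group": cond, "dataset": "cell_lines"})
    expr = ExpressionMatrix(pd.DataFrame(columns, index=config.gene_universe))
    return expr, SampleAnnotation(pd.DataFrame(rows))


def simulate_cohort(
    config: SyntheticConfig, signatures: list[GeneSignature]
) -> tuple[ExpressionMatrix, SampleAnnotation]:
    """Simulate the BRAF-like / RAS-like tissue cohort.

    BRAF-like samples have the BRAF-ward (down) genes of the BRS signature
    shifted up and the RAS-ward genes down; RAS-like samples the reverse.
    The dataset label differs from the cell-line batch.
    """
    by_name = {s.name: s for s in signatures}
    if "BRS_like" not in by_name:
        raise ValueError("cohort simulation needs a BRS_like signature")
    brs = by_name["BRS_like"]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _COHORT_STREAM]))
    baselines = _baselines(config, rng)
    d_brs = config.effects.get("BRS", 0.0)
    ras_shift = pd.Series(0.0, index=config.gene_universe)
    ras_shift[brs.up_genes] = d_brs
    ras_shift[brs.down_genes] = -d_brs
    ras_shift = ras_shift.to_numpy()

    n_braf, n_ras = config.cohort_sizes
    columns: dict[str, np.ndarray] = {}
    rows = []
    for group, n, shift in (
        ("BRAF-like", n_braf, -ras_shift),
        ("RAS-like", n_ras, ras_shift),
    ):
        for i in range(1, n + 1):
            sample = f"{group}_{i}"
            noise = rng.normal(0.0, config.noise_sd, size=config.n_genes)
            columns[sample] = baselines + shift + noise
            rows.append({"sample_id": sample, "group": group, "dataset": "tissues"})
    expr = ExpressionMatrix(pd.DataFrame(columns, index=config.gene_universe))
    return expr, SampleAnnotation(pd.DataFrame(rows))
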