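import numpy as np
import pandas as pd
import pytest

from thyrosig import (
    ExpressionMatrix,
    SampleAnnotation,
    SyntheticConfig,
    make_synthetic_signatures,
    simulate_cohort,
    simulate_experiment,
)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with simple hand-checkable values."""
    return ExpressionMatrix(
        pd.DataFrame(
            {
                "s1": [1.0, 5.0, 2.0],
                "s2": [2.0, 5.0, 4.0],
                "s3": [4.0, 5.0, 6.0],
                "s4": [3.0, 5.0, 8.0],
            },
            index=["TG", "TPO", "FN1"],
        )
    )


@pytest.fixture
def two_group_ann() -> SampleAnnotation:
    return SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "group": ["ctrl", "ctrl", "drug", "drug"],
                "dataset": ["d1"] * 4,
            }
        )
    )


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def planted(default_config):
    """Signatures plus cell-line experiment simulated at the default design."""
    sigs = make_synthetic_signatures(default_config)
    expr, ann = simulate_experiment(default_config, sigs)
    return default_config, sigs, expr, ann


@pytest.fixture(scope="session")
def cohort(default_config):
    sigs = make_synthetic_signatures(default_config)
    expr, ann = simulate_cohort(default_config, sigs)
    return default_config, sigs, expr, ann


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition, independent of the implementation.

    q_(i) = min over j >= i of p_(j) * m / j (sorted scale), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def brute_force_es(stats: np.ndarray, in_set: np.ndarray, weight: float = 1.0) -> float:
    """Literal running-sum ES definition over every position."""
    stats = np.asarray(stats, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    n = len(stats)
    n_s = int(in_set.sum())
    denom = np.sum(np.abs(stats[in_set]) ** weight)
    running = 0.0
    best = 0.0
    for i in range(n):
        if in_set[i]:
            if denom > 0:
                running += np.abs(stats[i]) ** weight / denom
            else:
                running += 1.0 / n_s
        else:
            running -= 1.0 / (n - n_s)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best
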