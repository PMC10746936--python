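"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive re-derivations (hand rank-averaging,
step-up enumeration, combinatorial tails, O−E/V accumulation) kept separate
from the library code paths they validate.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from dicoexnet import ExpressionStudy


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def average_ranks(x) -> np.ndarray:
    """Hand-rolled average ranks (1-based, ties share the mean rank)."""
    x = np.asarray(x, dtype=float)
    ranks = np.empty(len(x))
    for i, xi in enumerate(x):
        less = np.sum(x < xi)
        equal = np.sum(x == xi)
        # ranks occupied by the tie group: less+1 .. less+equal
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_oracle(x, y) -> float:
    """Average ranks then Pearson via np.corrcoef."""
    return float(np.corrcoef(average_ranks(x), average_ranks(y))[0, 1])


def bh_oracle(p_values) -> np.ndarray:
    """Step-up BH by explicit sort / cumulative-min / unsort."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = p[idx] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X ≥ k) by explicit combinatorial summation (math.comb)."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        if n - j > N - K:
            continue
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def logrank_oracle(time, event, groups):
    """Two-group log-rank chi-square by explicit O−E/V accumulation."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    assert len(labels) == 2
    g1 = groups == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return float("nan")
    return o_minus_e**2 / var


def km_oracle(time, event):
    """Product-limit estimate at event times by direct looping."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    surv = 1.0
    out = {}
    for t in sorted(set(time[event == 1])):
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        surv *= 1 - d / n
        out[t] = surv
    return out


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

def make_study(values, genes=None, n_disease=None, study_id="s1"):
    """Build a small ExpressionStudy; first half of columns = disease."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    if n_disease is None:
        n_disease = n_samples // 2
    samples = [f"smp{j}" for j in range(n_samples)]
    labels = pd.Series(
        ["disease"] * n_disease + ["control"] * (n_samples - n_disease),
        index=samples,
    )
    return ExpressionStudy(
        study_id, pd.DataFrame(values, index=genes, columns=samples), labels
    )


@pytest.fixture
def six_sample_study():
    rng = np.random.default_rng(7)
    return make_study(rng.normal(8, 1, size=(4, 6)))


@pytest.fixture(scope="session")
def small_sim():
    """One small synthetic experiment reused across tests (session scope)."""
    from dicoexnet import SimulationConfig, simulate_multistudy_expression

    config = SimulationConfig(
        n_studies=3, samples_per_phenotype=15, n_genes=200,
        n_planted_degs=40, module_size=10, seed=11,
    )
    studies, truth = simulate_multistudy_expression(config)
    return config, studies, truth
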