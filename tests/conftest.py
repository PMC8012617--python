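"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately written in the most literal way possible
(explicit loops, explicit formulas) so they stay independent of the
vectorized implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import optimize

from gcnsurv.datamodel_io import SurvivalTable
import pandas as pd


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_survival(time, event, node=None, sample_ids=None) -> SurvivalTable:
    time = np.asarray(time, float)
    n = len(time)
    df = pd.DataFrame(
        {
            "sample_id": sample_ids if sample_ids is not None else [f"S{i}" for i in range(n)],
            "time": time,
            "event": np.asarray(event, int),
        }
    )
    if node is not None:
        df["node"] = np.asarray(node, float)
    return SurvivalTable(df)


def simulate_ph(rng, n, beta, *, censor_scale=None, node_beta=0.0, node_prev=0.0):
    """Small proportional-hazards draw used across tests.

    Returns (X, survival_table).  ``beta`` is per-column of a standard
    normal design.
    """
    beta = np.atleast_1d(np.asarray(beta, float))
    X = rng.standard_normal((n, len(beta)))
    node = (rng.random(n) < node_prev).astype(float) if node_prev > 0 else np.zeros(n)
    lp = X @ beta + node_beta * node
    T = rng.exponential(1.0, n) / (0.1 * np.exp(lp))
    if censor_scale is not None:
        C = rng.exponential(censor_scale, n)
        t = np.minimum(T, C)
        e = (T <= C).astype(int)
    else:
        t, e = T, np.ones(n, int)
    return X, make_survival(t, e, node=node)


def cox_loglik_bruteforce(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Literal one-covariate Cox partial log-likelihood (no ties)."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] != 1:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def cox_beta_bruteforce(x, time, event, bound=8.0) -> float:
    """Golden-section maximizer of the brute-force partial likelihood."""
    res = optimize.minimize_scalar(
        lambda b: -cox_loglik_bruteforce(b, x, time, event),
        bounds=(-bound, bound),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def auc_pairwise_oracle(scores_pos, scores_neg) -> float:
    """Concordant-pair count / all pairs, ties counted one half."""
    num = 0.0
    for sp in scores_pos:
        for sn in scores_neg:
            if sp > sn:
                num += 1.0
            elif sp == sn:
                num += 0.5
    return num / (len(scores_pos) * len(scores_neg))
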