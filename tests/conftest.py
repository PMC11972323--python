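"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from efda import _dp
from efda.core import TimeSeries, WarpFunction


def two_peak_values(n: int, t1: float = 0.35, t2: float = 0.65,
                    a1: float = 1.0, a2: float = 1.5) -> np.ndarray:
    """A smooth two-peaked test signal (no flick)."""
    t = np.linspace(0.0, 1.0, n)
    return (a1 * np.exp(-((t - t1) / 0.08) ** 2)
            + a2 * np.exp(-((t - t2) / 0.10) ** 2))


def smooth_warp(rng: np.random.Generator, n: int, strength: float = 0.5) -> WarpFunction:
    """Random smooth boundary-fixed monotone warp.

    Built as the normalized cumulative integral of a strictly positive
    log-sinusoid rate, so monotonicity holds by construction.
    """
    t = np.linspace(0.0, 1.0, n)
    b = strength * rng.uniform(0.3, 1.0)
    phase = rng.uniform(0.0, 2 * np.pi)
    k = rng.integers(1, 3)
    rate = np.exp(b * np.sin(2 * np.pi * k * t + phase))
    gamma = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2)])
    gamma /= gamma[-1]
    gamma[0], gamma[-1] = 0.0, 1.0
    return WarpFunction(gamma)


def bruteforce_min_cost(qr: np.ndarray, qm: np.ndarray, lam: float,
                        stride: int) -> float:
    """Exhaustive minimum over all admissible monotone lattice paths.

    Independent search (plain depth-first enumeration, no memoization of
    partial optima) pricing edges with the same quadrature as the DP, so the
    two minima must agree exactly.
    """
    n = qr.size
    aa, bb = _dp.slope_set(stride)
    steps = list(zip(aa.tolist(), bb.tolist()))
    cost = {}
    for i in range(n):
        for j in range(n):
            for a, b in steps:
                if i + a <= n - 1 and j + b <= n - 1:
                    cost[(i, j, a, b)] = _dp.edge_cost(qr, qm, i, j, a, b, lam)
    best = np.inf
    stack = [(0, 0, 0.0)]
    while stack:
        i, j, acc = stack.pop()
        if i == n - 1 and j == n - 1:
            best = min(best, acc)
            continue
        for a, b in steps:
            key = (i, j, a, b)
            if key in cost:
                stack.append((i + a, j + b, acc + cost[key]))
    return best


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def two_peak() -> TimeSeries:
    return TimeSeries(two_peak_values(201))
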