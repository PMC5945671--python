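"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import itertools
import math

import numpy as np


def nnls_bruteforce(W: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, float]:
    """Exhaustive active-set NNLS: try every support set, solve the
    unconstrained least-squares subproblem, keep the best feasible solution."""
    k = W.shape[1]
    best_h = np.zeros(k)
    best_obj = float(np.linalg.norm(v))
    for r in range(1, k + 1):
        for support in itertools.combinations(range(k), r):
            sub = W[:, support]
            h_sub, *_ = np.linalg.lstsq(sub, v, rcond=None)
            if np.any(h_sub < -1e-10):
                continue
            h = np.zeros(k)
            h[list(support)] = np.clip(h_sub, 0.0, None)
            obj = float(np.linalg.norm(v - W @ h))
            if obj < best_obj - 1e-12:
                best_obj = obj
                best_h = h
    return best_h, best_obj


def ranksum_exact_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact Mann-Whitney p-value by full enumeration of group
    assignments (no ties)."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n + m) if i not in combo]
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        total += 1
        if min(u, n * m - u) <= min(u_obs, n * m - u_obs):
            count += 1
    return count / total


def revcomp_context(ref: str, alt: str, c5: str, c3: str) -> tuple[str, str, str, str]:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return comp[ref], comp[alt], comp[c3], comp[c5]
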