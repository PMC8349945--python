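"""Independent brute-force oracles used by the test suite.

Deliberately naive (loops, exhaustive enumeration) and kept free of any
code path they are checking.
"""

from __future__ import annotations

import numpy as np


def auc_by_pair_enumeration(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the mean over all (positive, negative) score pairs of
    1 / 0.5 / 0 for win / tie / loss (higher score = positive)."""
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


def youden_by_grid(values: np.ndarray, labels: np.ndarray, lower_is_positive: bool,
                   eps: float = 1e-9) -> tuple[float, float]:
    """Maximum Youden index by scanning every observed value +/- eps.

    Returns (best J, best sensitivity among J-maximisers). Positive call:
    value < c (lower_is_positive) or value > c otherwise.
    """
    pos = values[labels]
    neg = values[~labels]
    candidates = np.concatenate([values - eps, values + eps,
                                 [values.min() - 1.0, values.max() + 1.0]])
    best_j, best_sens = -np.inf, -np.inf
    for c in candidates:
        if lower_is_positive:
            sens = np.mean(pos < c)
            spec = np.mean(neg >= c)
        else:
            sens = np.mean(pos > c)
            spec = np.mean(neg <= c)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_sens = j, sens
        elif abs(j - best_j) <= 1e-12:
            best_sens = max(best_sens, sens)
    return float(best_j), float(best_sens)


def count_red(values: np.ndarray, mask: np.ndarray) -> int:
    """Exhaustive count of voxels equal to 100 inside a boolean mask."""
    n = 0
    it = np.nditer(mask, flags=["multi_index"])
    for m in it:
        if m and values[it.multi_index] == 100:
            n += 1
    return n


def sphere_voxel_count(shape, center, radius) -> int:
    """Brute-force enumeration of voxels with ||x - c|| <= r."""
    n = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                d2 = ((i - center[0]) ** 2 + (j - center[1]) ** 2
                      + (k - center[2]) ** 2)
                if d2 <= radius * radius:
                    n += 1
    return n


def delong_variance_by_hand(pos: np.ndarray, neg: np.ndarray) -> float:
    """Structural-components variance of a single AUC, written out longhand."""
    m, n = len(pos), len(neg)
    v10 = np.empty(m)
    for i, x in enumerate(pos):
        s = 0.0
        for y in neg:
            s += 1.0 if x > y else (0.5 if x == y else 0.0)
        v10[i] = s / n
    v01 = np.empty(n)
    for j, y in enumerate(neg):
        s = 0.0
        for x in pos:
            s += 1.0 if x > y else (0.5 if x == y else 0.0)
        v01[j] = s / m
    s10 = np.sum((v10 - v10.mean()) ** 2) / (m - 1)
    s01 = np.sum((v01 - v01.mean()) ** 2) / (n - 1)
    return s10 / m + s01 / n
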