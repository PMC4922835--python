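"""Independent brute-force oracles used by the tests.

These are deliberately naive loop-based transcriptions of the defining
formulas (means, distances, centering, normalised inner products), kept
separate from the package's vectorised implementations so that agreement
between the two is informative.
"""

from __future__ import annotations

import math

import numpy as np


def brute_pearson(x, y) -> float:
    x = [float(v) for v in np.ravel(x)]
    y = [float(v) for v in np.ravel(y)]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    den = math.sqrt(
        sum((x[i] - mx) ** 2 for i in range(n)) * sum((y[i] - my) ** 2 for i in range(n))
    )
    return num / den


def brute_distance_matrix(X) -> list[list[float]]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    n, v = X.shape
    return [
        [
            math.sqrt(sum((X[i, k] - X[j, k]) ** 2 for k in range(v)))
            for j in range(n)
        ]
        for i in range(n)
    ]


def brute_center(a, mode: str):
    """Centred matrix and normalisation K, straight from the definitions."""
    n = len(a)
    if mode == "double":
        row = [sum(a[i][j] for j in range(n)) / n for i in range(n)]
        col = [sum(a[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(sum(r) for r in a) / (n * n)
        A = [[a[i][j] - row[i] - col[j] + grand for j in range(n)] for i in range(n)]
        return A, float(n * n)
    if mode == "U":
        A = [[0.0] * n for _ in range(n)]
        total = sum(sum(r) for r in a)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                A[i][j] = (
                    a[i][j]
                    - sum(a[i][l] for l in range(n)) / (n - 2)
                    - sum(a[k][j] for k in range(n)) / (n - 2)
                    + total / ((n - 1) * (n - 2))
                )
        return A, float(n * (n - 3))
    raise ValueError(mode)


def brute_dcov_dvar(A, B, K) -> tuple[float, float, float]:
    n = len(A)
    dcov = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / K
    dvara = sum(A[i][j] ** 2 for i in range(n) for j in range(n)) / K
    dvarb = sum(B[i][j] ** 2 for i in range(n) for j in range(n)) / K
    return dcov, dvara, dvarb


def brute_distance_correlation(X, Y, mode: str) -> float:
    """Full chain: distances -> centering -> dCov/dVar -> truncated ratio."""
    a = brute_distance_matrix(X)
    b = brute_distance_matrix(Y)
    A, K = brute_center(a, mode)
    B, _ = brute_center(b, mode)
    dcov, dvara, dvarb = brute_dcov_dvar(A, B, K)
    if dvara <= 0 or dvarb <= 0:
        return 0.0
    if dcov <= 0:
        return 0.0
    return dcov / math.sqrt(dvara * dvarb)
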