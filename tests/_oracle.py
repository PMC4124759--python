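"""Brute-force reference for the weighted-IPR transform.

Deliberately independent of the package implementation: pairwise
correlations are recomputed from the raw binary columns with the plain
textbook formula, and the group allocation is an explicit double loop
over proteins and features.
"""

import math


def _corr(a, b):
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    if va == 0.0 or vb == 0.0:
        return 0.0
    return cov / math.sqrt(va * vb)


def brute_force_weighted(X):
    """Weighted transform of a 0/1 matrix (list of lists or ndarray)."""
    X = [[float(v) for v in row] for row in X]
    n, m = len(X), len(X[0])
    cols = [[X[i][j] for i in range(n)] for j in range(m)]
    cache = {}

    def corr(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            cache[key] = _corr(cols[key[0]], cols[key[1]])
        return cache[key]

    W = [[0.0] * m for _ in range(n)]
    for p in range(n):
        for value in (0.0, 1.0):
            members = [j for j in range(m) if X[p][j] == value]
            if not members:
                continue
            if len(members) == 1:
                W[p][members[0]] = 0.5
                continue
            weights = {
                i: sum(corr(i, j) for j in members if j != i) for i in members
            }
            total = sum(weights.values())
            for i in members:
                if abs(total) < 1e-12:
                    W[p][i] = 0.5 / len(members)
                else:
                    W[p][i] = 0.5 * weights[i] / total
    return W
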