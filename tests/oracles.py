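"""Independent reference computations used by several test modules."""

import math

import numpy as np


def brute_force_reconstruction(model, i):
    """Nested-loop evaluation of U g(Z1 g(Z2 ... g(ZN HN))), written with
    explicit scalar loops so it shares no code path with the package."""

    def act(x):
        if model.config.activation == "sigmoid":
            return 1.0 / (1.0 + math.exp(-x))
        if model.config.activation == "relu":
            return max(x, 0.0)
        return x

    def matmul(A, B):
        out = np.zeros((len(A), len(B[0])))
        for r in range(len(A)):
            for c in range(len(B[0])):
                out[r, c] = sum(A[r][t] * B[t][c] for t in range(len(B)))
        return out

    h = model.H_deep[i]
    for z in reversed(model.Z[i]):
        pre = matmul(z, h)
        h = np.array([[act(v) for v in row] for row in pre])
    return matmul(model.U, h)


def hypergeom_two_sided(a, b, c, d):
    """Two-sided Fisher p-value by exhaustive hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def pmf(k):
        return (math.comb(c1, k) * math.comb(n - c1, r1 - k)) / math.comb(n, r1)

    p_obs = pmf(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))
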