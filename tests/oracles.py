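"""Independent reference implementations used only to check the package."""

import numpy as np


def chi2_oracle(table):
    """Direct observed/expected chi-squared on a 2x2 table, no correction."""
    from scipy.stats import chi2 as chi2_dist

    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, float(chi2_dist.sf(stat, df=1))


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        q[i] = running_min
    return q


def logistic(t, n0, c, r):
    """Closed-form logistic growth N(t) = N0*C*e^{rt} / (C + N0*(e^{rt}-1))."""
    t = np.asarray(t, float)
    return n0 * c * np.exp(r * t) / (c + n0 * (np.exp(r * t) - 1.0))
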