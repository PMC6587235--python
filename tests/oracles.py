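"""Independent brute-force oracles used only by the test suite.

The ICC oracle computes the two-way ANOVA decomposition by explicit Python
summation loops — no numpy, no shared code with the implementation — and
then applies the single-measure ICC formulas directly.
"""

from __future__ import annotations


def brute_mean_squares(table):
    """(MSB, MSJ, MSE) of a list-of-lists n x k table, by explicit sums."""
    n = len(table)
    k = len(table[0])
    total = 0.0
    for row in table:
        for v in row:
            total += v
    grand = total / (n * k)

    ssb = 0.0
    for row in table:
        m = sum(row) / k
        ssb += (m - grand) ** 2
    ssb *= k

    ssj = 0.0
    for j in range(k):
        m = sum(table[i][j] for i in range(n)) / n
        ssj += (m - grand) ** 2
    ssj *= n

    sst = 0.0
    for row in table:
        for v in row:
            sst += (v - grand) ** 2
    sse = sst - ssb - ssj
    return ssb / (n - 1), ssj / (k - 1), sse / ((n - 1) * (k - 1))


def brute_icc(table, absolute_agreement=True):
    """Single-measure ICC of an n x k table from the brute-force decomposition."""
    n = len(table)
    k = len(table[0])
    msb, msj, mse = brute_mean_squares(table)
    if absolute_agreement:
        return (msb - mse) / (msb + (k - 1) * mse + k * (msj - mse) / n)
    return (msb - mse) / (msb + (k - 1) * mse)


def reject_low_reliability(table, rho0, alpha=0.05):
    """One-sided F-test of H0: ICC <= rho0 (consistency form) — used as the
    simulation power oracle for the sample-size calculation."""
    from scipy.stats import f as f_dist

    n = len(table)
    k = len(table[0])
    msb, _, mse = brute_mean_squares(table)
    crit = f_dist.ppf(1 - alpha, n - 1, (n - 1) * (k - 1))
    return (msb / mse) / (1 + k * rho0 / (1 - rho0)) > crit
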