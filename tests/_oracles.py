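"""Independent high-precision / brute-force oracles used by the test suite.

These never call the package code they check: the Cauchy combination and
Fisher formulas are evaluated with 50-digit mpmath arithmetic, the BH step-up
rule by exhaustive search over ranks, and the TWAS statistic by mpmath matrix
arithmetic.
"""

import mpmath as mp
import numpy as np

mp.mp.dps = 50


def scat_oracle(pvals, weights=None):
    """Eq.-style Cauchy aggregation at 50 significant digits.

    Returns (statistic, combined p) as floats.
    """
    pvals = [mp.mpf(p) for p in pvals]
    if weights is None:
        weights = [mp.mpf(1) / len(pvals)] * len(pvals)
    else:
        weights = [mp.mpf(w) for w in weights]
    half = mp.mpf(1) / 2
    # tan((1/2 - p) pi) == cot(p pi) exactly; the cot form stays accurate at
    # 50 dps even when 0.5 - p rounds to 0.5
    stat = mp.fsum(w * mp.cot(p * mp.pi) for w, p in zip(weights, pvals))
    total = mp.fsum(weights)
    x = stat / total
    # 1/2 - atan(x)/pi, rewritten as atan(1/x)/pi for x > 0 to dodge the
    # cancellation against pi/2 when x is astronomically large
    if x > 0:
        comb = mp.atan(1 / x) / mp.pi
    elif x < 0:
        comb = 1 - mp.atan(-1 / x) / mp.pi
    else:
        comb = half
    return float(stat), float(comb)


def fisher_oracle(pvals):
    """-2 sum log p and its chi-square(2k) tail at high precision."""
    pvals = [mp.mpf(p) for p in pvals]
    stat = -2 * mp.fsum(mp.log(p) for p in pvals)
    k = len(pvals)
    # chi-square(2k) survival = regularised upper incomplete gamma(k, stat/2)
    sf = mp.gammainc(k, stat / 2, mp.inf, regularized=True)
    return float(stat), float(sf)


def twas_oracle(z, w, R):
    """z w' / sqrt(w R w') in mpmath matrix arithmetic."""
    zm = mp.matrix([mp.mpf(v) for v in z])
    wm = mp.matrix([mp.mpf(v) for v in w])
    Rm = mp.matrix([[mp.mpf(v) for v in row] for row in R])
    num = (zm.T * wm)[0]
    var = (wm.T * Rm * wm)[0]
    zt = num / mp.sqrt(var)
    p = mp.erfc(abs(zt) / mp.sqrt(2))
    return float(zt), float(p)


def normal_two_sided_p(z):
    return float(mp.erfc(abs(mp.mpf(z)) / mp.sqrt(2)))


def bh_bruteforce(pvals):
    """BH step-up by direct evaluation of q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i in range(m):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_i, m)]
        q[order[rank_i]] = min(1.0, min(candidates))
    return q
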