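"""Independent reference implementations used as test oracles.

Everything here is written as plain, direct transcriptions of the published
formulas (loops, scipy distribution objects, itertools enumeration), kept
deliberately separate from the package's vectorized implementations.
"""

from itertools import combinations
from math import floor

import numpy as np
from scipy import stats
from scipy.special import betainc


# ------------------------------------------------------------------ TMM

def tmm_reference(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05):
    """Direct-formula TMM factors for a genes x samples array."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    n_samples = counts.shape[1]

    uq = []
    for j in range(n_samples):
        col = counts[:, j]
        uq.append(np.quantile(col[col > 0] / lib[j] * 1e6, 0.75))
    uq = np.array(uq)
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))

    factors = []
    for j in range(n_samples):
        if j == ref_j:
            factors.append(1.0)
            continue
        m_vals, a_vals, w_vals = [], [], []
        for g in range(counts.shape[0]):
            o, r = counts[g, j], counts[g, ref_j]
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref_j]
                m_vals.append(np.log2(po / pr))
                a_vals.append(0.5 * (np.log2(po) + np.log2(pr)))
                w_vals.append(
                    (lib[j] - o) / (lib[j] * o) + (lib[ref_j] - r) / (lib[ref_j] * r)
                )
        m_vals, a_vals, w_vals = map(np.array, (m_vals, a_vals, w_vals))
        if np.max(np.abs(m_vals)) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m_vals)
        lo_m, lo_a = floor(n * trim_m) + 1, floor(n * trim_a) + 1
        hi_m, hi_a = n + 1 - lo_m, n + 1 - lo_a
        rm = stats.rankdata(m_vals)
        ra = stats.rankdata(a_vals)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        f = np.sum(m_vals[keep] / w_vals[keep]) / np.sum(1.0 / w_vals[keep])
        factors.append(2.0**f)
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


# ------------------------------------------------- NB conditional exact test

def nb_exact_enum(sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Exhaustive conditional p-value by direct NB pmf convolution.

    Uses scipy's nbinom pmf at an arbitrary common per-sample mean (it
    cancels after normalization); phi = 0 falls back to the binomial.
    """
    s = sum_a + sum_b
    if s == 0:
        return 1.0
    y = np.arange(s + 1)
    if phi == 0:
        pmf = stats.binom.pmf(y, s, n_a / (n_a + n_b))
    else:
        mean = 7.3  # arbitrary; cancels on normalization
        ra, rb = n_a / phi, n_b / phi
        pa = ra / (ra + n_a * mean)
        pb = rb / (rb + n_b * mean)
        pmf = stats.nbinom.pmf(y, ra, pa) * stats.nbinom.pmf(s - y, rb, pb)
        pmf = pmf / pmf.sum()
    lower = pmf[: sum_a + 1].sum()
    upper = pmf[sum_a:].sum()
    return float(min(1.0, 2 * min(lower, upper)))


# ------------------------------------------------------------------ BH

def bh_reference(pvals):
    """Step-up BH transcribed from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return adj


# ------------------------------------------------------------------ OLS

def ols_reference(x, y):
    """Closed-form simple OLS: slope, intercept, R^2."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xb, yb = x.mean(), y.mean()
    slope = np.sum((x - xb) * (y - yb)) / np.sum((x - xb) ** 2)
    intercept = yb - slope * xb
    sse = np.sum((y - intercept - slope * x) ** 2)
    sst = np.sum((y - yb) ** 2)
    r2 = 1 - sse / sst if sst > 0 else 0.0
    return slope, intercept, r2


def r2_null_tail(r2: float, n_points: int = 5) -> float:
    """Analytic null tail P(R^2 >= r2): R^2 ~ Beta(1/2, (n-2)/2) for simple
    regression on Gaussian noise."""
    return float(1.0 - betainc(0.5, (n_points - 2) / 2.0, r2))


# ------------------------------------------------------------------ GSEA

def es_step_oracle(n: int, hit_ranks):
    """Hand-stepped unweighted running sum in exact rational arithmetic;
    hit_ranks are 0-based. Ties in magnitude prefer the positive extreme."""
    from fractions import Fraction

    hits = set(hit_ranks)
    n_hit, n_miss = len(hits), n - len(hits)
    running, best = Fraction(0), Fraction(0)
    for i in range(n):
        running += Fraction(1, n_hit) if i in hits else -Fraction(1, n_miss)
        if abs(running) > abs(best) or (
            abs(running) == abs(best) and running > best
        ):
            best = running
    return float(best)


def exhaustive_null_p(n: int, hit_ranks) -> float:
    """Permutation p over every same-size subset of the n ranks, with the
    +1 correction, sign-matched to the observed ES."""
    k = len(hit_ranks)
    obs = es_step_oracle(n, hit_ranks)
    null = [es_step_oracle(n, c) for c in combinations(range(n), k)]
    if obs > 0:
        same = [e for e in null if e > 0]
    elif obs < 0:
        same = [e for e in null if e < 0]
    else:
        return 1.0
    hits = sum(1 for e in same if abs(e) >= abs(obs))
    return (1 + hits) / (1 + len(same))
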