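"""Independent brute-force reference implementations used only by tests.

Each oracle is written in a deliberately direct style (explicit loops,
enumeration, closed forms) and shares no code with the package.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import stats


def t_test_oracle(case, ctrl, equal_var=True):
    """Two-sided two-sample t-test from the textbook formulas."""
    case = [float(x) for x in case]
    ctrl = [float(x) for x in ctrl]
    n1, n2 = len(case), len(ctrl)
    m1 = sum(case) / n1
    m2 = sum(ctrl) / n2
    v1 = sum((x - m1) ** 2 for x in case) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in ctrl) / (n2 - 1)
    if equal_var:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        a, b = v1 / n1, v2 / n2
        se = math.sqrt(a + b)
        df = (a + b) ** 2 / (a * a / (n1 - 1) + b * b / (n2 - 1))
    if se == 0:
        return m1 - m2, 1.0 if m1 == m2 else 0.0
    t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return m1 - m2, p


def ranks_oracle(values):
    """Mid-ranks computed by explicit sorting and tie averaging."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def dunn_oracle(group_a, group_b):
    """Tie-corrected Dunn z and two-sided p for two groups."""
    pooled = list(group_a) + list(group_b)
    n = len(pooled)
    ranks = ranks_oracle(pooled)
    tie_sum = 0.0
    for v in set(pooled):
        t = pooled.count(v)
        tie_sum += t**3 - t
    ra = sum(ranks[: len(group_a)]) / len(group_a)
    rb = sum(ranks[len(group_a):]) / len(group_b)
    var = (n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))) * (
        1.0 / len(group_a) + 1.0 / len(group_b))
    if var <= 0:
        return 0.0, 1.0
    z = (ra - rb) / math.sqrt(var)
    return z, 2.0 * stats.norm.sf(abs(z))


def hypergeom_oracle(k, universe, n_set, n_hits):
    """Upper-tail hypergeometric p by summing over the support."""
    total = 0.0
    denom = math.comb(universe, n_hits)
    for x in range(k, min(n_set, n_hits) + 1):
        if n_hits - x > universe - n_set:
            continue
        total += math.comb(n_set, x) * math.comb(universe - n_set, n_hits - x) / denom
    return min(total, 1.0)


def r2_oracle(x, y):
    """R^2 as 1 - SS_res / SS_tot of the least-squares line."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((v - mx) ** 2 for v in x)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    if sxx == 0:
        return float("nan")
    slope = sxy / sxx
    intercept = my - slope * mx
    ss_res = sum((b - (slope * a + intercept)) ** 2 for a, b in zip(x, y))
    ss_tot = sum((b - my) ** 2 for b in y)
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def poisson_midp_oracle(k, lam):
    """P(X < k) + 0.5 P(X = k) by direct summation of Poisson masses."""
    k = int(k)
    total = 0.0
    for x in range(k):
        total += math.exp(-lam) * lam**x / math.factorial(x)
    total += 0.5 * math.exp(-lam) * lam**k / math.factorial(k)
    return total


def nw_identity_oracle(a, b, match=1.0, mismatch=0.0, gap=-1.0):
    """Global-alignment identity by memoised recursion.

    Optimises (score, matches, diagonal steps) lexicographically — the same
    well-defined objective as the implementation, reached by a different
    route (top-down recursion instead of an iterative table).
    """

    @lru_cache(maxsize=None)
    def best(i, j):
        if i == 0 and j == 0:
            return (0.0, 0, 0)
        options = []
        if i > 0 and j > 0:
            s, m, d = best(i - 1, j - 1)
            hit = a[i - 1] == b[j - 1]
            options.append((s + (match if hit else mismatch), m + (1 if hit else 0), d + 1))
        if i > 0:
            s, m, d = best(i - 1, j)
            options.append((s + gap, m, d))
        if j > 0:
            s, m, d = best(i, j - 1)
            options.append((s + gap, m, d))
        return max(options)

    score, matches, diag = best(len(a), len(b))
    return 100.0 * matches / (len(a) + len(b) - diag)


def overlap_oracle(pmp70_labels, pts1_labels):
    """Per-PMP70-punctum overlap fractions by a pixel-by-pixel scan."""
    out = {}
    h, w = pmp70_labels.shape
    for r in range(h):
        for c in range(w):
            lab = int(pmp70_labels[r, c])
            if lab == 0:
                continue
            area, hit = out.get(lab, (0, 0))
            out[lab] = (area + 1, hit + (1 if pts1_labels[r, c] > 0 else 0))
    return {lab: hit / area for lab, (area, hit) in out.items()}


def null_call_rate_analytic(noise_sd, n_case, n_control, alpha=0.05, fc=0.2):
    """Exact null P(p < alpha and |log2fc| > fc) for the pooled t-test.

    Under normal theory the mean difference and the pooled SD are
    independent; integrate the joint rejection region over the pooled-SD
    density (chi distribution with n1+n2-2 dof).
    """
    from scipy.integrate import quad

    df = n_case + n_control - 2
    c_n = math.sqrt(1.0 / n_case + 1.0 / n_control)
    sd_diff = noise_sd * c_n
    t_crit = stats.t.ppf(1 - alpha / 2, df)

    def integrand(u):
        # u: pooled SD; s^2 ~ sigma^2 chi2_df / df
        dens = stats.chi.pdf(u * math.sqrt(df) / noise_sd, df) * math.sqrt(df) / noise_sd
        cut = max(fc, t_crit * u * c_n)
        return dens * 2.0 * stats.norm.sf(cut / sd_diff)

    val, _ = quad(integrand, 0, noise_sd * 10, limit=200)
    return val
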