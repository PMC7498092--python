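"""Independent reference implementations used only as test oracles.

Each function here deliberately takes the slow, explicit route (per-pair
model fits, exhaustive enumeration, loop-based recipes) so it shares no
code path with the package's batched implementations.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats
from scipy.stats import rankdata


def _whiten_all(K: np.ndarray, ridge: float, *arrays):
    Kr = K + ridge * np.mean(np.diag(K)) * np.eye(K.shape[0])
    L = np.linalg.cholesky(Kr)
    return [np.linalg.solve(L, np.asarray(a, float)) for a in arrays]


def gls_linear(y, g, C, K, ridge=1e-8):
    """Per-pair generalized least squares: t-test of the dosage slope in
    y ~ C + g with error covariance K."""
    yw, gw, Cw = _whiten_all(np.asarray(K, float), ridge, y, g, C)
    X = np.column_stack([Cw, gw])
    beta, _, _, _ = np.linalg.lstsq(X, yw, rcond=None)
    resid = yw - X @ beta
    df = len(yw) - X.shape[1]
    s2 = resid @ resid / df
    cov = np.linalg.inv(X.T @ X)
    se = math.sqrt(s2 * cov[-1, -1])
    t = beta[-1] / se
    return t, df, beta[-1], 2 * stats.t.sf(abs(t), df)


def gls_anova(y, g, C, K, ridge=1e-8):
    """Per-pair nested-model F-test of genotype-class indicators."""
    classes = np.unique(g)
    D = np.column_stack([(np.asarray(g) == c).astype(float)
                         for c in classes[1:]])
    yw, Cw, Dw = _whiten_all(np.asarray(K, float), ridge, y, C, D)

    def rss(X):
        beta, _, _, _ = np.linalg.lstsq(X, yw, rcond=None)
        r = yw - X @ beta
        return r @ r

    rss0 = rss(Cw)
    X1 = np.column_stack([Cw, Dw])
    rss1 = rss(X1)
    df_num = len(classes) - 1
    df_den = len(yw) - C.shape[1] - df_num
    F = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    return F, df_num, df_den, stats.f.sf(F, df_num, df_den)


def tmm_factors_naive(counts, logratio_trim=0.30, sum_trim=0.05):
    """Loop-based trimmed-mean-of-M-values factors following the published
    recipe step by step."""
    y = np.asarray(counts, float)
    n_samp = y.shape[1]
    lib = [sum(y[:, j]) for j in range(n_samp)]
    uq = [np.percentile(y[:, j], 75) / lib[j] for j in range(n_samp)]
    mean_uq = sum(uq) / n_samp
    ref = min(range(n_samp), key=lambda j: abs(uq[j] - mean_uq))

    factors = []
    for j in range(n_samp):
        if j == ref:
            factors.append(1.0)
            continue
        m_vals, a_vals, w_vals = [], [], []
        for i in range(y.shape[0]):
            o, r = y[i, j], y[i, ref]
            if o > 0 and r > 0:
                m = math.log2((o / lib[j]) / (r / lib[ref]))
                a = 0.5 * math.log2((o / lib[j]) * (r / lib[ref]))
                w = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
                if math.isfinite(m) and math.isfinite(a):
                    m_vals.append(m)
                    a_vals.append(a)
                    w_vals.append(w)
        if max(abs(m) for m in m_vals) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m_vals)
        lo_m = math.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * sum_trim) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(m_vals)
        ra = rankdata(a_vals)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += m_vals[i] / w_vals[i]
                den += 1.0 / w_vals[i]
        factors.append(2.0 ** (num / den) if den > 0 else 1.0)
    gm = math.exp(sum(math.log(f) for f in factors) / n_samp)
    return np.array([f / gm for f in factors])


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by exhaustive enumeration of all 2x2 tables
    with the observed margins (point-probability method)."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


def gene_drop_relationship(ped_rows, pair, n_drops, seed):
    """Monte-Carlo additive relationship: drop two distinct founder alleles
    per founder through the pedigree; relationship a(i,j) = 2 * P(random
    allele of i identical by descent to random allele of j)."""
    rng = np.random.default_rng(seed)
    parents = {a: (s, d) for a, s, d in ped_rows}
    order = []
    seen = set()

    def visit(a):
        if a in seen or a == "0" or a not in parents:
            return
        s, d = parents[a]
        visit(s)
        visit(d)
        seen.add(a)
        order.append(a)

    for a in parents:
        visit(a)

    i, j = pair
    ibd = 0.0
    for _ in range(n_drops):
        alleles = {}
        counter = 0
        for a in order:
            s, d = parents[a]
            pat = (alleles[s][rng.integers(2)] if s != "0" and s in alleles
                   else (counter := counter + 1))
            mat = (alleles[d][rng.integers(2)] if d != "0" and d in alleles
                   else (counter := counter + 1))
            alleles[a] = (pat, mat)
        ai, aj = alleles[i], alleles[j]
        ibd += sum(ai[x] == aj[y] for x in range(2) for y in range(2)) / 4.0
    return 2.0 * ibd / n_drops


def pearson_r2(a, b) -> float:
    """Brute-force squared Pearson correlation."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am @ bm) ** 2 / ((am @ am) * (bm @ bm)))


def bh_stepup_naive(p):
    """Step-up BH by the textbook formula."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q
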