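"""Independent brute-force oracles used by the test suite.

These are deliberately naive loop-level transcriptions of the underlying
definitions, kept separate from the library code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bh_bruteforce(p):
    """BH step-up by direct definition: adj_i = min_{j: p_j >= p_i over the
    sorted order} of p_(j) m / j, with cumulative minimum from the top."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj_sorted = [None] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, p[i] * m / (pos + 1))
        adj_sorted[pos] = running
    out = [None] * m
    for pos, i in enumerate(order):
        out[i] = adj_sorted[pos]
    return out


def auc_pair_counting(scores, labels):
    """AUC by explicit concordant-pair counting with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def fisher_closed_form_2(p1, p2):
    """Fisher combination of two p-values via the closed-form chi-square
    survival with 4 df: P = e^{-x/2} (1 + x/2)."""
    x = -2.0 * (math.log(p1) + math.log(p2))
    return math.exp(-x / 2.0) * (1.0 + x / 2.0)


def tmm_factor_bruteforce(obs, ref, n_obs, n_ref, trim_m=0.30, trim_a=0.05):
    """Doubly trimmed precision-weighted mean of M-values, naive loops."""
    pairs = [
        (o, r) for o, r in zip(obs, ref) if o > 0 and r > 0
    ]
    if not pairs:
        return 1.0
    ms, as_, ws = [], [], []
    for o, r in pairs:
        po, pr = o / n_obs, r / n_ref
        ms.append(math.log2(po / pr))
        as_.append(0.5 * math.log2(po * pr))
        ws.append(1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)))
    n = len(ms)
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a

    def first_ranks(values):
        order = sorted(range(n), key=lambda i: (values[i], i))
        ranks = [0] * n
        for rank, i in enumerate(order, start=1):
            ranks[i] = rank
        return ranks

    rm = first_ranks(ms)
    ra = first_ranks(as_)
    num = den = 0.0
    for i in range(n):
        if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
            num += ws[i] * ms[i]
            den += ws[i]
    if den == 0:
        return 1.0
    return 2.0 ** (num / den)


def normfinder_bruteforce(data, group_of):
    """Stability values by direct loop transcription of the variance
    decomposition: sample-centering, per-group gene means and residual
    variances with the two-way bias correction, empirical-Bayes shrinkage
    of intergroup deviations, stability = mean over groups of
    |shrunken deviation| + sqrt(sampling + posterior variance).

    ``data``: dict gene -> dict sample -> log expression.
    ``group_of``: dict sample -> group label.
    Returns dict gene -> stability.
    """
    genes = sorted(data)
    samples = sorted(next(iter(data.values())))
    groups = sorted(set(group_of.values()))
    I = len(genes)
    # center each sample by its mean over genes
    centered = {}
    for s in samples:
        mean_s = sum(data[g][s] for g in genes) / I
        for g in genes:
            centered[(g, s)] = data[g][s] - mean_s
    sizes = {gr: sum(1 for s in samples if group_of[s] == gr) for gr in groups}
    ntot = sum(sizes.values())
    z = {}
    s2 = {}
    for g in genes:
        for gr in groups:
            vals = [centered[(g, s)] for s in samples if group_of[s] == gr]
            mean_v = sum(vals) / len(vals)
            z[(g, gr)] = mean_v
            s2[(g, gr)] = sum((v - mean_v) ** 2 for v in vals) / (len(vals) - 1)
    sigma2 = {}
    for gr in groups:
        sbar = sum(s2[(g, gr)] for g in genes) / I / (1.0 - 1.0 / I)
        for g in genes:
            sigma2[(g, gr)] = max(
                (s2[(g, gr)] - sbar / I) / (1.0 - 2.0 / I), 0.0
            )
    d = {}
    for g in genes:
        wmean = sum(z[(g, gr)] * sizes[gr] for gr in groups) / ntot
        for gr in groups:
            d[(g, gr)] = z[(g, gr)] - wmean
    k = len(groups)
    v = {key: sigma2[key] / sizes[key[1]] for key in sigma2}
    gamma2 = max(
        sum(val**2 for val in d.values()) / ((I - 1) * (k - 1))
        - sum(v.values()) / len(v),
        0.0,
    )
    stab = {}
    for g in genes:
        parts = []
        for gr in groups:
            vg = v[(g, gr)]
            if gamma2 + vg > 0:
                dt = d[(g, gr)] * gamma2 / (gamma2 + vg)
                post = gamma2 * vg / (gamma2 + vg)
            else:
                dt, post = 0.0, 0.0
            parts.append(abs(dt) + math.sqrt(vg + post))
        stab[g] = sum(parts) / k
    return stab


def hypergeom_tail_enumeration(universe_n, pathway_n, selected_n, overlap):
    """P(X >= overlap) by enumerating all selections of ``selected_n`` genes
    out of ``universe_n`` (combinatorial counting, exact)."""
    total = math.comb(universe_n, selected_n)
    count = 0
    for k in range(overlap, min(pathway_n, selected_n) + 1):
        count += math.comb(pathway_n, k) * math.comb(
            universe_n - pathway_n, selected_n - k
        )
    return count / total


def ks_two_sided_enumeration(m_ranks, n_total):
    """Exact two-sided two-sample K-S p for a rank subset: enumerate all
    equally likely rank assignments and count those with D >= observed."""
    m = len(m_ranks)

    def d_stat(sub):
        sub = sorted(sub)
        rest = sorted(set(range(1, n_total + 1)) - set(sub))
        values = sorted(set(range(1, n_total + 1)))
        dmax = 0.0
        for x in values:
            f1 = sum(1 for v in sub if v <= x) / len(sub)
            f2 = sum(1 for v in rest if v <= x) / len(rest)
            dmax = max(dmax, abs(f1 - f2))
        return dmax

    obs = d_stat(m_ranks)
    count = total = 0
    for combo in itertools.combinations(range(1, n_total + 1), m):
        total += 1
        if d_stat(combo) >= obs - 1e-12:
            count += 1
    return count / total
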