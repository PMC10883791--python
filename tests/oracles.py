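"""Independent brute-force oracles used by the test suite.

Everything here is written as plain scalar loops, directly from the defining
formulas, so the vectorized package implementations are checked against an
independent computation path.
"""

from __future__ import annotations

import math

import numpy as np


def wc_theta(dosage_by_pop: list[list[list[int]]]) -> float:
    """Multilocus Weir-Cockerham theta by scalar evaluation of the
    variance components, averaged as a ratio of sums over loci.

    ``dosage_by_pop[p][l]`` is the list of called dosages of population p
    at locus l (missing genotypes simply absent).
    """
    n_loci = len(dosage_by_pop[0])
    sum_a = sum_abc = 0.0
    for l in range(n_loci):
        pops = [pop[l] for pop in dosage_by_pop if len(pop[l]) > 0]
        r = len(pops)
        if r < 2:
            continue
        n_i = [len(g) for g in pops]
        p_i = [sum(g) / (2 * n) for g, n in zip(pops, n_i)]
        h_i = [sum(1 for x in g if x == 1) / n for g, n in zip(pops, n_i)]
        n_tot = sum(n_i)
        nbar = n_tot / r
        if nbar <= 1:
            continue
        nc = (n_tot - sum(n * n for n in n_i) / n_tot) / (r - 1)
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / n_tot
        if pbar <= 0 or pbar >= 1:
            continue
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / n_tot
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc


def yang_ajk(x: list[int], y: list[int], p: list[float]) -> float:
    """Yang et al. relatedness of two samples: direct formula over loci with
    both genotypes called and 0 < p < 1."""
    num, cnt = 0.0, 0
    for xi, yi, pi in zip(x, y, p):
        if xi < 0 or yi < 0 or pi <= 0 or pi >= 1:
            continue
        num += (xi - 2 * pi) * (yi - 2 * pi) / (2 * pi * (1 - pi))
        cnt += 1
    return num / cnt


def hdplot_hd(dosages: list[int], ad: list[tuple[int, int]]) -> tuple[float, float]:
    """HDplot (H, D) for one locus: heterozygote fraction of called samples
    and (sum ref - sum alt)/sqrt(total) over heterozygous calls."""
    called = [d for d in dosages if d >= 0]
    h = sum(1 for d in called if d == 1) / len(called) if called else 0.0
    ref = alt = 0
    for d, (r, a) in zip(dosages, ad):
        if d == 1:
            ref += r
            alt += a
    tot = ref + alt
    d_stat = (ref - alt) / math.sqrt(tot) if tot > 0 else 0.0
    return h, d_stat


def chi2_homogeneity(table: list[list[float]]) -> float:
    """Pearson chi-squared: sum (O - E)^2 / E with E from the margins."""
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    total = sum(rows)
    stat = 0.0
    for i, r in enumerate(table):
        for j, o in enumerate(r):
            e = rows[i] * cols[j] / total
            stat += (o - e) ** 2 / e
    return stat


def amova_ss(x: np.ndarray, labels: list) -> float:
    """Within-group sum of squares via the pairwise-distance identity:
    SS(group g) = (1/n_g) * sum_{i<j in g} d2(i, j)."""
    ss = 0.0
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        acc = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += float(((x[idx[a]] - x[idx[b]]) ** 2).sum())
        ss += acc / len(idx)
    return ss


def greedy_panel(afd: dict[str, list[float]], target: int
                 ) -> tuple[dict[str, list[int]], dict[str, float], list[int]]:
    """Hand trace of the balanced-panel greedy loop on a small AFD table.

    ``afd[pair][locus]`` are AFD values; returns (per-pair lists, per-pair
    sums of AFD^2, union in insertion order).
    """
    order = {p: sorted(range(len(v)), key=lambda i: (-v[i], i))
             for p, v in afd.items()}
    lists = {p: [] for p in afd}
    sums = {p: 0.0 for p in afd}
    ptr = {p: 0 for p in afd}
    union: list[int] = []
    while len(union) < target:
        active = [p for p in afd if ptr[p] < len(afd[p])]
        if not active:
            break
        pick = min(active, key=lambda p: (sums[p], p))
        locus = order[pick][ptr[pick]]
        ptr[pick] += 1
        lists[pick].append(locus)
        sums[pick] += afd[pick][locus] ** 2
        if locus not in union:
            union.append(locus)
    return lists, sums, union


def qvalues_step(p: list[float], pi0: float = 1.0) -> list[float]:
    """q_i = min over t >= p_i of pi0 * m * t / #{p <= t}, t over observed p."""
    m = len(p)
    out = []
    for pi in p:
        cands = [pi0 * m * t / sum(1 for x in p if x <= t)
                 for t in p if t >= pi]
        out.append(min(min(cands), 1.0))
    return out


def nei_gst_pool(p_pool: list[float], p_pop: list[float]) -> float:
    """Multilocus Nei G_ST between two demes (ratio of sums)."""
    num = den = 0.0
    for pa, pb in zip(p_pool, p_pop):
        pbar = (pa + pb) / 2
        ht = 2 * pbar * (1 - pbar)
        hs = pa * (1 - pa) + pb * (1 - pb)
        num += ht - hs
        den += ht
    return num / den
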