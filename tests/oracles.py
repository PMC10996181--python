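"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (explicit loops, closed forms,
enumeration) and shares no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


def brute_pcc(x, y) -> float:
    """Pearson correlation via the textbook two-pass formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def brute_pcc_matrix(values: np.ndarray) -> np.ndarray:
    g = values.shape[0]
    out = np.empty((g, g))
    for i in range(g):
        for j in range(g):
            out[i, j] = 1.0 if i == j else brute_pcc(values[i], values[j])
    return out


def concordance_auc(scores, labels) -> float:
    """Mann-Whitney AUC: fraction of concordant positive x negative pairs,
    ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] by exhaustive summation of the hypergeometric pmf."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def triple_loop_project(ref_edges, ortholog_pairs) -> set[tuple[str, str]]:
    """Interolog transfer by explicit triple iteration over edges and pairs."""
    projected = set()
    for a1, a2 in ref_edges:
        for s1, t1 in ortholog_pairs:
            if s1 != a1:
                continue
            for s2, t2 in ortholog_pairs:
                if s2 != a2 or t1 == t2:
                    continue
                projected.add((min(t1, t2), max(t1, t2)))
    return projected


def student_t_pvalue(a, b) -> float:
    """Two-sided equal-variance t-test from the textbook formula plus the
    t distribution function."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    se = math.sqrt(sp2 * (1 / na + 1 / nb))
    if se == 0:
        return 1.0 if ma == mb else 0.0
    tstat = (ma - mb) / se
    return 2.0 * tdist.sf(abs(tstat), df)
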