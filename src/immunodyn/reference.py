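"""Brute-force reference implementations used for validation.

These deliberately share no code with the production paths: the Fisher
reference enumerates the hypergeometric outcome space with exact integer
arithmetic, and the ssGSEA reference walks the ranked gene list with an
explicit running sum.  They are slow and exist so the fast implementations
can be checked against an independent derivation.
"""

from __future__ import annotations

from math import comb

import numpy as np


def fisher_two_sided_exact(count_a: int, total_a: int,
                           count_b: int, total_b: int) -> float:
    """Two-sided Fisher exact p by full enumeration with integer weights.

    Conditional on the margins, P(k) ∝ C(total_a, k)·C(total_b, s−k) with
    s = count_a + count_b; the two-sided p sums outcomes whose probability
    does not exceed the observed one (with the conventional 1e-7 relative
    tie tolerance, applied here in exact arithmetic).
    """
    s = count_a + count_b
    kmin = max(0, s - total_b)
    kmax = min(s, total_a)
    weights = {k: comb(total_a, k) * comb(total_b, s - k)
               for k in range(kmin, kmax + 1)}
    w_obs = weights[count_a]
    # w <= w_obs * (1 + 1e-7), kept in integers: 1e7 * w <= (1e7 + 1) * w_obs
    sel = sum(w for w in weights.values() if 10_000_000 * w <= 10_000_001 * w_obs)
    return sel / sum(weights.values())


def ssgsea_naive(expression: np.ndarray, in_set: np.ndarray,
                 alpha: float = 0.25) -> float:
    """Single-sample enrichment score by an explicit running-sum walk.

    ``expression`` is one sample's values over all genes; ``in_set`` flags
    signature membership.  Genes are ranked ascending (average rank for
    ties) so the highest expression carries the largest rank, the list is
    walked from the top, and at every position the difference between the
    rank**alpha-weighted in-set ECDF and the uniform out-of-set ECDF is
    accumulated.
    """
    n = len(expression)
    # average ranks, computed by hand
    order = sorted(range(n), key=lambda i: expression[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and expression[order[j + 1]] == expression[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1

    descending = sorted(range(n), key=lambda i: (-ranks[i], i))
    total_in_weight = sum(abs(ranks[i]) ** alpha for i in range(n) if in_set[i])
    n_out = sum(1 for i in range(n) if not in_set[i])
    running_in = 0.0
    running_out = 0
    es = 0.0
    for g in descending:
        if in_set[g]:
            running_in += abs(ranks[g]) ** alpha
        else:
            running_out += 1
        es += running_in / total_in_weight - running_out / n_out
    return es
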