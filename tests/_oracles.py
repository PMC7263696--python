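"""Independent oracles used only by the test suite.

These deliberately avoid the code paths they check: the MSS maximum-
likelihood estimator below consumes :func:`recscreen.ld.ld_pmf` (the
recursion being validated separately against hand-derived values) but is
otherwise an independent route to the event number ``m``, and the
hypergeometric enumeration oracle counts subsets directly.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
from scipy import optimize

from recscreen.ld import ld_pmf


def mss_mle(counts: Sequence[int], m_lo: float = 1e-3, m_hi: float = 1e3,
            cap: int = 400) -> float:
    """Maximum-likelihood ``m`` under the MSS pmf, censored at ``cap``.

    Counts above ``cap`` (jackpots) enter the likelihood through the tail
    probability P(R > cap), keeping the pmf recursion O(cap^2).  Optimized
    over log m with bounded scalar minimization (golden-section/Brent).
    """
    counts = np.asarray(counts, dtype=np.int64)
    capped = np.minimum(counts, cap)
    is_censored = counts > cap

    def nll(log_m: float) -> float:
        m = math.exp(log_m)
        pmf = ld_pmf(m, cap)
        pmf = np.clip(pmf, 1e-300, None)
        tail = max(1.0 - float(pmf.sum()), 1e-300)
        ll = np.where(is_censored, math.log(tail), np.log(pmf[capped]))
        return -float(ll.sum())

    res = optimize.minimize_scalar(
        nll, bounds=(math.log(m_lo), math.log(m_hi)), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(math.exp(res.x))


def hypergeom_tail_enumerate(k: int, N: int, K: int, n: int) -> float:
    """P(|draw & marked| >= k) by exhaustive enumeration of all C(N, n) draws."""
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total
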