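"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library's own code paths: likelihoods are
enumerated over all internal-state assignments, ORFs come from Biopython
six-frame translation, BH comes straight from its min-over-suffix definition,
and Fisher's test from full hypergeometric enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Seq import Seq


def mk2_matrix(q: float, t: float) -> np.ndarray:
    stay = 0.5 + 0.5 * math.exp(-2.0 * q * t)
    return np.array([[stay, 1 - stay], [1 - stay, stay]])


def enumerate_likelihood_and_marginals(tree, states: dict[str, str], q: float):
    """Total likelihood and per-internal-node P(silk) by exhaustive enumeration."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_tip()]
    total = 0.0
    marg = {id(n): 0.0 for n in internals}
    for assign in itertools.product((0, 1), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        p = 0.5  # flat root prior on the root's assigned state
        for n in nodes:
            if n.parent is None:
                continue
            sp = amap[id(n.parent)]
            sc = (1 if states[n.name] == "silk" else 0) if n.is_tip() else amap[id(n)]
            p *= mk2_matrix(q, n.length or 0.0)[sp, sc]
        total += p
        for n in internals:
            if amap[id(n)] == 1:
                marg[id(n)] += p
    posts = {k: (v / total if total > 0 else 0.5) for k, v in marg.items()}
    return total, posts


def six_frame_orfs(seq: str, min_aa: int):
    """All stop-free codon runs >= min_aa via Biopython translation.

    Returns a set of (frame, protein) pairs.
    """
    out = set()
    rc = str(Seq(seq).reverse_complement())
    for strand, s in ((1, seq), (-1, rc)):
        for offset in range(3):
            sub = s[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            protein = str(Seq(sub).translate())
            for run in protein.split("*"):
                if len(run) >= min_aa:
                    out.add((strand * (offset + 1), run))
    return out


def bh_min_over_suffix(pvalues):
    """BH adjusted values straight from the definition q_i = min_{j>=i} p_(j)*n/j."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher p by summing all same-margin tables with pmf <= observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_pmf(x):
        return (
            _lchoose(r1, x) + _lchoose(r2, c1 - x) - _lchoose(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    obs = log_pmf(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_pmf(x)
        if lp <= obs + 1e-12:
            total += math.exp(lp)
    return min(total, 1.0)


def _lchoose(n, k):
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
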