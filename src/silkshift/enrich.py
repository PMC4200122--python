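"""Annotation, taxonomy screening, and category enrichment for SST sets.

Enrichment follows the biased-urn approach used for length-biased RNA-seq
category tests: each transcript's probability of being called silk-specific
may depend on its length, so a monotone probability weighting function (PWF)
is fitted to the call-vs-length relationship, and each Gene Ontology term is
tested with the Wallenius noncentral hypergeometric distribution whose odds
parameter is the mean PWF weight inside the category over the mean weight
outside.  With odds 1 the test reduces exactly to the central hypergeometric.

The Wallenius distribution is computed by an exact, vectorized recursion over
draws: if ``x`` of the first ``d`` draws were category members, the next draw
is a member with probability ``odds*(K-x) / (odds*(K-x) + (N-K-(d-x)))``.
Probabilities stay on the simplex at every step, so no underflow guard is
needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

WEIGHT_FLOOR = 1e-6


@dataclass(frozen=True)
class HomologyHit:
    """One tabular homology hit (BLAST outfmt-6 style) for a query transcript."""

    query: str
    subject: str
    evalue: float
    bitscore: float
    qstart: int = 0  # 0-based half-open on the query
    qend: int = 0
    taxon: str | None = None
    database: str | None = None


def best_hit(hits: list[HomologyHit], e_cutoff: float = 1e-5) -> HomologyHit | None:
    """Best hit of one query: lowest E-value, ties by highest bitscore, then input order."""
    queries = {h.query for h in hits}
    if len(queries) > 1:
        raise ValueError(f"best_hit expects hits of a single query, got {sorted(queries)}")
    passing = [(h.evalue, -h.bitscore, i) for i, h in enumerate(hits) if h.evalue <= e_cutoff]
    if not passing:
        return None
    _, _, idx = min(passing)
    return hits[idx]


def taxonomic_profile(
    taxa: dict[str, str | None], ecpm: pd.DataFrame
) -> pd.DataFrame:
    """Per-taxon transcript counts and expression shares (contamination screen).

    ``taxa`` maps transcript id to the taxon label of its best database hit
    (None or missing = unannotated).  Expression share is the fraction of the
    summed eCPM (over all libraries) attributed to each taxon; unannotated
    transcripts form their own bucket.
    """
    total_expr = ecpm.sum(axis=1)
    labels = pd.Series(
        {t: (taxa.get(t) or "unannotated") for t in ecpm.index}, name="taxon"
    )
    df = pd.DataFrame({"taxon": labels, "expression": total_expr})
    out = df.groupby("taxon").agg(n_transcripts=("taxon", "size"), expression=("expression", "sum"))
    grand = out["expression"].sum()
    out["expression_share"] = out["expression"] / grand if grand > 0 else 0.0
    out["count_share"] = out["n_transcripts"] / out["n_transcripts"].sum()
    return out.sort_values("n_transcripts", ascending=False)


@dataclass
class ProbabilityWeightFunction:
    """Monotone fit of P(transcript is in the selected set) against length."""

    iso: IsotonicRegression | None
    constant: float | None = None

    def __call__(self, lengths) -> np.ndarray:
        lengths = np.asarray(lengths, dtype=float)
        if self.iso is None:
            w = np.full(lengths.shape, self.constant)
        else:
            w = self.iso.predict(lengths)
        return np.clip(w, WEIGHT_FLOOR, 1.0 - WEIGHT_FLOOR)


def estimate_pwf(lengths, flags, n_bins: int = 20) -> ProbabilityWeightFunction:
    """Fit a monotone probability weighting function by binned isotonic regression.

    Lengths are cut into ``n_bins`` equal-occupancy bins; the per-bin fraction
    of flagged transcripts is regressed monotonically on the bin mean length
    (pool-adjacent-violators), with the direction chosen by the sign of the
    Spearman rank correlation between length and flag.  All-identical flags
    yield a uniform weight with a warning.
    """
    lengths = np.asarray(lengths, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if lengths.shape != flags.shape:
        raise ValueError("lengths and flags must have the same shape")
    rate = float(flags.mean())
    if len(np.unique(lengths)) < 2:
        # no length signal to fit: constant weight, so the Wallenius odds
        # reduce exactly to 1
        warnings.warn("all lengths identical; using uniform weights")
        return ProbabilityWeightFunction(iso=None, constant=rate)
    if rate in (0.0, 1.0):
        warnings.warn("all selection flags identical; using uniform weights")
        return ProbabilityWeightFunction(iso=None, constant=rate)

    order = np.argsort(lengths, kind="stable")
    bins = np.array_split(order, min(n_bins, len(lengths)))
    bin_x = np.array([lengths[b].mean() for b in bins if len(b)])
    bin_y = np.array([flags[b].mean() for b in bins if len(b)])
    bin_w = np.array([len(b) for b in bins if len(b)], dtype=float)

    rho = stats.spearmanr(lengths, flags).statistic
    increasing = bool(rho >= 0) if np.isfinite(rho) else True
    iso = IsotonicRegression(increasing=increasing, out_of_bounds="clip")
    iso.fit(bin_x, bin_y, sample_weight=bin_w)
    return ProbabilityWeightFunction(iso=iso)


def wallenius_pmf(K: int, n: int, N: int, odds: float) -> np.ndarray:
    """Exact pmf of the Wallenius noncentral hypergeometric distribution.

    Returns P(X = x) for x = 0..min(K, n) when ``n`` items are drawn one at a
    time without replacement from ``N`` items of which ``K`` are category
    members weighted by ``odds`` relative to the rest.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if odds <= 0:
        raise ValueError("odds must be positive")
    x_max = min(K, n)
    f = np.zeros(x_max + 1)
    f[0] = 1.0
    for d in range(n):
        x = np.arange(x_max + 1)
        rem_in = np.maximum(K - x, 0).astype(float)
        rem_out = np.maximum((N - K) - (d - x), 0).astype(float)
        denom = odds * rem_in + rem_out
        with np.errstate(invalid="ignore", divide="ignore"):
            p_in = np.where(denom > 0, odds * rem_in / np.where(denom > 0, denom, 1.0), 0.0)
        g = np.zeros_like(f)
        g += f * (1.0 - p_in)  # next draw outside the category
        g[1:] += (f * p_in)[:-1]  # next draw inside
        f = g
    return f


def wallenius_test(
    k: int, K: int, n: int, N: int, odds: float = 1.0
) -> tuple[float, float]:
    """Tail probabilities (p_enriched, p_depleted) of the biased-urn category test.

    ``k`` category members among ``n`` selected out of ``N`` with ``K`` in the
    category; ``p_enriched`` = P(X >= k), ``p_depleted`` = P(X <= k).  With
    ``odds == 1`` this is the central hypergeometric test.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError("infeasible counts: need 0 <= k <= min(K, n)")
    if k < n - (N - K):
        raise ValueError("infeasible counts: too few non-category items")
    pmf = wallenius_pmf(K, n, N, odds)
    p_enr = float(pmf[k:].sum())
    p_dep = float(pmf[: k + 1].sum())
    return min(p_enr, 1.0), min(p_dep, 1.0)


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table ((a, b), (c, d))."""
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    term: str
    in_group: int
    group_size: int
    background: int
    background_size: int
    direction: str  # "enriched" or "depleted"
    p: float
    q: float = field(default=np.nan)
    significant: bool = False


def enrichment_report(
    sst_ids,
    term_sets: dict[str, set[str]],
    universe,
    lengths: dict[str, float] | None = None,
    alpha: float = 0.05,
    use_pwf: bool = True,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Per-term enrichment/depletion of the SST set against the annotated universe.

    ``term_sets`` maps transcript id to its set of category terms; the
    universe should be the annotated, floor-passing transcripts.  With
    ``use_pwf`` a length-based PWF sets the Wallenius odds per term (category
    mean weight / non-category mean weight); otherwise odds = 1 (central
    hypergeometric).  Both directions are BH-corrected separately across
    terms; rows with q < alpha are flagged.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty enrichment universe")
    uni_set = set(universe)
    sst_in = [t for t in sst_ids if t in uni_set]
    n, N = len(sst_in), len(universe)
    sst_set = set(sst_in)

    if use_pwf:
        if lengths is None:
            raise ValueError("use_pwf requires transcript lengths")
        lens = np.array([lengths[t] for t in universe], dtype=float)
        flags = np.array([t in sst_set for t in universe])
        pwf = estimate_pwf(lens, flags, n_bins=n_bins)
        weights = pwf(lens)
    else:
        weights = np.ones(N)

    term_members: dict[str, list[int]] = {}
    for i, t in enumerate(universe):
        for term in term_sets.get(t, ()):
            term_members.setdefault(term, []).append(i)

    rows = []
    for term, members in sorted(term_members.items()):
        K = len(members)
        k = sum(1 for i in members if universe[i] in sst_set)
        if use_pwf and 0 < K < N:
            in_mask = np.zeros(N, dtype=bool)
            in_mask[members] = True
            odds = float(weights[in_mask].mean() / weights[~in_mask].mean())
        else:
            odds = 1.0
        p_enr, p_dep = wallenius_test(k, K, n, N, odds=odds)
        rows.append((term, k, n, K, N, "enriched", p_enr))
        rows.append((term, k, n, K, N, "depleted", p_dep))

    df = pd.DataFrame(
        rows,
        columns=["term", "in_group", "group_size", "background", "background_size",
                 "direction", "p"],
    )
    df["q"] = np.nan
    for direction in ("enriched", "depleted"):
        mask = df["direction"] == direction
        if mask.any():
            df.loc[mask, "q"] = bh_fdr(df.loc[mask, "p"])
    df["significant"] = df["q"] < alpha
    return df


def slim_rollup(term_sets: dict[str, set[str]], slim_map: dict[str, str]) -> dict[str, set[str]]:
    """Map full GO term sets to GO-SLIM term sets via a user-supplied table."""
    return {
        t: {slim_map[term] for term in terms if term in slim_map}
        for t, terms in term_sets.items()
    }
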