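"""Ancestral-state reconstruction of silk-gland-specific expression on gene-family trees.

The central question this module answers: within a gene family whose tips are
labelled silk-specific or not, how many times was silk-specific expression
gained (a non-silk parent with a silk child), and is that number smaller than
expected if the same tip labels were scattered over random trees?

The character model is the 2-state equal-rates Markov model (Mk2/ER): a single
rate ``q`` governs both gain and loss, the transition probability over a branch
of length ``t`` is ``P(stay) = 1/2 + exp(-2qt)/2``, and the root prior is flat
(1/2, 1/2).  Internal nodes are labelled from their marginal posterior with
ties resolved to non-silk, so a family must carry positive evidence before a
gain is counted.
"""

from __future__ import annotations

import io as _io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

NON_SILK = "non-silk"
SILK = "silk"
STATES = (NON_SILK, SILK)

#: below this margin around 1/2 a marginal posterior counts as a tie
TIE_TOL = 1e-9

RATE_LOWER = 1e-8
RATE_UPPER = 1e3


def transition_matrix(q: float, t: float) -> np.ndarray:
    """2x2 transition matrix of the equal-rates binary Markov chain.

    Row/column order is (non-silk, silk).  Rows sum to one; the off-diagonal
    entry is bounded by 1/2 (the stationary probability of the other state).
    """
    if q < 0 or t < 0:
        raise ValueError("rate and branch length must be non-negative")
    stay = 0.5 + 0.5 * math.exp(-2.0 * q * t)
    change = 1.0 - stay
    return np.array([[stay, change], [change, stay]])


def _branch_length(node: TreeNode) -> float:
    bl = node.length
    if bl is None:
        return 0.0
    return max(float(bl), 0.0)


def _check_states(tree: TreeNode, states: dict[str, str]) -> None:
    for tip in tree.tips():
        if tip.name not in states:
            raise ValueError(f"tip {tip.name!r} has no silk/non-silk state")
        if states[tip.name] not in STATES:
            raise ValueError(f"invalid state {states[tip.name]!r} for tip {tip.name!r}")


def _downward_likelihoods(tree: TreeNode, states: dict[str, str], q: float):
    """Post-order conditional likelihoods with per-node underflow scaling.

    Returns (dict id(node) -> 2-vector, accumulated log scale).
    """
    down: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_tip():
            vec = np.array([1.0, 0.0]) if states[node.name] == NON_SILK else np.array([0.0, 1.0])
        else:
            vec = np.ones(2)
            for child in node.children:
                P = transition_matrix(q, _branch_length(child))
                vec = vec * (P @ down[id(child)])
            s = vec.sum()
            if s > 0.0:
                vec = vec / s
                log_scale += math.log(s)
        down[id(node)] = vec
    return down, log_scale


def prune_likelihood(tree: TreeNode, states: dict[str, str], q: float) -> float:
    """Log-likelihood of binary tip states under the Mk2/ER model.

    Felsenstein pruning with a flat (1/2, 1/2) root prior.  Returns ``-inf``
    when the data are impossible (e.g. ``q == 0`` with both states present).
    """
    _check_states(tree, states)
    if q < 0:
        raise ValueError("rate must be non-negative")
    down, log_scale = _downward_likelihoods(tree, states, q)
    lik = 0.5 * down[id(tree)].sum()
    if lik <= 0.0:
        return -math.inf
    return math.log(lik) + log_scale


@dataclass
class RateFit:
    """ML estimate of the Mk2 rate on one tree."""

    q: float
    log_likelihood: float
    at_bound: bool = False


def fit_rate(tree: TreeNode, states: dict[str, str]) -> RateFit:
    """Maximize the pruning likelihood over ``q`` on [1e-8, 1e3].

    Bounded scalar (Brent) optimization; a monotone profile (all tips in one
    state) drives the optimum to the lower bound, which is flagged.
    """
    _check_states(tree, states)
    if len(list(tree.tips())) < 2:
        raise ValueError("rate fitting needs at least 2 tips")

    def neg_ll_log(log_q: float) -> float:
        ll = prune_likelihood(tree, states, math.exp(log_q))
        return -ll if math.isfinite(ll) else 1e300

    # optimize in log-rate space: the likelihood surface is flat for large q
    # and sharply curved near 0, so the log scale keeps the profile unimodal
    # and well-conditioned for golden-section search
    res = minimize_scalar(
        neg_ll_log,
        bounds=(math.log(RATE_LOWER), math.log(RATE_UPPER)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    q_hat = float(math.exp(res.x))
    at_bound = q_hat <= RATE_LOWER * 10 or q_hat >= RATE_UPPER * 0.99
    return RateFit(q=q_hat, log_likelihood=-float(res.fun), at_bound=at_bound)


@dataclass
class AncestralReconstruction:
    """Marginal posteriors and hard labels for the internal nodes of one tree."""

    q: float
    log_likelihood: float
    #: id(node) -> posterior probability of the silk state
    posterior_silk: dict[int, float]
    #: id(node) -> label; ties (|posterior - 1/2| <= TIE_TOL) resolve to non-silk
    labels: dict[int, str]


def marginal_states(tree: TreeNode, states: dict[str, str], q: float) -> AncestralReconstruction:
    """Marginal ancestral reconstruction by the outside/inside (rerooting) method.

    For every internal node the posterior combines the conditional likelihood
    of the data below it with the likelihood of the rest of the tree, under the
    flat root prior.  Node labels apply the tie rule: silk only when
    ``P(silk) - 1/2 > TIE_TOL``.
    """
    _check_states(tree, states)
    down, log_scale = _downward_likelihoods(tree, states, q)
    root_lik = 0.5 * down[id(tree)].sum()
    log_lik = math.log(root_lik) + log_scale if root_lik > 0 else -math.inf

    # outside pass: O[v][s] ∝ P(data not below v, state(v)=s)
    outside: dict[int, np.ndarray] = {id(tree): np.array([0.5, 0.5])}
    for node in tree.preorder():
        if node.is_tip():
            continue
        # message each child receives from its parent and siblings
        child_msgs = {
            id(c): transition_matrix(q, _branch_length(c)) @ down[id(c)]
            for c in node.children
        }
        for child in node.children:
            acc = outside[id(node)].copy()
            for sib in node.children:
                if sib is child:
                    continue
                acc = acc * child_msgs[id(sib)]
            P = transition_matrix(q, _branch_length(child))
            vec = acc @ P
            s = vec.sum()
            outside[id(child)] = vec / s if s > 0 else vec

    posterior: dict[int, float] = {}
    labels: dict[int, str] = {}
    for node in tree.non_tips(include_self=True):
        joint = outside[id(node)] * down[id(node)]
        tot = joint.sum()
        p_silk = float(joint[1] / tot) if tot > 0 else 0.5
        posterior[id(node)] = p_silk
        labels[id(node)] = SILK if p_silk - 0.5 > TIE_TOL else NON_SILK
    return AncestralReconstruction(
        q=q, log_likelihood=log_lik, posterior_silk=posterior, labels=labels
    )


def count_shifts(
    tree: TreeNode, reconstruction: AncestralReconstruction, states: dict[str, str]
) -> int:
    """Number of edges whose parent is non-silk and child silk (tip edges included)."""
    _check_states(tree, states)
    n = 0
    for node in tree.postorder():
        if node.parent is None:
            continue
        parent_label = reconstruction.labels[id(node.parent)]
        child_label = states[node.name] if node.is_tip() else reconstruction.labels[id(node)]
        if parent_label == NON_SILK and child_label == SILK:
            n += 1
    return n


def reconstruct_and_count(tree: TreeNode, states: dict[str, str]) -> tuple[int, RateFit]:
    """Fit the rate, reconstruct ancestral states, and count non-silk→silk gains."""
    fit = fit_rate(tree, states)
    recon = marginal_states(tree, states, fit.q)
    return count_shifts(tree, recon, states), fit


# ---------------------------------------------------------------------------
# tree construction


def random_rooted_tree(
    n_tips: int, rng: np.random.Generator, labels: list[str] | None = None
) -> TreeNode:
    """Rooted binary tree by recursive random splitting.

    At every ``k``-tip subproblem the left subtree receives a uniform number of
    tips on {1..k-1}; every edge gets an i.i.d. uniform(0,1) branch length.
    Tips are labelled ``labels`` in order (default ``t1..tn``).
    """
    if n_tips < 2:
        raise ValueError("random_rooted_tree needs n_tips >= 2")
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")
    counter = iter(labels)

    def build(k: int) -> TreeNode:
        if k == 1:
            return TreeNode(name=next(counter), length=float(rng.uniform()))
        left = int(rng.integers(1, k))
        node = TreeNode(length=float(rng.uniform()))
        node.extend([build(left), build(k - left)])
        return node

    root = build(n_tips)
    root.length = None
    return root


def build_distance_tree(proteins: dict[str, str]) -> TreeNode:
    """Neighbor-joining tree from pairwise p-distances of protein sequences.

    Plumbing for families without an externally supplied tree: pairwise global
    alignments give p-distances (mismatched columns / aligned columns, gap
    columns counted as differences), NJ joins them, and negative branch
    lengths are clamped to zero.  Identical sequences yield a star-like tree
    with zero lengths.
    """
    ids = list(proteins)
    if len(ids) < 3:
        raise ValueError("distance tree needs at least 3 sequences")
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _p_distance(proteins[ids[i]], proteins[ids[j]])
            dm[i, j] = dm[j, i] = d
    tree = nj(DistanceMatrix(dm, ids))
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def _p_distance(a: str, b: str) -> float:
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner(
        mode="global", match_score=1, mismatch_score=0,
        open_gap_score=-1, extend_gap_score=-0.5,
    )
    aln = aligner.align(a, b)[0]
    matches = 0
    cols = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        cols += e1 - s1
        matches += sum(1 for x, y in zip(a[s1:e1], b[s2:e2]) if x == y)
    total_cols = max(len(a), len(b))  # gap columns counted via the longer length
    cols = max(cols, 1)
    return 1.0 - matches / total_cols


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest tip-to-tip path.

    All-zero branch lengths cannot define a midpoint; the root then falls on
    the first internal edge, with a warning.
    """
    work = tree.copy()
    tips = list(work.tips())
    if len(tips) == 2:
        # the midpoint halves the single tip-to-tip path
        total = sum(_branch_length(n) for n in work.postorder() if n.parent is not None)
        root = TreeNode()
        root.extend(
            [
                TreeNode(name=tips[0].name, length=total / 2),
                TreeNode(name=tips[1].name, length=total / 2),
            ]
        )
        return root
    lengths = [_branch_length(n) for n in work.postorder() if n.parent is not None]
    if sum(lengths) == 0.0:
        warnings.warn("all branch lengths are zero; rooting on an arbitrary edge")
        for node in work.postorder():
            if not node.is_tip() and node.parent is not None:
                return work.root_at(node, reset=True)
        return work
    rooted = work.root_at_midpoint(reset=True)
    return rooted


# ---------------------------------------------------------------------------
# the co-option test


@dataclass
class ShiftNull:
    """Observed non-silk→silk gains vs the random-tree null for one family."""

    observed: int
    null_counts: list[int] = field(repr=False)
    reps: int = 0
    degenerate: bool = False

    @property
    def mean(self) -> float:
        return float(np.mean(self.null_counts)) if self.null_counts else math.nan

    @property
    def sd(self) -> float:
        if len(self.null_counts) < 2:
            return 0.0 if self.null_counts else math.nan
        return float(np.std(self.null_counts, ddof=1))

    @property
    def p_empirical(self) -> float:
        """Add-one-smoothed one-sided p: fraction of null reps with <= observed shifts."""
        if not self.null_counts:
            return math.nan
        less = sum(1 for c in self.null_counts if c <= self.observed)
        return (1 + less) / (len(self.null_counts) + 1)


def cooption_test(
    tree: TreeNode,
    states: dict[str, str],
    reps: int = 100,
    rng: np.random.Generator | None = None,
) -> ShiftNull:
    """Compare observed silk-expression gains with a random-tree null.

    Observed gains come from ML reconstruction on the input (midpoint-rooted)
    tree.  Each null replicate draws a fresh random rooted tree over the same
    tips, permutes the same state multiset onto the leaves, re-fits the rate,
    reconstructs, and counts gains.  Families lacking 2 tips in each state are
    flagged degenerate (the test was designed for >=2 silk and >=2 non-silk
    members) but still computed.
    """
    if rng is None:
        rng = np.random.default_rng()
    _check_states(tree, states)
    tip_names = [t.name for t in tree.tips()]
    n_silk = sum(1 for t in tip_names if states[t] == SILK)
    degenerate = n_silk < 2 or len(tip_names) - n_silk < 2

    observed, _ = reconstruct_and_count(tree, states)

    state_multiset = [states[t] for t in tip_names]
    null_counts = []
    for _ in range(reps):
        rand_tree = random_rooted_tree(len(tip_names), rng, labels=tip_names)
        perm = rng.permutation(len(tip_names))
        rand_states = {tip_names[i]: state_multiset[perm[i]] for i in range(len(tip_names))}
        count, _ = reconstruct_and_count(rand_tree, rand_states)
        null_counts.append(count)
    return ShiftNull(
        observed=observed, null_counts=null_counts, reps=reps, degenerate=degenerate
    )


# ---------------------------------------------------------------------------
# Newick I/O helpers


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(text))


def write_newick(tree: TreeNode) -> str:
    out = _io.StringIO()
    tree.write(out)
    return out.getvalue().strip()
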