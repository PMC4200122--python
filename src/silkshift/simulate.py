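"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates a three-library (silk gland, venom gland,
cephalothorax) bulk RNA-seq experiment over a de novo transcriptome:

- expected counts are negative-binomial draws around per-transcript means; the
  mean expression profile is log-normal, a planted fraction of silk-specific
  transcripts (SSTs) carries a configurable silk:other expected eCPM fold
  change, and a handful of dominant transcripts may jointly absorb a large
  share of the silk library (the spidroin-dominance pattern, where ~30
  transcripts can account for nearly half of silk-gland expression);
- protein families evolve along trees drawn from the same random-rooted-tree
  generator used by the co-option null, with a known number of planted
  non-silk→silk origin edges;
- FASTQ read pairs carry per-position qualities with an optional planted
  low-quality 3' tail, so post-trim lengths are predictable.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.tree import TreeNode

from . import phylo
from .phylo import NON_SILK, SILK
from .quantify import LIBRARIES, ExpressionMatrix

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FamilySpec:
    """One simulated gene family: tip count, silk tips, planted origins, rate."""

    n_tips: int
    n_silk_tips: int
    n_origins: int
    rate: float = 0.05  # substitutions per site per branch-length unit
    seq_length: int = 200
    #: minimum branch length of a planted origin edge; keeps the planted
    #: character history identifiable by reconstruction (origin clades on
    #: near-zero stems are not recoverable by any method)
    min_stem: float = 0.25

    def validate(self) -> None:
        if self.n_tips < 2:
            raise ValueError("family_spec: n_tips must be >= 2")
        if not 0 <= self.n_silk_tips <= self.n_tips:
            raise ValueError("family_spec: n_silk_tips out of range")
        if self.n_origins > self.n_silk_tips:
            raise ValueError("family_spec: n_origins must be <= n_silk_tips")
        if self.n_silk_tips and self.n_origins < 1:
            raise ValueError("family_spec: silk tips present but n_origins < 1")
        if self.rate < 0:
            raise ValueError("family_spec: rate must be non-negative")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic three-library experiment."""

    n_transcripts: int = 5000
    library_sizes: tuple[float, float, float] = (2.0e6, 2.4e6, 3.0e6)
    sst_fraction: float = 0.004
    sst_fold: float = 10_000.0
    n_dominant: int = 0
    dominant_share: float = 0.0
    nb_dispersion: float = 10.0
    mean_sd_log: float = 1.5  # sd of the log-normal expression prior
    length_range: tuple[int, int] = (300, 3000)
    family_specs: list[FamilySpec] = field(default_factory=list)
    tail_fraction: float = 0.0  # fraction of simulated reads with a bad 3' tail
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be positive")
        if len(self.library_sizes) != 3 or any(s <= 0 for s in self.library_sizes):
            raise ValueError("library_sizes must be 3 positive totals")
        if not 0.0 <= self.sst_fraction <= 1.0:
            raise ValueError("sst_fraction must lie in [0, 1]")
        if self.sst_fold <= 0:
            raise ValueError("sst_fold must be positive")
        if self.n_dominant < 0:
            raise ValueError("n_dominant must be non-negative")
        if not 0.0 <= self.dominant_share < 1.0:
            raise ValueError("dominant_share must lie in [0, 1)")
        if self.n_dominant and self.n_dominant > int(self.sst_fraction * self.n_transcripts):
            raise ValueError("n_dominant exceeds the number of planted SSTs")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for spec in self.family_specs:
            spec.validate()


@dataclass
class FamilyTruth:
    family_id: str
    tree: TreeNode
    sequences: dict[str, str]
    tip_states: dict[str, str]
    true_origins: int


@dataclass
class TruthLabels:
    """Planted per-transcript classes and per-family ground truth."""

    is_sst: pd.Series  # bool, indexed by transcript id
    is_dominant: pd.Series
    families: list[FamilyTruth] = field(default_factory=list)


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # NB with var = mu + mu^2/dispersion
    mean = np.maximum(mean, 1e-12)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(float)


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, TruthLabels]:
    """Simulate the transcripts-by-libraries expected-count matrix.

    The silk column keeps the baseline log-normal expression proportions; in
    the venom and cephalothorax columns each planted SST is divided by
    ``sst_fold`` (and the background slightly rescaled to keep proportions on
    the simplex), so the expected silk:other eCPM ratio of a planted SST is
    exactly ``sst_fold``.  Dominance, when requested, reassigns
    ``dominant_share`` of silk mass uniformly to ``n_dominant`` of the SSTs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    ids = [f"UAT{i + 1:06d}" for i in range(n)]

    base = rng.lognormal(mean=0.0, sigma=config.mean_sd_log, size=n)
    base_p = base / base.sum()

    n_sst = int(round(config.sst_fraction * n))
    sst_idx = rng.choice(n, size=n_sst, replace=False) if n_sst else np.array([], int)
    is_sst = np.zeros(n, dtype=bool)
    is_sst[sst_idx] = True

    # silk proportions: baseline, optionally with dominance reallocation
    silk_p = base_p.copy()
    is_dom = np.zeros(n, dtype=bool)
    if config.n_dominant and config.dominant_share > 0:
        dom_idx = sst_idx[: config.n_dominant]
        is_dom[dom_idx] = True
        rest = ~is_dom
        silk_p[dom_idx] = config.dominant_share / config.n_dominant
        silk_p[rest] *= (1.0 - config.dominant_share) / silk_p[rest].sum()

    # other-tissue proportions: SSTs depressed by the fold factor, background
    # rescaled so the column stays on the simplex
    other_p = silk_p.copy()
    other_p[is_sst] = silk_p[is_sst] / config.sst_fold
    s_sst = silk_p[is_sst].sum()
    bg = ~is_sst
    if bg.any():
        other_p[bg] *= (1.0 - s_sst / config.sst_fold) / silk_p[bg].sum()

    props = {"silk": silk_p, "venom": other_p, "cephalothorax": other_p}
    counts = {}
    for lib, size in zip(LIBRARIES, config.library_sizes):
        counts[lib] = _nb_draws(rng, props[lib] * size, config.nb_dispersion)
    lengths = pd.Series(
        rng.integers(config.length_range[0], config.length_range[1] + 1, size=n),
        index=ids, name="length",
    )
    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=ids)[list(LIBRARIES)], lengths=lengths
    )

    families = [
        simulate_family(spec, seed=int(rng.integers(2**31 - 1)), family_id=f"SF{i + 1}")
        for i, spec in enumerate(config.family_specs)
    ]
    truth = TruthLabels(
        is_sst=pd.Series(is_sst, index=ids, name="is_sst"),
        is_dominant=pd.Series(is_dom, index=ids, name="is_dominant"),
        families=families,
    )
    return matrix, truth


def _clade_sets(tree: TreeNode) -> list[tuple[TreeNode, frozenset[str]]]:
    out = []
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_tip():
            below[id(node)] = frozenset([node.name])
        else:
            s: frozenset[str] = frozenset()
            for c in node.children:
                s |= below[id(c)]
            below[id(node)] = s
        if node.parent is not None:
            out.append((node, below[id(node)]))
    return out


def _count_true_origins(tree: TreeNode, tip_states: dict[str, str]) -> int:
    """Non-silk→silk edges when internal nodes are silk iff all tips below are silk."""
    silk_below: dict[int, bool] = {}
    origins = 0
    for node in tree.postorder():
        if node.is_tip():
            silk_below[id(node)] = tip_states[node.name] == SILK
        else:
            silk_below[id(node)] = all(silk_below[id(c)] for c in node.children)
    for node in tree.postorder():
        if node.parent is None:
            continue
        if silk_below[id(node)] and not silk_below[id(node.parent)]:
            origins += 1
    return origins


def simulate_family(
    spec: FamilySpec, seed: int, family_id: str = "SF1", max_tries: int = 500
) -> FamilyTruth:
    """Simulate one gene family with a planted number of silk-origin edges.

    The tree is drawn from the same generator as the co-option null
    (:func:`silkshift.phylo.random_rooted_tree`); trees are redrawn until
    ``n_origins`` disjoint, non-sibling clades exactly covering
    ``n_silk_tips`` silk tips exist.  Protein sequences evolve by per-site
    uniform substitution along branches (no indels), so at low rates
    within-family identity stays far above the 50% clustering threshold.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    labels = [f"{family_id}_t{i + 1}" for i in range(spec.n_tips)]

    for _ in range(max_tries):
        tree = phylo.random_rooted_tree(spec.n_tips, rng, labels=labels)
        silk_tips = _plant_silk_tips(tree, spec, rng)
        if silk_tips is None:
            continue
        tip_states = {
            name: (SILK if name in silk_tips else NON_SILK) for name in labels
        }
        true_origins = _count_true_origins(tree, tip_states)
        if true_origins != spec.n_origins:
            continue
        sequences = _evolve_sequences(tree, spec, rng)
        return FamilyTruth(family_id, tree, sequences, tip_states, true_origins)
    raise ValueError(
        f"family {family_id}: cannot split {spec.n_silk_tips} silk tips into "
        f"{spec.n_origins} clades on {spec.n_tips}-tip trees"
    )


def _plant_silk_tips(
    tree: TreeNode, spec: FamilySpec, rng: np.random.Generator
) -> set[str] | None:
    if spec.n_silk_tips == 0:
        return set()
    # candidate origin clades: not a root child, stem at least min_stem
    clades = [
        (node, tipset)
        for node, tipset in _clade_sets(tree)
        if node.parent is not None
        and node.parent.parent is not None
        and (node.length or 0.0) >= spec.min_stem
    ]
    if not clades:
        return None
    for _ in range(50):  # shuffled greedy passes over this tree's clades
        order = rng.permutation(len(clades))
        chosen: list[tuple[TreeNode, frozenset[str]]] = []
        covered: set[str] = set()
        for j in order:
            node, tipset = clades[j]
            if len(chosen) == spec.n_origins:
                break
            remaining_slots = spec.n_origins - len(chosen) - 1
            size = len(tipset)
            budget = spec.n_silk_tips - len(covered)
            if remaining_slots == 0:
                if size != budget:
                    continue
            elif size > budget - remaining_slots:
                continue
            if covered & tipset:
                continue
            # avoid sibling clades: they would merge into a single origin
            if any(node.parent is prev.parent for prev, _ in chosen):
                continue
            chosen.append((node, tipset))
            covered |= tipset
        if len(chosen) == spec.n_origins and len(covered) == spec.n_silk_tips:
            return set(covered)
    return None


def _evolve_sequences(
    tree: TreeNode, spec: FamilySpec, rng: np.random.Generator
) -> dict[str, str]:
    aa = np.array(list(AMINO_ACIDS))
    root_seq = rng.integers(0, len(aa), size=spec.seq_length)
    seqs: dict[int, np.ndarray] = {id(tree): root_seq}
    out: dict[str, str] = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_seq = seqs[id(node.parent)]
        t = node.length or 0.0
        p_change = 1.0 - math.exp(-spec.rate * t)
        child = parent_seq.copy()
        if p_change > 0:
            mask = rng.random(spec.seq_length) < p_change
            n_mut = int(mask.sum())
            if n_mut:
                # substitute to a uniformly drawn different residue
                shift = rng.integers(1, len(aa), size=n_mut)
                child[mask] = (child[mask] + shift) % len(aa)
        seqs[id(node)] = child
        if node.is_tip():
            out[node.name] = "".join(aa[child])
    return out


@dataclass
class SimulatedReadPair:
    read_id: str
    seq1: str
    qual1: tuple[int, ...]
    seq2: str
    qual2: tuple[int, ...]


def simulate_read_pairs(
    n_pairs: int,
    read_len: int = 100,
    base_quality: int = 38,
    quality_sd: float = 2.0,
    tail_fraction: float = 0.0,
    tail_length: int = 0,
    tail_quality: int = 20,
    seed: int = 0,
) -> list[SimulatedReadPair]:
    """Random read pairs with per-position qualities and optional bad 3' tails.

    A ``tail_fraction`` of pairs get both mates' final ``tail_length`` bases
    set to ``tail_quality`` (below the usual trimming threshold of 28), so
    post-trim lengths are read_len - tail_length by construction.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    if not 0.0 <= tail_fraction <= 1.0:
        raise ValueError("tail_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    pairs = []
    for i in range(n_pairs):
        has_tail = rng.random() < tail_fraction
        mates = []
        for _ in range(2):
            seq = "".join(bases[rng.integers(0, 4, size=read_len)])
            qual = np.clip(
                np.round(rng.normal(base_quality, quality_sd, size=read_len)), 30, 41
            ).astype(int)
            if has_tail and tail_length:
                qual[-tail_length:] = tail_quality
            mates.append((seq, tuple(int(q) for q in qual)))
        pairs.append(
            SimulatedReadPair(f"read{i + 1}", mates[0][0], mates[0][1], mates[1][0], mates[1][1])
        )
    return pairs
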