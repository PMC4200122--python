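"""Identity-threshold protein clustering into putative gene families.

Families are seeded by single-linkage clustering of silk-specific proteins:
two proteins are linked when a local alignment reaches at least 50% identity
over at least 50% of the shorter sequence.  Non-silk-specific proteins are
then attached to the family holding their best-scoring passing edge, giving
disjoint families suitable for tree building.  A family enters the
phylogenetic co-option test only when it holds at least two silk-specific
members (extended 2.5%-tail set or stricter) and at least two others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

from .enrich import HomologyHit

SST_LABELS = frozenset({"SST", "extended-SST"})


@dataclass(frozen=True)
class PairwiseAlignment:
    id_a: str
    id_b: str
    identity: float  # matches / aligned columns
    coverage: float  # aligned span on the shorter sequence / shorter length
    score: float


_ALIGNER: PairwiseAligner | None = None


def _aligner() -> PairwiseAligner:
    # BLOSUM62 with BLASTP-default affine gaps (open 11, extend 1; Biopython's
    # open score includes the first extension, hence -12/-1)
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = PairwiseAligner(
            mode="local",
            substitution_matrix=substitution_matrices.load("BLOSUM62"),
            open_gap_score=-12.0,
            extend_gap_score=-1.0,
        )
    return _ALIGNER


def align_pair(id_a: str, seq_a: str, id_b: str, seq_b: str) -> PairwiseAlignment:
    """Local alignment of two proteins with identity and shorter-sequence coverage.

    Identity counts matched columns over all aligned columns (gap columns in
    the local alignment included, the BLAST pident convention); coverage is
    the aligned span of the shorter sequence over its full length.
    """
    if not seq_a or not seq_b:
        raise ValueError("align_pair requires non-empty sequences")
    # canonical argument order: tie-breaking among co-optimal alignments can
    # otherwise differ between (a, b) and (b, a)
    if (len(seq_b), seq_b) < (len(seq_a), seq_a):
        swapped = align_pair(id_b, seq_b, id_a, seq_a)
        return PairwiseAlignment(
            id_a, id_b, swapped.identity, swapped.coverage, swapped.score
        )
    aln = _aligner().align(seq_a.upper(), seq_b.upper())[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return PairwiseAlignment(id_a, id_b, 0.0, 0.0, float(aln.score))
    matches = 0
    aligned_res = 0
    for (s1, e1), (s2, e2) in zip(blocks_a, blocks_b):
        aligned_res += e1 - s1
        matches += sum(1 for x, y in zip(seq_a[s1:e1].upper(), seq_b[s2:e2].upper()) if x == y)
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    gap_cols = (span_a - aligned_res) + (span_b - aligned_res)
    columns = aligned_res + gap_cols
    identity = matches / columns if columns else 0.0
    shorter_len = min(len(seq_a), len(seq_b))
    shorter_span = span_a if len(seq_a) <= len(seq_b) else span_b
    coverage = shorter_span / shorter_len
    return PairwiseAlignment(id_a, id_b, identity, coverage, float(aln.score))


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _passes(aln: PairwiseAlignment, min_identity: float, min_coverage: float) -> bool:
    return aln.identity >= min_identity and aln.coverage >= min_coverage


def cluster_ssts(
    sst_proteins: dict[str, str],
    min_identity: float = 0.5,
    min_coverage: float = 0.5,
) -> list[list[str]]:
    """Single-linkage clusters of SST proteins under the 50/50 rule.

    Returned clusters are sorted by decreasing size, ties by the
    lexicographically smallest member; members within a cluster are sorted.
    The result is therefore invariant to input order.
    """
    ids = sorted(sst_proteins)
    uf = _UnionFind(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            aln = align_pair(a, sst_proteins[a], b, sst_proteins[b])
            if _passes(aln, min_identity, min_coverage):
                uf.union(a, b)
    groups: dict[str, list[str]] = {}
    for x in ids:
        groups.setdefault(uf.find(x), []).append(x)
    clusters = [sorted(g) for g in groups.values()]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


@dataclass
class GeneFamily:
    """One putative gene family: member ids with specificity labels."""

    family_id: str
    members: dict[str, str] = field(default_factory=dict)  # id -> label

    def count(self, *labels: str) -> int:
        return sum(1 for v in self.members.values() if v in labels)

    @property
    def n_sst(self) -> int:
        return self.count("SST")

    @property
    def n_extended(self) -> int:
        return self.count("SST", "extended-SST")

    @property
    def n_non_sst(self) -> int:
        return self.count("non-SST", "below-floor")


def augment_families(
    clusters: list[list[str]],
    sst_proteins: dict[str, str],
    other_proteins: dict[str, str],
    labels: dict[str, str] | None = None,
    min_identity: float = 0.5,
    min_coverage: float = 0.5,
) -> list[GeneFamily]:
    """Attach non-SST proteins to SST seed clusters under the same 50/50 rule.

    A non-SST protein joins the cluster holding its best-scoring passing edge
    (ties: larger cluster, then lexicographically smaller family id), so
    families stay disjoint.  ``labels`` assigns each member's specificity
    label (defaults: seed members "SST", joined members "non-SST").
    """
    labels = labels or {}
    families = [
        GeneFamily(
            family_id=f"F{i + 1}",
            members={m: labels.get(m, "SST") for m in cluster},
        )
        for i, cluster in enumerate(clusters)
    ]
    for pid in sorted(other_proteins):
        best = None  # (score, cluster_size, family_id index)
        for fi, (fam, cluster) in enumerate(zip(families, clusters)):
            for member in cluster:
                aln = align_pair(pid, other_proteins[pid], member, sst_proteins[member])
                if _passes(aln, min_identity, min_coverage):
                    key = (-aln.score, -len(cluster), fi)
                    if best is None or key < best[0]:
                        best = (key, fi)
        if best is not None:
            families[best[1]].members[pid] = labels.get(pid, "non-SST")
    return families


def tree_eligible(family: GeneFamily) -> bool:
    """True when the family supports the co-option test: >=2 silk-specific
    members (strict or extended tail) and >=2 other members."""
    return family.n_extended >= 2 and (len(family.members) - family.n_extended) >= 2


def detect_chimeras(
    hits_by_query: dict[str, list[HomologyHit]],
    top_n: int = 20,
    max_overlap: int = 10,
    e_cutoff: float = 1e-5,
) -> dict[str, bool]:
    """Flag transcripts whose top hits hit different proteins in disjoint regions.

    Among the ``top_n`` lowest-E hits passing ``e_cutoff``, a query is a
    chimera candidate when two hits with different subject ids overlap by at
    most ``max_overlap`` bases on the query (intervals are 0-based half-open;
    overlap is the intersection length).
    """
    flags: dict[str, bool] = {}
    for query, hits in hits_by_query.items():
        passing = sorted(
            (h for h in hits if h.evalue <= e_cutoff), key=lambda h: h.evalue
        )[:top_n]
        flagged = False
        for i, h1 in enumerate(passing):
            for h2 in passing[i + 1 :]:
                if h1.subject == h2.subject:
                    continue
                overlap = min(h1.qend, h2.qend) - max(h1.qstart, h2.qstart)
                if overlap <= max_overlap:
                    flagged = True
                    break
            if flagged:
                break
        flags[query] = flagged
    return flags
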