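"""Read trimming, ORF prediction, translation selection, and redundancy collapse.

These are the de novo transcriptome bookkeeping rules applied before
quantification: 3'-quality trimming of read pairs with a minimum-length pair
filter, six-frame ORF scanning with a 30-aa floor, translation frame choice
(homology frame first, else longest ORF with a first-methionine rule), and
collapsing proteins that are identical over the full length of the shorter
member.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

REMOVED = "REMOVED"

STOP = "*"


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    qual1: tuple[int, ...]
    seq2: str
    qual2: tuple[int, ...]

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(
                f"read {self.read_id}: sequence and quality lengths differ"
            )


def _trim_tail(seq: str, qual: tuple[int, ...], threshold: int) -> tuple[str, tuple[int, ...]]:
    # drop the maximal 3' suffix of bases below the threshold; stop at the
    # first base (from the end) at or above it
    end = len(seq)
    while end > 0 and qual[end - 1] < threshold:
        end -= 1
    return seq[:end], qual[:end]


def trim_read_pair(
    pair: ReadPair, qual_threshold: int = 28, min_len: int = 60
) -> ReadPair | str:
    """3'-quality-trim both mates; remove the pair if either mate ends < min_len.

    Trimming is 3'-anchored only: internal low-quality bases are kept.
    Returns the trimmed pair, or the sentinel ``REMOVED``.
    """
    s1, q1 = _trim_tail(pair.seq1, pair.qual1, qual_threshold)
    s2, q2 = _trim_tail(pair.seq2, pair.qual2, qual_threshold)
    if len(s1) < min_len or len(s2) < min_len:
        return REMOVED
    return ReadPair(pair.read_id, s1, q1, s2, q2)


@dataclass(frozen=True)
class OrfRecord:
    """A maximal stop-free codon run in one of the six frames.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand of the transcript; ``frame`` is +1..+3 or -1..-3.
    ``bounded_5prime``/``bounded_3prime`` record whether a stop codon flanks
    the ORF on that side (in reading direction).
    """

    frame: int
    start: int
    end: int
    protein: str
    bounded_5prime: bool
    bounded_3prime: bool

    @property
    def length_aa(self) -> int:
        return len(self.protein)


def _scan_frame(seq: str, offset: int) -> list[tuple[int, int, str, bool, bool]]:
    """Maximal stop-free runs in one forward frame of ``seq``.

    Returns (codon_start, codon_end, protein, bounded5, bounded3) with
    coordinates on ``seq`` (reading direction), excluding any bounding stop.
    """
    n = len(seq)
    runs = []
    pos = offset
    run_start = offset
    aa: list[str] = []
    bounded5 = False
    while pos + 3 <= n:
        codon = seq[pos : pos + 3]
        residue = str(Seq(codon).translate())
        if residue == STOP:
            if aa:
                runs.append((run_start, pos, "".join(aa), bounded5, True))
            aa = []
            run_start = pos + 3
            bounded5 = True
        else:
            aa.append(residue)
        pos += 3
    if aa:
        runs.append((run_start, run_start + 3 * len(aa), "".join(aa), bounded5, False))
    return runs


def find_orfs(seq: str, min_aa: int = 30) -> list[OrfRecord]:
    """All six-frame ORFs of at least ``min_aa`` amino acids.

    An ORF is a maximal stop-free codon run, bounded by stop codons or the
    transcript ends (open bounds).  Reverse-strand ORFs are reported in
    forward coordinates with negative frames.
    """
    seq = seq.upper()
    if not seq:
        return []
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotides: {sorted(bad)}")
    out = []
    for offset in range(3):
        for start, end, protein, b5, b3 in _scan_frame(seq, offset):
            if len(protein) >= min_aa:
                out.append(OrfRecord(offset + 1, start, end, protein, b5, b3))
    rc = str(Seq(seq).reverse_complement())
    n = len(seq)
    for offset in range(3):
        for start, end, protein, b5, b3 in _scan_frame(rc, offset):
            if len(protein) >= min_aa:
                # map reverse-strand run back to forward coordinates
                out.append(OrfRecord(-(offset + 1), n - end, n - start, protein, b5, b3))
    return out


@dataclass(frozen=True)
class ProteinRecord:
    transcript_id: str
    sequence: str
    provenance: str  # homology-frame | longest-ORF | first-M-trimmed

    @property
    def starts_with_m(self) -> bool:
        return self.sequence.startswith("M")


def select_translation(
    transcript_id: str,
    orfs: list[OrfRecord],
    homology_frame: int | None = None,
    min_m_fraction: float = 0.75,
) -> ProteinRecord:
    """Choose the predicted protein for one transcript.

    With a homology frame, translate that frame's longest ORF.  Otherwise take
    the longest ORF overall (ties: lowest |frame| then positive strand, then
    leftmost); when that ORF is stop-bounded on both sides and contains an M
    whose suffix covers at least ``min_m_fraction`` of the ORF, start the
    protein at the first such M.
    """
    if homology_frame is not None:
        candidates = [o for o in orfs if o.frame == homology_frame]
        if not candidates:
            raise ValueError(
                f"transcript {transcript_id}: no ORF in homology frame {homology_frame}"
            )
        orf = max(candidates, key=lambda o: o.length_aa)
        return ProteinRecord(transcript_id, orf.protein, "homology-frame")
    if not orfs:
        raise ValueError(f"transcript {transcript_id}: no ORF and no homology frame")
    orf = min(orfs, key=lambda o: (-o.length_aa, abs(o.frame), o.frame < 0, o.start))
    if orf.bounded_5prime and orf.bounded_3prime:
        first_m = orf.protein.find("M")
        if first_m >= 0:
            suffix = len(orf.protein) - first_m
            if suffix >= min_m_fraction * len(orf.protein):
                return ProteinRecord(
                    transcript_id, orf.protein[first_m:], "first-M-trimmed"
                )
    return ProteinRecord(transcript_id, orf.protein, "longest-ORF")


def collapse_redundant(
    proteins: list[ProteinRecord],
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Group proteins identical over the full length of the shorter member.

    Grouping is exact substring containment, closed transitively; the
    representative is the longest member (ties: first in input order).
    Returns the representatives (input order) and a total member->
    representative id map.  Idempotent.
    """
    n = len(proteins)
    uf = _UnionFindIdx(n)
    order = sorted(range(n), key=lambda i: len(proteins[i].sequence))
    for ai in range(n):
        for bi in range(ai + 1, n):
            a, b = proteins[order[ai]], proteins[order[bi]]
            if a.sequence in b.sequence:
                uf.union(order[ai], order[bi])
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    rep_map: dict[str, str] = {}
    rep_indices = []
    for members in groups.values():
        rep = max(members, key=lambda i: (len(proteins[i].sequence), -i))
        rep_indices.append(rep)
        for i in members:
            rep_map[proteins[i].transcript_id] = proteins[rep].transcript_id
    rep_indices.sort()
    return [proteins[i] for i in rep_indices], rep_map


class _UnionFindIdx:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb
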