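"""Hierarchical small-RNA read classification.

Reads are assigned in the order the wet-lab pipeline used: exact match to
the miRNA/ncRNA set first (either orientation); remaining reads are mapped
to the genome with no mismatches (all occurrences, both strands; a unique
genome hit fully contained in an annotated piRNA cluster marks the read as
cluster-derived) and, independently, to transposon consensus sequences by
gapless Hamming comparison allowing up to 2 substitutions, keeping a single
deterministic best hit per read.

Alignment is seed-and-verify: an 11-mer index for exact genome matching,
and a pigeonhole split (max_mm + 1 segments, at least one of which must
match exactly) for the mismatch-tolerant consensus search. Both are exact
algorithms, verified against brute-force scan oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .io import GenomicInterval, revcomp

DEFAULT_K = 11


@dataclass(frozen=True)
class AlignmentHit:
    """A gapless placement of a read on a reference forward strand.

    strand '-' means the read's reverse complement matches at ``offset``.
    """

    ref: str
    offset: int
    strand: str
    mismatches: int


class KmerIndex:
    """Exact-match k-mer index over the forward strand of each reference."""

    def __init__(self, references: Sequence[tuple[str, str]], k: int = DEFAULT_K):
        if k < 8:
            raise ValueError("k must be >= 8")
        self.k = k
        self.references = list(references)
        self._index: dict[str, list[tuple[int, int]]] = {}
        for ref_idx, (_name, seq) in enumerate(self.references):
            for pos in range(len(seq) - k + 1):
                self._index.setdefault(seq[pos : pos + k], []).append((ref_idx, pos))

    def __len__(self) -> int:
        return sum(len(v) for v in self._index.values())

    def n_positions(self) -> int:
        return len(self)

    def candidates(self, kmer: str) -> list[tuple[int, int]]:
        return self._index.get(kmer, [])


def build_index(references: Sequence[tuple[str, str]], k: int = DEFAULT_K) -> KmerIndex:
    """Index reference forward strands; reverse strand is handled by
    querying the read's reverse complement."""
    for name, seq in references:
        if 0 < len(seq) < k:
            # short references fall back to a direct scan in align_exact;
            # refuse only if nothing can ever be indexed or scanned
            continue
    return KmerIndex(references, k)


def align_exact(read: str, index: KmerIndex) -> list[AlignmentHit]:
    """All exact occurrences of the read on both strands (mismatches=0).

    Seeds on the read's first k-mer; every exact occurrence necessarily
    shares it, so the search is complete. References shorter than k are
    scanned directly.
    """
    hits: list[AlignmentHit] = []
    k = index.k
    n = len(read)
    for strand, query in (("+", read), ("-", revcomp(read))):
        if "N" in query:
            continue  # N matches nothing
        if n >= k:
            for ref_idx, pos in index.candidates(query[:k]):
                name, seq = index.references[ref_idx]
                if seq[pos : pos + n] == query:
                    hits.append(AlignmentHit(name, pos, strand, 0))
        else:
            for name, seq in index.references:
                p = seq.find(query)
                while p != -1:
                    hits.append(AlignmentHit(name, p, strand, 0))
                    p = seq.find(query, p + 1)
    return hits


def _hamming_at(query: str, ref: str, offset: int, max_mm: int) -> int:
    """Mismatch count of query vs ref[offset:], early exit above max_mm.

    N in either sequence counts as a mismatch (N matches nothing).
    """
    mm = 0
    for a, b in zip(query, ref[offset : offset + len(query)]):
        if a != b or a == "N":
            mm += 1
            if mm > max_mm:
                return mm
    return mm


def _segments(query: str, n_seg: int) -> list[tuple[int, str]]:
    """Split a query into n_seg near-equal contiguous segments."""
    n = len(query)
    bounds = [round(i * n / n_seg) for i in range(n_seg + 1)]
    return [(bounds[i], query[bounds[i] : bounds[i + 1]]) for i in range(n_seg)]


def align_hamming(
    read: str,
    consensus_set: Sequence[tuple[str, str]],
    max_mm: int = 2,
) -> Optional[AlignmentHit]:
    """Best gapless hit of the read on a set of consensus sequences.

    Compares the read and its reverse complement at every offset of every
    consensus (substitutions only, N counts as mismatch) and returns a
    single best hit: fewest mismatches, ties broken by consensus input
    order, then smaller offset, then '+' before '-'. Returns None when no
    placement has <= max_mm mismatches.

    Pigeonhole completeness: the read is split into max_mm + 1 segments;
    any placement with <= max_mm mismatches leaves at least one segment
    intact, so seeding on exact segment occurrences finds every
    qualifying placement.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    n = len(read)
    queries = (("+", read), ("-", revcomp(read)))

    # fast path: exact occurrence anywhere
    if "N" not in read:
        best_exact: Optional[tuple[int, int, int, AlignmentHit]] = None
        for ci, (name, cseq) in enumerate(consensus_set):
            for srank, (strand, query) in enumerate(queries):
                p = cseq.find(query)
                if p != -1:
                    key = (ci, p, srank)
                    if best_exact is None or key < best_exact[:3]:
                        best_exact = (*key, AlignmentHit(name, p, strand, 0))
        if best_exact is not None:
            return best_exact[3]
    if max_mm == 0:
        return None

    best: Optional[tuple[int, int, int, int, AlignmentHit]] = None
    n_seg = max_mm + 1
    for ci, (name, cseq) in enumerate(consensus_set):
        limit = len(cseq) - n
        if limit < 0:
            continue
        for srank, (strand, query) in enumerate(queries):
            candidates: set[int] = set()
            for seg_off, seg in _segments(query, n_seg):
                if not seg or "N" in seg:
                    continue
                p = cseq.find(seg)
                while p != -1:
                    start = p - seg_off
                    if 0 <= start <= limit:
                        candidates.add(start)
                    p = cseq.find(seg, p + 1)
            for start in candidates:
                mm = _hamming_at(query, cseq, start, max_mm)
                if mm <= max_mm:
                    key = (mm, ci, start, srank)
                    if best is None or key < best[:4]:
                        best = (*key, AlignmentHit(name, start, strand, mm))
    return best[4] if best else None


FINAL_CLASSES = ("mirna_ncrna", "cluster", "transposon_only", "genome_other", "unmapped")


@dataclass
class ReadAssignment:
    """Hierarchical classification of one read."""

    read_id: str
    length: int
    is_mirna: bool = False
    mirna_name: Optional[str] = None
    genome_hits: int = 0
    genome_offset: Optional[int] = None
    genome_strand: Optional[str] = None
    cluster_id: Optional[str] = None
    transposon_hit: Optional[AlignmentHit] = None
    final_class: str = "unmapped"


class ReferenceBundle:
    """Pre-built lookup structures shared across a library's reads."""

    def __init__(
        self,
        mirnas: Sequence[tuple[str, str]],
        genome: Sequence[tuple[str, str]],
        clusters: Sequence[GenomicInterval],
        consensus_set: Sequence[tuple[str, str]],
        k: int = DEFAULT_K,
        max_mm: int = 2,
    ):
        self.mirna_lookup: dict[str, str] = {}
        for name, seq in mirnas:
            self.mirna_lookup.setdefault(seq, name)
            self.mirna_lookup.setdefault(revcomp(seq), name)
        self.genome_index = build_index(genome, k)
        self.clusters = list(clusters)
        self.consensus_set = list(consensus_set)
        self.max_mm = max_mm


def classify(read_id: str, sequence: str, refs: ReferenceBundle) -> ReadAssignment:
    """Assign one read through the full hierarchy.

    miRNA/ncRNA exact full-length match (either orientation) wins outright.
    Otherwise the read is mapped exactly to the genome (cluster membership
    requires a unique genome hit fully contained in one cluster interval)
    and, independently, to the transposon consensus set with <= max_mm
    substitutions. Reporting precedence:
    cluster > transposon_only > genome_other > unmapped.
    """
    asn = ReadAssignment(read_id=read_id, length=len(sequence))
    mirna = refs.mirna_lookup.get(sequence)
    if mirna is not None:
        asn.is_mirna = True
        asn.mirna_name = mirna
        asn.final_class = "mirna_ncrna"
        return asn

    genome_hits = align_exact(sequence, refs.genome_index)
    asn.genome_hits = len(genome_hits)
    if len(genome_hits) == 1:
        hit = genome_hits[0]
        asn.genome_offset = hit.offset
        asn.genome_strand = hit.strand
        iv = GenomicInterval(hit.ref, hit.offset, hit.offset + len(sequence), hit.strand)
        for cluster in refs.clusters:
            if cluster.contains(iv):
                asn.cluster_id = cluster.name
                break

    asn.transposon_hit = align_hamming(sequence, refs.consensus_set, refs.max_mm)

    if asn.cluster_id is not None:
        asn.final_class = "cluster"
    elif asn.transposon_hit is not None:
        asn.final_class = "transposon_only"
    elif asn.genome_hits > 0:
        asn.final_class = "genome_other"
    else:
        asn.final_class = "unmapped"
    return asn
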