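"""Exact and mismatch-tolerant alignment, verified against brute-force
scan oracles, and the hierarchical classification contract."""

import numpy as np
import pytest

from pirnapipe.io import GenomicInterval, revcomp
from pirnapipe.mapping import (
    AlignmentHit,
    KmerIndex,
    ReferenceBundle,
    align_exact,
    align_hamming,
    build_index,
    classify,
)

# ------------------------------------------------------------- oracles


def oracle_exact(read: str, references) -> set:
    """Enumerate every exact occurrence on both strands by direct scan."""
    hits = set()
    for name, seq in references:
        for strand, q in (("+", read), ("-", revcomp(read))):
            if "N" in q:
                continue
            for off in range(len(seq) - len(q) + 1):
                if seq[off : off + len(q)] == q:
                    hits.add((name, off, strand))
    return hits


def oracle_hamming(read: str, references, max_mm=2):
    """Exhaustive double-loop Hamming search with the documented
    tie-break: fewest mismatches, then reference order, offset, + first."""
    best = None
    for ci, (name, seq) in enumerate(references):
        for srank, q in enumerate((read, revcomp(read))):
            for off in range(len(seq) - len(q) + 1):
                mm = sum(
                    1
                    for a, b in zip(q, seq[off : off + len(q)])
                    if a != b or a == "N" or b == "N"
                )
                if mm <= max_mm:
                    key = (mm, ci, off, srank)
                    if best is None or key < best[0]:
                        best = (key, AlignmentHit(name, off, "+-"[srank], mm))
    return best[1] if best else None


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ------------------------------------------------------------- k-mer index


class TestIndex:
    def test_position_count(self):
        idx = build_index([("r", "ACGTACGTACGT")], k=8)
        assert len(idx) == 12 - 8 + 1

    def test_duplicate_kmers_keep_both_positions(self):
        idx = build_index([("r", "AAAAAAAACCAAAAAAAA")], k=8)
        assert len(idx.candidates("AAAAAAAA")) == 2

    def test_empty_reference_set(self):
        idx = build_index([], k=8)
        assert len(idx) == 0


class TestAlignExact:
    def test_single_forward_occurrence(self):
        rng = np.random.default_rng(0)
        genome = random_seq(rng, 500)
        read = genome[100:130]
        idx = build_index([("g", genome)])
        hits = align_exact(read, idx)
        assert AlignmentHit("g", 100, "+", 0) in hits
        assert oracle_exact(read, [("g", genome)]) == {
            (h.ref, h.offset, h.strand) for h in hits
        }

    def test_forward_and_reverse_complement_occurrences(self):
        rng = np.random.default_rng(1)
        core = random_seq(rng, 30)
        genome = random_seq(rng, 100) + core + random_seq(rng, 100) + revcomp(core) + random_seq(rng, 50)
        idx = build_index([("g", genome)])
        hits = align_exact(core, idx)
        assert sorted(h.strand for h in hits) == ["+", "-"]
        assert {h.offset for h in hits} == {100, 230}

    def test_absent_read_matches_oracle_zero_hits(self):
        rng = np.random.default_rng(2)
        genome = random_seq(rng, 2000)
        for _ in range(20):
            read = random_seq(rng, 30)
            hits = align_exact(read, idx := build_index([("g", genome)]))
            assert {(h.ref, h.offset, h.strand) for h in hits} == oracle_exact(
                read, [("g", genome)]
            )


class TestAlignHamming:
    def test_one_substitution_hit(self):
        rng = np.random.default_rng(3)
        cons = random_seq(rng, 300)
        read = list(cons[50:80])
        read[12] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[12]]
        hit = align_hamming("".join(read), [("fam", cons)])
        assert (hit.offset, hit.mismatches, hit.strand) == (50, 1, "+")

    def test_best_hit_prefers_fewer_mismatches_across_families(self):
        rng = np.random.default_rng(4)
        a, b = random_seq(rng, 200), random_seq(rng, 200)
        read = list(a[20:50])
        read[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[5]]
        read[9] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[9]]
        mutated = "".join(read)  # 2 mm vs family a
        b = b[:100] + mutated + b[130:]  # 0 mm vs family b, later in order
        hit = align_hamming(mutated, [("a", a), ("b", b)])
        assert hit.ref == "b" and hit.mismatches == 0

    def test_tie_break_is_input_order_then_offset_then_strand(self):
        cons = "ACGTACGTACGTACGTACGTACGT"
        read = cons[:12]
        hit = align_hamming(read, [("x", cons), ("y", cons)])
        assert (hit.ref, hit.offset, hit.strand) == ("x", 0, "+")

    def test_n_counts_as_mismatch(self):
        cons = "ACGTACGTACGTACGTACGT"
        read = "N" + cons[1:15]
        hit = align_hamming(read, [("x", cons)])
        assert hit is not None and hit.mismatches == 1 and hit.offset == 0

    def test_oracle_equivalence_on_random_reads(self):
        """Seed-and-verify search agrees with the exhaustive double-loop
        Hamming oracle, including mutated and reverse-complement reads."""
        rng = np.random.default_rng(5)
        refs = [("c1", random_seq(rng, 400)), ("c2", random_seq(rng, 350))]
        reads = []
        for _ in range(60):
            kind = rng.integers(0, 4)
            L = int(rng.integers(11, 34))
            if kind == 0:
                reads.append(random_seq(rng, L))
            else:
                ci = int(rng.integers(0, 2))
                seq = refs[ci][1]
                off = int(rng.integers(0, len(seq) - L + 1))
                r = list(seq[off : off + L])
                for pos in rng.choice(L, size=int(rng.integers(0, 4)), replace=False):
                    r[pos] = "ACGT"[int(rng.integers(0, 4))]
                read = "".join(r)
                reads.append(read if rng.random() < 0.5 else revcomp(read))
        for read in reads:
            assert align_hamming(read, refs) == oracle_hamming(read, refs)

    def test_exact_search_property_vs_scan_oracle(self):
        rng = np.random.default_rng(6)
        genome = random_seq(rng, 5000)
        idx = build_index([("g", genome)])
        for _ in range(50):
            L = int(rng.integers(11, 36))
            if rng.random() < 0.7:
                off = int(rng.integers(0, len(genome) - L + 1))
                read = genome[off : off + L]
                if rng.random() < 0.5:
                    read = revcomp(read)
            else:
                read = random_seq(rng, L)
            got = {(h.ref, h.offset, h.strand) for h in align_exact(read, idx)}
            assert got == oracle_exact(read, [("g", genome)])


# ------------------------------------------------------------- classify


def tiny_bundle():
    rng = np.random.default_rng(7)
    mirna = random_seq(rng, 22)
    cons = random_seq(rng, 300)
    cluster_seq = random_seq(rng, 200)
    genome = (
        random_seq(rng, 50) + mirna + random_seq(rng, 30) + cons
        + random_seq(rng, 40) + cluster_seq + random_seq(rng, 30)
    )
    cluster_start = 50 + 22 + 30 + 300 + 40
    clusters = [GenomicInterval("g", cluster_start, cluster_start + 200, "+", "cl1")]
    # embed the miRNA inside the consensus too: hierarchy must still win
    cons_with_mirna = cons[:100] + mirna + cons[122:]
    genome = genome.replace(cons, cons_with_mirna)
    return (
        ReferenceBundle(
            mirnas=[("mir1", mirna)],
            genome=[("g", genome)],
            clusters=clusters,
            consensus_set=[("fam1", cons_with_mirna)],
        ),
        genome,
        cluster_start,
        mirna,
        cons_with_mirna,
    )


class TestClassify:
    def test_mirna_wins_over_consensus_hit(self):
        refs, _, _, mirna, _ = tiny_bundle()
        asn = classify("r", mirna, refs)
        assert asn.final_class == "mirna_ncrna"
        assert asn.cluster_id is None and asn.transposon_hit is None

    def test_mirna_matches_either_orientation(self):
        refs, _, _, mirna, _ = tiny_bundle()
        assert classify("r", revcomp(mirna), refs).final_class == "mirna_ncrna"

    def test_unique_cluster_contained_read(self):
        refs, genome, cstart, _, _ = tiny_bundle()
        read = genome[cstart + 10 : cstart + 38]
        asn = classify("r", read, refs)
        assert asn.final_class == "cluster" and asn.cluster_id == "cl1"
        assert asn.genome_hits == 1

    def test_multi_mapping_read_gets_no_cluster(self):
        refs, genome, cstart, _, _ = tiny_bundle()
        read = genome[cstart + 10 : cstart + 38]
        genome2 = genome + read  # second copy outside the cluster
        refs2 = ReferenceBundle(
            mirnas=[], genome=[("g", genome2)], clusters=refs.clusters,
            consensus_set=refs.consensus_set,
        )
        asn = classify("r", read, refs2)
        assert asn.genome_hits == 2 and asn.cluster_id is None
        assert asn.final_class == "genome_other"

    def test_consensus_only_read_with_mismatches(self):
        refs, _, _, _, cons = tiny_bundle()
        read = list(cons[200:228])
        read[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[3]]
        read[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[20]]
        asn = classify("r", "".join(read), refs)
        assert asn.final_class == "transposon_only"
        assert asn.genome_hits == 0
        assert asn.transposon_hit.mismatches == 2

    def test_unmapped_read(self):
        refs, *_ = tiny_bundle()
        asn = classify("r", "TTTTTTTTTTTTTTTTTTTTAAAAAAAAAA", refs)
        assert asn.final_class == "unmapped"

    def test_partition_every_read_exactly_one_class(self, small_assignments):
        for df in small_assignments.values():
            assert df["final_class"].isin(
                ["mirna_ncrna", "cluster", "transposon_only", "genome_other", "unmapped"]
            ).all()
            assert df["final_class"].value_counts().sum() == len(df)

    def test_strand_consistency_mirror_assignments(self):
        """Classifying every read's RC against the RC'd reference world
        yields the same final classes."""
        refs, genome, cstart, mirna, cons = tiny_bundle()
        n = len(genome)
        flipped = ReferenceBundle(
            mirnas=[("mir1", revcomp(mirna))],
            genome=[("g", revcomp(genome))],
            clusters=[
                GenomicInterval("g", n - c.end, n - c.start, "-", c.name)
                for c in refs.clusters
            ],
            consensus_set=[("fam1", revcomp(cons))],
        )
        rng = np.random.default_rng(8)
        reads = [mirna, genome[cstart + 5 : cstart + 33], cons[40:70]]
        reads += [random_seq(rng, 28) for _ in range(5)]
        for read in reads:
            a = classify("r", read, refs)
            b = classify("r", revcomp(read), flipped)
            assert a.final_class == b.final_class

    def test_truth_recovery_on_synthetic_library(self, small_assignments):
        """>= 99% of non-degradation reads get the class their generative
        origin dictates (exact substring construction)."""
        expected = {
            "mirna": "mirna_ncrna",
            "cluster_primary": "cluster",
            "pingpong_guide": "transposon_only",
            "pingpong_responder": "transposon_only",
            "byproduct": "transposon_only",
        }
        for df in small_assignments.values():
            sel = df[df["true_class"] != "degradation"]
            want = sel["true_class"].map(expected)
            assert (sel["final_class"] == want).mean() >= 0.99
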