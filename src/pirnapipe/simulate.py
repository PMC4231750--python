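"""Synthetic fetal small-RNA library generator.

Emulates the statistical structure of paired wild-type / knockout E16.5
testis small-RNA libraries: an abundant miRNA background, cluster-derived
primary piRNAs (24-33 nt, strong 1U bias), transposon-derived ping-pong
pairs whose 5' ends overlap by exactly 10 bp on opposite strands of a
consensus (mechanistic 10A on responders when the guide starts with U),
captured slicer byproducts (upstream cleavage fragments of length
guide - 10 whose coordinates obey the two adjacency rules the linkage
analysis tests), and a uniform degradation class as null background.
Knockout libraries scale expected class counts by a per-class,
per-length-window depletion profile; two presets mirror the published
mutant phenotypes (uniform ~3-fold loss of 24-33-nt piRNAs, or loss
confined to the 28-32-nt window).

Every read is an exact substring of the synthetic genome (reverse
complemented for - strand), so the mapping stage can recover the true
class of every non-degradation read. All randomness flows from a single
integer seed; identical seed + config produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import CleanRead, GenomicInterval, revcomp, write_bed, write_fasta, write_fastq

BASES = "ACGT"

DEFAULT_FAMILY_NAMES = ("L1A_like", "L1Gf_like", "IAP_like")

#: Primary piRNA length distribution over 24-33 nt, bimodal at 26 and 29
#: (the MILI- and MIWI2-favoured sizes).
DEFAULT_PRIMARY_LENGTHS = {
    24: 0.04, 25: 0.08, 26: 0.20, 27: 0.12, 28: 0.12,
    29: 0.20, 30: 0.10, 31: 0.07, 32: 0.05, 33: 0.02,
}

#: Secondary (responder) piRNA lengths, single mode at 29 nt.
DEFAULT_RESPONDER_LENGTHS = {
    24: 0.02, 25: 0.03, 26: 0.06, 27: 0.08, 28: 0.15,
    29: 0.30, 30: 0.16, 31: 0.10, 32: 0.07, 33: 0.03,
}

TRUE_CLASSES = (
    "mirna",
    "cluster_primary",
    "pingpong_guide",
    "pingpong_responder",
    "byproduct",
    "degradation",
)

GENOTYPES = ("WT", "KO")

PIRNA_CLASSES = ("cluster_primary", "pingpong_guide", "pingpong_responder")


class SimulationError(ValueError):
    pass


class SizingError(SimulationError):
    """Requested features do not fit in the genome."""


@dataclass(frozen=True)
class DepletionRule:
    """Scale factor applied to a true class within a length window."""

    classes: tuple[str, ...]
    min_length: int
    max_length: int
    factor: float


@dataclass(frozen=True)
class DepletionProfile:
    """Per-genotype expected-count scaling; WT is always 1.0."""

    name: str
    ko_rules: tuple[DepletionRule, ...]

    def factor(self, genotype: str, true_class: str, length: int) -> float:
        if genotype not in GENOTYPES:
            raise SimulationError(f"unknown genotype label {genotype!r}")
        if genotype == "WT":
            return 1.0
        for rule in self.ko_rules:
            if true_class in rule.classes and rule.min_length <= length <= rule.max_length:
                return rule.factor
        return 1.0

    @classmethod
    def preset(cls, name: str) -> "DepletionProfile":
        """'hsp90a': 1/3 on all 24-33-nt piRNA classes (miRNA untouched);
        'fkbp6': 1/3 confined to the 28-32-nt window; 'none': flat."""
        if name == "hsp90a":
            return cls(name, (DepletionRule(PIRNA_CLASSES, 24, 33, 1 / 3),))
        if name == "fkbp6":
            return cls(name, (DepletionRule(PIRNA_CLASSES, 28, 32, 1 / 3),))
        if name == "none":
            return cls(name, ())
        raise SimulationError(f"unknown depletion preset {name!r}")


@dataclass
class SimulationConfig:
    seed: int = 7
    genome_length: int = 200_000
    n_clusters: int = 5
    cluster_length_range: tuple[int, int] = (3_000, 8_000)
    n_transposon_families: int = 3
    family_names: tuple[str, ...] = DEFAULT_FAMILY_NAMES
    consensus_length_range: tuple[int, int] = (5_000, 7_000)
    copies_per_family: int = 4
    n_mirnas: int = 50
    mirna_length_range: tuple[int, int] = (20, 23)
    depth: int = 200_000
    class_mix: dict = field(
        default_factory=lambda: {
            "mirna": 0.40,
            "cluster_primary": 0.20,
            "pingpong": 0.30,
            "degradation": 0.10,
        }
    )
    u1_bias: float = 0.85
    primary_length_dist: dict = field(default_factory=lambda: dict(DEFAULT_PRIMARY_LENGTHS))
    responder_length_dist: dict = field(
        default_factory=lambda: dict(DEFAULT_RESPONDER_LENGTHS)
    )
    guide_lengths: tuple[int, ...] = (26, 29)
    p_byproduct: float = 0.15
    depletion: DepletionProfile = field(default_factory=lambda: DepletionProfile.preset("hsp90a"))
    pingpong_sites_per_family: int = 40
    degradation_length_range: tuple[int, int] = (11, 35)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.depth <= 0:
            raise SimulationError("depth must be > 0")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise SimulationError("class_mix must sum to 1")
        for p in (self.u1_bias, self.p_byproduct):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("probabilities must lie in [0, 1]")
        if not set(self.guide_lengths) <= set(range(24, 34)):
            raise SimulationError("guide_lengths must lie within 24-33 nt")
        for dist in (self.primary_length_dist, self.responder_length_dist):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise SimulationError("length distributions must sum to 1")
            if not set(dist) <= set(range(24, 34)):
                raise SimulationError("piRNA lengths must lie within 24-33 nt")
        if self.n_transposon_families > len(self.family_names):
            raise SimulationError("not enough family names configured")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["depletion"] = {
            "name": self.depletion.name,
            "ko_rules": [dataclasses.asdict(r) for r in self.depletion.ko_rules],
        }
        return d


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth provenance of one simulated read.

    Coordinates are on the genome for cluster/degradation reads, on the
    family consensus for ping-pong and byproduct reads, and on the mature
    miRNA for miRNA reads.
    """

    read_id: str
    true_class: str
    ref: str
    start: int
    end: int
    strand: str
    feature: str
    guide_length: Optional[int] = None


@dataclass
class SyntheticReference:
    chrom: str
    genome: str
    clusters: list[GenomicInterval]
    consensus: list[tuple[str, str]]
    insertions: list[GenomicInterval]  # name = family
    mirnas: list[tuple[str, str]]
    mirna_loci: list[GenomicInterval]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


class _Placer:
    """Rejection-samples non-overlapping feature intervals."""

    def __init__(self, genome_length: int, rng: np.random.Generator):
        self.genome_length = genome_length
        self.rng = rng
        self.occupied: list[tuple[int, int]] = []

    def place(self, length: int, tries: int = 2000) -> int:
        if length > self.genome_length:
            raise SizingError("feature longer than genome")
        for _ in range(tries):
            start = int(self.rng.integers(0, self.genome_length - length + 1))
            end = start + length
            if all(end <= s or start >= e for s, e in self.occupied):
                self.occupied.append((start, end))
                return start
        raise SizingError(
            "could not place feature; total feature length exceeds genome capacity"
        )


def build_reference(config: SimulationConfig) -> SyntheticReference:
    """Deterministically build genome, clusters, consensus insertions and
    embedded miRNAs from the config seed.

    Consensus copies are written verbatim into the genome (reverse
    complemented for - strand insertions); miRNA loci and clusters never
    overlap insertions or each other.
    """
    rng = np.random.default_rng([config.seed, 11])
    n_fam = config.n_transposon_families
    fam_names = list(config.family_names[:n_fam])

    cluster_lengths = [
        int(rng.integers(*config.cluster_length_range, endpoint=True))
        for _ in range(config.n_clusters)
    ]
    consensus = [
        (fam_names[i], _random_seq(rng, int(rng.integers(*config.consensus_length_range, endpoint=True))))
        for i in range(n_fam)
    ]
    mirna_lengths = [
        int(rng.integers(*config.mirna_length_range, endpoint=True))
        for _ in range(config.n_mirnas)
    ]
    total = (
        sum(cluster_lengths)
        + sum(len(s) for _, s in consensus) * config.copies_per_family
        + sum(mirna_lengths)
    )
    if total > 0.9 * config.genome_length:
        raise SizingError(
            f"features need {total} bases but genome is {config.genome_length}"
        )

    genome = list(_random_seq(rng, config.genome_length))
    placer = _Placer(config.genome_length, rng)

    clusters = []
    for i, length in enumerate(cluster_lengths):
        start = placer.place(length)
        strand = "+" if rng.random() < 0.5 else "-"
        clusters.append(
            GenomicInterval("chr1", start, start + length, strand, f"cluster_{i + 1:02d}")
        )

    insertions = []
    for name, cseq in consensus:
        for _ in range(config.copies_per_family):
            start = placer.place(len(cseq))
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = cseq if strand == "+" else revcomp(cseq)
            genome[start : start + len(cseq)] = inserted
            insertions.append(
                GenomicInterval("chr1", start, start + len(cseq), strand, name)
            )

    mirnas = []
    mirna_loci = []
    for i, length in enumerate(mirna_lengths):
        seq = _random_seq(rng, length)
        start = placer.place(length)
        genome[start : start + length] = seq
        name = f"mir_{i + 1:03d}"
        mirnas.append((name, seq))
        mirna_loci.append(GenomicInterval("chr1", start, start + length, "+", name))

    return SyntheticReference(
        chrom="chr1",
        genome="".join(genome),
        clusters=clusters,
        consensus=consensus,
        insertions=insertions,
        mirnas=mirnas,
        mirna_loci=mirna_loci,
    )


@dataclass(frozen=True)
class PingPongSite:
    """One slicer target site on a consensus.

    The guide piRNA sits on ``guide_strand``; the responder's 5' end lies
    opposite guide position 10 (5'-5' overlap exactly 10 bp). The captured
    byproduct spans from the guide's 3'-end coordinate to one base before
    the responder's 5' start, hence length = guide_length - 10.
    """

    family: str
    guide_strand: str
    guide_start: int
    guide_end: int
    guide_length: int

    @property
    def guide_five_prime(self) -> int:
        return self.guide_start if self.guide_strand == "+" else self.guide_end - 1

    @property
    def responder_strand(self) -> str:
        return "-" if self.guide_strand == "+" else "+"

    @property
    def responder_five_prime(self) -> int:
        # overlap d = fp(-) - fp(+) + 1 = 10
        if self.guide_strand == "+":
            return self.guide_five_prime + 9
        return self.guide_five_prime - 9

    def responder_interval(self, length: int) -> tuple[int, int]:
        fp = self.responder_five_prime
        if self.responder_strand == "+":
            return fp, fp + length
        return fp - length + 1, fp + 1

    def byproduct_interval(self) -> tuple[int, int]:
        # 5' end pinned at the guide's 3'-end coordinate; 3' end abuts the
        # responder's 5' start (same strand as the responder)
        if self.guide_strand == "-":
            return self.guide_start, self.responder_five_prime
        return self.responder_five_prime + 1, self.guide_end


def _biased_choice(
    rng: np.random.Generator, hit: np.ndarray, miss: np.ndarray, p_hit: float
) -> int:
    """Pick a coordinate from `hit` with probability p_hit, else `miss`."""
    use_hit = rng.random() < p_hit
    pool = hit if (use_hit and hit.size) or not miss.size else miss
    return int(pool[rng.integers(0, pool.size)])


def _make_sites(ref: SyntheticReference, config: SimulationConfig) -> list[PingPongSite]:
    """Ping-pong sites shared between genotypes (seeded from config only).

    Guide 5' coordinates are chosen so that the guide's first base is U(T)
    with probability u1_bias; by complementarity the responder's 10th base
    is then A (the mechanistic 10A signature).
    """
    rng = np.random.default_rng([config.seed, 22])
    guide_lengths = list(config.guide_lengths)
    sites: list[PingPongSite] = []
    max_resp = max(config.responder_length_dist, default=33)
    for fam, cseq in ref.consensus:
        arr = np.frombuffer(cseq.encode(), dtype="S1")
        n = len(cseq)
        for i in range(config.pingpong_sites_per_family):
            glen = guide_lengths[i % len(guide_lengths)]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                # s in [max_resp - 9, n - glen]; first base cseq[s] == 'T'
                lo, hi = max_resp - 9, n - glen
                want = b"T"
            else:
                # g5 in [glen - 1, n - max_resp + 8]; complement(cseq[g5]) == 'T'
                lo, hi = glen - 1, n - max_resp + 8
                want = b"A"
            if hi < lo:
                raise SizingError("consensus too short for ping-pong geometry")
            window = arr[lo : hi + 1]
            hit = np.flatnonzero(window == want) + lo
            miss = np.flatnonzero(window != want) + lo
            pos = _biased_choice(rng, hit, miss, config.u1_bias)
            if strand == "+":
                sites.append(PingPongSite(fam, "+", pos, pos + glen, glen))
            else:
                sites.append(PingPongSite(fam, "-", pos - glen + 1, pos + 1, glen))
    return sites


def _cluster_start_pools(
    ref: SyntheticReference,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per cluster: coordinates of the base that becomes the read's first
    nucleotide, split into U-yielding and other positions."""
    garr = np.frombuffer(ref.genome.encode(), dtype="S1")
    pools = {}
    for cl in ref.clusters:
        window = garr[cl.start : cl.end]
        want = b"T" if cl.strand == "+" else b"A"
        hit = np.flatnonzero(window == want) + cl.start
        miss = np.flatnonzero(window != want) + cl.start
        pools[cl.name] = (hit, miss)
    return pools


def expected_class_weights(config: SimulationConfig, genotype: str) -> dict[tuple[str, int], float]:
    """Unnormalised expected sampling weight per (true_class, length) cell.

    miRNA and degradation lengths are resolved at draw time; their cells
    use length 0 as a placeholder.
    """
    dep = config.depletion.factor
    mix = config.class_mix
    cells: dict[tuple[str, int], float] = {}
    cells[("mirna", 0)] = mix["mirna"] * dep(genotype, "mirna", 21)
    for L, p in sorted(config.primary_length_dist.items()):
        cells[("cluster_primary", L)] = mix["cluster_primary"] * p * dep(
            genotype, "cluster_primary", L
        )
    n_guides = len(config.guide_lengths)
    for L in config.guide_lengths:
        cells[("pingpong_guide", L)] = (
            mix["pingpong"] * 0.5 / n_guides * dep(genotype, "pingpong_guide", L)
        )
    for L, p in sorted(config.responder_length_dist.items()):
        cells[("pingpong_responder", L)] = (
            mix["pingpong"] * 0.5 * p * dep(genotype, "pingpong_responder", L)
        )
    cells[("degradation", 0)] = mix["degradation"]
    return cells


def simulate_library(
    ref: SyntheticReference, config: SimulationConfig, genotype: str
) -> tuple[list[CleanRead], list[TruthRecord]]:
    """Draw one library for the given genotype ('WT' or 'KO').

    Class/length cell counts are multinomial over the depletion-scaled
    expected weights; byproduct reads are emitted on top of `depth`, one
    per responder read with probability p_byproduct.
    """
    if genotype not in GENOTYPES:
        raise SimulationError(f"unknown genotype label {genotype!r}")
    rng = np.random.default_rng([config.seed, 33, GENOTYPES.index(genotype)])
    sites = _make_sites(ref, config)
    sites_by_glen: dict[int, list[PingPongSite]] = {}
    for s in sites:
        sites_by_glen.setdefault(s.guide_length, []).append(s)
    pools = _cluster_start_pools(ref)

    cells = expected_class_weights(config, genotype)
    keys = list(cells)
    probs = np.array([cells[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    counts = rng.multinomial(config.depth, probs)

    reads: list[CleanRead] = []
    truth: list[TruthRecord] = []
    serial = 0

    def emit(seq: str, cls: str, rname: str, start: int, end: int, strand: str,
             feature: str, guide_length: Optional[int] = None) -> None:
        nonlocal serial
        rid = f"{genotype}_{serial:07d}"
        serial += 1
        reads.append(CleanRead(rid, seq, genotype))
        truth.append(TruthRecord(rid, cls, rname, start, end, strand, feature, guide_length))

    genome = ref.genome
    consensus = dict(ref.consensus)

    for (cls, L), n in zip(keys, counts):
        if n == 0:
            continue
        if cls == "mirna":
            for idx in rng.integers(0, len(ref.mirnas), n):
                name, seq = ref.mirnas[int(idx)]
                emit(seq, "mirna", name, 0, len(seq), "+", name)
        elif cls == "cluster_primary":
            cl_idx = rng.integers(0, len(ref.clusters), n)
            for ci in cl_idx:
                cl = ref.clusters[int(ci)]
                hit, miss = pools[cl.name]
                if cl.strand == "+":
                    lo, hi = cl.start, cl.end - L
                else:
                    lo, hi = cl.start + L - 1, cl.end - 1
                h = hit[(hit >= lo) & (hit <= hi)]
                m = miss[(miss >= lo) & (miss <= hi)]
                pos = _biased_choice(rng, h, m, config.u1_bias)
                start, end = (pos, pos + L) if cl.strand == "+" else (pos - L + 1, pos + 1)
                seq = genome[start:end]
                if cl.strand == "-":
                    seq = revcomp(seq)
                emit(seq, "cluster_primary", ref.chrom, start, end, cl.strand, cl.name)
        elif cls == "pingpong_guide":
            pool = sites_by_glen[L]
            for si in rng.integers(0, len(pool), n):
                site = pool[int(si)]
                seq = consensus[site.family][site.guide_start : site.guide_end]
                if site.guide_strand == "-":
                    seq = revcomp(seq)
                emit(seq, "pingpong_guide", site.family, site.guide_start,
                     site.guide_end, site.guide_strand, site.family, site.guide_length)
        elif cls == "pingpong_responder":
            site_idx = rng.integers(0, len(sites), n)
            capture = rng.random(n) < config.p_byproduct
            for si, cap in zip(site_idx, capture):
                site = sites[int(si)]
                start, end = site.responder_interval(int(L))
                seq = consensus[site.family][start:end]
                if site.responder_strand == "-":
                    seq = revcomp(seq)
                emit(seq, "pingpong_responder", site.family, start, end,
                     site.responder_strand, site.family, site.guide_length)
                if cap:
                    bstart, bend = site.byproduct_interval()
                    bseq = consensus[site.family][bstart:bend]
                    if site.responder_strand == "-":
                        bseq = revcomp(bseq)
                    emit(bseq, "byproduct", site.family, bstart, bend,
                         site.responder_strand, site.family, site.guide_length)
        elif cls == "degradation":
            lo, hi = config.degradation_length_range
            lens = rng.integers(lo, hi, n, endpoint=True)
            for dl in lens:
                dl = int(dl)
                start = int(rng.integers(0, len(genome) - dl + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                seq = genome[start : start + dl]
                if strand == "-":
                    seq = revcomp(seq)
                emit(seq, "degradation", ref.chrom, start, start + dl, strand, "")
    return reads, truth


TRUTH_COLUMNS = (
    "read_id", "true_class", "ref", "start", "end", "strand", "feature", "guide_length",
)


def write_truth(truth: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            gl = "" if t.guide_length is None else str(t.guide_length)
            out.write(
                f"{t.read_id}\t{t.true_class}\t{t.ref}\t{t.start}\t{t.end}\t"
                f"{t.strand}\t{t.feature}\t{gl}\n"
            )


def write_reference(ref: SyntheticReference, outdir) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "genome": str(outdir / "genome.fa"),
        "transposons": str(outdir / "transposons.fa"),
        "mirnas": str(outdir / "mirnas.fa"),
        "clusters": str(outdir / "clusters.bed"),
        "insertions": str(outdir / "insertions.bed"),
    }
    write_fasta([(ref.chrom, ref.genome)], files["genome"])
    write_fasta(ref.consensus, files["transposons"])
    write_fasta(ref.mirnas, files["mirnas"])
    write_bed(ref.clusters, files["clusters"])
    write_bed(ref.insertions, files["insertions"])
    return files


def write_library(
    reads: Sequence[CleanRead],
    truth: Sequence[TruthRecord],
    ref: SyntheticReference,
    outdir,
    label: str,
    adapter: Optional[str] = None,
) -> dict[str, str]:
    """Write FASTQ + truth TSV for one library and the shared references.

    When ``adapter`` is given, it is appended in full to every read so the
    clipping stage can be exercised end to end.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = write_reference(ref, outdir)
    fastq = outdir / f"{label}.fastq"
    suffix = adapter or ""
    write_fastq(((r.id, r.sequence + suffix) for r in reads), fastq)
    truth_path = outdir / f"{label}_truth.tsv"
    write_truth(truth, truth_path)
    files["fastq"] = str(fastq)
    files["truth"] = str(truth_path)
    return files
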