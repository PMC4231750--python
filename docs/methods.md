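# Methods

## Pipeline model

The analysis reproduces a classic fetal small-RNA workflow. Reads are
3′-adapter-clipped and filtered to inserts of **more than 10 bp** (kept
length ≥ 11 nt, the strict reading), then classified hierarchically:

1. **miRNA/ncRNA** — exact, full-length match to the miRNA set, either
   orientation. Matching stops here; the miRNA count is the normalisation
   denominator (`norm = raw × 10⁶ / miRNA_total`).
2. **Genome** — every exact occurrence on both strands (no mismatches). A
   read is *cluster-derived* iff it has exactly one genome hit and that hit
   is fully contained in one annotated piRNA-cluster interval. Containment,
   not overlap, was chosen for boundary reads; multi-mappers never count.
3. **Transposon consensus** — gapless Hamming comparison of the read and its
   reverse complement at every offset of every consensus, at most 2
   substitutions (no indels, matching 50-bp-chemistry practice). One best
   hit per read: fewest mismatches, then consensus input order, smaller
   offset, + before −. `N` matches nothing. Consensus mapping is applied to
   all non-miRNA reads, not only genome-unmapped ones, since consensus-based
   piRNA analyses must include genome-mappable transposon copies.

Reporting precedence is cluster > transposon-only > genome-other > unmapped;
each read gets exactly one final class, while the transposon hit is recorded
independently for the consensus-based analyses.

Alignment is seed-and-verify: an 11-mer index for exact genome search (the
first k-mer of the read seeds every exact occurrence; references shorter
than k are scanned directly), and a pigeonhole split into `max_mm + 1`
segments for the mismatch-tolerant search — any qualifying placement leaves
one segment intact, so the search is complete. Both are checked against
brute-force scan oracles in the test suite. Throughput is ~6,000 reads/s on
one core against the default synthetic references; the mapper is deliberately
desk-scale (no genome-size engineering).

## Statistics

- **Overlap histogram.** For each transposon family, all-vs-all pairs of
  24–33-nt reads on opposite strands at
  `d = five′(−) − five′(+) + 1`, d ∈ [1, 30], weighted by multiplicity
  (reads are never collapsed to unique sequences). d = 10 is the ping-pong
  configuration. The all-vs-all definition (not nearest-neighbour) matches
  standard population-level ping-pong histograms.
- **Nucleotide bias.** Base fractions at read positions 1 and 10 on the
  read's own sequence (a mismatched base belongs to the RNA, not the
  reference); reads with N at the queried position are excluded from the
  denominator and reported.
- **Feature counts.** Per-cluster and per-family 24–33-nt counts, normalised
  per million miRNA reads per library; `fold = WT_norm / KO_norm`, flagged
  at fold ≥ 3.0 (inclusive, for determinism); fold is reported as undefined
  when the KO count is zero.
- **Byproduct linkage.** For each 11–23-nt consensus-mapped read: rule A
  (required) — a same-strand 24–33-nt read starts exactly at its 3′ end
  (half-open adjacency; on the − strand this is `piRNA.end == short.start`);
  rule B (recorded) — an opposite-strand 24–33-nt read's 3′-end coordinate
  equals the short read's 5′ coordinate; that read is the candidate guide,
  preferring one whose 5′–5′ overlap with the downstream piRNA is exactly
  10. For dual-rule links with d = 10 the identity
  `short length = guide length − 10` is geometric. The summary reports the
  A10 fraction of downstream piRNAs for rule-A and dual-rule links
  separately (the analysis does not resolve which conditioning the published
  79 % figure used, so both are given).
- **Window depletion.** KO/WT normalised ratios in the MILI (24–27 nt) and
  MIWI2 (28–32 nt) windows for the cluster and transposon classes.

## Synthetic libraries

The generator emulates a paired WT/KO E16.5-testis-like library set on a
desk-scale reference world: a 200-kb random genome carrying 5 stranded
piRNA clusters (3–8 kb), 3 transposon families (5–7-kb consensus, 4
verbatim insertions each, random strand) and 50 embedded miRNAs (20–23 nt);
all features disjoint. Per library (default 200,000 reads): 40 % miRNA,
20 % cluster-primary, 30 % ping-pong, 10 % degradation. Class/length cell
counts are multinomial over depletion-scaled expected weights, so realised
counts are exact multinomial draws around the configured mix.

- *Cluster-primary* reads are genomic substrings of a cluster on its
  strand; lengths follow a bimodal 24–33 distribution peaking at 26 and 29;
  the start is chosen so the first base is U(T) with probability
  `u1_bias = 0.85`, which keeps every read an exact genomic substring.
- *Ping-pong* reads come from 40 sites per family. Each site fixes a guide
  (26 or 29 nt, either strand, first base U with probability `u1_bias` via
  site placement) and the responder 5′ end opposite guide position 10
  (5′–5′ overlap exactly 10). The responder's 10th base is therefore the
  complement of the guide's first base — the 10A signature is mechanistic,
  not painted on, and its sampling unit is the site (n = 120), not the read.
- *Byproducts* are emitted with probability `p_byproduct = 0.15` per
  responder read, on top of the configured depth so the four-class mix stays
  exact: the fragment spans from the guide's 3′-end coordinate to one base
  before the responder's 5′ start (length = guide − 10), pinned to that
  configuration so the linkage rules are exactly recoverable. Byproducts
  ride along responders, so the KO library loses them proportionally.
- *Degradation* reads are uniform random genomic substrings (11–35 nt,
  random strand): a null class that cannot produce a coherent ping-pong
  signal.
- *Depletion presets.* `hsp90a`: KO expected counts × 1/3 for all 24–33-nt
  piRNA classes; `fkbp6`: × 1/3 confined to 28–32 nt; miRNAs untouched.
  Total depth is held fixed, so raw KO counts of undepleted classes inflate
  — exactly why all comparisons normalise per million miRNA reads.

Reads are written as 4-line FASTQ (constant quality `I`; the analysis never
uses quality), DNA alphabet (T for U), optionally with the TruSeq small-RNA
3′ adapter appended in full to exercise clipping. References go to FASTA
(70-column wrap) and BED6; ground truth to TSV. Identical seed + config
give byte-identical files.

**What the generator does not model:** sequencing errors, PCR duplicates,
isomiRs, diverged transposon copies (insertions match their consensus
exactly), piRNA-loading kinetics, chromatin or DNA methylation. Passing
tests therefore demonstrate correctness of the *measurement machinery* on
data with the assumed generative structure, not performance on real
libraries — e.g. real consensus mapping exercises the 2-mismatch tolerance
far more than the synthetic reads do (the tolerance is instead covered by
oracle-equivalence tests on mutated reads).

## Calibration of expectations

Two systematic effects matter when comparing pipeline output with the
configured parameters:

- The 10 % degradation class contributes *undepleted* background: 24–33-nt
  degradation reads inside insertions (or uniquely inside clusters) are
  classified like piRNAs in both libraries. The analytic end-to-end
  expectation is therefore a median fold of ≈ 2.75 (transposon) / ≈ 2.86
  (cluster) rather than exactly 3.0, and a 28–32-nt KO/WT ratio of ≈ 0.355
  rather than 1/3. Tests assert the pipeline against these derived
  expectations (and the truth-restricted piRNA classes against the exact
  1/3), mirroring how a "∼3-fold" reduction reads on real data.
- The observed 1U fraction of cluster-classified reads (~0.83) is the
  configured 0.85 diluted by the same background; truth-selected
  cluster-primary reads recover 0.85 within binomial error.

## Problem sizes and tolerances

Defaults are the study conditions: 200,000 reads/library for signature and
recovery analyses (the depth at which the 10 % fold-change tolerance is
assessed, over seeds 7/8/9), 40,000 reads for the byproduct-arithmetic runs
(the quantities there are exact geometry, not estimates). Binomial checks
use 3 SD at the appropriate sampling unit (reads for 1U, ping-pong sites
for 10A); class-mix calibration uses 4 SD. The multinomial/delta-method SD
for window ratios treats category counts as independent Poisson, which is
slightly conservative under the fixed-depth constraint.

## Known limitations

Single-chromosome reference world; no gapped or spliced alignment; no
mapping-quality model; no significance testing on the ping-pong signal (a
z-score was deliberately left out of scope); the CLI holds whole libraries
in memory (fine up to a few million reads).
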