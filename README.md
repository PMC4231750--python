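# pirnapipe

Small-RNA sequencing analysis of fetal piRNA biogenesis defects, built as a
tested, reusable pipeline with a matched synthetic-data generator.

## The scientific problem

In fetal mouse male germ cells, PIWI-interacting RNAs (piRNAs, 24–33 nt)
silence transposons. Primary piRNAs arise from piRNA-cluster transcripts and
carry a strong uracil bias at position 1 (1U). A PIWI protein loaded with a
piRNA cleaves complementary transposon RNA between guide positions 10 and 11,
producing a secondary piRNA whose 5′ end overlaps the guide's 5′ end by
exactly 10 bp and which carries adenine at position 10 (10A) — the
*ping-pong* signature. The upstream fragment of the cleaved target is a
slicer byproduct: its 3′ end abuts the new piRNA's 5′ end, and when its 5′
end coincides with the guide's 3′ end its length is *guide − 10* (16 nt for
26-nt guides, 19 nt for 29-nt guides).

Comparing a knockout to its wild-type control requires: hierarchical read
classification (miRNA/ncRNA first, then genome with no mismatches — unique
hits feed the cluster analysis — then transposon consensus sequences with up
to 2 substitutions), normalisation *per million miRNA reads*
(`norm = raw × 10⁶ / miRNA_total`), per-cluster and per-family WT/KO fold
changes against a 3-fold reference line, 5′–5′ overlap histograms
(`d = five′(−) − five′(+) + 1`, hallmark at d = 10), 1st/10th-position
nucleotide bias, byproduct linkage, and KO/WT depletion ratios in the
MILI-bound (24–27 nt) and MIWI2-bound (28–32 nt) size windows.

The package is aimed at people analysing (or teaching the analysis of)
germline small-RNA libraries who want every one of those steps as an
importable, unit-tested function, plus a generator of ground-truthed
synthetic libraries on which the whole pipeline is verifiable end to end.

## Layout

- `src/pirnapipe/` — the library: `simulate` (synthetic WT/KO libraries with
  truth tables), `io` (FASTQ/FASTA/BED, adapter clipping, >10 bp filter),
  `mapping` (k-mer exact matcher, pigeonhole ≤2-mismatch Hamming search,
  hierarchical classifier), `stats` (all signature statistics), `cli`
  (subcommand pipeline).
- `analysis/` — numbered narrative drivers: simulate → process → ping-pong
  signatures → depletion comparison.
- `tests/` — unit, property and end-to-end acceptance tests.
- `scripts/acceptance.py` — recomputes the headline structural numbers.

## Worked example

```sh
pirnapipe simulate --preset hsp90a --adapter-mode --out sim/
pirnapipe process --fastq sim/WT.fastq --refs sim/ --label WT --out proc/
pirnapipe process --fastq sim/KO.fastq --refs sim/ --label KO --out proc/
pirnapipe compare --wt proc/assignments_WT.tsv --ko proc/assignments_KO.tsv --out cmp/
```

or equivalently `python analysis/01_simulate_libraries.py` … `04_…`. On the
default configuration (seed 7, 200,000 reads/library) the drivers print:

```
WT L1A_like: overlap mode d=10, 83% of pair mass at d=10
WT: 4415 dual-rule byproduct links (A10 association 83%),
    short/guide pairs dominated by 16/26 (2202) and 19/29 (2204)
WT cluster piRNAs pos 1: T 0.83
[hsp90a] median WT/KO fold: cluster=2.86, transposon=2.77
[hsp90a] cluster 24-27: KO/WT = 0.35   28-32: KO/WT = 0.35
[fkbp6]  cluster 24-27: KO/WT = 1.00   28-32: KO/WT = 0.35
```

Reading: every transposon family shows the 10-bp ping-pong overlap mode;
byproduct linkage recovers the 16 = 26 − 10 and 19 = 29 − 10 arithmetic; the
1U bias of cluster piRNAs is recovered (0.83 observed vs 0.85 simulated,
diluted by background reads inside clusters); uniform depletion reduces both
size windows ~3-fold, while the window-confined preset spares 24–27-nt
piRNAs — the signature distinguishing the two mutant phenotypes. Fold
changes sit slightly below 3.0 because the 10% degradation class contributes
undepleted background in both libraries (see `docs/methods.md`).

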