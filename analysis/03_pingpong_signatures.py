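#!/usr/bin/env python
"""Ping-pong signature analysis of the processed libraries.

For each library and transposon family: the 5'-5' overlap-distance
histogram (ping-pong hallmark: mode at 10 bp), 1st/10th-position
nucleotide bias of 24-33-nt reads, strand-separated length
distributions, and the 16/19-nt slicer-byproduct linkage scan. Tables go
to results/analysis/; a short narrative is printed.
"""

import json
from pathlib import Path

import pandas as pd

from pirnapipe import stats
from pirnapipe.cli import load_assignments

PROCDIR = Path("scratch/analysis/proc")
OUTDIR = Path("results/analysis")


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    dfs = {lab: load_assignments(PROCDIR / f"assignments_{lab}.tsv") for lab in ("WT", "KO")}

    hist_rows, byp = [], {}
    for lab, df in dfs.items():
        families = sorted(df["family"].dropna().unique())
        for fam in families:
            hist = stats.overlap_histogram(df, fam)
            mode, frac = int(hist.idxmax()), hist[10] / max(hist.sum(), 1)
            print(f"{lab} {fam}: overlap mode d={mode}, {frac:.0%} of pair mass at d=10")
            for d, c in hist.items():
                hist_rows.append({"library": lab, "family": fam, "d": d, "count": c})
        links, summary = stats.byproduct_scan(df)
        byp[lab] = summary
        print(
            f"{lab}: {summary['n_dual_rule_d10']} dual-rule byproduct links "
            f"(A10 association {summary['frac_A10_ruleA']:.0%}), "
            f"short/guide pairs {summary['pair_counts']}"
        )
        sel = df[(df["final_class"] == "cluster") & df["length"].between(24, 33)]
        for nb in stats.first_tenth_bias(sel):
            top = max(nb.fractions, key=nb.fractions.get)
            print(f"{lab} cluster piRNAs pos {nb.position}: {top} {nb.fractions[top]:.2f}")

    pd.DataFrame(hist_rows).to_csv(OUTDIR / "overlap_histograms.tsv", sep="\t", index=False)
    with open(OUTDIR / "byproduct_summary.json", "w") as fh:
        json.dump(byp, fh, indent=2, sort_keys=True)
    lengths = stats.length_distribution(
        pd.concat(dfs.values()), group_by=("library", "final_class", "t_strand")
    )
    lengths.to_csv(OUTDIR / "length_distributions.tsv", sep="\t", index=False)
    print(f"tables written to {OUTDIR}/")


if __name__ == "__main__":
    main()
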