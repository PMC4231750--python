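#!/usr/bin/env python
"""WT/KO depletion comparison, per feature and per size window.

Part 1 uses the processed uniform-depletion (Hsp90a-like) pair: per-
cluster and per-family normalised counts with WT/KO fold changes (the
3-fold scatter comparison) and KO/WT ratios in the MILI (24-27 nt) and
MIWI2 (28-32 nt) windows. Part 2 simulates and processes a window-
confined (Fkbp6-like) pair in memory to contrast the two depletion
signatures. Tables go to results/analysis/.
"""

from pathlib import Path

from pirnapipe import SimulationConfig, build_reference, simulate_library
from pirnapipe.cli import load_assignments, process_reads
from pirnapipe.mapping import ReferenceBundle
from pirnapipe.simulate import DepletionProfile
from pirnapipe import stats

PROCDIR = Path("scratch/analysis/proc")
OUTDIR = Path("results/analysis")


def report(tag: str, wt, ko) -> None:
    feats = stats.feature_counts(wt, ko)
    feats.to_csv(OUTDIR / f"feature_counts_{tag}.tsv", sep="\t", index=False, na_rep="NA")
    med = feats.groupby("feature_type")["fold"].median()
    print(f"[{tag}] median WT/KO fold: " +
          ", ".join(f"{k}={v:.2f}" for k, v in med.items()))
    depl = stats.depletion_by_window(wt, ko)
    depl.to_csv(OUTDIR / f"depletion_windows_{tag}.tsv", sep="\t", index=False, na_rep="NA")
    for _, row in depl.iterrows():
        print(f"[{tag}] {row['class']:>10} {row['window']}: KO/WT = {row['ko_wt_ratio']:.2f}")


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    wt = load_assignments(PROCDIR / "assignments_WT.tsv")
    ko = load_assignments(PROCDIR / "assignments_KO.tsv")
    report("hsp90a", wt, ko)

    cfg = SimulationConfig(seed=7, depletion=DepletionProfile.preset("fkbp6"))
    ref = build_reference(cfg)
    bundle = ReferenceBundle(
        mirnas=ref.mirnas, genome=[(ref.chrom, ref.genome)],
        clusters=ref.clusters, consensus_set=ref.consensus,
    )
    pair = {}
    for g in ("WT", "KO"):
        reads, _ = simulate_library(ref, cfg, g)
        pair[g] = process_reads(reads, bundle, g)
    report("fkbp6", pair["WT"], pair["KO"])


if __name__ == "__main__":
    main()
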