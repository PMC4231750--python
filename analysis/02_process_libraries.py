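#!/usr/bin/env python
"""Clip, length-filter and hierarchically classify both libraries.

Reads the simulated FASTQ pair from scratch/analysis/sim/ (run
01_simulate_libraries.py first) and writes per-read assignment tables and
stage-count manifests to scratch/analysis/proc/. Prints the read fate at
every stage: the counts must be conserved (input = dropped + retained).
"""

from pathlib import Path

from pirnapipe.cli import run_process

SIMDIR = Path("scratch/analysis/sim")
OUTDIR = Path("scratch/analysis/proc")


def main() -> None:
    for label in ("WT", "KO"):
        _df, manifest = run_process(SIMDIR / f"{label}.fastq", SIMDIR, label, OUTDIR)
        counts = manifest["stage_counts"]
        print(f"--- {label}")
        for stage in ("input", "dropped_no_adapter", "clipped", "dropped_short", "retained"):
            print(f"{stage:>20}: {counts[stage]}")
        for cls, n in counts["classes"].items():
            print(f"{cls:>20}: {n}")


if __name__ == "__main__":
    main()
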