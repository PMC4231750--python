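"""Ping-pong and piRNA population statistics.

All operations consume a per-read assignment table (one row per read, with
multiplicity — no collapsing to unique sequences) carrying the columns
produced by the processing stage:

    read_id, library, length, sequence, final_class, mirna_name,
    genome_hits, genome_offset, genome_strand, cluster_id,
    family, t_strand, t_offset, t_mm

Conventions: read coordinates are 0-based half-open on the mapped
reference; for a + strand read the 5' end is ``offset`` and for a - strand
read it is ``offset + length - 1``. The 5'-5' overlap distance between a
sense and an antisense read sharing a reference is

    d = five_prime(-) - five_prime(+) + 1

so the ping-pong hallmark (guide position 10 opposite the responder 5'
end) appears as d = 10. Nucleotide bias is measured on the read's own
sequence, not the reference. Counts are normalised per million miRNA
reads of the same library before any cross-library comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

PIRNA_WINDOW = (24, 33)
SHORT_WINDOW = (11, 23)
MILI_WINDOW = (24, 27)
MIWI2_WINDOW = (28, 32)
DEFAULT_GUIDE_LENGTHS = (26, 29)
LENGTH_RANGE = (11, 35)


class StatsError(ValueError):
    pass


def five_prime_positions(offsets: np.ndarray, lengths: np.ndarray, strands: np.ndarray) -> np.ndarray:
    """Vector of 5'-end coordinates for reads on a shared reference."""
    fp = offsets.copy()
    minus = strands == "-"
    fp[minus] = offsets[minus] + lengths[minus] - 1
    return fp


def length_distribution(
    df: pd.DataFrame,
    group_by: Sequence[str] = ("library", "final_class"),
    lengths: tuple[int, int] = LENGTH_RANGE,
) -> pd.DataFrame:
    """Read-length histograms, one per group, all lengths always present.

    ``group_by`` may reference any assignment column (e.g. ``t_strand``
    for consensus-based strand-separated histograms, ``genome_strand`` for
    cluster-based ones). Groups observed in the table are emitted even
    when a length bin is empty.
    """
    for key in group_by:
        if key not in df.columns:
            raise StatsError(f"unknown grouping key {key!r}")
    lo, hi = lengths
    bins = range(lo, hi + 1)
    if df.empty:
        return pd.DataFrame(columns=[*group_by, "length", "count"])
    counts = (
        df.groupby([*group_by], dropna=False, observed=True)["length"]
        .value_counts()
        .rename("count")
    )
    groups = counts.index.droplevel("length").unique()
    full = pd.MultiIndex.from_tuples(
        [
            (*(g if isinstance(g, tuple) else (g,)), L)
            for g in groups
            for L in bins
        ],
        names=[*group_by, "length"],
    )
    out = counts.reindex(full, fill_value=0).reset_index()
    return out


@dataclass(frozen=True)
class NucleotideBias:
    """Base fractions at a 1-based read position (N-bearing reads excluded)."""

    position: int
    fractions: dict
    n_used: int
    n_excluded: int


def first_tenth_bias(df: pd.DataFrame, positions: tuple[int, ...] = (1, 10)) -> list[NucleotideBias]:
    """Base composition at the 1st and 10th read positions.

    Callers restrict ``df`` to the window/class of interest (typically
    24-33-nt reads of one class); every read must cover the queried
    positions. Raises on empty input (no denominator).
    """
    if df.empty:
        raise StatsError("no reads selected; nucleotide bias undefined")
    out = []
    seqs = df["sequence"].to_numpy()
    for pos in positions:
        if (df["length"] < pos).any():
            raise StatsError(f"reads shorter than position {pos}")
        bases = np.array([s[pos - 1] for s in seqs])
        keep = bases != "N"
        used = bases[keep]
        if used.size == 0:
            raise StatsError(f"all reads have N at position {pos}")
        fractions = {b: float((used == b).mean()) for b in "ACGT"}
        out.append(NucleotideBias(pos, fractions, int(used.size), int((~keep).sum())))
    return out


def mirna_total(df: pd.DataFrame, mirna_names: Optional[set] = None) -> int:
    """Number of reads matching the miRNA subset (normalisation denominator)."""
    hits = df[df["final_class"] == "mirna_ncrna"]
    if mirna_names is not None:
        hits = hits[hits["mirna_name"].isin(mirna_names)]
    return int(len(hits))


def normalize_per_million_mirna(raw: float, mirna_total: int) -> float:
    """raw * 1e6 / miRNA reads of the library."""
    if mirna_total <= 0:
        raise StatsError("library has no miRNA reads; cannot normalize")
    return raw * 1e6 / mirna_total


def _window_mask(df: pd.DataFrame, window: tuple[int, int]) -> pd.Series:
    return (df["length"] >= window[0]) & (df["length"] <= window[1])


def feature_counts(
    wt: pd.DataFrame,
    ko: pd.DataFrame,
    clusters: Sequence[str] = (),
    families: Sequence[str] = (),
    window: tuple[int, int] = PIRNA_WINDOW,
) -> pd.DataFrame:
    """Per-cluster and per-transposon-family count table with fold changes.

    Raw counts are 24-33-nt reads uniquely mapped within a cluster, or
    carrying a consensus hit for a family; normalised columns are per
    million miRNA reads of each library; fold = WT_norm / KO_norm (NaN
    when the KO count is zero) and ``fold_ge3`` flags fold >= 3.0, the
    dashed-line threshold of the published scatter comparison.
    """
    feats_c = list(clusters) or sorted(
        set(wt["cluster_id"].dropna()) | set(ko["cluster_id"].dropna())
    )
    feats_f = list(families) or sorted(
        set(wt["family"].dropna()) | set(ko["family"].dropna())
    )
    totals = {"WT": mirna_total(wt), "KO": mirna_total(ko)}
    rows = []
    for kind, feats, col in (("cluster", feats_c, "cluster_id"), ("transposon", feats_f, "family")):
        for feat in feats:
            row = {"feature_type": kind, "feature_id": feat}
            for lab, df in (("WT", wt), ("KO", ko)):
                sel = df[_window_mask(df, window) & (df[col] == feat)]
                raw = int(len(sel))
                row[f"{lab}_raw"] = raw
                row[f"{lab}_norm"] = normalize_per_million_mirna(raw, totals[lab])
            fold = row["WT_norm"] / row["KO_norm"] if row["KO_norm"] > 0 else np.nan
            row["fold"] = fold
            row["fold_ge3"] = bool(fold >= 3.0) if np.isfinite(fold) else False
            rows.append(row)
    return pd.DataFrame(rows)


def overlap_histogram(
    df: pd.DataFrame,
    family: str,
    window: tuple[int, int] = PIRNA_WINDOW,
    d_range: tuple[int, int] = (1, 30),
) -> pd.Series:
    """All-vs-all 5'-5' overlap-distance histogram on one consensus.

    Counts every (sense, antisense) pair of window-length reads mapped to
    ``family`` at d = five_prime(-) - five_prime(+) + 1 for d in
    ``d_range``, weighted by read multiplicity. Returns a Series indexed
    by d; ``Series.idxmax()`` is the mode.
    """
    if family not in set(df["family"].dropna()):
        raise StatsError(f"no reads assigned to family {family!r}")
    sel = df[(df["family"] == family) & _window_mask(df, window)]
    offsets = sel["t_offset"].to_numpy(dtype=int)
    lengths = sel["length"].to_numpy(dtype=int)
    strands = sel["t_strand"].to_numpy()
    fp = five_prime_positions(offsets, lengths, strands)
    lo, hi = d_range
    hist = pd.Series(0, index=pd.RangeIndex(lo, hi + 1, name="d"), dtype=int)
    plus_fp = fp[strands == "+"]
    minus_fp = fp[strands == "-"]
    if plus_fp.size == 0 or minus_fp.size == 0:
        return hist
    size = int(max(plus_fp.max(), minus_fp.max())) + 1
    cp = np.bincount(plus_fp, minlength=size)
    cm = np.bincount(minus_fp, minlength=size)
    for d in range(lo, hi + 1):
        shift = d - 1  # minus 5' sits at plus 5' + (d - 1)
        if shift >= 0:
            hist[d] = int(np.dot(cp[: size - shift], cm[shift:]) if shift else np.dot(cp, cm))
        else:
            hist[d] = int(np.dot(cp[-shift:], cm[: size + shift]))
    return hist


@dataclass(frozen=True)
class ByproductLink:
    """A short RNA tied to its downstream piRNA and (optionally) a guide."""

    short_id: str
    family: str
    strand: str
    short_start: int
    short_end: int
    short_length: int
    downstream_id: str
    downstream_length: int
    downstream_A10: bool
    guide_id: Optional[str]
    guide_length: Optional[int]
    guide_d: Optional[int]  # 5'-5' overlap of the (downstream, guide) pair


def byproduct_scan(
    df: pd.DataFrame,
    short_window: tuple[int, int] = SHORT_WINDOW,
    pirna_window: tuple[int, int] = PIRNA_WINDOW,
    guide_lengths: tuple[int, ...] = DEFAULT_GUIDE_LENGTHS,
) -> tuple[pd.DataFrame, dict]:
    """Slicer-byproduct linkage on consensus-mapped reads.

    For each short (11-23 nt) consensus-mapped read, rule A (required for
    a link) demands a same-strand piRNA-length read starting immediately
    at the short read's 3' end (half-open adjacency); rule B (recorded
    when present) demands an opposite-strand piRNA whose 3'-end coordinate
    equals the short read's 5' coordinate — that piRNA is the candidate
    guide. When several guides qualify, one whose 5'-5' overlap with the
    downstream piRNA is exactly 10 is preferred. Returns the link table
    and a summary with per-(short length, guide length) counts and the
    A-at-position-10 fraction of downstream piRNAs.
    """
    links: list[ByproductLink] = []
    n_short = 0
    for family, fam_df in df[df["family"].notna()].groupby("family", observed=True):
        offsets = fam_df["t_offset"].to_numpy(dtype=int)
        lengths = fam_df["length"].to_numpy(dtype=int)
        strands = fam_df["t_strand"].to_numpy()
        ids = fam_df["read_id"].to_numpy()
        seqs = fam_df["sequence"].to_numpy()
        is_pi = (lengths >= pirna_window[0]) & (lengths <= pirna_window[1])
        is_short = (lengths >= short_window[0]) & (lengths <= short_window[1])

        # piRNA lookups keyed by the coordinate each rule tests
        by_start: dict[tuple[str, int], list[int]] = {}
        by_end: dict[tuple[str, int], list[int]] = {}
        pi_idx = np.flatnonzero(is_pi)
        order = pi_idx[np.lexsort((offsets[pi_idx], lengths[pi_idx]))]
        for i in order:
            by_start.setdefault((strands[i], offsets[i]), []).append(i)
            by_end.setdefault((strands[i], offsets[i] + lengths[i]), []).append(i)

        for i in np.flatnonzero(is_short):
            n_short += 1
            strand = strands[i]
            start, end = int(offsets[i]), int(offsets[i] + lengths[i])
            opp = "-" if strand == "+" else "+"
            if strand == "+":
                downstream = by_start.get(("+", end), [])
                # guide 3' (= start for - strand) at short 5' (= start)
                guides = by_start.get(("-", start), [])
            else:
                downstream = by_end.get(("-", start), [])
                # guide 3' (= end - 1 for + strand) at short 5' (= end - 1)
                guides = by_end.get(("+", end), [])
            if not downstream:
                continue
            dn = downstream[0]
            dn_fp = offsets[dn] if strands[dn] == "+" else offsets[dn] + lengths[dn] - 1
            chosen, chosen_d = None, None
            for g in guides:
                g_fp = offsets[g] if strands[g] == "+" else offsets[g] + lengths[g] - 1
                d = (g_fp - dn_fp + 1) if strands[g] == "-" else (dn_fp - g_fp + 1)
                if chosen is None or (d == 10 and chosen_d != 10):
                    chosen, chosen_d = g, d
            links.append(
                ByproductLink(
                    short_id=ids[i],
                    family=str(family),
                    strand=strand,
                    short_start=start,
                    short_end=end,
                    short_length=int(lengths[i]),
                    downstream_id=ids[dn],
                    downstream_length=int(lengths[dn]),
                    downstream_A10=bool(len(seqs[dn]) >= 10 and seqs[dn][9] == "A"),
                    guide_id=ids[chosen] if chosen is not None else None,
                    guide_length=int(lengths[chosen]) if chosen is not None else None,
                    guide_d=int(chosen_d) if chosen is not None else None,
                )
            )
    link_df = pd.DataFrame([l.__dict__ for l in links])
    dual = link_df[link_df["guide_id"].notna()] if not link_df.empty else link_df
    dual10 = dual[dual["guide_d"] == 10] if not dual.empty else dual
    pair_counts = (
        dual.groupby(["short_length", "guide_length"]).size().to_dict() if not dual.empty else {}
    )
    summary = {
        "n_short_reads": n_short,
        "n_links": int(len(link_df)),
        "n_dual_rule": int(len(dual)),
        "n_dual_rule_d10": int(len(dual10)),
        "pair_counts": {f"{int(s)}/{int(g)}": int(c) for (s, g), c in sorted(pair_counts.items())},
        "frac_A10_ruleA": float(link_df["downstream_A10"].mean()) if len(link_df) else float("nan"),
        "frac_A10_dual": float(dual["downstream_A10"].mean()) if len(dual) else float("nan"),
    }
    return link_df, summary


def depletion_by_window(
    wt: pd.DataFrame,
    ko: pd.DataFrame,
    windows: Sequence[tuple[int, int]] = (MILI_WINDOW, MIWI2_WINDOW),
    classes: Sequence[str] = ("cluster", "transposon"),
) -> pd.DataFrame:
    """KO/WT normalised-count ratio per length window per piRNA class.

    'cluster' rows count uniquely cluster-mapped reads; 'transposon' rows
    count consensus-hit reads. Ratio is NaN when the WT window is empty.
    """
    totals = {"WT": mirna_total(wt), "KO": mirna_total(ko)}
    rows = []
    for cls in classes:
        for lo, hi in windows:
            row = {"class": cls, "window": f"{lo}-{hi}"}
            for lab, df in (("WT", wt), ("KO", ko)):
                if cls == "cluster":
                    sel = df[(df["final_class"] == "cluster")]
                elif cls == "transposon":
                    sel = df[df["family"].notna()]
                else:
                    raise StatsError(f"unknown class {cls!r}")
                raw = int(_window_mask(sel, (lo, hi)).sum())
                row[f"{lab}_raw"] = raw
                row[f"{lab}_norm"] = normalize_per_million_mirna(raw, totals[lab])
            row["ko_wt_ratio"] = (
                row["KO_norm"] / row["WT_norm"] if row["WT_norm"] > 0 else np.nan
            )
            rows.append(row)
    return pd.DataFrame(rows)
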