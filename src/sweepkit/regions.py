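"""Candidate-region calling, cross-method intersection and gene annotation.

Coordinates are 1-based inclusive internally; BED input/output is
converted at the boundary.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .types import CandidateRegion, MarkerMap, RegionOverlap, ScanTrack, WindowTrack

__all__ = ["call_runs", "call_window_regions", "intersect_region_sets",
           "annotate_regions", "read_gene_intervals", "merge_regions"]


def merge_regions(regions: list[CandidateRegion]) -> list[CandidateRegion]:
    """Merge overlapping regions (same method), returning a sorted,
    pairwise-disjoint list."""
    out: list[CandidateRegion] = []
    by_key = sorted(regions, key=lambda r: (str(r.chrom), r.start, r.end))
    for r in by_key:
        if out and out[-1].chrom == r.chrom and r.start <= out[-1].end:
            prev = out[-1]
            out[-1] = CandidateRegion(
                prev.chrom, prev.start, max(prev.end, r.end), prev.method,
                prev.n_snps + r.n_snps, prev.snp_ids + r.snp_ids)
        else:
            out.append(r)
    return out


def call_runs(track: ScanTrack, mm: MarkerMap, min_run: int = 2,
              pad_bp: int = 500, method: str | None = None,
              ) -> list[CandidateRegion]:
    """Regions from runs of consecutive significant SNPs.

    Maximal runs of >= ``min_run`` flagged SNPs, consecutive in map order
    on one chromosome, become regions padded ``pad_bp`` up- and downstream
    of the extreme significant SNPs (floored at position 1); overlapping
    padded regions are merged.
    """
    if len(track) != mm.n_snps:
        raise ValueError("track not aligned to MarkerMap")
    method = method or track.name
    regions: list[CandidateRegion] = []
    for chrom, idx in mm.chrom_slices():
        flags = track.flags[idx]
        i = 0
        while i < len(idx):
            if not flags[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(idx) and flags[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                members = idx[i:j + 1]
                regions.append(CandidateRegion(
                    chrom, max(1, int(mm.pos[members[0]]) - pad_bp),
                    int(mm.pos[members[-1]]) + pad_bp, method,
                    n_snps=len(members),
                    snp_ids=tuple(mm.snp_id[members])))
            i = j + 1
    return merge_regions(regions)


def call_window_regions(wt: WindowTrack, min_windows: int = 2,
                        mode: str = "adjacent", method: str | None = None,
                        ) -> list[CandidateRegion]:
    """Regions from flagged windows.

    ``adjacent`` (default): runs of >= ``min_windows`` consecutive flagged
    windows on one chromosome become a single region from the first
    window's start bp to the last window's end bp. ``any``: every flagged
    window on a chromosome carrying >= ``min_windows`` flagged windows
    becomes its own region.
    """
    method = method or wt.name
    regions: list[CandidateRegion] = []
    order = np.arange(len(wt))
    for chrom in dict.fromkeys(wt.chrom):
        widx = order[wt.chrom == chrom]
        flags = wt.flags[widx]
        if mode == "any":
            if flags.sum() >= min_windows:
                for w in widx[flags]:
                    regions.append(CandidateRegion(
                        chrom, int(wt.first_bp[w]), int(wt.last_bp[w]),
                        method))
            continue
        if mode != "adjacent":
            raise ValueError(f"unknown mode {mode!r}")
        i = 0
        while i < len(widx):
            if not flags[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(widx) and flags[j + 1]:
                j += 1
            if j - i + 1 >= min_windows:
                regions.append(CandidateRegion(
                    chrom, int(wt.first_bp[widx[i]]),
                    int(wt.last_bp[widx[j]]), method))
            i = j + 1
    return merge_regions(regions)


def intersect_region_sets(named_sets: dict) -> list[RegionOverlap]:
    """Maximal intervals shared by one region from each of >= 2 methods.

    For every combination of two or more method names, every tuple of
    regions (one per method) on a common chromosome with a non-empty
    mutual intersection yields one RegionOverlap.
    """
    overlaps: list[RegionOverlap] = []
    names = sorted(named_sets)
    for k in range(2, len(names) + 1):
        for combo in combinations(names, k):
            overlaps.extend(_intersect_combo(combo, named_sets))
    return overlaps


def _intersect_combo(combo, named_sets) -> list[RegionOverlap]:
    out = []
    # current partial intersections: (chrom, start, end, member tuple)
    current = [(r.chrom, r.start, r.end, (r,)) for r in named_sets[combo[0]]]
    for name in combo[1:]:
        nxt = []
        for chrom, start, end, members in current:
            for r in named_sets[name]:
                if r.chrom != chrom:
                    continue
                s, e = max(start, r.start), min(end, r.end)
                if s <= e:
                    nxt.append((chrom, s, e, members + (r,)))
        current = nxt
        if not current:
            break
    for chrom, s, e, members in current:
        out.append(RegionOverlap(tuple(combo), chrom, s, e, members))
    return out


def read_gene_intervals(path) -> pd.DataFrame:
    """Load gene intervals from BED (0-based half-open) or GFF3 (1-based
    inclusive), normalized to 1-based inclusive columns
    (gene, chrom, start, end)."""
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         dtype={0: str})
        if df.shape[1] < 9:
            raise ValueError("GFF3 requires 9 columns")
        attrs = df[8].astype(str)
        name = attrs.str.extract(r"(?:Name|ID|gene_id)=([^;]+)")[0]
        name = name.fillna(pd.Series([f"gene_{i}" for i in range(len(df))]))
        out = pd.DataFrame({"gene": name, "chrom": df[0].astype(str),
                            "start": df[3].astype(np.int64),
                            "end": df[4].astype(np.int64)})
    else:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         dtype={0: str})
        if df.shape[1] < 3:
            raise ValueError("BED requires at least 3 columns")
        name = (df[3].astype(str) if df.shape[1] > 3
                else pd.Series([f"gene_{i}" for i in range(len(df))]))
        out = pd.DataFrame({"gene": name, "chrom": df[0].astype(str),
                            "start": df[1].astype(np.int64) + 1,
                            "end": df[2].astype(np.int64)})
    if (out["start"] > out["end"]).any():
        raise ValueError("gene interval with start > end after normalization")
    return out


def annotate_regions(regions: list[CandidateRegion],
                     gene_intervals: pd.DataFrame) -> pd.DataFrame:
    """All (region, gene) pairs sharing >= 1 bp.

    Returns a DataFrame with region coordinates, method, gene name and the
    overlap span; ``df.attrs['n_distinct_genes']`` carries the distinct
    gene count.
    """
    rows = []
    for r in regions:
        sub = gene_intervals[gene_intervals["chrom"].astype(str) == str(r.chrom)]
        for g in sub.itertuples(index=False):
            s, e = max(r.start, g.start), min(r.end, g.end)
            if s <= e:
                rows.append({"chrom": r.chrom, "region_start": r.start,
                             "region_end": r.end, "method": r.method,
                             "gene": g.gene, "overlap_start": s,
                             "overlap_end": e})
    df = pd.DataFrame(rows, columns=["chrom", "region_start", "region_end",
                                     "method", "gene", "overlap_start",
                                     "overlap_end"])
    df.attrs["n_distinct_genes"] = int(df["gene"].nunique()) if len(df) else 0
    return df
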