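"""Allele-frequency differentiation: per-SNP Weir-Cockerham FST, the di
statistic (summed z-standardized pairwise FST), window aggregation and
significance flagging."""

from __future__ import annotations

import warnings

import numpy as np

from .types import (MISSING, GenotypeMatrix, MarkerMap, ScanTrack,
                    WindowTrack)

__all__ = ["wc_fst_per_snp", "di_track", "window_means",
           "flag_top_fraction", "flag_threshold"]


def _pop_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (n non-missing, alt frequency, observed het proportion)."""
    called = values != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, values, 0).sum(axis=0)
    het = ((values == 1) & called).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def wc_fst_per_snp(G: GenotypeMatrix, labels, pop_a: str, pop_b: str,
                   name: str | None = None) -> ScanTrack:
    """Two-population Weir & Cockerham (1984) theta-hat per SNP.

    Uses observed heterozygosity from genotype counts. A SNP is undefined
    (NaN) where either population has fewer than 2 non-missing individuals
    or where the SNP is monomorphic across both populations.
    """
    labels = np.asarray(labels, dtype=object)
    for pop in (pop_a, pop_b):
        if pop not in labels:
            raise ValueError(f"unknown population label {pop!r}")
    n1, p1, h1 = _pop_stats(G.values[labels == pop_a])
    n2, p2, h2 = _pop_stats(G.values[labels == pop_b])

    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1.0 - pbar)
                                 - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1.0 - pbar)
                                     - s2 * (r - 1.0) / r
                                     - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    theta[(n1 < 2) | (n2 < 2)] = np.nan
    # monomorphic across both populations -> undefined
    mono = ((pbar == 0) | (pbar == 1)) & (hbar == 0)
    theta[mono] = np.nan
    return ScanTrack(name or f"fst:{pop_a}|{pop_b}", theta)


def di_track(fst_tracks: dict, focal_group: str = "", *,
             ddof: int = 0, name: str = "di") -> ScanTrack:
    """Sum of per-pair z-standardized FST tracks.

    Each pairwise track is standardized by the genome-wide mean and
    standard deviation of its defined values (population form, ``ddof=0``,
    by default), then summed per SNP over all comparisons involving the
    focal group. With exactly two groups this is the per-SNP FST z-score.
    SNPs undefined in any contributing pair are undefined in di.
    """
    if not fst_tracks:
        raise ValueError("no FST tracks given")
    tracks = list(fst_tracks.values())
    n = len(tracks[0])
    total = np.zeros(n)
    for t in tracks:
        if len(t) != n:
            raise ValueError("FST tracks have mismatched lengths")
        vals = t.values
        defined = ~np.isnan(vals)
        if defined.sum() < 2:
            raise ValueError(f"track {t.name!r} has <2 defined values")
        mu = vals[defined].mean()
        sd = vals[defined].std(ddof=ddof)
        if sd <= 1e-12 * max(1.0, abs(mu)):  # constant up to rounding
            raise ValueError(f"degenerate FST distribution in {t.name!r} "
                             "(zero standard deviation)")
        total = total + (vals - mu) / sd
    return ScanTrack(name, total)


def window_means(track: ScanTrack, mm: MarkerMap, w: int = 20,
                 ) -> WindowTrack:
    """Mean statistic in consecutive non-overlapping blocks of ``w`` SNPs.

    Blocks are cut per chromosome in map order; a trailing block of fewer
    than ``w`` SNPs is dropped. Window value is the mean over defined
    statistics in the block (NaN if none are defined).
    """
    if w < 1:
        raise ValueError(f"window size must be >= 1, got {w}")
    if len(track) != mm.n_snps:
        raise ValueError("track not aligned to MarkerMap")
    chroms, fi, li, fb, lb, means = [], [], [], [], [], []
    for chrom, idx in mm.chrom_slices():
        n_win = len(idx) // w
        if n_win == 0:
            warnings.warn(f"chromosome {chrom} has <{w} SNPs: no windows")
            continue
        for b in range(n_win):
            block = idx[b * w:(b + 1) * w]
            vals = track.values[block]
            defined = ~np.isnan(vals)
            chroms.append(chrom)
            fi.append(block[0])
            li.append(block[-1])
            fb.append(mm.pos[block[0]])
            lb.append(mm.pos[block[-1]])
            means.append(vals[defined].mean() if defined.any() else np.nan)
    return WindowTrack(track.name, np.array(chroms, dtype=object),
                       np.array(fi), np.array(li), np.array(fb),
                       np.array(lb), np.array(means))


def flag_top_fraction(wt: WindowTrack, frac: float = 0.01) -> WindowTrack:
    """Flag windows whose mean is >= the empirical (1 - frac) quantile.

    Ties at the cutoff are all flagged. Returns a new WindowTrack.
    """
    if not (0.0 < frac <= 1.0):
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    if len(wt) == 0:
        raise ValueError("no windows to flag")
    defined = ~np.isnan(wt.mean)
    if not defined.any():
        raise ValueError("all window means undefined")
    cutoff = np.quantile(wt.mean[defined], 1.0 - frac, method="higher")
    flags = defined & (wt.mean >= cutoff)
    return WindowTrack(wt.name, wt.chrom, wt.first_idx, wt.last_idx,
                       wt.first_bp, wt.last_bp, wt.mean, flags)


def flag_threshold(track: ScanTrack, thr: float) -> ScanTrack:
    """Flag SNPs whose defined statistic is >= ``thr`` (inclusive)."""
    if not np.isfinite(thr):
        raise ValueError("threshold must be finite")
    with np.errstate(invalid="ignore"):
        flags = ~np.isnan(track.values) & (track.values >= thr)
    return ScanTrack(track.name, track.values, flags)
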