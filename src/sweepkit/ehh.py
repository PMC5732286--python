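"""Extended-haplotype-homozygosity statistics.

EHH at a test marker is the probability that two randomly chosen
chromosome copies carrying the core allele are identical over the
interval from the core to that marker; it is computed here by partition
refinement (haplotype strings grown outward one marker at a time).
``ihs_scan`` integrates EHH for the ancestral vs derived core allele
within one group; ``rsb_scan`` contrasts the site-specific (all-copies)
integral between two groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .types import HaplotypeSet, MarkerMap, ScanTrack

__all__ = [
    "AncestralAssignment", "EhhCurve", "EhhScanTrack",
    "assign_ancestral_major", "assign_ancestral_random",
    "ehh_curve", "ehhs_curve", "integrate_ihh",
    "ihs_scan", "rsb_scan", "p_transform", "consistency_check",
]


# ---------------------------------------------------------------------------
# Ancestral-allele assignment
# ---------------------------------------------------------------------------

@dataclass
class AncestralAssignment:
    """Per-SNP ancestral allele (0/1) with provenance."""

    alleles: np.ndarray
    provenance: str           # "major" | "random"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("ancestral alleles must be 0/1")

    def __len__(self) -> int:
        return len(self.alleles)


def assign_ancestral_major(freqs) -> AncestralAssignment:
    """Ancestral = the higher-frequency allele; exact ties break to allele 0.

    ``freqs`` is the per-SNP frequency of allele 1.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.isnan(freqs).any():
        raise ValueError("undefined frequency in ancestral assignment")
    return AncestralAssignment((freqs > 0.5).astype(np.int8), "major")


def assign_ancestral_random(n_snps: int, seed: int) -> AncestralAssignment:
    """Independent fair-coin ancestral state per SNP, reproducible by seed."""
    rng = np.random.default_rng(seed)
    return AncestralAssignment(rng.integers(0, 2, size=n_snps,
                                            dtype=np.int8), "random", seed)


# ---------------------------------------------------------------------------
# EHH / EHHS curves
# ---------------------------------------------------------------------------

@dataclass
class EhhCurve:
    """One EHH (or EHHS) curve around a core SNP.

    ``left_idx``/``right_idx`` list marker indices from the core outward
    (the core itself first, value 1); only markers with value >= the
    cutoff are retained. ``truncated_*`` marks a chromosome edge reached
    while still above the cutoff.
    """

    core: int
    allele_class: str
    left_idx: np.ndarray
    left_ehh: np.ndarray
    right_idx: np.ndarray
    right_ehh: np.ndarray
    truncated_left: bool = False
    truncated_right: bool = False

    def values(self) -> np.ndarray:
        """All curve values, left side reversed then right side (core twice)."""
        return np.concatenate([self.left_ehh[::-1], self.right_ehh])


def _extend(V: np.ndarray, rows: np.ndarray, start_labels: np.ndarray,
            core: int, step: int, lo: int, hi: int, cutoff: float,
            norm_h: float) -> tuple[list, list, bool]:
    """Grow haplotype-string partitions outward from the core.

    Returns (marker indices, EHH values, truncated-at-edge flag); the core
    is included with value 1. Stops after the last marker whose value is
    >= cutoff.
    """
    n = len(rows)
    pairs_tot = n * (n - 1)
    labels = start_labels
    idxs, vals = [core], [1.0]
    t = core + step
    while True:
        if t < lo or t > hi:
            return idxs, vals, True
        labels = labels * 2 + V[rows, t]
        _, labels = np.unique(labels, return_inverse=True)
        counts = np.bincount(labels)
        h = (counts * (counts - 1)).sum() / pairs_tot
        e = h / norm_h
        if e < cutoff:
            return idxs, vals, False
        idxs.append(t)
        vals.append(e)
        t += step


def ehh_curve(H: HaplotypeSet, core: int, allele: int, cutoff: float = 0.05,
              bounds: tuple[int, int] | None = None) -> EhhCurve | None:
    """EHH among carriers of ``allele`` at the core SNP.

    At marker *t* the carriers are partitioned by their allele string from
    core to *t* inclusive; EHH is the fraction of carrier pairs falling in
    the same class. Returns None (undefined) with fewer than 2 carriers.
    ``bounds`` restricts the walk to an inclusive marker index range
    (normally the core's chromosome).
    """
    V = H.values
    lo, hi = bounds if bounds is not None else (0, V.shape[1] - 1)
    rows = np.flatnonzero(V[:, core] == allele)
    if len(rows) < 2:
        return None
    start = np.zeros(len(rows), dtype=np.int64)
    li, lv, tl = _extend(V, rows, start, core, -1, lo, hi, cutoff, 1.0)
    ri, rv, tr = _extend(V, rows, start, core, +1, lo, hi, cutoff, 1.0)
    return EhhCurve(core, str(allele), np.array(li), np.array(lv),
                    np.array(ri), np.array(rv), tl, tr)


def ehhs_curve(H: HaplotypeSet, core: int, cutoff: float = 0.05,
               bounds: tuple[int, int] | None = None) -> EhhCurve | None:
    """Site-specific EHH over all chromosome copies, normalized to 1 at
    the core (division by the core-column homozygosity).

    Undefined (None) when the core column has no homozygous pair.
    """
    V = H.values
    lo, hi = bounds if bounds is not None else (0, V.shape[1] - 1)
    n = V.shape[0]
    if n < 2:
        return None
    rows = np.arange(n)
    start = V[:, core].astype(np.int64)
    counts = np.bincount(start)
    h_core = (counts * (counts - 1)).sum() / (n * (n - 1))
    if h_core == 0:
        return None
    li, lv, tl = _extend(V, rows, start.copy(), core, -1, lo, hi, cutoff, h_core)
    ri, rv, tr = _extend(V, rows, start.copy(), core, +1, lo, hi, cutoff, h_core)
    return EhhCurve(core, "all", np.array(li), np.array(lv),
                    np.array(ri), np.array(rv), tl, tr)


def integrate_ihh(curve: EhhCurve, mm: MarkerMap) -> float:
    """Trapezoidal integral of the curve against bp position, both sides."""
    total = 0.0
    for idx, vals in ((curve.left_idx, curve.left_ehh),
                      (curve.right_idx, curve.right_ehh)):
        if len(idx) > 1:
            x = np.abs(mm.pos[idx] - mm.pos[curve.core]).astype(float)
            total += float(np.trapezoid(vals, x))
    return total


# ---------------------------------------------------------------------------
# Scan tracks
# ---------------------------------------------------------------------------

@dataclass
class EhhScanTrack(ScanTrack):
    """ScanTrack whose ``values`` hold the -log10-scale transformed
    statistic, with the raw ln-ratio and standardized tracks alongside."""

    raw: np.ndarray = field(default=None)           # type: ignore[assignment]
    standardized: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_frame(self, mm: MarkerMap) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": mm.snp_id, "chrom": mm.chrom, "pos": mm.pos,
            "raw": self.raw, "standardized": self.standardized,
            "transformed": self.values, "flag": self.flags.astype(int),
        })


def p_transform(values, side: str = "two-sided") -> np.ndarray:
    """-log10 of the Gaussian tail probability of a standardized statistic.

    Default (``two-sided``): ``-log10(2 * (1 - Phi(|v|)))``, symmetric in
    the sign of v and 0 at v = 0. ``one-sided`` applies the printed form
    literally (``-log10(2 * (1 - Phi(v)))``), which is negative for v < 0.
    """
    v = np.asarray(values, dtype=float)
    if side == "two-sided":
        tail = 2.0 * norm.sf(np.abs(v))
    elif side == "one-sided":
        tail = 2.0 * norm.sf(v)
    else:
        raise ValueError(f"unknown side {side!r}")
    with np.errstate(divide="ignore"):
        return -np.log10(tail)


def _chrom_bounds(mm: MarkerMap) -> list[tuple[int, int]]:
    """Per-SNP inclusive (lo, hi) marker-index range of its chromosome."""
    bounds: list[tuple[int, int]] = [None] * mm.n_snps  # type: ignore
    for _, idx in mm.chrom_slices():
        lo, hi = int(idx[0]), int(idx[-1])
        for i in idx:
            bounds[i] = (lo, hi)
    return bounds


def ihs_scan(H: HaplotypeSet, anc: AncestralAssignment, mm: MarkerMap,
             freq_bounds: tuple[float, float] = (0.05, 0.95),
             bin_width: float = 0.05, threshold: float = 4.0,
             cutoff: float = 0.05, side: str = "two-sided") -> EhhScanTrack:
    """Integrated haplotype score scan within one group.

    Per SNP: ``raw = ln(iHH_ancestral / iHH_derived)``; standardized by
    mean/sd within derived-allele-frequency bins of width ``bin_width``;
    transformed via `p_transform`; flagged where transformed >= threshold.
    Cores with derived frequency outside ``freq_bounds`` are skipped.
    """
    if len(anc) != mm.n_snps or H.n_snps != mm.n_snps:
        raise ValueError("haplotypes, ancestral assignment and map misaligned")
    V = H.values
    bounds = _chrom_bounds(mm)
    n = mm.n_snps
    raw = np.full(n, np.nan)
    dfreq = np.full(n, np.nan)
    for s in range(n):
        der = 1 - int(anc.alleles[s])
        f = float((V[:, s] == der).mean())
        dfreq[s] = f
        if not (freq_bounds[0] <= f <= freq_bounds[1]):
            continue
        c_anc = ehh_curve(H, s, int(anc.alleles[s]), cutoff, bounds[s])
        c_der = ehh_curve(H, s, der, cutoff, bounds[s])
        if c_anc is None or c_der is None:
            continue
        ihh_a = integrate_ihh(c_anc, mm)
        ihh_d = integrate_ihh(c_der, mm)
        if ihh_a > 0 and ihh_d > 0:
            raw[s] = np.log(ihh_a / ihh_d)

    std = np.full(n, np.nan)
    defined = ~np.isnan(raw)
    bins = np.floor(np.clip(dfreq, 0.0, 1.0 - 1e-12) / bin_width).astype(int)
    for b in np.unique(bins[defined]):
        sel = defined & (bins == b)
        if sel.sum() < 2:
            warnings.warn(f"iHS frequency bin {b * bin_width:.2f} has <2 "
                          "SNPs; left unstandardized")
            continue
        mu, sd = raw[sel].mean(), raw[sel].std(ddof=0)
        if sd == 0:
            warnings.warn(f"iHS frequency bin {b * bin_width:.2f} has zero "
                          "variance; left unstandardized")
            continue
        std[sel] = (raw[sel] - mu) / sd
    transformed = p_transform(std, side=side)
    with np.errstate(invalid="ignore"):
        flags = ~np.isnan(transformed) & (transformed >= threshold)
    return EhhScanTrack("ihs", transformed, flags, raw=raw, standardized=std)


def rsb_scan(H_a: HaplotypeSet, H_b: HaplotypeSet, mm: MarkerMap,
             threshold: float = 4.0, cutoff: float = 0.05,
             side: str = "two-sided") -> EhhScanTrack:
    """Cross-group haplotype-homozygosity contrast.

    Per SNP: ``raw = ln(iES_A / iES_B)`` from site-specific EHH integrals;
    standardized by subtracting the genome-wide median and dividing by the
    genome-wide standard deviation; transformed via `p_transform`.
    Positive standardized values mean longer homozygosity in group A.
    """
    if H_a.n_snps != mm.n_snps or H_b.n_snps != mm.n_snps:
        raise ValueError("haplotype sets not aligned to MarkerMap")
    bounds = _chrom_bounds(mm)
    n = mm.n_snps
    raw = np.full(n, np.nan)
    for s in range(n):
        ca = ehhs_curve(H_a, s, cutoff, bounds[s])
        cb = ehhs_curve(H_b, s, cutoff, bounds[s])
        if ca is None or cb is None:
            continue
        ies_a = integrate_ihh(ca, mm)
        ies_b = integrate_ihh(cb, mm)
        if ies_a > 0 and ies_b > 0:
            raw[s] = np.log(ies_a / ies_b)
    defined = ~np.isnan(raw)
    if defined.sum() < 2:
        raise ValueError("fewer than 2 defined Rsb values")
    med = np.median(raw[defined])
    sd = raw[defined].std(ddof=0)
    if sd == 0:
        # constant raw track (e.g. identical groups): no scale to divide by
        warnings.warn("degenerate Rsb distribution (zero sd); standardized "
                      "values are median-centered only")
        std = raw - med
    else:
        std = (raw - med) / sd
    transformed = p_transform(std, side=side)
    with np.errstate(invalid="ignore"):
        flags = ~np.isnan(transformed) & (transformed >= threshold)
    return EhhScanTrack("rsb", transformed, flags, raw=raw, standardized=std)


# ---------------------------------------------------------------------------
# Random-assignment consistency check
# ---------------------------------------------------------------------------

def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return 1.0 if union == 0 else float((a & b).sum() / union)


def consistency_check(H: HaplotypeSet, mm: MarkerMap, n_perm: int = 100,
                      seed: int = 0, assignments=None,
                      **scan_kwargs) -> pd.DataFrame:
    """Stability of the iHS scan under random ancestral assignments.

    Runs the scan once with the major-allele assignment (the reference),
    then under ``n_perm`` random assignments (or explicitly supplied
    ones), reporting per run the Spearman rank correlation of
    |standardized iHS| against the reference and the Jaccard overlap of
    significant SNP sets.
    """
    freqs = H.values.mean(axis=0)
    ref = ihs_scan(H, assign_ancestral_major(freqs), mm, **scan_kwargs)
    ref_abs = np.abs(ref.standardized)
    if assignments is None:
        rng = np.random.default_rng(seed)
        assignments = [assign_ancestral_random(mm.n_snps,
                                               int(rng.integers(2 ** 31)))
                       for _ in range(n_perm)]
    rows = []
    for k, anc in enumerate(assignments):
        scan = ihs_scan(H, anc, mm, **scan_kwargs)
        both = ~np.isnan(ref_abs) & ~np.isnan(scan.standardized)
        if both.sum() >= 2:
            x = rankdata(ref_abs[both])
            y = rankdata(np.abs(scan.standardized[both]))
            rho = float(np.corrcoef(x, y)[0, 1])
        else:
            rho = np.nan
        rows.append({"perm": k, "spearman_abs": rho,
                     "jaccard_significant": _jaccard(ref.flags, scan.flags),
                     "n_common_defined": int(both.sum())})
    return pd.DataFrame(rows)
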