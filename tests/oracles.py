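"""Independent brute-force oracles, deliberately coded without reference
to the package internals."""

from itertools import combinations

import numpy as np


def wc_fst_oracle(geno_a, geno_b):
    """Weir & Cockerham (1984) two-population theta-hat from dosage lists.

    Scalar, loop-based, straight from the published component formulas.
    Dosages are lists over individuals; -1 means missing. Returns NaN
    where undefined.
    """
    stats = []
    for geno in (geno_a, geno_b):
        called = [g for g in geno if g != -1]
        n = len(called)
        if n < 2:
            return float("nan")
        p = sum(called) / (2 * n)
        h = sum(1 for g in called if g == 1) / n
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    if (pbar in (0.0, 1.0)) and hbar == 0:
        return float("nan")
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    if a + b + c == 0:
        return float("nan")
    return a / (a + b + c)


def ehh_oracle(hap_matrix, core, allele, t):
    """EHH at marker t by enumerating all carrier pairs and comparing
    their allele strings from core to t inclusive."""
    H = np.asarray(hap_matrix)
    carriers = [i for i in range(H.shape[0]) if H[i, core] == allele]
    if len(carriers) < 2:
        return None
    lo, hi = (t, core) if t <= core else (core, t)
    same = 0
    for i, j in combinations(carriers, 2):
        if np.array_equal(H[i, lo:hi + 1], H[j, lo:hi + 1]):
            same += 1
    return same / (len(carriers) * (len(carriers) - 1) / 2)


def ehhs_oracle(hap_matrix, core, t):
    """Site-specific EHH at marker t: pair-sharing over all chromosomes
    from core to t, normalized by pair-sharing at the core alone."""
    H = np.asarray(hap_matrix)
    n = H.shape[0]
    lo, hi = (t, core) if t <= core else (core, t)
    same_ext = sum(1 for i, j in combinations(range(n), 2)
                   if np.array_equal(H[i, lo:hi + 1], H[j, lo:hi + 1]))
    same_core = sum(1 for i, j in combinations(range(n), 2)
                    if H[i, core] == H[j, core])
    if same_core == 0:
        return None
    return same_ext / same_core


def call_runs_oracle(flags, chroms, positions, min_run=2, pad_bp=500):
    """Brute force: enumerate every contiguous index window, keep those
    that are all-flagged, single-chromosome and maximal, convert to
    padded intervals, then merge overlaps."""
    n = len(flags)
    runs = []
    for i in range(n):
        for j in range(i, n):
            span = range(i, j + 1)
            if not all(flags[k] for k in span):
                continue
            if len({chroms[k] for k in span}) != 1:
                continue
            left_ok = i == 0 or not flags[i - 1] or chroms[i - 1] != chroms[i]
            right_ok = (j == n - 1 or not flags[j + 1]
                        or chroms[j + 1] != chroms[j])
            if left_ok and right_ok and j - i + 1 >= min_run:
                runs.append((chroms[i], max(1, positions[i] - pad_bp),
                             positions[j] + pad_bp))
    runs.sort()
    merged = []
    for chrom, s, e in runs:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append((chrom, s, e))
    return merged


def lda_axes_oracle(scores, groups, n_axes):
    """Discriminant axes via explicit inv(Sw) @ Sb eigendecomposition."""
    groups = np.asarray(groups, dtype=object)
    names = list(dict.fromkeys(groups))
    grand = scores.mean(axis=0)
    d = scores.shape[1]
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for g in names:
        sub = scores[groups == g]
        mu = sub.mean(axis=0)
        Sw += (sub - mu).T @ (sub - mu)
        diff = (mu - grand)[:, None]
        Sb += len(sub) * diff @ diff.T
    evals, evecs = np.linalg.eig(np.linalg.inv(Sw) @ Sb)
    order = np.argsort(evals.real)[::-1][:n_axes]
    return evals.real[order], evecs.real[:, order]
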