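"""Population structure: allele frequencies, PCA and DAPC."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .types import MISSING, GenotypeMatrix

__all__ = ["allele_frequencies", "pca", "dapc", "PcaResult", "DapcResult"]


def allele_frequencies(G: GenotypeMatrix, labels) -> pd.DataFrame:
    """Per-population alternate-allele frequencies.

    Returns a populations × SNPs DataFrame. Frequency at a SNP is the
    alternate-allele count over twice the non-missing individuals; cells
    where every individual is missing are NaN.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != G.n_samples:
        raise ValueError("labels length must equal number of samples")
    pops = list(dict.fromkeys(labels))
    out = np.empty((len(pops), G.n_snps))
    for i, pop in enumerate(pops):
        idx = np.flatnonzero(labels == pop)
        if idx.size == 0:
            raise ValueError(f"empty population {pop!r}")
        sub = G.values[idx]
        called = sub != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i] = np.where(n > 0, alt / (2.0 * n), np.nan)
    return pd.DataFrame(out, index=pops)


@dataclass
class PcaResult:
    coordinates: np.ndarray      # individuals × components
    eigenvalues: np.ndarray      # non-increasing
    pct_variance: np.ndarray     # eigenvalue / total × 100
    loadings: np.ndarray         # components × SNPs (kept columns)
    kept_snps: np.ndarray        # indices of non-zero-variance SNPs
    mean_dosage: np.ndarray      # per kept SNP, used for centering/imputation


def _impute_and_scale(values: np.ndarray, scaling: str
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.asarray(values, dtype=float)
    X[values == MISSING] = np.nan
    mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mean, inds[1])
    X = X - mean
    var = X.var(axis=0)
    keep = np.flatnonzero(var > 0)
    if keep.size < X.shape[1]:
        warnings.warn(f"dropping {X.shape[1] - keep.size} zero-variance SNPs "
                      "before PCA")
    X, mean = X[:, keep], mean[keep]
    if scaling == "patterson":
        p = mean / 2.0
        X = X / np.sqrt(2.0 * p * (1.0 - p))
    elif scaling != "center":
        raise ValueError(f"unknown scaling {scaling!r}")
    return X, keep, mean


def pca(G: GenotypeMatrix, scaling: str = "patterson",
        n_components: int | None = None) -> PcaResult:
    """Principal component analysis of a genotype matrix.

    Missing entries are mean-imputed per SNP; columns are centred by the
    mean dosage and, under Patterson scaling, divided by
    ``sqrt(2 p (1 - p))``. Component loadings are sign-fixed so that each
    component's largest-magnitude loading is positive.
    """
    if G.n_samples < 2:
        raise ValueError("PCA needs at least 2 individuals")
    X, keep, mean = _impute_and_scale(G.values, scaling)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    eig = S ** 2 / (X.shape[0] - 1)
    if n_components is not None:
        U, S, Vt, eig = U[:, :n_components], S[:n_components], \
            Vt[:n_components], eig[:n_components]
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    total = (S ** 2).sum() if n_components is None else None
    total = eig.sum() if total is None else total / (X.shape[0] - 1)
    pct = 100.0 * eig / total
    return PcaResult(coordinates=U * S, eigenvalues=eig, pct_variance=pct,
                     loadings=Vt, kept_snps=keep, mean_dosage=mean)


@dataclass
class DapcResult:
    retained_pc_count: int
    coordinates: np.ndarray          # individuals × discriminant axes
    axes: np.ndarray                 # n_pcs × n_axes, in PC-score space
    group_centroids: pd.DataFrame    # groups × axes
    discrimination_ratio: np.ndarray  # between/within variance per axis
    pca: PcaResult


def _pcs_for_variance(eig: np.ndarray, frac: float) -> int:
    cum = np.cumsum(eig) / eig.sum()
    return int(np.searchsorted(cum, frac) + 1)


def dapc(G: GenotypeMatrix, groups, n_pcs: int | None = None,
         n_axes: int | None = None, scaling: str = "patterson") -> DapcResult:
    """Discriminant analysis of principal components.

    PCA is run first and ``n_pcs`` component scores retained (default:
    enough to explain 80% of variance); linear discriminant axes are then
    found on the scores by solving the generalized eigenproblem
    ``Sb v = λ Sw v`` (between- vs within-group scatter). Eigenvalues are
    the per-axis discrimination ratios.
    """
    groups = np.asarray(groups, dtype=object)
    names = list(dict.fromkeys(groups))
    if len(names) < 2:
        raise ValueError("DAPC needs at least 2 groups")
    p = pca(G, scaling=scaling)
    if n_pcs is None:
        n_pcs = _pcs_for_variance(p.eigenvalues, 0.80)
    if n_pcs > len(p.eigenvalues):
        raise ValueError(f"n_pcs={n_pcs} exceeds available components "
                         f"({len(p.eigenvalues)})")
    scores = p.coordinates[:, :n_pcs]
    max_axes = len(names) - 1
    n_axes = max_axes if n_axes is None else min(n_axes, max_axes)

    grand = scores.mean(axis=0)
    Sw = np.zeros((n_pcs, n_pcs))
    Sb = np.zeros((n_pcs, n_pcs))
    for g in names:
        sub = scores[groups == g]
        mu = sub.mean(axis=0)
        d = sub - mu
        Sw += d.T @ d
        dm = (mu - grand)[:, None]
        Sb += len(sub) * (dm @ dm.T)
    try:
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("singular within-group scatter (group too small "
                         "for the retained PCs?)") from exc
    order = np.argsort(evals)[::-1][:n_axes]
    ratios = evals[order]
    axes = evecs[:, order]
    # sign convention as in pca(): largest-|entry| positive
    for c in range(axes.shape[1]):
        j = np.argmax(np.abs(axes[:, c]))
        if axes[j, c] < 0:
            axes[:, c] *= -1.0
    coords = scores @ axes
    centroids = pd.DataFrame(
        [coords[groups == g].mean(axis=0) for g in names], index=names)
    return DapcResult(retained_pc_count=n_pcs, coordinates=coords, axes=axes,
                      group_centroids=centroids, discrimination_ratio=ratios,
                      pca=p)
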