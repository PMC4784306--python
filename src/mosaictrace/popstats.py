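"""Pairwise IBS, classical MDS, relatedness screening and masked PCA.

These are the population-structure summaries used to place admixed query
genomes among continental reference panels: an identity-by-state matrix,
Torgerson classical scaling of its complement (the ``cmdscale`` family of
methods), a PLINK-style method-of-moments identity-by-descent screen for
cryptic relatedness, and a haplotype-level PCA restricted to segments
called as a single ancestry ("masked" PCA).
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .tracts import AncestryPath
from .vcfio import MISSING, GeneticMap, VariantTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def allele_freqs(table: VariantTable, group: str | Sequence[str] | None = None):
    """Derived (ALT) allele frequency per site over non-missing haplotypes.

    Returns ``(freqs, n_haplotypes_used)``; sites where every haplotype is
    missing get frequency NaN.
    """
    if group is None:
        h = table.haplotypes
    else:
        names = table.samples_in(group)
        h = table.haplotypes[:, table.hap_columns(names)]
    ok = h != MISSING
    n = ok.sum(axis=1)
    alt = np.where(ok, h, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return f, n


# ---------------------------------------------------------------------------
# identity by state
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimilarityMatrix:
    samples: list[str]
    values: np.ndarray   # symmetric, in [0, 1]
    counts: np.ndarray   # sites used per pair

    def distance(self) -> np.ndarray:
        return 1.0 - self.values


def ibs_matrix(table: VariantTable) -> SimilarityMatrix:
    """Mean proportion of shared alleles per pair: IBS = (2 - |g_i - g_j|)/2."""
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    g = table.dosage().astype(np.float64)
    g[g == MISSING] = np.nan
    n = table.n_samples
    vals = np.ones((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    counts[np.diag_indices(n)] = np.sum(~np.isnan(g), axis=0)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.abs(g[:, i] - g[:, j])
            ok = ~np.isnan(d)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"samples {table.samples[i]}/{table.samples[j]} share no sites")
            s = float(np.mean((2.0 - d[ok]) / 2.0))
            vals[i, j] = vals[j, i] = s
            counts[i, j] = counts[j, i] = m
    return SimilarityMatrix(list(table.samples), vals, counts)


# ---------------------------------------------------------------------------
# classical multidimensional scaling (Torgerson / cmdscale)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MDSResult:
    samples: list[str]
    coords: np.ndarray       # (n, k), columns scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all n eigenvalues, descending
    n_negative: int


def classical_mds(matrix: SimilarityMatrix | np.ndarray, k: int) -> MDSResult:
    """Torgerson classical scaling on the distance ``d = 1 - IBS``.

    Double-centers ``-d^2 / 2``, eigendecomposes, and returns the top-``k``
    coordinates scaled by the square root of each (positive) eigenvalue.
    Axis orientation is arbitrary, as for any eigenvector method.
    """
    if isinstance(matrix, SimilarityMatrix):
        d = matrix.distance()
        samples = matrix.samples
    else:
        d = np.asarray(matrix, dtype=float)
        samples = [str(i) for i in range(len(d))]
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if not (1 <= k < n):
        raise ValueError("need 1 <= k < n_samples")
    b = -0.5 * d ** 2
    b = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    n_neg = int(np.sum(w < -1e-10 * max(1.0, abs(w[0]))))
    if n_neg:
        log.info("classical_mds: %d negative eigenvalues (non-Euclidean distances)", n_neg)
    coords = v[:, :k] * np.sqrt(np.clip(w[:k], 0.0, None))
    return MDSResult(list(samples), coords, w, n_neg)


# ---------------------------------------------------------------------------
# method-of-moments identity by descent (PLINK-style)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class IBDEstimate:
    p_ibd0: float
    p_ibd1: float
    p_ibd2: float
    pi_hat: float
    n_sites: int
    related: bool


def ibd_moments(g1: np.ndarray, g2: np.ndarray, freqs: np.ndarray,
                related_threshold: float = 0.1875) -> IBDEstimate:
    """Method-of-moments IBD sharing for one diploid pair.

    Observed IBS-state counts are equated to their expectations under
    IBD = 0/1/2 given the supplied allele frequencies, solved sequentially,
    truncated to [0, 1] and renormalized.  ``PI_HAT = P(IBD1)/2 + P(IBD2)``;
    the default relatedness threshold is the conventional midpoint between
    second- and third-degree relatives.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    p = np.asarray(freqs, dtype=float)
    ok = (g1 >= 0) & (g2 >= 0) & np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not ok.any():
        raise ValueError("no informative (polymorphic, non-missing) sites")
    g1, g2, p = g1[ok], g2[ok], p[ok]
    n = len(p)
    if n < 1000:
        warnings.warn(f"only {n} informative sites; IBD moments will be noisy",
                      stacklevel=2)
    q = 1.0 - p
    diff = np.abs(g1 - g2)
    n_ibs0 = float(np.sum(diff == 2))
    n_ibs1 = float(np.sum(diff == 1))
    n_ibs2 = float(np.sum(diff == 0))
    # expected per-site IBS-state probabilities given the IBD state
    e0_i0 = float(np.sum(2.0 * p ** 2 * q ** 2))
    e1_i0 = float(np.sum(4.0 * p ** 3 * q + 4.0 * p * q ** 3))
    e1_i1 = float(np.sum(2.0 * p ** 2 * q + 2.0 * p * q ** 2))
    e2_i0 = n - e0_i0 - e1_i0
    e2_i1 = n - e1_i1
    p0 = n_ibs0 / e0_i0 if e0_i0 > 0 else 0.0
    p1 = (n_ibs1 - p0 * e1_i0) / e1_i1 if e1_i1 > 0 else 0.0
    p2 = (n_ibs2 - p0 * e2_i0 - p1 * e2_i1) / n
    est = np.clip([p0, p1, p2], 0.0, 1.0)
    total = est.sum()
    if total <= 0:
        raise ValueError("degenerate IBD system (all estimates truncated to zero)")
    est = est / total
    pi_hat = est[1] / 2.0 + est[2]
    return IBDEstimate(float(est[0]), float(est[1]), float(est[2]),
                       float(pi_hat), n, bool(pi_hat > related_threshold))


# ---------------------------------------------------------------------------
# ancestry-masked haplotype PCA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MaskedPCAResult:
    hap_ids: list[str]
    coords: np.ndarray
    dropped: list[str]
    explained_variance_ratio: np.ndarray


def masked_pca(table: VariantTable, calls: Mapping[str, AncestryPath],
               ancestry: str, genetic_map: GeneticMap, k: int = 2,
               min_retained: float = 0.05) -> MaskedPCAResult:
    """Haplotype-level PCA restricted to segments called as ``ancestry``.

    Alleles on segments carrying any other call (including unassigned) are
    set missing; missing entries are mean-imputed per site before the PCA.
    Haplotypes retaining fewer than ``min_retained`` of their sites are
    dropped.  Haplotypes absent from ``calls`` are used unmasked (the usual
    choice for unadmixed reference panels).
    """
    seen = set()
    for path in calls.values():
        for tr in path.tracts.values():
            seen.update(t.label for t in tr)
    if ancestry not in seen:
        raise KeyError(f"ancestry {ancestry!r} absent from the supplied calls")
    gpos = table.gpos(genetic_map)
    hap_ids = table.haplotype_ids()
    X = table.haplotypes.T.astype(float)
    X[X == MISSING] = np.nan
    for h, hid in enumerate(hap_ids):
        path = calls.get(hid)
        if path is None:
            continue
        drop = np.zeros(table.n_sites, dtype=bool)
        for c in dict.fromkeys(table.chrom.tolist()):
            m = table.chrom == c
            drop[m] = path.label_at(str(c), gpos[m]) != ancestry
        X[h, drop] = np.nan
    retained = np.mean(~np.isnan(X), axis=1)
    keep = retained >= min_retained
    dropped = [hid for hid, k_ in zip(hap_ids, keep) if not k_]
    if dropped:
        log.warning("masked_pca: dropped %d haplotypes with < %.0f%% retained sites",
                    len(dropped), 100 * min_retained)
    X = X[keep]
    if X.shape[0] <= k:
        raise ValueError("too few haplotypes survive masking for the requested k")
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    pca = PCA(n_components=k, svd_solver="full")   # deterministic, exact
    coords = pca.fit_transform(X)
    return MaskedPCAResult([h for h, k_ in zip(hap_ids, keep) if k_],
                           coords, dropped, pca.explained_variance_ratio_)
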