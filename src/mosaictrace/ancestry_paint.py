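"""Windowed-PCA local ancestry painting of phased haplotypes.

The chromosome is tiled with fixed-size SNP windows.  Within each window,
reference haplotypes from the ancestral panels are reduced by PCA; each
panel's scores define a Gaussian class model (panel mean, pooled diagonal
covariance).  A query haplotype is projected window by window, scored
under each class, and the window log-likelihoods are smoothed along the
genetic map with a continuous-time HMM whose switch rate is expressed per
Morgan.  Windows whose posterior clears a threshold (default 0.8) are
assigned; the rest stay "unassigned".  Assigned windows are merged into
ancestry tracts, which also drive genome masking and global ancestry
fractions.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np

from .tracts import UNASSIGNED, AncestryPath, Tract
from .vcfio import MISSING, GeneticMap, VariantTable

log = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# reference window models
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class WindowModel:
    chrom: str
    sites: np.ndarray        # indices into the site frame used at fit time
    mid_morgans: float
    col_means: np.ndarray    # (w,) reference allele means, used for centering
    loadings: np.ndarray     # (w, p)
    class_means: np.ndarray  # (K, p)
    class_var: np.ndarray    # (p,) pooled diagonal covariance, floored
    informative: bool


@dataclasses.dataclass
class ReferencePCA:
    """Per-window PCA + Gaussian class models fit on reference panels."""

    windows: list[WindowModel]
    labels: list[str]
    window_size: int
    n_pcs: int

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def midpoints(self) -> np.ndarray:
        return np.array([w.mid_morgans for w in self.windows])

    def chroms(self) -> np.ndarray:
        return np.array([w.chrom for w in self.windows], dtype=object)


def fit_reference_pca(refs: VariantTable, panels: Mapping[str, Sequence[str]],
                      genetic_map: GeneticMap, window_size: int = 30,
                      n_pcs: int | None = None, var_floor: float = 1e-6,
                      ) -> ReferencePCA:
    """Fit per-window PCA and per-ancestry Gaussian score models.

    ``n_pcs`` defaults to ``max(2, K - 1)`` for ``K`` panels.  A window
    with no allele variance among the references is flagged uninformative
    and later contributes only the prior.
    """
    labels = list(panels)
    if len(labels) < 2:
        raise ValueError("need at least two reference panels")
    n_pcs = n_pcs if n_pcs is not None else max(2, len(labels) - 1)
    cols: dict[str, np.ndarray] = {}
    for lab in labels:
        cols[lab] = refs.hap_columns(panels[lab])
        if len(cols[lab]) < 2 * n_pcs:
            raise ValueError(f"panel {lab!r} has fewer than {2 * n_pcs} haplotypes")
    all_cols = np.concatenate([cols[lab] for lab in labels])
    owner = np.concatenate([np.full(len(cols[lab]), i) for i, lab in enumerate(labels)])
    H = refs.haplotypes[:, all_cols].astype(float)
    H[H == MISSING] = np.nan
    gpos = refs.gpos(genetic_map)

    windows: list[WindowModel] = []
    for c in dict.fromkeys(refs.chrom.tolist()):
        sites = np.flatnonzero(refs.chrom == c)
        for start in range(0, len(sites), window_size):
            w_sites = sites[start:start + window_size]
            X = H[w_sites].T.copy()                       # (n_ref_hap, w)
            col_means = np.nanmean(X, axis=0)
            col_means = np.where(np.isfinite(col_means), col_means, 0.5)
            nan = np.isnan(X)
            X[nan] = col_means[np.where(nan)[1]]
            Xc = X - col_means
            mid = float(np.mean(gpos[w_sites]))
            if np.allclose(Xc, 0.0):
                windows.append(WindowModel(str(c), w_sites, mid, col_means,
                                           np.zeros((len(w_sites), n_pcs)),
                                           np.zeros((len(labels), n_pcs)),
                                           np.full(n_pcs, var_floor), False))
                continue
            _, _, vt = np.linalg.svd(Xc, full_matrices=False)
            p = min(n_pcs, vt.shape[0])
            loadings = np.zeros((len(w_sites), n_pcs))
            loadings[:, :p] = vt[:p].T
            scores = Xc @ loadings
            means = np.vstack([scores[owner == i].mean(axis=0)
                               for i in range(len(labels))])
            resid = scores - means[owner]
            dof = max(scores.shape[0] - len(labels), 1)
            var = np.maximum((resid ** 2).sum(axis=0) / dof, var_floor)
            windows.append(WindowModel(str(c), w_sites, mid, col_means,
                                       loadings, means, var, True))
    return ReferencePCA(windows, labels, window_size, n_pcs)


# ---------------------------------------------------------------------------
# query scoring and HMM smoothing
# ---------------------------------------------------------------------------

def window_loglik(hap: np.ndarray, model: ReferencePCA) -> np.ndarray:
    """Per-window, per-ancestry Gaussian log-likelihood of one haplotype.

    Missing alleles are imputed to the reference window mean before
    projection.  Uninformative windows score zero for every ancestry.
    """
    hap = np.asarray(hap)
    K = len(model.labels)
    out = np.zeros((model.n_windows, K))
    for wi, w in enumerate(model.windows):
        if not w.informative:
            continue
        x = hap[w.sites].astype(float)
        miss = x == MISSING
        x[miss] = w.col_means[miss]
        s = (x - w.col_means) @ w.loadings
        d = s[None, :] - w.class_means
        out[wi] = -0.5 * np.sum(d ** 2 / w.class_var + np.log(w.class_var)
                                + _LOG2PI, axis=1)
    return out


@dataclasses.dataclass
class WindowPosterior:
    hap_id: str
    chroms: np.ndarray       # (W,)
    mid_morgans: np.ndarray  # (W,)
    posteriors: np.ndarray   # (W, K), rows sum to 1
    labels: list[str]


def hmm_posteriors(logliks: np.ndarray, mid_morgans: np.ndarray,
                   chroms: np.ndarray, switch_rate: float = 10.0,
                   priors: np.ndarray | None = None,
                   hap_id: str = "query") -> WindowPosterior:
    """Forward--backward smoothing of window log-likelihoods.

    Between windows ``d`` Morgans apart the transition kernel is
    ``exp(-rho d) I + (1 - exp(-rho d)) 1 pi^T``: with probability
    ``exp(-rho d)`` the ancestry is carried over, otherwise it is redrawn
    from the prior.  Chromosomes are smoothed independently.
    """
    ll = np.asarray(logliks, dtype=float)
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite window log-likelihoods")
    W, K = ll.shape
    pi = np.full(K, 1.0 / K) if priors is None else np.asarray(priors, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("priors must sum to 1")
    post = np.empty_like(ll)
    for c in dict.fromkeys(np.asarray(chroms).tolist()):
        w = np.flatnonzero(np.asarray(chroms) == c)
        mids = np.asarray(mid_morgans)[w]
        if np.any(np.diff(mids) < 0):
            raise ValueError(f"window midpoints not increasing on {c}")
        e = np.exp(ll[w] - ll[w].max(axis=1, keepdims=True))
        T = len(w)
        stay = np.exp(-switch_rate * np.diff(mids))
        alpha = np.empty((T, K))
        scale = np.empty(T)
        a = pi * e[0]
        scale[0] = a.sum()
        alpha[0] = a / scale[0]
        for t in range(1, T):
            pred = stay[t - 1] * alpha[t - 1] + (1.0 - stay[t - 1]) * pi
            a = pred * e[t]
            scale[t] = a.sum()
            alpha[t] = a / scale[t]
        beta = np.empty((T, K))
        beta[-1] = 1.0
        for t in range(T - 2, -1, -1):
            nxt = e[t + 1] * beta[t + 1]
            beta[t] = (stay[t] * nxt + (1.0 - stay[t]) * (pi @ nxt)) / scale[t + 1]
        g = alpha * beta
        post[w] = g / g.sum(axis=1, keepdims=True)
    return WindowPosterior(hap_id, np.asarray(chroms, dtype=object),
                           np.asarray(mid_morgans, dtype=float), post,
                           labels=[str(k) for k in range(K)])


# ---------------------------------------------------------------------------
# calling, masking, fractions
# ---------------------------------------------------------------------------

def call_ancestry(post: WindowPosterior, genetic_map: GeneticMap,
                  labels: Sequence[str] | None = None,
                  threshold: float = 0.8) -> AncestryPath:
    """Threshold posteriors into an ancestry path.

    A window is assigned to its argmax ancestry when that posterior is
    ``>= threshold`` (ties at the boundary pass), otherwise it is
    "unassigned".  Tract boundaries fall midway between adjacent window
    midpoints; chromosome ends extend to [0, L].  Unassigned windows break
    tracts; they are never bridged.
    """
    labels = list(labels) if labels is not None else list(post.labels)
    K = post.posteriors.shape[1]
    if not (1.0 / K < threshold <= 1.0):
        raise ValueError(f"threshold must lie in (1/{K}, 1]")
    tracts: dict[str, list[Tract]] = {}
    for c in dict.fromkeys(post.chroms.tolist()):
        w = np.flatnonzero(post.chroms == c)
        p = post.posteriors[w]
        mids = post.mid_morgans[w]
        best = np.argmax(p, axis=1)
        called = p[np.arange(len(w)), best] >= threshold
        win_labels = [labels[b] if ok else UNASSIGNED for b, ok in zip(best, called)]
        L = genetic_map.chrom_length(str(c))
        edges = np.concatenate([[0.0], (mids[1:] + mids[:-1]) / 2.0, [L]])
        out: list[Tract] = []
        for i, lab in enumerate(win_labels):
            if out and out[-1].label == lab:
                out[-1] = Tract(out[-1].start, edges[i + 1], lab)
            else:
                out.append(Tract(edges[i], edges[i + 1], lab))
        tracts[str(c)] = out
    return AncestryPath(tracts)


def mask_genome(table: VariantTable, calls: Mapping[str, AncestryPath],
                keep: str, genetic_map: GeneticMap) -> VariantTable:
    """Set haplotype alleles outside ``keep`` tracts (incl. unassigned) missing.

    Only haplotypes present in ``calls`` are touched, so reference samples
    pass through unchanged.  Downstream frequency code uses non-missing
    haplotypes only, so diploid sites may become hemi-informative.
    """
    out = table.copy()
    gpos = table.gpos(genetic_map)
    hap_ids = table.haplotype_ids()
    chrom_masks = {c: table.chrom == c for c in dict.fromkeys(table.chrom.tolist())}
    for h, hid in enumerate(hap_ids):
        path = calls.get(hid)
        if path is None:
            continue
        for c, m in chrom_masks.items():
            lab = path.label_at(str(c), gpos[m])
            col = out.haplotypes[:, h]
            sites = np.flatnonzero(m)[lab != keep]
            col[sites] = MISSING
    return out


def global_fractions(paths: Sequence[AncestryPath]) -> dict[str, float]:
    """Ancestry fractions of assigned genetic length, pooled over paths.

    The unassigned share of the *total* length is reported separately
    under the "unassigned" key; assigned fractions sum to 1.
    """
    lengths: dict[str, float] = {}
    for p in paths:
        for lab, L in p.lengths_by_label().items():
            lengths[lab] = lengths.get(lab, 0.0) + L
    unassigned = lengths.pop(UNASSIGNED, 0.0)
    assigned = sum(lengths.values())
    if assigned <= 0:
        raise ValueError("zero assigned genetic length")
    total = assigned + unassigned
    out = {lab: L / assigned for lab, L in lengths.items()}
    out[UNASSIGNED] = unassigned / total
    return out


def paint_haplotypes(refs: VariantTable, panels: Mapping[str, Sequence[str]],
                     queries: VariantTable, genetic_map: GeneticMap,
                     window_size: int = 30, n_pcs: int | None = None,
                     switch_rate: float = 10.0, threshold: float = 0.8,
                     ) -> tuple[dict[str, WindowPosterior], dict[str, AncestryPath]]:
    """Paint every query haplotype against the reference panels.

    Convenience wrapper chaining :func:`fit_reference_pca`,
    :func:`window_loglik`, :func:`hmm_posteriors` and
    :func:`call_ancestry`.  Queries must share the reference site frame.
    """
    if not (np.array_equal(queries.chrom, refs.chrom)
            and np.array_equal(queries.pos, refs.pos)):
        raise ValueError("queries and references must share one site frame")
    model = fit_reference_pca(refs, panels, genetic_map, window_size, n_pcs)
    mids = model.midpoints()
    chroms = model.chroms()
    posteriors: dict[str, WindowPosterior] = {}
    calls: dict[str, AncestryPath] = {}
    for h, hid in enumerate(queries.haplotype_ids()):
        ll = window_loglik(queries.haplotypes[:, h], model)
        post = hmm_posteriors(ll, mids, chroms, switch_rate, hap_id=hid)
        post.labels = list(model.labels)
        posteriors[hid] = post
        calls[hid] = call_ancestry(post, genetic_map, model.labels, threshold)
    return posteriors, calls
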