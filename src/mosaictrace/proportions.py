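"""Supervised maximum-likelihood ancestry proportions.

For a single individual with diploid dosages ``g_s`` and fixed reference
allele frequencies ``f_{ks}``, the admixture fractions ``q`` maximize

    sum_s [ g_s log(sum_k q_k f_ks) + (2 - g_s) log(sum_k q_k (1 - f_ks)) ]

over the probability simplex.  With the frequencies fixed this is a
concave mixture problem solved by EM on allele-wise responsibilities;
the log-likelihood is non-decreasing every iteration and the uniform
start is benign.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .simulate import FreqTable

log = logging.getLogger(__name__)

_FREQ_CLIP = 1e-6


@dataclasses.dataclass
class AncestryProportions:
    labels: list[str]
    q: np.ndarray
    log_likelihood: float
    iterations: int
    converged: bool
    non_identifiable: bool

    def __post_init__(self) -> None:
        if np.any(self.q < -1e-12) or abs(self.q.sum() - 1.0) > 1e-9:
            raise ValueError("q must lie on the probability simplex")

    def as_dict(self) -> dict[str, float]:
        return {lab: float(v) for lab, v in zip(self.labels, self.q)}


def _loglik(g, two_minus_g, f, q):
    theta = f @ q
    return float(g @ np.log(theta) + two_minus_g @ np.log1p(-theta))


def supervised_em(dosages: np.ndarray, ref_freqs: FreqTable | np.ndarray,
                  labels: Sequence[str] | None = None,
                  tol: float = 1e-7, max_iter: int = 2000) -> AncestryProportions:
    """EM estimate of one individual's ancestry fractions.

    ``ref_freqs`` is a :class:`~mosaictrace.simulate.FreqTable` or a plain
    (n_sites, K) frequency array; frequencies are clipped to
    ``[1e-6, 1 - 1e-6]``.  Missing dosages (negative) are skipped
    site-wise.  Exactly duplicated frequency columns make the split
    between those ancestries non-identifiable; the EM's symmetric start
    then returns the uniform split among them, and the result is flagged.
    """
    if isinstance(ref_freqs, FreqTable):
        labels = list(ref_freqs.populations) if labels is None else list(labels)
        f = ref_freqs.subset_pops(labels).freqs
    else:
        f = np.asarray(ref_freqs, dtype=float)
        labels = [str(k) for k in range(f.shape[1])] if labels is None else list(labels)
    g = np.asarray(dosages, dtype=float)
    if g.shape[0] != f.shape[0]:
        raise ValueError("dosages and frequencies disagree on site count")
    keep = g >= 0
    g, f = g[keep], np.clip(f[keep], _FREQ_CLIP, 1.0 - _FREQ_CLIP)
    if g.size == 0:
        raise ValueError("no non-missing genotypes")
    K = f.shape[1]
    non_ident = any(np.allclose(f[:, a], f[:, b])
                    for a in range(K) for b in range(a + 1, K))
    if non_ident:
        log.warning("supervised_em: duplicated frequency columns; "
                    "the split among tied ancestries is not identifiable")
    if K == 1:
        ll = _loglik(g, 2.0 - g, f, np.ones(1))
        return AncestryProportions(labels, np.ones(1), ll, 0, True, non_ident)

    two_minus_g = 2.0 - g
    n_alleles = 2.0 * len(g)
    q = np.full(K, 1.0 / K)
    ll_prev = _loglik(g, two_minus_g, f, q)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        theta = f @ q
        # allele-wise responsibilities for derived and ancestral copies
        r_der = (q * f) / theta[:, None]
        r_anc = (q * (1.0 - f)) / (1.0 - theta)[:, None]
        q = (g @ r_der + two_minus_g @ r_anc) / n_alleles
        q = np.maximum(q, 0.0)
        q /= q.sum()
        ll = _loglik(g, two_minus_g, f, q)
        if ll < ll_prev - 1e-8:
            raise RuntimeError(f"EM log-likelihood decreased: {ll_prev} -> {ll}")
        if ll - ll_prev < tol:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    if not converged:
        log.warning("supervised_em: no convergence in %d iterations", max_iter)
    return AncestryProportions(labels, q, ll_prev, it, converged, non_ident)
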