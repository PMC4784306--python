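"""Patterson's D (four-population test) with a weighted block jackknife.

``D(P1, P2; P3, O) = sum (p1-p2)(p3-p4) / sum (p1+p2-2 p1 p2)(p3+p4-2 p3 p4)``
over biallelic sites, with frequencies polarized so the outgroup carries
the ancestral state.  ``D > 0`` means P1 shares an excess of derived
alleles with P3; ``D < 0`` means P2 does.  Standard errors come from a
leave-one-block-out jackknife over contiguous physical blocks (default
5 Mb), weighted by each block's informative-site count (Busing-style),
and significance is read from ``Z = D / SE``.

When the ancestral allele is taken as the outgroup directly
(``outgroup="AA"``), the polarized outgroup frequency is identically
zero, which sidesteps the genotype-encoding ambiguity of a synthetic
outgroup sample.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .popstats import allele_freqs
from .vcfio import VariantTable

log = logging.getLogger(__name__)


@dataclasses.dataclass
class DStatResult:
    d: float
    se: float
    z: float
    n_sites: int
    n_blocks: int
    config: str

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.d <= 1.0 + 1e-12:
            raise ValueError(f"|D| > 1: {self.d}")


def d_statistic(p1, p2, p3, p4):
    """Per-site ABBA/BABA numerators and denominators plus the pooled D.

    Sites where any frequency is missing (NaN) contribute nothing and are
    masked out of the returned arrays.  Returns ``(num, den, used, D)``
    where ``used`` marks the retained sites.
    """
    arrs = [np.asarray(p, dtype=float) for p in (p1, p2, p3, p4)]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("frequency vectors must have equal length")
    p1, p2, p3, p4 = arrs
    used = np.isfinite(p1) & np.isfinite(p2) & np.isfinite(p3) & np.isfinite(p4)
    num = np.zeros(n)
    den = np.zeros(n)
    num[used] = (p1[used] - p2[used]) * (p3[used] - p4[used])
    den[used] = ((p1[used] + p2[used] - 2 * p1[used] * p2[used])
                 * (p3[used] + p4[used] - 2 * p3[used] * p4[used]))
    total_den = den.sum()
    if total_den == 0:
        raise ValueError("zero D denominator: no informative sites "
                         f"({int(used.sum())} sites with complete frequencies)")
    return num, den, used, float(num.sum() / total_den)


def block_jackknife(num: np.ndarray, den: np.ndarray, chrom: np.ndarray,
                    pos: np.ndarray, used: np.ndarray | None = None,
                    block_bp: int = 5_000_000, config: str = "D") -> DStatResult:
    """Weighted leave-one-block-out jackknife over contiguous physical blocks.

    Blocks are ``block_bp`` windows per chromosome (last partial block
    kept); block weights are informative-site counts.  Identical
    leave-one-out estimates (SE = 0) raise a diagnostics error rather than
    reporting an infinite Z.
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    used = np.ones(len(num), dtype=bool) if used is None else np.asarray(used, bool)
    pos = np.asarray(pos)
    block_key = np.array([f"{c}:{int(p) // int(block_bp)}"
                          for c, p in zip(chrom, pos)], dtype=object)
    blocks = list(dict.fromkeys(block_key[used].tolist()))
    g = len(blocks)
    if g < 2:
        raise ValueError("need at least two non-empty blocks for the jackknife")
    b_num = np.array([num[(block_key == b)].sum() for b in blocks])
    b_den = np.array([den[(block_key == b)].sum() for b in blocks])
    b_m = np.array([float((used & (block_key == b)).sum()) for b in blocks])
    tot_num, tot_den, n = num.sum(), den.sum(), b_m.sum()
    if tot_den == 0:
        raise ValueError("zero D denominator")
    theta = tot_num / tot_den
    loo_den = tot_den - b_den
    if np.any(loo_den == 0):
        raise ValueError("a leave-one-out denominator is zero; blocks too coarse")
    theta_j = (tot_num - b_num) / loo_den
    # Busing et al. weighted delete-one jackknife
    h = n / b_m
    theta_dot = g * theta - np.sum((1.0 - b_m / n) * theta_j)
    pseudo = h * theta - (h - 1.0) * theta_j
    var = np.sum((pseudo - theta_dot) ** 2 / (h - 1.0)) / g
    se = float(np.sqrt(var))
    if se == 0.0:
        raise ValueError("degenerate jackknife: all leave-one-block-out estimates "
                         "are identical (SE = 0)")
    return DStatResult(float(theta), se, float(theta / se),
                       int(used.sum()), g, config)


def polarized_freqs(table: VariantTable, group) -> np.ndarray:
    """Derived-allele frequency for a group, polarized by the ancestral allele.

    Sites whose ancestral allele is missing or matches neither REF nor ALT
    get NaN; where the ancestral allele is ALT the frequency is flipped.
    """
    f, _ = allele_freqs(table, group)
    f = f.copy()
    flip = table.ancestral == table.alt
    keep = flip | (table.ancestral == table.ref)
    f[flip] = 1.0 - f[flip]
    f[~keep] = np.nan
    return f


def dstat_test(table: VariantTable, p1, p2, p3, outgroup: str = "AA",
               block_bp: int = 5_000_000, config: str | None = None) -> DStatResult:
    """Run ``D(P1, P2; P3, Outgroup)`` on a merged variant table.

    ``p1``/``p2``/``p3`` are population labels or explicit sample lists.
    With ``outgroup="AA"`` the ancestral state itself is the outgroup
    (polarized ``p4 = 0``); otherwise ``outgroup`` names a sample or
    population (e.g. a synthetic all-ancestral individual) whose allele
    frequency is used.  Masked samples contribute their non-missing
    haplotypes only.
    """
    groups = [table.samples_in(p) for p in (p1, p2, p3)]
    if outgroup != "AA":
        groups.append(table.samples_in([outgroup] if outgroup in table.samples
                                       else outgroup))
    flat = [s for grp in groups for s in grp]
    if len(set(flat)) != len(flat):
        raise ValueError("a sample appears in more than one role")
    f1, f2, f3 = (polarized_freqs(table, g) for g in groups[:3])
    if outgroup == "AA":
        f4 = np.zeros_like(f1)
        f4[~np.isfinite(f1)] = np.nan
    else:
        f4 = polarized_freqs(table, groups[3])
    num, den, used, d = d_statistic(f1, f2, f3, f4)
    name = config or f"D({p1}, {p2}; {p3}, {'AA' if outgroup == 'AA' else outgroup})"
    return block_jackknife(num, den, table.chrom, table.pos, used,
                           block_bp=block_bp, config=name)
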