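"""Synthetic reference panels and admixed genomes with known ancestry truth.

Reference-panel allele frequencies follow the Balding--Nichols model:
given an ancestral frequency ``p`` and a differentiation parameter
``F`` (an FST analogue), each population's frequency is an independent
``Beta(p (1-F)/F, (1-p)(1-F)/F)`` draw.  Admixed genomes come from an
explicit forward-in-time Wright--Fisher simulation with pulse migration
and Poisson crossovers (one per Morgan per meiosis, no interference),
which yields exact per-haplotype ancestry tracts.

Pulse convention: a pulse ``T`` generations ago replaces each haplotype
of the receiving generation independently with an unadmixed migrant
haplotype with probability ``m``.  Present-day haplotypes are then
separated from the migrants by ``T`` meioses, so ancestry junctions
accumulate at density ``T`` per Morgan and tracts of an ancestry with
fraction ``m`` are approximately Exponential with rate ``(1-m) T`` --
the same convention the tract-dating likelihood uses.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from bisect import bisect_right
from typing import Mapping, Sequence

import numpy as np

from .tracts import AncestryPath, Tract
from .vcfio import GeneticMap, VariantTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# frequency tables
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FreqTable:
    """Per-site, per-population derived-allele frequencies on a genome frame."""

    populations: list[str]
    p_anc: np.ndarray          # ancestral (pre-divergence) derived frequency
    freqs: np.ndarray          # (n_sites, n_pops)
    chrom: np.ndarray          # site chromosome ids
    pos: np.ndarray            # 1-based bp
    gpos: np.ndarray           # Morgans within chromosome

    @property
    def n_sites(self) -> int:
        return len(self.p_anc)

    def freq(self, population: str) -> np.ndarray:
        return self.freqs[:, self.pop_index(population)]

    def pop_index(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"population {population!r} not in table") from None

    def subset_pops(self, populations: Sequence[str]) -> "FreqTable":
        idx = [self.pop_index(p) for p in populations]
        return FreqTable(list(populations), self.p_anc, self.freqs[:, idx],
                         self.chrom, self.pos, self.gpos)

    def with_population(self, name: str, freqs: np.ndarray) -> "FreqTable":
        """Return a table extended (or overwritten) with one population column."""
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (self.n_sites,):
            raise ValueError("frequency column has wrong length")
        if name in self.populations:
            out = self.freqs.copy()
            out[:, self.pop_index(name)] = freqs
            return FreqTable(list(self.populations), self.p_anc, out,
                             self.chrom, self.pos, self.gpos)
        return FreqTable(self.populations + [name], self.p_anc,
                         np.column_stack([self.freqs, freqs]),
                         self.chrom, self.pos, self.gpos)


def _site_frame(n_sites: int, genetic_map: GeneticMap):
    """Spread sites evenly in genetic distance across the genome."""
    chroms = genetic_map.chroms
    lengths = np.array([genetic_map.chrom_length(c) for c in chroms])
    total = lengths.sum()
    t = (np.arange(n_sites) + 0.5) / n_sites * total
    offsets = np.concatenate([[0.0], np.cumsum(lengths)])
    ci = np.minimum(np.searchsorted(offsets, t, side="right") - 1, len(chroms) - 1)
    gpos = t - offsets[ci]
    chrom = np.array([chroms[i] for i in ci], dtype=object)
    pos = np.empty(n_sites, dtype=np.int64)
    for i, c in enumerate(chroms):
        m = ci == i
        pos[m] = np.round(genetic_map.bp_at(c, gpos[m])).astype(np.int64)
        # bp rounding must keep positions strictly increasing
        if m.sum() > 1:
            p = pos[m]
            for j in range(1, len(p)):
                if p[j] <= p[j - 1]:
                    p[j] = p[j - 1] + 1
            pos[m] = p
    return chrom, pos, gpos


def sample_ref_freqs(n_sites: int, populations: Sequence[str],
                     fst: float | Mapping[str, float],
                     seed=None, rng: np.random.Generator | None = None,
                     anc_freq_bounds: tuple[float, float] = (0.05, 0.95),
                     genetic_map: GeneticMap | None = None) -> FreqTable:
    """Draw Balding--Nichols reference-panel frequencies.

    ``fst`` may be a scalar (shared by all populations) or a per-population
    mapping; each value must lie strictly in (0, 1).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    lo, hi = anc_freq_bounds
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("ancestral frequency bounds must lie strictly inside (0, 1)")
    if not isinstance(fst, Mapping):
        fst = {p: float(fst) for p in populations}
    for p in populations:
        f = fst.get(p)
        if f is None or not (0.0 < f < 1.0):
            raise ValueError(f"fst for {p!r} must be in (0, 1), got {f}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    if genetic_map is None:
        genetic_map = GeneticMap.uniform()
    p_anc = rng.uniform(lo, hi, n_sites)
    cols = []
    for pop in populations:
        F = fst[pop]
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        cols.append(rng.beta(a, b))
    chrom, pos, gpos = _site_frame(n_sites, genetic_map)
    return FreqTable(list(populations), p_anc, np.column_stack(cols), chrom, pos, gpos)


# ---------------------------------------------------------------------------
# panels
# ---------------------------------------------------------------------------

def _table_from_haplotypes(freqs: FreqTable, hap: np.ndarray, prefix: str,
                           population: str) -> VariantTable:
    n_hap = hap.shape[1]
    samples = [f"{prefix}{i}" for i in range(n_hap // 2)]
    S = freqs.n_sites
    return VariantTable(
        freqs.chrom, freqs.pos,
        np.full(S, "A", dtype=object), np.full(S, "G", dtype=object),
        np.full(S, "A", dtype=object),   # ancestral == REF: ALT is the derived allele
        hap.astype(np.int8), samples, {s: population for s in samples},
    )


def simulate_panel(freqs: FreqTable, population: str, n_hap: int,
                   seed=None, rng: np.random.Generator | None = None,
                   sample_prefix: str | None = None) -> VariantTable:
    """Draw a phased panel: haplotype alleles are Bernoulli(f) per site."""
    if n_hap < 1:
        raise ValueError("n_hap must be >= 1")
    if n_hap % 2:
        raise ValueError("n_hap must be even (haplotypes are paired into diploids)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    f = freqs.freq(population)
    hap = (rng.random((freqs.n_sites, n_hap)) < f[:, None]).astype(np.int8)
    return _table_from_haplotypes(freqs, hap, sample_prefix or f"{population}_", population)


# ---------------------------------------------------------------------------
# pulse histories and the forward simulator
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Pulse:
    generation: int
    ancestry: str
    fraction: float


@dataclasses.dataclass
class PulseHistory:
    """Founding ancestry plus ordered migration pulses (oldest first)."""

    founding: str
    pulses: tuple[Pulse, ...] = ()

    def __post_init__(self) -> None:
        gens = [p.generation for p in self.pulses]
        if any(g < 1 for g in gens):
            raise ValueError("pulse generations must be >= 1")
        if any(g1 <= g2 for g1, g2 in zip(gens, gens[1:])):
            raise ValueError("pulse generations must be strictly decreasing (oldest first)")
        if any(not (0.0 < p.fraction < 1.0) for p in self.pulses):
            raise ValueError("pulse fractions must lie in (0, 1)")
        seen = {(p.generation, p.ancestry) for p in self.pulses}
        if len(seen) != len(self.pulses):
            raise ValueError("at most one pulse per (generation, ancestry)")

    def ancestries(self) -> list[str]:
        out = [self.founding]
        for p in self.pulses:
            if p.ancestry not in out:
                out.append(p.ancestry)
        return out

    def expected_fractions(self) -> dict[str, float]:
        """Expected final ancestry fractions under the replacement model."""
        frac = {self.founding: 1.0}
        for p in self.pulses:
            for k in frac:
                frac[k] *= 1.0 - p.fraction
            frac[p.ancestry] = frac.get(p.ancestry, 0.0) + p.fraction
        return frac


# a haplotype chromosome is (ends, labels): tract end positions in Morgans
_HapChrom = tuple[list, list]


def _cross(h1: _HapChrom, h2: _HapChrom, xs: np.ndarray, start: int,
           L: float) -> _HapChrom:
    """Recombine two parental chromosomes at crossover points ``xs``."""
    haps = (h1, h2)
    cur = start
    out_e: list = []
    out_l: list = []
    prev = 0.0
    for x in list(xs) + [L]:
        ends, labs = haps[cur]
        i = bisect_right(ends, prev)
        while i < len(ends) and ends[i] < x:
            e, lab = ends[i], labs[i]
            if out_l and out_l[-1] == lab:
                out_e[-1] = e
            elif not out_e or e > out_e[-1]:
                out_e.append(e)
                out_l.append(lab)
            i += 1
        lab = labs[min(i, len(labs) - 1)]
        if out_l and out_l[-1] == lab:
            out_e[-1] = x
        elif not out_e or x > out_e[-1]:
            out_e.append(x)
            out_l.append(lab)
        prev = x
        cur ^= 1
    return (out_e, out_l)


def _next_generation(pop: list, lengths: Sequence[float],
                     rng: np.random.Generator) -> list:
    """One round of random-mating Wright--Fisher reproduction."""
    N = len(pop)
    C = len(lengths)
    parents = rng.integers(0, N, size=(N, 2))
    counts = rng.poisson(lam=np.asarray(lengths), size=(N, 2, C))
    starts = rng.integers(0, 2, size=(N, 2, C))
    total = int(counts.sum())
    flat = rng.random(total)
    offsets = np.concatenate([[0], np.cumsum(counts.reshape(-1))])
    nxt = []
    slot = 0
    for i in range(N):
        ind = []
        for j in (0, 1):
            par = pop[parents[i, j]]
            hap = []
            for c in range(C):
                k = counts[i, j, c]
                s = starts[i, j, c]
                if k == 0:
                    hap.append(par[s][c])
                else:
                    xs = np.sort(flat[offsets[slot + c]:offsets[slot + c] + k]) * lengths[c]
                    hap.append(_cross(par[0][c], par[1][c], xs, s, lengths[c]))
            slot += C
            ind.append(hap)
        nxt.append(ind)
    return nxt


def simulate_admixed_forward(history: PulseHistory, genetic_map: GeneticMap,
                             pop_size: int = 500, n_out: int = 2,
                             seed=None, rng: np.random.Generator | None = None,
                             founding_generation: int | None = None,
                             ) -> list[AncestryPath]:
    """Forward Wright--Fisher simulation of pulse admixture.

    Returns exact ancestry tracts for ``n_out`` haplotypes sampled without
    replacement from the final generation.
    """
    if not genetic_map.chroms:
        raise ValueError("empty genetic map")
    if pop_size < 50:
        warnings.warn(f"pop_size={pop_size} is small; drift will be strong", stacklevel=2)
    rng = rng if rng is not None else np.random.default_rng(seed)
    chroms = genetic_map.chroms
    lengths = [genetic_map.chrom_length(c) for c in chroms]
    deepest = max((p.generation for p in history.pulses), default=0)
    if founding_generation is not None and founding_generation < deepest:
        raise ValueError("pulses deeper than the founding generation")
    if n_out > 2 * pop_size:
        raise ValueError("n_out exceeds the number of haplotypes in the population")

    def whole(label: str):
        return [([L], [label]) for L in lengths]

    pop = [[whole(history.founding), whole(history.founding)] for _ in range(pop_size)]
    by_gen: dict[int, list[Pulse]] = {}
    for p in history.pulses:
        by_gen.setdefault(p.generation, []).append(p)
    for g in range(deepest, 0, -1):
        for pulse in by_gen.get(g, ()):
            migrant = whole(pulse.ancestry)
            replace = rng.random((pop_size, 2)) < pulse.fraction
            for i in range(pop_size):
                for j in (0, 1):
                    if replace[i, j]:
                        pop[i][j] = migrant
        pop = _next_generation(pop, lengths, rng)

    idx = rng.choice(2 * pop_size, size=n_out, replace=False)
    out = []
    for h in idx:
        hap = pop[h // 2][h % 2]
        out.append(AncestryPath({
            c: [Tract(0.0 if i == 0 else hap[ci][0][i - 1], e, lab)
                for i, (e, lab) in enumerate(zip(hap[ci][0], hap[ci][1]))]
            for ci, c in enumerate(chroms)
        }))
    return out


# ---------------------------------------------------------------------------
# genotype painting from truth paths
# ---------------------------------------------------------------------------

def paint_alleles(paths: Sequence[AncestryPath], freqs: FreqTable,
                  seed=None, rng: np.random.Generator | None = None,
                  sample_prefix: str = "ADMIX_", population: str = "ADMIX",
                  ) -> VariantTable:
    """Draw phased alleles for each haplotype from its tract ancestries.

    Site ``s`` on a tract of ancestry ``a`` carries the derived allele with
    probability ``f_{a,s}``.  Paths are paired in order into diploids.
    """
    if len(paths) % 2:
        raise ValueError("need an even number of haplotype paths")
    rng = rng if rng is not None else np.random.default_rng(seed)
    labels = set()
    for p in paths:
        for tr in p.tracts.values():
            labels.update(t.label for t in tr)
    unknown = labels - set(freqs.populations)
    if unknown:
        raise KeyError(f"ancestries absent from frequency table: {sorted(unknown)}")
    pop_idx = {p: i for i, p in enumerate(freqs.populations)}
    chrom_slices = {}
    for c in dict.fromkeys(freqs.chrom.tolist()):
        w = np.flatnonzero(freqs.chrom == c)
        chrom_slices[c] = w
    hap = np.empty((freqs.n_sites, len(paths)), dtype=np.int8)
    for h, path in enumerate(paths):
        for c, sites in chrom_slices.items():
            lab = path.label_at(c, freqs.gpos[sites])
            ki = np.array([pop_idx[l] for l in lab])
            f = freqs.freqs[sites, ki]
            hap[sites, h] = rng.random(len(sites)) < f
    return _table_from_haplotypes(freqs, hap, sample_prefix, population)


def simulate_admixture_dosages(q: Sequence[float], freqs: FreqTable,
                               populations: Sequence[str] | None = None,
                               seed=None, rng: np.random.Generator | None = None,
                               ) -> np.ndarray:
    """Diploid dosages from the site-independent mixture model.

    Each allele copy draws its ancestry from ``q`` and is then Bernoulli
    with that ancestry's frequency, i.e. dosage ~ Binomial(2, f @ q).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    q = np.asarray(q, dtype=float)
    if populations is not None:
        f = freqs.subset_pops(populations).freqs
    else:
        f = freqs.freqs
    if len(q) != f.shape[1]:
        raise ValueError("q length does not match number of populations")
    if abs(q.sum() - 1.0) > 1e-9 or np.any(q < 0):
        raise ValueError("q must be a probability vector")
    theta = f @ q
    return rng.binomial(2, theta).astype(np.int8)
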