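"""VCF, genetic-map and sample-grouping I/O for phased biallelic SNP data.

The supported VCF dialect is deliberately small: VCFv4.2, biallelic SNPs
only, a ``GT`` FORMAT field, and an optional ``INFO/AA`` ancestral-allele
tag.  Parsing goes through :mod:`cyvcf2`; writing emits a fixed header so
that ``write_vcf(read_vcf(x))`` is byte-identical on files produced by
this module.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

log = logging.getLogger(__name__)

MISSING = np.int8(-1)
_BASES = frozenset("ACGT")
#: strand-ambiguous REF/ALT pairs, indistinguishable after a strand flip
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VariantTable:
    """Phased biallelic SNP matrix.

    ``haplotypes`` has shape ``(n_sites, 2 * n_samples)`` with codes
    0 (REF), 1 (ALT) and -1 (missing); the two haplotypes of sample ``i``
    occupy columns ``2 i`` and ``2 i + 1``.  ``ancestral`` holds one base
    per site or ``""`` when the ancestral state is unknown.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    ancestral: np.ndarray
    haplotypes: np.ndarray
    samples: list[str]
    populations: dict[str, str] = dataclasses.field(default_factory=dict)
    phased: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.phased is None:
            self.phased = np.ones(len(self.samples), dtype=bool)

    # -- shape -------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return 2 * len(self.samples)

    def haplotype_ids(self) -> list[str]:
        return [f"{s}_h{j}" for s in self.samples for j in (0, 1)]

    # -- access ------------------------------------------------------------
    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    def hap_columns(self, names: Sequence[str]) -> np.ndarray:
        cols = []
        for n in names:
            i = self.sample_index(n)
            cols += [2 * i, 2 * i + 1]
        return np.array(cols, dtype=int)

    def samples_in(self, group: str | Sequence[str]) -> list[str]:
        """Resolve a population label or explicit sample list to sample names."""
        if isinstance(group, str):
            out = [s for s in self.samples if self.populations.get(s) == group]
            if not out:
                raise KeyError(f"no samples in population {group!r}")
            return out
        return list(group)

    def dosage(self) -> np.ndarray:
        """Diploid ALT dosage (n_sites, n_samples); -1 if either haplotype missing."""
        h = self.haplotypes
        a = h[:, 0::2]
        b = h[:, 1::2]
        d = (a + b).astype(np.int8)
        d[(a == MISSING) | (b == MISSING)] = MISSING
        return d

    # -- subsetting --------------------------------------------------------
    def subset_samples(self, names: Sequence[str]) -> "VariantTable":
        cols = self.hap_columns(names)
        idx = [self.sample_index(n) for n in names]
        return VariantTable(
            self.chrom, self.pos, self.ref, self.alt, self.ancestral,
            self.haplotypes[:, cols], list(names),
            {n: self.populations[n] for n in names if n in self.populations},
            self.phased[idx].copy(),
        )

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(
            self.chrom[mask], self.pos[mask], self.ref[mask], self.alt[mask],
            self.ancestral[mask], self.haplotypes[mask], list(self.samples),
            dict(self.populations), self.phased.copy(),
        )

    def copy(self) -> "VariantTable":
        return VariantTable(
            self.chrom.copy(), self.pos.copy(), self.ref.copy(), self.alt.copy(),
            self.ancestral.copy(), self.haplotypes.copy(), list(self.samples),
            dict(self.populations), self.phased.copy(),
        )

    def gpos(self, genetic_map: "GeneticMap") -> np.ndarray:
        """Genetic position (Morgans) of every site under ``genetic_map``."""
        out = np.empty(self.n_sites, dtype=float)
        for c in np.unique(self.chrom):
            m = self.chrom == c
            out[m] = genetic_map.morgans_at(str(c), self.pos[m])
        return out

    def validate(self) -> None:
        if self.haplotypes.shape != (self.n_sites, self.n_haplotypes):
            raise ValueError("haplotype matrix shape mismatch")
        codes = np.unique(self.haplotypes)
        if not np.all(np.isin(codes, [-1, 0, 1])):
            raise ValueError(f"invalid allele codes {codes}")
        for c in dict.fromkeys(self.chrom.tolist()):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")


@dataclasses.dataclass
class GeneticMap:
    """Piecewise-linear bp <-> Morgans interpolation per chromosome."""

    bp: dict[str, np.ndarray]
    morgans: dict[str, np.ndarray]

    @property
    def chroms(self) -> list[str]:
        return list(self.bp)

    @classmethod
    def uniform(cls, n_chrom: int = 22, morgans: float = 1.5,
                bp_per_morgan: float = 1e8) -> "GeneticMap":
        """A constant-rate genome (default 22 chromosomes of 1.5 M at 1 cM/Mb)."""
        bp = {}
        gm = {}
        for i in range(1, n_chrom + 1):
            bp[str(i)] = np.array([1.0, morgans * bp_per_morgan])
            gm[str(i)] = np.array([0.0, morgans])
        return cls(bp, gm)

    def morgans_at(self, chrom: str, pos) -> np.ndarray:
        return np.interp(np.asarray(pos, dtype=float), self.bp[chrom], self.morgans[chrom])

    def bp_at(self, chrom: str, gpos) -> np.ndarray:
        return np.interp(np.asarray(gpos, dtype=float), self.morgans[chrom], self.bp[chrom])

    def chrom_length(self, chrom: str) -> float:
        return float(self.morgans[chrom][-1])

    def lengths(self) -> dict[str, float]:
        return {c: self.chrom_length(c) for c in self.chroms}

    def total_length(self) -> float:
        return sum(self.chrom_length(c) for c in self.chroms)

    @classmethod
    def read(cls, path) -> "GeneticMap":
        """Read a 4-column map: chrom, bp, rate(cM/Mb, unused), cumulative Morgans."""
        bp: dict[str, list] = {}
        gm: dict[str, list] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                c, b, _rate, m = line.split()[:4]
                bp.setdefault(c, []).append(float(b))
                gm.setdefault(c, []).append(float(m))
        out = cls({c: np.array(v) for c, v in bp.items()},
                  {c: np.array(v) for c, v in gm.items()})
        for c in out.chroms:
            if np.any(np.diff(out.morgans[c]) < 0):
                raise ValueError(f"map on {c} is not non-decreasing")
        return out

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tbp\trate_cM_Mb\tmorgans\n")
            for c in self.chroms:
                b, m = self.bp[c], self.morgans[c]
                for i in range(len(b)):
                    if i == 0:
                        rate = 0.0
                    else:
                        db = b[i] - b[i - 1]
                        rate = 1e8 * (m[i] - m[i - 1]) / db if db > 0 else 0.0
                    fh.write(f"{c}\t{int(b[i])}\t{rate:.6f}\t{m[i]:.8f}\n")


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_vcf(path, sample_subset: Sequence[str] | None = None,
             populations: Mapping[str, str] | None = None) -> VariantTable:
    """Read phased biallelic SNPs from a VCF file.

    Multi-allelic and non-SNP records are skipped (with a logged count).
    ``INFO/AA`` is parsed case-insensitively; non-ACGT values are treated
    as missing.  Samples whose genotypes use ``/`` separators anywhere are
    flagged unphased.
    """
    vcf = VCF(str(path), samples=list(sample_subset) if sample_subset else None)
    samples = list(vcf.samples)
    if sample_subset is not None:
        missing = set(sample_subset) - set(samples)
        if missing:
            raise KeyError(f"samples not in VCF: {sorted(missing)}")
    chrom, pos, ref, alt, anc, rows = [], [], [], [], [], []
    phased = np.ones(len(samples), dtype=bool)
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1 \
                or v.REF not in _BASES or v.ALT[0] not in _BASES:
            n_skipped += 1
            continue
        aa = v.INFO.get("AA")
        if aa is not None:
            aa = str(aa).upper()
            if aa not in _BASES:
                aa = ""
        else:
            aa = ""
        g = np.array(v.genotypes, dtype=object)
        alleles = np.array([[int(row[0]), int(row[1])] for row in g], dtype=np.int8)
        phased &= np.array([bool(row[2]) for row in g])
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        anc.append(aa)
        rows.append(alleles.reshape(-1))
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not rows:
        raise ValueError(f"no biallelic SNPs in {path}")
    if not phased.all():
        log.warning("read_vcf: samples flagged unphased: %s",
                    [s for s, p in zip(samples, phased) if not p])
    table = VariantTable(
        np.array(chrom, dtype=object), np.array(pos, dtype=np.int64),
        np.array(ref, dtype=object), np.array(alt, dtype=object),
        np.array(anc, dtype=object),
        np.vstack(rows).astype(np.int8), samples,
        dict(populations) if populations else {}, phased,
    )
    table.validate()
    return table


def write_vcf(table: VariantTable, path) -> None:
    """Write a :class:`VariantTable` in the module's VCFv4.2 dialect."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mosaictrace\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(table.chrom.tolist()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        seps = ["|" if p else "/" for p in table.phased]
        for s in range(table.n_sites):
            info = f"AA={table.ancestral[s]}" if table.ancestral[s] else "."
            gts = []
            h = table.haplotypes[s]
            for i in range(table.n_samples):
                a, b = h[2 * i], h[2 * i + 1]
                gts.append(f"{'.' if a < 0 else a}{seps[i]}{'.' if b < 0 else b}")
            fh.write(f"{table.chrom[s]}\t{table.pos[s]}\t.\t{table.ref[s]}\t"
                     f"{table.alt[s]}\t.\t.\t{info}\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# derived tables
# ---------------------------------------------------------------------------

def build_ancestral_outgroup(table: VariantTable, mode: str = "paper",
                             name: str = "ANCESTOR") -> VariantTable:
    """Append a synthetic all-ancestral outgroup individual.

    Where the ancestral allele equals REF the outgroup is 0|0.  Where it
    equals ALT, ``mode="paper"`` writes the 0|1 heterozygote (reproducing
    the published construction) while ``mode="strict"`` writes the fully
    ancestral 1|1.  Sites with missing or REF/ALT-mismatching ancestral
    alleles are dropped.
    """
    if mode not in ("paper", "strict"):
        raise ValueError(f"unknown outgroup mode {mode!r}")
    is_ref = table.ancestral == table.ref
    is_alt = table.ancestral == table.alt
    usable = is_ref | is_alt
    if not usable.any():
        raise ValueError("no sites with a usable ancestral allele")
    n_drop = int((~usable).sum())
    if n_drop:
        log.info("outgroup: dropped %d sites with missing/mismatching AA", n_drop)
    sub = table.subset_sites(usable)
    col = np.zeros((sub.n_sites, 2), dtype=np.int8)
    alt_sites = is_alt[usable]
    col[alt_sites, 1] = 1
    if mode == "strict":
        col[alt_sites, 0] = 1
    out = VariantTable(
        sub.chrom, sub.pos, sub.ref, sub.alt, sub.ancestral,
        np.hstack([sub.haplotypes, col]), sub.samples + [name],
        {**sub.populations, name: "OUTGROUP"},
        np.append(sub.phased, True),
    )
    return out


def merge_samples(tables: Sequence[VariantTable]) -> VariantTable:
    """Column-concatenate tables that share an identical site frame."""
    first = tables[0]
    for t in tables[1:]:
        if not (np.array_equal(t.chrom, first.chrom) and np.array_equal(t.pos, first.pos)
                and np.array_equal(t.ref, first.ref) and np.array_equal(t.alt, first.alt)):
            raise ValueError("merge_samples requires identical site frames; "
                             "use intersect_datasets for heterogeneous inputs")
    samples: list[str] = []
    for t in tables:
        dup = set(samples) & set(t.samples)
        if dup:
            raise ValueError(f"duplicate sample names: {sorted(dup)}")
        samples += t.samples
    return VariantTable(
        first.chrom, first.pos, first.ref, first.alt, first.ancestral,
        np.hstack([t.haplotypes for t in tables]), samples,
        {k: v for t in tables for k, v in t.populations.items()},
        np.concatenate([t.phased for t in tables]),
    )


def intersect_datasets(tables: Sequence[VariantTable], drop_ambiguous: bool = True,
                       return_stats: bool = False):
    """Intersect datasets on (chrom, pos, unordered {REF, ALT}).

    Allele codes are flipped where REF/ALT are swapped relative to the
    first table; strand-ambiguous A/T and C/G sites are dropped when
    ``drop_ambiguous`` is set.  Sample name collisions raise.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    first = tables[0]
    keys = [{(t.chrom[i], int(t.pos[i])): i for i in range(t.n_sites)} for t in tables]
    keep_first: list[int] = []
    rows_per_table: list[list[int]] = [[] for _ in tables]
    flips: list[list[bool]] = [[] for _ in tables]
    for i in range(first.n_sites):
        key = (first.chrom[i], int(first.pos[i]))
        pair0 = frozenset((first.ref[i], first.alt[i]))
        if drop_ambiguous and pair0 in _AMBIGUOUS:
            continue
        site_rows, site_flips, ok = [], [], True
        for t, kmap in zip(tables, keys):
            j = kmap.get(key)
            if j is None or frozenset((t.ref[j], t.alt[j])) != pair0:
                ok = False
                break
            site_rows.append(j)
            site_flips.append(t.ref[j] != first.ref[i])
        if ok:
            keep_first.append(i)
            for k in range(len(tables)):
                rows_per_table[k].append(site_rows[k])
                flips[k].append(site_flips[k])
    if not keep_first:
        raise ValueError("empty intersection")
    stats = {k: {"input_sites": t.n_sites, "retained": len(keep_first)}
             for k, t in enumerate(tables)}
    log.info("intersect: retained %d sites; per-table inputs %s",
             len(keep_first), [t.n_sites for t in tables])

    blocks = []
    phased = []
    samples: list[str] = []
    pops: dict[str, str] = {}
    anc = None
    for k, t in enumerate(tables):
        rows = np.array(rows_per_table[k], dtype=int)
        fl = np.array(flips[k], dtype=bool)
        h = t.haplotypes[rows].copy()
        if fl.any():
            sel = h[fl]
            sel[sel >= 0] = 1 - sel[sel >= 0]
            h[fl] = sel
        dup = set(samples) & set(t.samples)
        if dup:
            raise ValueError(f"duplicate sample names: {sorted(dup)}")
        blocks.append(h)
        phased.append(t.phased)
        samples += t.samples
        pops.update(t.populations)
        if anc is None:
            a = t.ancestral[rows]
            anc = a
    idx = np.array(keep_first, dtype=int)
    merged = VariantTable(
        first.chrom[idx], first.pos[idx], first.ref[idx], first.alt[idx],
        anc, np.hstack(blocks), samples, pops, np.concatenate(phased),
    )
    return (merged, stats) if return_stats else merged


def read_populations(path) -> dict[str, str]:
    """Two-column sample-to-population file (whitespace separated)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sample, pop = line.split()[:2]
            out[sample] = pop
    return out
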