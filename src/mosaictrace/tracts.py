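"""Ancestry tracts in genetic-map coordinates.

An :class:`AncestryPath` describes one phased haplotype as a contiguous,
non-overlapping partition of each chromosome into ancestry tracts, measured
in Morgans.  Paths serve both as simulation ground truth and as the output
of local-ancestry calling (where an ``"unassigned"`` label is allowed).
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

UNASSIGNED = "unassigned"


@dataclasses.dataclass(frozen=True)
class Tract:
    """One ancestry tract: half-open interval [start, end) in Morgans."""

    start: float
    end: float
    label: str

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclasses.dataclass
class AncestryPath:
    """Per-chromosome ancestry tracts for a single haplotype.

    Invariants (see :meth:`validate`): tracts tile ``[0, L]`` exactly,
    adjacent tracts carry distinct labels, and all lengths are positive.
    """

    tracts: dict[str, list[Tract]]

    @classmethod
    def single(cls, label: str, lengths: Mapping[str, float]) -> "AncestryPath":
        """A path carrying one ancestry over every chromosome."""
        return cls({c: [Tract(0.0, float(L), label)] for c, L in lengths.items()})

    def chromosomes(self) -> list[str]:
        return list(self.tracts)

    def chrom_length(self, chrom: str) -> float:
        return self.tracts[chrom][-1].end

    def validate(self, lengths: Mapping[str, float] | None = None, atol: float = 1e-9) -> None:
        for chrom, tr in self.tracts.items():
            if not tr:
                raise ValueError(f"chromosome {chrom} has no tracts")
            if abs(tr[0].start) > atol:
                raise ValueError(f"{chrom}: first tract starts at {tr[0].start}, not 0")
            prev = None
            for t in tr:
                if t.length <= 0:
                    raise ValueError(f"{chrom}: non-positive tract length {t.length}")
                if prev is not None:
                    if abs(t.start - prev.end) > atol:
                        raise ValueError(f"{chrom}: gap/overlap at {prev.end} -> {t.start}")
                    if t.label == prev.label:
                        raise ValueError(f"{chrom}: adjacent tracts share label {t.label}")
                prev = t
            if lengths is not None and abs(tr[-1].end - lengths[chrom]) > atol:
                raise ValueError(
                    f"{chrom}: tracts end at {tr[-1].end}, expected {lengths[chrom]}"
                )

    def label_at(self, chrom: str, gpos: np.ndarray) -> np.ndarray:
        """Ancestry label covering each genetic position (Morgans) on ``chrom``."""
        tr = self.tracts[chrom]
        ends = np.array([t.end for t in tr])
        gpos = np.asarray(gpos, dtype=float)
        if gpos.size and (gpos.min() < -1e-9 or gpos.max() > ends[-1] + 1e-9):
            raise ValueError(f"{chrom}: positions outside tract coverage [0, {ends[-1]}]")
        idx = np.minimum(np.searchsorted(ends, gpos, side="right"), len(tr) - 1)
        labels = np.array([t.label for t in tr], dtype=object)
        return labels[idx]

    def lengths_by_label(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for tr in self.tracts.values():
            for t in tr:
                out[t.label] = out.get(t.label, 0.0) + t.length
        return out

    def total_length(self) -> float:
        return sum(tr[-1].end for tr in self.tracts.values())


def write_tracts(paths: Mapping[str, AncestryPath], genetic_map, out_path) -> None:
    """Write per-haplotype tracts as a BED-like tab file.

    Columns: hap_id, chrom, start_bp, end_bp (0-based half-open),
    start_morgans, end_morgans, ancestry.
    """
    with open(out_path, "w") as fh:
        fh.write("#hap_id\tchrom\tstart_bp\tend_bp\tstart_morgans\tend_morgans\tancestry\n")
        for hap_id, path in paths.items():
            for chrom, tr in path.tracts.items():
                for t in tr:
                    sb = int(round(genetic_map.bp_at(chrom, t.start))) - 1
                    eb = int(round(genetic_map.bp_at(chrom, t.end)))
                    fh.write(
                        f"{hap_id}\t{chrom}\t{max(sb, 0)}\t{eb}"
                        f"\t{t.start:.8f}\t{t.end:.8f}\t{t.label}\n"
                    )


def read_tracts(path) -> dict[str, AncestryPath]:
    """Read a tract file written by :func:`write_tracts`.

    Genetic (Morgan) coordinates are authoritative; bp columns are ignored.
    """
    out: dict[str, dict[str, list[Tract]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            hap_id, chrom, _sb, _eb, sm, em, label = line.rstrip("\n").split("\t")
            out.setdefault(hap_id, {}).setdefault(chrom, []).append(
                Tract(float(sm), float(em), label)
            )
    return {hap: AncestryPath(chroms) for hap, chroms in out.items()}
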