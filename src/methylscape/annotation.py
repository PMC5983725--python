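"""Genome annotation: GFF3 parsing, interval index, category assignment.

Two classification schemes are provided, matching the two ways methylation
is reported against gene models in plant WGBS studies:

* **mC-site scheme** — each methylcytosine falls in exactly one of
  ``exon``, ``intron``, ``promoter`` (1 kb upstream of the TSS, strand
  aware) or ``intergenic``, with precedence exon > intron > promoter.
* **DMR scheme** — each region falls in exactly one of ``gene_body``
  (exon and intron), ``upstream`` (2 kb upstream of the TSS),
  ``downstream`` (2 kb downstream of the transcription end site),
  ``transposon`` or ``intergenic``.  The label is the category with the
  largest base-pair overlap, ties broken by the precedence
  gene_body > upstream > downstream > transposon.

All internal coordinates are 0-based half-open; GFF3 on disk is 1-based
inclusive.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

MC_CATEGORIES = ("exon", "intron", "promoter", "intergenic")
DMR_CATEGORIES = ("gene_body", "upstream", "downstream", "transposon", "intergenic")

DEFAULT_MC_PRECEDENCE = ("exon", "intron", "promoter")
DEFAULT_DMR_PRECEDENCE = ("gene_body", "upstream", "downstream", "transposon")


@dataclass
class Gene:
    """A protein-coding gene model with exon structure (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end <= start")
        self.exons = sorted(tuple(e) for e in self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside gene span")

    @property
    def tss(self) -> int:
        """Transcription start: leftmost coordinate on +, rightmost on -."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


@dataclass
class Transposon:
    te_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class Annotation:
    """In-memory feature set: genes, transposable elements, chromosome sizes."""

    chrom_lengths: dict[str, int]
    genes: list[Gene] = field(default_factory=list)
    tes: list[Transposon] = field(default_factory=list)

    def reverse_strands(self) -> "Annotation":
        """Annotation with every feature's strand flipped (for symmetry checks)."""
        flip = {"+": "-", "-": "+"}
        genes = [
            Gene(g.gene_id, g.chrom, g.start, g.end, flip[g.strand], list(g.exons))
            for g in self.genes
        ]
        tes = [Transposon(t.te_id, t.chrom, t.start, t.end, flip[t.strand]) for t in self.tes]
        return Annotation(dict(self.chrom_lengths), genes, tes)


def write_gff3(annotation: Annotation, path: str | Path) -> None:
    """Write genes (with exon children) and TEs as GFF3, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in annotation.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tmethylscape\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tmethylscape\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
        for t in sorted(annotation.tes, key=lambda t: (t.chrom, t.start)):
            fh.write(
                f"{t.chrom}\tmethylscape\ttransposable_element\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\tID={t.te_id}\n"
            )


def _validate_gff3(path: str | Path) -> None:
    """Pre-scan a GFF3 file; raise with the offending line number."""
    gene_spans: dict[str, tuple[str, int, int]] = {}
    chroms: set[str] = set()
    lines = Path(path).read_text().splitlines()
    for line in lines:
        if line.startswith("##sequence-region"):
            chroms.add(line.split()[1])
    for lineno, line in enumerate(lines, start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            raise ValueError(f"{path} line {lineno}: malformed GFF3 record")
        chrom, _, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
        if chroms and chrom not in chroms:
            raise ValueError(f"{path} line {lineno}: unknown chromosome {chrom!r}")
        if ftype == "gene":
            gid = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            ).get("ID")
            if gid:
                gene_spans[gid] = (chrom, int(start), int(end))
    for lineno, line in enumerate(lines, start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[2] != "exon":
            continue
        attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
        parent = attrs.get("Parent")
        if parent and parent in gene_spans:
            gchrom, gs, ge = gene_spans[parent]
            if parts[0] != gchrom or int(parts[3]) < gs or int(parts[4]) > ge:
                raise ValueError(
                    f"{path} line {lineno}: exon outside span of gene {parent!r}"
                )


def read_gff3(path: str | Path) -> Annotation:
    """Parse a GFF3 file into an :class:`Annotation` (via gffutils)."""
    _validate_gff3(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    chrom_lengths: dict[str, int] = {}
    for d in db.directives:
        if d.startswith("sequence-region"):
            _, chrom, _, end = d.split()[:4]
            chrom_lengths[chrom] = int(end)
    genes = []
    for g in db.features_of_type("gene"):
        exons = [(e.start - 1, e.end) for e in db.children(g, featuretype="exon")]
        genes.append(Gene(g.id, g.seqid, g.start - 1, g.end, g.strand, exons))
    tes = [
        Transposon(t.id, t.seqid, t.start - 1, t.end, t.strand or "+")
        for t in db.features_of_type(("transposable_element", "transposon"))
    ]
    if not chrom_lengths:
        for f in list(genes) + list(tes):
            chrom_lengths[f.chrom] = max(chrom_lengths.get(f.chrom, 0), f.end)
    return Annotation(chrom_lengths, genes, tes)


def _clip(start: int, end: int, length: int) -> tuple[int, int]:
    return max(0, start), min(length, end)


def _interval_union(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _interval_difference(
    ivs: list[tuple[int, int]], minus: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


class FeatureIndex:
    """Interval index over genes, exons, introns, TEs and derived windows.

    Supports point queries (mC-site scheme) and interval overlap queries
    (DMR scheme) via per-chromosome interval trees.
    """

    def __init__(
        self,
        annotation: Annotation,
        promoter_bp: int = 1000,
        upstream_bp: int = 2000,
        downstream_bp: int = 2000,
        mc_precedence: Sequence[str] = DEFAULT_MC_PRECEDENCE,
        dmr_precedence: Sequence[str] = DEFAULT_DMR_PRECEDENCE,
    ) -> None:
        self.annotation = annotation
        self.promoter_bp = promoter_bp
        self.upstream_bp = upstream_bp
        self.downstream_bp = downstream_bp
        self.mc_precedence = tuple(mc_precedence)
        self.dmr_precedence = tuple(dmr_precedence)
        self.chrom_lengths = dict(annotation.chrom_lengths)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self._build()

    # ------------------------------------------------------------------
    @classmethod
    def from_gff3(cls, path: str | Path, **kwargs) -> "FeatureIndex":
        return cls(read_gff3(path), **kwargs)

    def _add(self, kind: str, chrom: str, start: int, end: int, data=None) -> None:
        start, end = _clip(start, end, self.chrom_lengths[chrom])
        if end > start:
            self._trees.setdefault((chrom, kind), IntervalTree()).addi(start, end, data)

    def _build(self) -> None:
        for g in self.annotation.genes:
            L = self.chrom_lengths.get(g.chrom)
            if L is None:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > L:
                raise ValueError(f"gene {g.gene_id} extends beyond {g.chrom} (length {L})")
            self._add("gene_body", g.chrom, g.start, g.end, g.gene_id)
            for s, e in g.exons:
                self._add("exon", g.chrom, s, e, g.gene_id)
            for s, e in g.introns:
                self._add("intron", g.chrom, s, e, g.gene_id)
            self._add("promoter", g.chrom, *self.upstream_interval(g, self.promoter_bp), g.gene_id)
            self._add("upstream", g.chrom, *self.upstream_interval(g, self.upstream_bp), g.gene_id)
            self._add("downstream", g.chrom, *self.downstream_interval(g, self.downstream_bp), g.gene_id)
        for t in self.annotation.tes:
            if t.chrom not in self.chrom_lengths:
                raise ValueError(f"TE {t.te_id} on unknown chromosome {t.chrom}")
            self._add("transposon", t.chrom, t.start, t.end, t.te_id)

    # ------------------------------------------------------------------
    def upstream_interval(self, gene: Gene, bp: int) -> tuple[int, int]:
        """The window ``bp`` base pairs 5' of the TSS, unclipped."""
        if gene.strand == "+":
            return gene.start - bp, gene.start
        return gene.end, gene.end + bp

    def downstream_interval(self, gene: Gene, bp: int) -> tuple[int, int]:
        if gene.strand == "+":
            return gene.end, gene.end + bp
        return gene.start - bp, gene.start

    def overlapping(self, kind: str, chrom: str, start: int, end: int):
        """All intervals of ``kind`` overlapping [start, end) on ``chrom``."""
        tree = self._trees.get((chrom, kind))
        return [] if tree is None else sorted(tree.overlap(start, end))

    def overlap_length(self, kind: str, chrom: str, start: int, end: int) -> int:
        """Union length of the overlap between [start, end) and ``kind`` intervals."""
        ivs = self.overlapping(kind, chrom, start, end)
        covered = 0
        cur_s = cur_e = None
        for iv in ivs:
            s, e = max(iv.begin, start), min(iv.end, end)
            if cur_e is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
        if cur_e is not None:
            covered += cur_e - cur_s
        return covered

    # ------------------------------------------------------------------
    def mc_category(self, chrom: str, pos: int) -> str:
        """mC-site scheme category of a 1-based site position."""
        L = self.chrom_lengths.get(chrom)
        if L is None:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (1 <= pos <= L):
            raise ValueError(f"site {chrom}:{pos} beyond chromosome end ({L})")
        p0 = pos - 1
        for kind in self.mc_precedence:
            tree = self._trees.get((chrom, kind))
            if tree is not None and tree.overlaps_point(p0):
                return kind
        return "intergenic"

    def mc_categories(self, sites: pd.DataFrame) -> pd.Series:
        """Vectorised :meth:`mc_category` over a frame with chrom/pos columns."""
        return pd.Series(
            [self.mc_category(c, p) for c, p in zip(sites["chrom"], sites["pos"])],
            index=sites.index,
            name="category",
        )

    def dmr_category(self, chrom: str, start: int, end: int) -> str:
        """DMR scheme category of a 0-based half-open interval.

        Each base of the interval is claimed by the highest-precedence
        category covering it; the category claiming the most bases wins,
        ties broken by the precedence order.  An interval touching no
        feature class is intergenic.
        """
        L = self.chrom_lengths.get(chrom)
        if L is None:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > L or end <= start:
            raise ValueError(f"interval {chrom}:{start}-{end} outside chromosome bounds")
        claimed: list[tuple[int, int]] = []
        best_kind, best_len = "intergenic", 0
        for kind in self.dmr_precedence:
            ivs = [
                (max(iv.begin, start), min(iv.end, end))
                for iv in self.overlapping(kind, chrom, start, end)
            ]
            new = _interval_difference(_interval_union(ivs), claimed)
            length = sum(e - s for s, e in new)
            claimed = _interval_union(claimed + new)
            if length > best_len:
                best_kind, best_len = kind, length
        return best_kind if best_len > 0 else "intergenic"

    def genes_overlapping(self, chrom: str, start: int, end: int, kind: str = "gene_body"):
        """Gene ids whose ``kind`` interval overlaps [start, end)."""
        return sorted({iv.data for iv in self.overlapping(kind, chrom, start, end)})
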