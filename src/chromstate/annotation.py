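"""Gene-model annotation container.

Coordinates are 0-based half-open throughout; GFF3 I/O converts at the
boundary. The TSS of a minus-strand gene is its end coordinate (last base),
per the strand convention used everywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .expression import GeneAnnotationInfo
from .intervals import Anchor, GenomicInterval, IntervalSet

__all__ = ["GeneModel", "Annotation"]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]  # sorted, non-overlapping, within span
    kind: str = "coding"  # coding | lincRNA

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev = self.start
        for a, b in self.exons:
            if a < prev or b <= a or b > self.end:
                raise ValueError(f"bad exon structure in {self.gene_id}")
            prev = b

    @property
    def tss(self) -> Anchor:
        pos = self.start if self.strand == "+" else self.end - 1
        return Anchor(self.scaffold, pos, self.strand, self.gene_id)

    @property
    def tes(self) -> Anchor:
        pos = self.end - 1 if self.strand == "+" else self.start
        return Anchor(self.scaffold, pos, self.strand, self.gene_id)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.scaffold, self.start, self.end, self.strand, self.gene_id
        )

    def introns(self) -> list[GenomicInterval]:
        out = []
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c > b:
                out.append(
                    GenomicInterval(self.scaffold, b, c, self.strand, self.gene_id)
                )
        return out

    def exon_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.scaffold, a, b, self.strand, self.gene_id)
            for a, b in self.exons
        ]


@dataclass
class Annotation:
    scaffold_lengths: dict[str, int]
    genes: dict[str, GeneModel] = field(default_factory=dict)
    lincrnas: dict[str, GeneModel] = field(default_factory=dict)

    @property
    def genome_size(self) -> int:
        return sum(self.scaffold_lengths.values())

    def gene_intervals(self, kind: str = "coding") -> IntervalSet:
        src = self.genes if kind == "coding" else self.lincrnas
        return IntervalSet([g.interval for g in src.values()])

    def coding_tss(self) -> list[Anchor]:
        return [g.tss for g in self.genes.values()]

    def lincrna_tss(self) -> list[Anchor]:
        return [g.tss for g in self.lincrnas.values()]

    def all_tss(self) -> list[Anchor]:
        return self.coding_tss() + self.lincrna_tss()

    def coding_tes(self) -> list[Anchor]:
        return [g.tes for g in self.genes.values()]

    def all_introns(self) -> IntervalSet:
        out = []
        for g in self.genes.values():
            out.extend(g.introns())
        return IntervalSet(out)

    def all_exons(self) -> IntervalSet:
        out = []
        for g in self.genes.values():
            out.extend(g.exon_intervals())
        return IntervalSet(out)

    def intergenic(self) -> IntervalSet:
        """Spans not covered by any gene or lincRNA."""
        from .intervals import merge

        genic = merge(
            IntervalSet(
                [g.interval for g in self.genes.values()]
                + [g.interval for g in self.lincrnas.values()]
            ),
            0,
        )
        by_scaf: dict[str, list[GenomicInterval]] = {}
        for iv in genic:
            by_scaf.setdefault(iv.scaffold, []).append(iv)
        out = []
        for s, length in self.scaffold_lengths.items():
            pos = 0
            for iv in by_scaf.get(s, []):
                if iv.start > pos:
                    out.append(GenomicInterval(s, pos, iv.start))
                pos = max(pos, iv.end)
            if pos < length:
                out.append(GenomicInterval(s, pos, length))
        return IntervalSet(out)

    def to_info(self) -> GeneAnnotationInfo:
        """Positional facts for the expression eligibility filters."""
        return GeneAnnotationInfo(
            gene_scaffold={g.gene_id: g.scaffold for g in self.genes.values()},
            gene_span={g.gene_id: (g.start, g.end) for g in self.genes.values()},
            scaffold_length=dict(self.scaffold_lengths),
        )

    def neighboring_pairs(self) -> list[tuple[str, str]]:
        """Immediately adjacent coding-gene pairs per scaffold (by start)."""
        by_scaf: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            by_scaf.setdefault(g.scaffold, []).append(g)
        pairs = []
        for s in sorted(by_scaf):
            genes = sorted(by_scaf[s], key=lambda g: (g.start, g.end))
            for a, b in zip(genes, genes[1:]):
                pairs.append((a.gene_id, b.gene_id))
        return pairs
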