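"""File readers and writers.

Internal coordinates are 0-based half-open; GFF3 (1-based, closed) is
converted at the boundary. Parsers are strict: any malformed line raises a
``ParseError`` carrying the file name and line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Annotation, GeneModel
from .intervals import GenomicInterval, IntervalSet
from .tracks import BinnedTrack

__all__ = [
    "ParseError",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "read_bedgraph",
    "write_bedgraph",
    "write_track_tsv",
    "read_track_tsv",
    "read_tsv_matrix",
    "write_tsv_matrix",
    "read_stage_map",
    "write_stage_map",
]


class ParseError(ValueError):
    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path, self.lineno = str(path), lineno


def _data_lines(path):
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield i, line


def read_bed(path) -> IntervalSet:
    """BED3/BED6 (extra columns ignored); 0-based half-open as on disk."""
    out = []
    for i, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 3:
            raise ParseError(path, i, "expected at least 3 BED columns")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as exc:
            raise ParseError(path, i, f"non-integer coordinate: {exc}") from None
        name = f[3] if len(f) > 3 and f[3] != "." else None
        score = None
        if len(f) > 4 and f[4] != ".":
            try:
                score = float(f[4])
            except ValueError:
                raise ParseError(path, i, f"non-numeric score {f[4]!r}") from None
        strand = f[5] if len(f) > 5 else "."
        try:
            out.append(GenomicInterval(f[0], start, end, strand, name, score))
        except ValueError as exc:
            raise ParseError(path, i, str(exc)) from None
    return IntervalSet(out)


def write_bed(path, intervals: IntervalSet) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(
                f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                f"\t{score}\t{iv.strand}\n"
            )


def read_gff3(path) -> Annotation:
    """Minimal GFF3: region/gene/exon features (1-based closed on disk).

    Genes carrying ``biotype=lincRNA`` (or type lincRNA) go to the lincRNA
    table; everything else is a coding gene.
    """
    scaffolds: dict[str, int] = {}
    genes: dict[str, dict] = {}
    for i, line in _data_lines(path):
        f = line.split("\t")
        if len(f) != 9:
            raise ParseError(path, i, f"expected 9 GFF3 columns, got {len(f)}")
        scaf, _, ftype, start_s, end_s, _, strand, _, attrs_s = f
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(path, i, "non-integer coordinates") from None
        if start1 < 1 or end1 < start1:
            raise ParseError(path, i, f"invalid 1-based span {start1}..{end1}")
        attrs = dict(
            kv.split("=", 1) for kv in attrs_s.split(";") if "=" in kv
        )
        start, end = start1 - 1, end1  # to half-open
        if ftype == "region":
            scaffolds[scaf] = end
        elif ftype in ("gene", "lincRNA", "lnc_RNA"):
            gid = attrs.get("ID")
            if not gid:
                raise ParseError(path, i, "gene feature without ID attribute")
            kind = (
                "lincRNA"
                if ftype != "gene" or attrs.get("biotype") == "lincRNA"
                else "coding"
            )
            genes[gid] = {
                "scaffold": scaf,
                "start": start,
                "end": end,
                "strand": strand,
                "kind": kind,
                "exons": [],
            }
        elif ftype == "exon":
            parent = attrs.get("Parent")
            if parent not in genes:
                raise ParseError(path, i, f"exon with unknown Parent {parent!r}")
            genes[parent]["exons"].append((start, end))
    ann = Annotation(scaffolds or {})
    for gid, g in genes.items():
        exons = tuple(sorted(g["exons"])) or ((g["start"], g["end"]),)
        model = GeneModel(
            gid, g["scaffold"], g["start"], g["end"], g["strand"], exons, g["kind"]
        )
        (ann.lincrnas if g["kind"] == "lincRNA" else ann.genes)[gid] = model
    if not scaffolds:
        lengths: dict[str, int] = {}
        for g in list(ann.genes.values()) + list(ann.lincrnas.values()):
            lengths[g.scaffold] = max(lengths.get(g.scaffold, 0), g.end)
        ann.scaffold_lengths = lengths
    return ann


def write_gff3(path, ann: Annotation) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaf in sorted(ann.scaffold_lengths):
            fh.write(
                f"{scaf}\tchromstate\tregion\t1\t{ann.scaffold_lengths[scaf]}"
                f"\t.\t.\t.\tID={scaf}\n"
            )
        for table, biotype in ((ann.genes, "protein_coding"), (ann.lincrnas, "lincRNA")):
            for gid in sorted(table):
                g = table[gid]
                fh.write(
                    f"{g.scaffold}\tchromstate\tgene\t{g.start + 1}\t{g.end}"
                    f"\t.\t{g.strand}\t.\tID={gid};biotype={biotype}\n"
                )
                for k, (a, b) in enumerate(g.exons, start=1):
                    fh.write(
                        f"{g.scaffold}\tchromstate\texon\t{a + 1}\t{b}"
                        f"\t.\t{g.strand}\t.\tID={gid}.exon{k};Parent={gid}\n"
                    )


def read_bedgraph(path, bin_width: int | None = None) -> IntervalSet:
    """bedGraph spans with values; overlapping spans are rejected."""
    out = []
    last: dict[str, int] = {}
    for i, line in _data_lines(path):
        f = line.split("\t")
        if len(f) != 4:
            raise ParseError(path, i, "expected 4 bedGraph columns")
        try:
            start, end, value = int(f[1]), int(f[2]), float(f[3])
        except ValueError:
            raise ParseError(path, i, "malformed bedGraph record") from None
        if f[0] in last and start < last[f[0]]:
            raise ParseError(path, i, "overlapping bedGraph intervals")
        last[f[0]] = end
        out.append(GenomicInterval(f[0], start, end, score=value))
    return IntervalSet(out)


def write_bedgraph(path, track: BinnedTrack) -> None:
    bw = track.bin_width
    with open(path, "w") as fh:
        for scaf in track.scaffolds():
            for b, v in enumerate(track.data[scaf]):
                fh.write(f"{scaf}\t{b * bw}\t{(b + 1) * bw}\t{v:g}\n")


def write_track_tsv(path, track: BinnedTrack) -> None:
    """Binned TSV: scaffold, bin_start, count."""
    with open(path, "w") as fh:
        fh.write("scaffold\tbin_start\tcount\n")
        for scaf in track.scaffolds():
            for b, v in enumerate(track.data[scaf]):
                fh.write(f"{scaf}\t{b * track.bin_width}\t{v:g}\n")


def read_track_tsv(path, bin_width: int = 200) -> BinnedTrack:
    df = pd.read_csv(path, sep="\t")
    data = {}
    for scaf, grp in df.groupby("scaffold"):
        grp = grp.sort_values("bin_start")
        expected = np.arange(len(grp)) * bin_width
        if not (grp["bin_start"].to_numpy() == expected).all():
            raise ParseError(path, 0, f"bins do not tile scaffold {scaf}")
        data[str(scaf)] = grp["count"].to_numpy()
    return BinnedTrack(data, bin_width=bin_width)


def read_tsv_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv_matrix(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t")


def read_stage_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["sample", "stage"]:
        raise ParseError(path, 1, "stage map needs 'sample' and 'stage' columns")
    return dict(zip(df["sample"], df["stage"]))


def write_stage_map(path, stage_map: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tstage\n")
        for sample, stage in stage_map.items():
            fh.write(f"{sample}\t{stage}\n")
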