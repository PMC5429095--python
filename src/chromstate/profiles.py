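"""TSS-centred coverage metaprofiles and the lincRNA ratio classifier.

Profiles are strand-aware: minus-strand anchors are mirrored so that
positive offsets always point downstream of transcription. lincRNAs are
split into enhancer-like (elincRNA) and promoter-like (plincRNA) classes by
the mean H3K4me1 : H3K4me3 fold-enrichment ratio in a 4-kb window centred
on the TSS, with thresholds > 1.2 (elinc) and < 0.8 (plinc); the band in
between is unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import Anchor, GenomicInterval, IntervalSet, intersect
from .tracks import BinnedTrack

__all__ = ["ProfileMatrix", "RatioClassification", "tss_profile", "classify_lincrnas"]


@dataclass
class ProfileMatrix:
    """Anchors x offset-bins matrix of mean track values (NaN = off-scaffold)."""

    matrix: np.ndarray
    offsets: np.ndarray  # left edge of each offset bin, bases from the anchor
    step: int
    anchor_names: list[str]

    @property
    def aggregate(self) -> np.ndarray:
        """Column means over non-missing rows."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.matrix, axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.anchor_names, columns=self.offsets
        )


def tss_profile(
    fe_track: BinnedTrack,
    anchors: list[Anchor],
    flank: int = 3000,
    step: int = 50,
) -> ProfileMatrix:
    """Mean input-normalised track value per offset bin around each anchor.

    Offset bins tile [-flank, flank) in ``step``-base increments. Each
    offset position takes the value of the track bin containing it; offset
    bins that run past a scaffold end are NaN and drop out of the aggregate.
    Anchors on scaffolds absent from the track are skipped (counted).
    """
    offsets = np.arange(-flank, flank, step)
    rows, names = [], []
    skipped = 0
    bw = fe_track.bin_width
    for an in anchors:
        v = fe_track.data.get(an.scaffold)
        if v is None:
            skipped += 1
            continue
        scaf_len = v.size * bw
        row = np.full(offsets.size, np.nan)
        for i, off in enumerate(offsets):
            # mirror: genomic span of this offset bin, downstream positive
            if an.strand == "-":
                lo = an.pos - off - step + 1
            else:
                lo = an.pos + off
            hi = lo + step
            if lo < 0 or hi > scaf_len:
                continue
            b0, b1 = lo // bw, (hi - 1) // bw
            if b0 == b1:
                row[i] = float(v[b0])
            else:  # straddles track bins: weight by base coverage
                total = 0.0
                for b in range(b0, b1 + 1):
                    ov = min(hi, (b + 1) * bw) - max(lo, b * bw)
                    total += v[b] * ov
                row[i] = total / (hi - lo)
        rows.append(row)
        names.append(an.name or f"{an.scaffold}:{an.pos}")
    matrix = np.array(rows) if rows else np.empty((0, offsets.size))
    pm = ProfileMatrix(matrix, offsets, step, names)
    pm.skipped_anchors = skipped  # type: ignore[attr-defined]
    return pm


@dataclass
class RatioClassification:
    labels: pd.Series  # lincRNA -> elinc | plinc | unassigned | ineligible
    ratios: pd.Series  # NaN for ineligible
    window: int
    hi: float
    lo: float

    def counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    @property
    def eligible_count(self) -> int:
        return int((self.labels != "ineligible").sum())


def _mean_fe_window(track: BinnedTrack, an: Anchor, half: int) -> float:
    v = track.data.get(an.scaffold)
    if v is None:
        return float("nan")
    bw = track.bin_width
    lo = max(0, an.pos - half)
    hi = min(v.size * bw, an.pos + half)
    if lo >= hi:
        return float("nan")
    b0, b1 = lo // bw, (hi - 1) // bw
    return float(v[b0 : b1 + 1].mean())


def classify_lincrnas(
    me1_fe: BinnedTrack,
    me3_fe: BinnedTrack,
    loci: IntervalSet,
    tss: dict[str, Anchor],
    scaffold_length: dict[str, int],
    peak_sets: dict[str, IntervalSet],
    hi: float = 1.2,
    lo: float = 0.8,
    window: int = 4000,
    pseudocount: float = 0.1,
    min_scaffold: int = 10_000,
) -> RatioClassification:
    """Classify lincRNAs by the H3K4me1 : H3K4me3 ratio at their TSS.

    Eligibility: the locus must sit on a scaffold longer than
    ``min_scaffold`` and overlap (>= 1 bp) every peak set in ``peak_sets``
    (H3K4me1, H3K4me3 and RNAPII regions of enrichment in the reference
    design). The ratio is (mean me1 FE + c) / (mean me3 FE + c) over
    TSS +/- window/2; classes use strict thresholds, so boundary values are
    unassigned.
    """
    half = window // 2
    overlap_ok: dict[str, set[str]] = {}
    for name, pset in peak_sets.items():
        hits = intersect(loci, pset, 0.0)
        overlap_ok[name] = {iv.name for iv in hits if iv.name}
    labels, ratios = {}, {}
    for iv in loci:
        gid = iv.name or f"{iv.scaffold}:{iv.start}"
        if scaffold_length.get(iv.scaffold, 0) <= min_scaffold or any(
            gid not in ok for ok in overlap_ok.values()
        ):
            labels[gid] = "ineligible"
            ratios[gid] = float("nan")
            continue
        an = tss[gid]
        m1 = _mean_fe_window(me1_fe, an, half)
        m3 = _mean_fe_window(me3_fe, an, half)
        ratio = (m1 + pseudocount) / (m3 + pseudocount)
        ratios[gid] = ratio
        if ratio > hi:
            labels[gid] = "elinc"
        elif ratio < lo:
            labels[gid] = "plinc"
        else:
            labels[gid] = "unassigned"
    return RatioClassification(
        pd.Series(labels), pd.Series(ratios), window, hi, lo
    )
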