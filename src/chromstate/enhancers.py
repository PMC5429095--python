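"""Distal enhancer prediction cascade and downstream characterisation.

Candidate enhancers are H3K4me1 regions of enrichment that (1) stay clear
of every TSS +/- 200 bp window (coding genes and lincRNAs alike) and
(2) overlap at least one chromatin-state segment in an enhancer-designated
state. Candidates become "activated" when at least half their bases are
covered by H3K27ac peaks. Activated elements are assigned to their nearest
TSS, located relative to gene structure, checked for RNAPII co-occupancy,
and the introns harbouring them are compared in size to all introns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .annotation import Annotation
from .intervals import (
    Anchor,
    GenomicInterval,
    IntervalSet,
    _merged_by_scaffold,
    _overlap_bases,
    intersect,
    merge,
    nearest_anchor,
    subtract_window_hits,
)

__all__ = [
    "EnhancerCandidateSet",
    "predict_enhancers",
    "activate",
    "assign_targets",
    "classify_location",
    "intron_size_comparison",
    "rnapii_cooccupancy",
]

ADULT_ENHANCER_STATES = ("TxEnhA", "EnhWk", "EnhP")
LARVA_ENHANCER_STATES = ("TxEnhA1", "TxEnhA2", "EnhWk", "EnhP")


@dataclass
class EnhancerCandidateSet:
    candidates: IntervalSet
    removed: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    activated: dict[tuple[str, int, int], bool] = field(default_factory=dict)

    def removal_counts(self) -> Counter:
        return Counter({k: len(v) for k, v in self.removed.items()})

    @property
    def n_input(self) -> int:
        return len(self.candidates) + sum(len(v) for v in self.removed.values())

    def activated_set(self) -> IntervalSet:
        return IntervalSet(
            [
                iv
                for iv in self.candidates
                if self.activated.get((iv.scaffold, iv.start, iv.end), False)
            ]
        )


def predict_enhancers(
    me1_regions: IntervalSet,
    coding_tss: list[Anchor],
    lincrna_tss: list[Anchor],
    state_segments: IntervalSet,
    tss_flank: int = 200,
) -> EnhancerCandidateSet:
    """Filter H3K4me1 regions down to distal enhancer candidates.

    ``state_segments`` is the union of genomic segments assigned to the
    enhancer-designated chromatin states (>= 1 bp overlap required).
    Removal reasons: ``tss_proximal`` then ``no_enhancer_state``.
    """
    anchors = list(coding_tss) + list(lincrna_tss)
    removed: dict[str, list[GenomicInterval]] = {
        "tss_proximal": [],
        "no_enhancer_state": [],
    }
    distal = subtract_window_hits(me1_regions, anchors, tss_flank)
    distal_keys = {(iv.scaffold, iv.start, iv.end) for iv in distal}
    removed["tss_proximal"] = [
        iv for iv in me1_regions if (iv.scaffold, iv.start, iv.end) not in distal_keys
    ]
    kept = intersect(distal, state_segments, 0.0)
    kept_keys = {(iv.scaffold, iv.start, iv.end) for iv in kept}
    removed["no_enhancer_state"] = [
        iv for iv in distal if (iv.scaffold, iv.start, iv.end) not in kept_keys
    ]
    return EnhancerCandidateSet(kept, removed)


def activate(
    candidates: EnhancerCandidateSet,
    k27ac_regions: IntervalSet,
    min_fraction: float = 0.5,
) -> EnhancerCandidateSet:
    """Flag candidates with >= ``min_fraction`` of their bases covered by
    H3K27ac peaks as activated (the boundary fraction counts)."""
    spans = _merged_by_scaffold(k27ac_regions)
    for iv in candidates.candidates:
        ov = _overlap_bases(iv, spans.get(iv.scaffold, ()))
        candidates.activated[(iv.scaffold, iv.start, iv.end)] = (
            ov >= min_fraction * len(iv) - 1e-9
        )
    return candidates


def assign_targets(
    elements: IntervalSet, tss: list[Anchor]
) -> list[tuple[GenomicInterval, Anchor | None, int | None]]:
    """Nearest-TSS target per element (lower coordinate wins ties)."""
    if not tss:
        raise ValueError("TSS set is empty")
    return [(h.query, h.anchor, h.distance) for h in nearest_anchor(elements, tss)]


def classify_location(
    candidates: IntervalSet, annotation: Annotation
) -> tuple[dict[tuple[str, int, int], str], dict[str, float]]:
    """Locate each candidate by majority base overlap.

    Labels: intronic / exonic (majority of bases in that genic feature) or
    intergenic (majority outside genes). Returns per-candidate labels plus
    summary fractions (intragenic = intronic + exonic).
    """
    exon_spans = _merged_by_scaffold(annotation.all_exons())
    intron_spans = _merged_by_scaffold(annotation.all_introns())
    labels: dict[tuple[str, int, int], str] = {}
    tally: Counter = Counter()
    for iv in candidates:
        n = len(iv)
        ex = _overlap_bases(iv, exon_spans.get(iv.scaffold, ()))
        inr = _overlap_bases(iv, intron_spans.get(iv.scaffold, ()))
        inter = n - ex - inr
        best = max(
            [("exonic", ex), ("intronic", inr), ("intergenic", inter)],
            key=lambda kv: kv[1],
        )[0]
        labels[(iv.scaffold, iv.start, iv.end)] = best
        tally[best] += 1
    total = max(1, len(candidates))
    fractions = {
        "intronic": tally["intronic"] / total,
        "exonic": tally["exonic"] / total,
        "intergenic": tally["intergenic"] / total,
        "intragenic": (tally["intronic"] + tally["exonic"]) / total,
    }
    return labels, fractions


def intron_size_comparison(
    candidates: IntervalSet, introns: IntervalSet
) -> dict:
    """Compare sizes of enhancer-harbouring introns with all introns.

    Harbouring introns have >= 1 bp overlap with a candidate. Returns both
    size samples, their means/medians, and a two-sided Mann-Whitney p
    (None when either sample is empty).
    """
    if len(introns) == 0:
        raise ValueError("no introns supplied")
    harboring = intersect(introns, candidates, 0.0)
    all_sizes = np.array([len(iv) for iv in introns], dtype=float)
    harb_sizes = np.array([len(iv) for iv in harboring], dtype=float)
    result = {
        "harboring_sizes": harb_sizes,
        "all_sizes": all_sizes,
        "mean_harboring": float(harb_sizes.mean()) if harb_sizes.size else None,
        "mean_all": float(all_sizes.mean()),
        "median_harboring": float(np.median(harb_sizes)) if harb_sizes.size else None,
        "median_all": float(np.median(all_sizes)),
        "p_value": None,
    }
    if harb_sizes.size:
        from .stats import mann_whitney_u

        _, p = mann_whitney_u(harb_sizes, all_sizes, alternative="two-sided")
        result["p_value"] = p
    return result


def rnapii_cooccupancy(
    candidates: IntervalSet, rnapii_regions: IntervalSet
) -> tuple[float, dict[tuple[str, int, int], bool]]:
    """Fraction of candidates with >= 1 bp RNAPII peak overlap."""
    hit = intersect(candidates, rnapii_regions, 0.0)
    hit_keys = {(iv.scaffold, iv.start, iv.end) for iv in hit}
    flags = {
        (iv.scaffold, iv.start, iv.end): (iv.scaffold, iv.start, iv.end) in hit_keys
        for iv in candidates
    }
    frac = (sum(flags.values()) / len(candidates)) if len(candidates) else 0.0
    return frac, flags
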